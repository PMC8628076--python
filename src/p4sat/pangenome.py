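"""Satellite pangenome: protein families, spectra, rarefaction, associations.

Families are single-linkage connected components of the similarity graph
(edges at >= 40% identity and bidirectional coverage, mirroring an
mmseqs2 cluster_mode-1 run).  On top of the partition this module
computes family frequency spectra, seeded rarefaction curves, the local
pangenome of each inter-component interval, and variant/accessory-gene
enrichment with one-sided hypergeometric tests and Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import (
    CANONICAL_ORDER,
    Component,
    GeneFamily,
    SatelliteGenome,
    SatelliteSet,
    HomologyHit,
    ValidationError,
)

logger = logging.getLogger(__name__)


def cluster_proteins(
    hits: Iterable[HomologyHit],
    proteins: Iterable[str],
    min_id: float = 0.4,
    min_cov: float = 0.8,
) -> list[GeneFamily]:
    """Partition proteins into families by single-linkage clustering.

    An edge joins two proteins when any hit between them reaches
    ``min_id`` identity with both coverages >= ``min_cov``; families are
    the connected components, proteins without qualifying edges become
    singleton families.  Family ids are assigned in order of the
    lexicographically smallest member, which doubles as representative.
    """
    g = nx.Graph()
    g.add_nodes_from(proteins)
    n_edges = 0
    for h in hits:
        if h.is_self or h.query not in g or h.target not in g:
            continue
        if (
            h.identity >= min_id
            and h.query_coverage >= min_cov
            and h.target_coverage >= min_cov
        ):
            g.add_edge(h.query, h.target)
            n_edges += 1
    comps = sorted(nx.connected_components(g), key=min)
    families = [
        GeneFamily(
            family_id=f"FAM{i:05d}",
            members=frozenset(c),
            representative=min(c),
        )
        for i, c in enumerate(comps, start=1)
    ]
    logger.info(
        "cluster_proteins: %d proteins, %d qualifying edges, %d families",
        g.number_of_nodes(),
        n_edges,
        len(families),
    )
    return families


def family_index(families: Iterable[GeneFamily]) -> dict[str, str]:
    """protein_id -> family_id lookup for a family partition."""
    out: dict[str, str] = {}
    for f in families:
        for p in f.members:
            out[p] = f.family_id
    return out


@dataclasses.dataclass
class PangenomeSpectrum:
    """Per-family genome-presence counts and the derived frequency histogram."""

    counts: dict[str, int]  # family_id -> number of genomes containing it
    n_genomes: int

    def histogram(self) -> pd.DataFrame:
        freq: dict[int, int] = {}
        for c in self.counts.values():
            freq[c] = freq.get(c, 0) + 1
        return pd.DataFrame(
            [{"genomes": k, "n_families": v} for k, v in sorted(freq.items())],
            columns=["genomes", "n_families"],
        )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"family_id": f, "n_genomes": c} for f, c in sorted(self.counts.items())],
            columns=["family_id", "n_genomes"],
        )


def genome_family_sets(
    families: Iterable[GeneFamily], genomes: Sequence[SatelliteGenome]
) -> dict[str, set[str]]:
    """Set of families present in each delimited genome."""
    fam_of = family_index(families)
    return {
        g.set_id: {fam_of[p] for p in g.protein_ids if p in fam_of}
        for g in genomes
    }


def frequency_spectrum(
    families: Sequence[GeneFamily],
    genomes: Sequence[SatelliteGenome],
    exclude_core: bool = False,
    core_proteins: frozenset[str] = frozenset(),
) -> PangenomeSpectrum:
    """Count, for each family, the genomes containing at least one member.

    With ``exclude_core`` the families containing any core-component
    protein are removed before counting.
    """
    if exclude_core:
        families = [f for f in families if not (f.members & core_proteins)]
    fam_ids = {f.family_id for f in families}
    per_genome = genome_family_sets(families, genomes)
    counts = {fid: 0 for fid in fam_ids}
    for fams in per_genome.values():
        for fid in fams & fam_ids:
            counts[fid] += 1
    return PangenomeSpectrum(counts=counts, n_genomes=len(genomes))


@dataclasses.dataclass
class RarefactionCurve:
    """Cumulative new-family counts over random genome orderings."""

    curves: np.ndarray  # (n_permutations, n_genomes)
    seed: Optional[int]

    @property
    def mean(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    def envelope(self, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.quantile(self.curves, q, axis=0),
            np.quantile(self.curves, 1 - q, axis=0),
        )

    def table(self) -> pd.DataFrame:
        lo, hi = self.envelope()
        return pd.DataFrame(
            {
                "genomes_added": np.arange(1, self.curves.shape[1] + 1),
                "mean_families": self.mean,
                "q05": lo,
                "q95": hi,
            }
        )


def rarefaction(
    genome_families: Mapping[str, set[str]],
    n_permutations: int = 100,
    seed: Optional[int] = None,
) -> RarefactionCurve:
    """Rarefaction of gene families over randomly ordered genomes.

    Each permutation accumulates the number of distinct families seen
    after adding each genome; every curve ends at the total family count.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if not genome_families:
        raise ValidationError("rarefaction requires at least one genome")
    ids = sorted(genome_families)
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, len(ids)), dtype=int)
    for p in range(n_permutations):
        seen: set[str] = set()
        for j, k in enumerate(rng.permutation(len(ids))):
            seen |= genome_families[ids[k]]
            curves[p, j] = len(seen)
    return RarefactionCurve(curves=curves, seed=seed)


def local_pangenome(
    genomes: Sequence[SatelliteGenome],
    sets: Mapping[str, SatelliteSet],
    family_of: Mapping[str, str],
) -> pd.DataFrame:
    """Accessory families strictly between consecutive core components.

    Meant for the Type A canonical-organization subset: for every pair of
    components that are consecutive in a genome's organization, the
    families of the genes strictly between them are pooled across the
    corpus.  Returns one row per interval with the distinct-family count.
    """
    interval_families: dict[tuple[str, str], set[str]] = {}
    component_proteins = {
        h.gene.protein_id for s in sets.values() for h in s.members.values()
    }
    for g in genomes:
        s = sets[g.set_id]
        ordered = s.members_in_order()
        gene_by_index = {gene.gene_index: gene for gene in g.gene_list}
        for a, b in zip(ordered, ordered[1:]):
            key = (a.component.value, b.component.value)
            fams = interval_families.setdefault(key, set())
            for idx in range(a.gene_index + 1, b.gene_index):
                gene = gene_by_index.get(idx)
                if gene is None or gene.protein_id in component_proteins:
                    continue
                fam = family_of.get(gene.protein_id)
                if fam is not None:
                    fams.add(fam)
    rows = [
        {
            "component_a": a,
            "component_b": b,
            "n_families": len(fams),
            "families": ",".join(sorted(fams)),
        }
        for (a, b), fams in sorted(interval_families.items())
    ]
    return pd.DataFrame(
        rows, columns=["component_a", "component_b", "n_families", "families"]
    )


def hypergeom_enrichment_p(k: int, big_k: int, n: int, big_n: int) -> float:
    """One-sided over-representation p-value, P(X >= k).

    X ~ Hypergeometric(N=big_n population, K=big_k successes, n draws).
    """
    if big_k == 0 or big_k == big_n or n == 0 or n == big_n:
        return 1.0
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def variant_accessory_association(
    genomes: Sequence[SatelliteGenome],
    sets: Mapping[str, SatelliteSet],
    family_of: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (variant, accessory family) enrichment table.

    Counts genomes of the variant carrying the family against the rest
    of the corpus, computes the one-sided hypergeometric p-value per pair
    and Benjamini-Hochberg q-values across all tested pairs.  Degenerate
    margins (family in all or no genomes, single-variant corpus) yield
    p = 1 and a flag.
    """
    component_proteins = {
        h.gene.protein_id for s in sets.values() for h in s.members.values()
    }
    genome_fams: dict[str, set[str]] = {}
    variant_of: dict[str, str] = {}
    for g in genomes:
        variant_of[g.set_id] = sets[g.set_id].variant_code or "unclassified"
        genome_fams[g.set_id] = {
            family_of[gene.protein_id]
            for gene in g.gene_list
            if gene.protein_id in family_of
            and gene.protein_id not in component_proteins
        }
    variants = sorted(set(variant_of.values()))
    if len(variants) < 2:
        return pd.DataFrame(
            columns=["variant", "family_id", "k", "n_variant", "K", "N", "p", "q", "degenerate", "enriched"]
        )
    all_fams = sorted(set().union(*genome_fams.values()) if genome_fams else set())
    big_n = len(genomes)
    rows = []
    for variant in variants:
        members = [sid for sid, v in variant_of.items() if v == variant]
        n = len(members)
        for fam in all_fams:
            big_k = sum(1 for fams in genome_fams.values() if fam in fams)
            k = sum(1 for sid in members if fam in genome_fams[sid])
            degenerate = big_k in (0, big_n) or n in (0, big_n)
            p = hypergeom_enrichment_p(k, big_k, n, big_n)
            rows.append(
                {
                    "variant": variant,
                    "family_id": fam,
                    "k": k,
                    "n_variant": n,
                    "K": big_k,
                    "N": big_n,
                    "p": p,
                    "degenerate": degenerate,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["enriched"] = []
        return df
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["enriched"] = (df["q"] <= alpha) & ~df["degenerate"]
    return df[
        ["variant", "family_id", "k", "n_variant", "K", "N", "p", "q", "degenerate", "enriched"]
    ]


def families_table(families: Iterable[GeneFamily]) -> pd.DataFrame:
    rows = [
        {
            "family_id": f.family_id,
            "size": len(f.members),
            "representative": f.representative,
            "members": ",".join(sorted(f.members)),
        }
        for f in families
    ]
    return pd.DataFrame(rows, columns=["family_id", "size", "representative", "members"])
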