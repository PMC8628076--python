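"""Delimitation, genetic organization and chromosomal positioning.

Each satellite genome is delimited by its integrase and the component
furthest from it in gene order (psu replaces the integrase when the
variant lacks one).  Organization signatures read the component order
from the integrase end, which supports the canonical / psu-delta-swap /
reversed labelling; adjacency statistics and inter-component gap
distributions summarize a corpus of signatures.  Elements are placed on
the host chromosome relative to an ordered core-gene backbone with the
N+1 rule: an element whose nearest upstream core family has rank N sits
at position N+1.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    CANONICAL_ORDER,
    ChromosomePosition,
    Component,
    DelimitationError,
    GeneRecord,
    OrganizationSignature,
    Replicon,
    SatelliteGenome,
    SatelliteSet,
    restrict_canonical,
)

logger = logging.getLogger(__name__)


def _anchor_of(s: SatelliteSet) -> Component:
    if Component.INTEGRASE in s.members:
        return Component.INTEGRASE
    if Component.PSU in s.members:  # integrase-less variants (TypeB#07 etc.)
        return Component.PSU
    raise DelimitationError(f"{s.set_id}: neither integrase nor psu present")


def delimit_genome(s: SatelliteSet, replicon: Replicon) -> SatelliteGenome:
    """Delimit the element from the anchor to the furthest component.

    Distance is measured in gene indices (ties broken by bp distance);
    the span includes both delimiting genes' full coordinates.
    """
    anchor_comp = _anchor_of(s)
    anchor = s.members[anchor_comp].gene
    others = [h.gene for c, h in s.members.items() if c is not anchor_comp]
    if not others:
        raise DelimitationError(f"{s.set_id}: single-component set")
    furthest = max(
        others,
        key=lambda g: (
            abs(g.gene_index - anchor.gene_index),
            abs(g.start - anchor.start),
            g.protein_id,
        ),
    )
    furthest_comp = next(
        c for c, h in s.members.items() if h.gene.protein_id == furthest.protein_id
    )
    lo_idx = min(anchor.gene_index, furthest.gene_index)
    hi_idx = max(anchor.gene_index, furthest.gene_index)
    start = min(anchor.start, furthest.start)
    end = max(anchor.end, furthest.end)
    gene_list = [g for g in replicon.genes if lo_idx <= g.gene_index <= hi_idx]
    return SatelliteGenome(
        set_id=s.set_id,
        replicon_id=s.replicon_id,
        span_bp=(start, end),
        gene_list=gene_list,
        anchor=anchor_comp,
        furthest=furthest_comp,
        variant_code=s.variant_code,
    )


def organization_signature(
    s: SatelliteSet, replicon: Optional[Replicon] = None
) -> OrganizationSignature:
    """Component order in gene order, read starting from the integrase end."""
    ordered = s.members_in_order()
    anchor = _anchor_of(s)
    comps = [h.component for h in ordered]
    if comps and comps[-1] is anchor:
        ordered = ordered[::-1]
        comps = comps[::-1]
    gaps = tuple(
        abs(b.gene_index - a.gene_index) - 1 for a, b in zip(ordered, ordered[1:])
    )
    canon = restrict_canonical(comps)
    canonical = tuple(comps) == canon
    label = "canonical" if canonical else _organization_label(tuple(comps), canon)
    return OrganizationSignature(
        set_id=s.set_id,
        order=tuple(comps),
        gaps=gaps,
        canonical=canonical,
        label=label,
    )


def _organization_label(
    order: tuple[Component, ...], canon: tuple[Component, ...]
) -> str:
    if Component.PSU in order and Component.DELTA in order:
        swapped = list(canon)
        i, j = swapped.index(Component.PSU), swapped.index(Component.DELTA)
        swapped[i], swapped[j] = swapped[j], swapped[i]
        if order == tuple(swapped):
            return "psu_delta_swap"
    if len(order) >= 2 and order[0] is canon[0]:
        if order[1:] == tuple(reversed(canon[1:])):
            return "reversed"
    return "other"


def adjacency_graph(
    sigs: Iterable[OrganizationSignature],
) -> tuple[pd.DataFrame, dict[tuple[Component, Component], list[int]]]:
    """Adjacency frequencies and ORF-gap distributions over a signature corpus.

    Returns a table with one row per ordered component pair that is
    directly consecutive in at least one signature, and the per-pair list
    of intervening-ORF counts.
    """
    counts: dict[tuple[Component, Component], int] = {}
    gap_dists: dict[tuple[Component, Component], list[int]] = {}
    n_sets = 0
    for sig in sigs:
        n_sets += 1
        for (a, b), gap in zip(zip(sig.order, sig.order[1:]), sig.gaps):
            counts[(a, b)] = counts.get((a, b), 0) + 1
            gap_dists.setdefault((a, b), []).append(gap)
    rows = [
        {
            "component_a": a.value,
            "component_b": b.value,
            "adjacency_count": n,
            "frequency": n / n_sets if n_sets else 0.0,
            "mean_gap_orfs": sum(gap_dists[(a, b)]) / n,
        }
        for (a, b), n in sorted(
            counts.items(), key=lambda kv: (kv[0][0].canonical_rank, kv[0][1].canonical_rank)
        )
    ]
    cols = ["component_a", "component_b", "adjacency_count", "frequency", "mean_gap_orfs"]
    return pd.DataFrame(rows, columns=cols), gap_dists


@dataclasses.dataclass
class FlankReport:
    """Prevalence of gene families in the element flanks."""

    table: pd.DataFrame  # side, family_id, prevalence, flagged
    short_flank_sets: list[str]


def flank_conservation_scan(
    genomes: Sequence[SatelliteGenome],
    replicons: Mapping[str, Replicon],
    family_of: Mapping[str, str],
    window: int = 5,
    threshold: float = 0.25,
) -> FlankReport:
    """Scan the ``window`` genes strictly outside each element for conserved families.

    The upstream flank precedes the first gene of the delimited span and
    the downstream flank follows its last gene (in gene order).  A family
    is flagged when present in more than ``threshold`` of the elements on
    a given side.  Elements near a replicon edge contribute a shorter
    flank and are listed in ``short_flank_sets``.
    """
    presence: dict[tuple[str, str], set[str]] = {}
    short: list[str] = []
    n = len(genomes)
    for g in genomes:
        rep = replicons[g.replicon_id]
        lo = g.gene_list[0].gene_index
        hi = g.gene_list[-1].gene_index
        up = [gene for gene in rep.genes if lo - window <= gene.gene_index < lo]
        down = [gene for gene in rep.genes if hi < gene.gene_index <= hi + window]
        if len(up) < window or len(down) < window:
            short.append(g.set_id)
        for side, flank in (("upstream", up), ("downstream", down)):
            for gene in flank:
                fam = family_of.get(gene.protein_id)
                if fam is not None:
                    presence.setdefault((side, fam), set()).add(g.set_id)
    rows = [
        {
            "side": side,
            "family_id": fam,
            "prevalence": len(sets) / n if n else 0.0,
            "flagged": (len(sets) / n if n else 0.0) > threshold,
        }
        for (side, fam), sets in sorted(presence.items())
    ]
    table = pd.DataFrame(rows, columns=["side", "family_id", "prevalence", "flagged"])
    if window == 0:
        table = table.iloc[0:0]
    return FlankReport(table=table, short_flank_sets=short)


def genome_size_table(genomes: Iterable[SatelliteGenome]) -> pd.DataFrame:
    """Span/size summary, flagging non-standard delimitation pairs.

    Elements delimited by a pair other than integrase<->alpha (e.g. the
    small psu..epsilon variants) are flagged so that size statistics can
    be recomputed without them.
    """
    rows = []
    for g in genomes:
        standard = g.anchor is Component.INTEGRASE and g.furthest is Component.ALPHA
        rows.append(
            {
                "set_id": g.set_id,
                "replicon_id": g.replicon_id,
                "start_bp": g.span_bp[0],
                "end_bp": g.span_bp[1],
                "size_bp": g.size_bp,
                "n_proteins": g.n_proteins,
                "anchor": g.anchor.value,
                "furthest": g.furthest.value,
                "standard_delimiters": standard,
            }
        )
    cols = [
        "set_id",
        "replicon_id",
        "start_bp",
        "end_bp",
        "size_bp",
        "n_proteins",
        "anchor",
        "furthest",
        "standard_delimiters",
    ]
    return pd.DataFrame(rows, columns=cols)


def map_position(
    genome: SatelliteGenome,
    focal_core_genes: Sequence[tuple[int, str]],
    reference_order: Mapping[str, int],
    replicon: Optional[Replicon] = None,
    wrap: str = "n_plus_1",
) -> ChromosomePosition:
    """Position the element relative to the ordered core genome (N+1 rule).

    ``focal_core_genes`` lists (gene_index, core_family) occurrences on
    the element's replicon; ``reference_order`` maps each core family to
    its rank 1..n in the reference strain.  The immediately upstream core
    family of rank N yields position N+1.  On a circular replicon an
    element upstream of the rank-1 gene wraps to the last core gene;
    whether that reports n+1 or 1 is selected by ``wrap``
    ("n_plus_1" or "one").
    """
    if wrap not in ("n_plus_1", "one"):
        raise ValueError(f"bad wrap convention {wrap!r}")
    n_core = max(reference_order.values())
    start_idx = genome.gene_list[0].gene_index
    upstream = [(idx, fam) for idx, fam in focal_core_genes if idx < start_idx]
    flagged = False
    if upstream:
        _, fam = max(upstream)
    elif replicon is not None and replicon.topology == "circular" and focal_core_genes:
        _, fam = max(focal_core_genes)  # wrap: last core gene precedes the origin
    else:
        return ChromosomePosition(
            set_id=genome.set_id, upstream_core_family=None, position=1, flagged=True
        )
    position = reference_order[fam] + 1
    if position > n_core and wrap == "one":
        position = 1
    return ChromosomePosition(
        set_id=genome.set_id,
        upstream_core_family=fam,
        position=position,
        flagged=flagged,
    )


def organization_table(sigs: Iterable[OrganizationSignature]) -> pd.DataFrame:
    rows = [
        {
            "set_id": sig.set_id,
            "order": ",".join(c.value for c in sig.order),
            "gaps": ",".join(str(g) for g in sig.gaps),
            "canonical": sig.canonical,
            "label": sig.label,
        }
        for sig in sigs
    ]
    return pd.DataFrame(rows, columns=["set_id", "order", "gaps", "canonical", "label"])


def positions_table(positions: Iterable[ChromosomePosition]) -> pd.DataFrame:
    rows = [
        {
            "set_id": p.set_id,
            "upstream_core_family": p.upstream_core_family,
            "position": p.position,
            "flagged": p.flagged,
        }
        for p in positions
    ]
    return pd.DataFrame(
        rows, columns=["set_id", "upstream_core_family", "position", "flagged"]
    )
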