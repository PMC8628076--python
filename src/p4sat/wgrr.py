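"""Weighted Gene Repertoire Relatedness (wGRR) between satellite genomes.

wGRR(A, B) = sum_i id(A_i, B_i) / min(|A|, |B|), the sum over
bidirectional best hits (BBH) of their alignment identities divided by
the size of the smaller proteome.  It is 0 when the genomes share no BBH
and 1 when every protein of the smaller genome has an identical
homologue in the larger one; e.g. with a 10-protein smaller genome, two
identical BBH pairs or five at 40% identity both give wGRR = 0.2.

Similarity hits are first filtered (e-value < 1e-4, identity >= 35%,
both coverages >= 50%); best hits use a fixed deterministic tie-break
(bitscore desc, e-value asc, identity desc, lexicographic id).  The
all-pairs matrix feeds UPGMA (average-linkage) clustering on 1 - wGRR
with flat labels cut at a fixed cluster count (maxclust).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .model import BBHPair, HomologyHit, ValidationError

logger = logging.getLogger(__name__)


def filter_homology(
    hits: Iterable[HomologyHit],
    evalue_max: float = 1e-4,
    identity_min: float = 0.35,
    coverage_min: float = 0.5,
    coverage_side: str = "both",
) -> list[HomologyHit]:
    """Retain hits with e-value strictly below the cap and inclusive identity/coverage bounds."""
    if coverage_side not in ("both", "either"):
        raise ValidationError(f"bad coverage_side {coverage_side!r}")
    kept = []
    for h in hits:
        if h.evalue >= evalue_max or h.identity < identity_min:
            continue
        covs = (h.query_coverage, h.target_coverage)
        ok = min(covs) >= coverage_min if coverage_side == "both" else max(covs) >= coverage_min
        if ok:
            kept.append(h)
    return kept


def _best_hits(
    hits: Sequence[HomologyHit], sources: set[str], targets: set[str]
) -> dict[str, str]:
    """Best hit in ``targets`` for each protein of ``sources``."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.query not in sources or h.target not in targets or h.is_self:
            continue
        cur = best.get(h.query)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query] = h
    return {q: h.target for q, h in best.items()}


def _hit_key(h: HomologyHit) -> tuple:
    return (-h.bitscore, h.evalue, -h.identity, h.target)


def bbh(
    hits: Sequence[HomologyHit], proteins_a: Iterable[str], proteins_b: Iterable[str]
) -> list[BBHPair]:
    """Bidirectional best hits between two proteomes.

    A pair (a, b) is a BBH when b is a's best hit among B and a is b's
    best hit among A under the deterministic tie-break order.  The
    reported identity is the maximum over the two directions' hits.
    """
    set_a, set_b = set(proteins_a), set(proteins_b)
    fwd = _best_hits(hits, set_a, set_b)
    rev = _best_hits(hits, set_b, set_a)
    identity: dict[tuple[str, str], float] = {}
    for h in hits:
        for a, b in ((h.query, h.target), (h.target, h.query)):
            if a in set_a and b in set_b:
                key = (a, b)
                identity[key] = max(identity.get(key, 0.0), h.identity)
    pairs = [
        BBHPair(protein_a=a, protein_b=b, identity=identity[(a, b)])
        for a, b in sorted(fwd.items())
        if rev.get(b) == a
    ]
    return pairs


def wgrr_score(pairs: Sequence[BBHPair], size_a: int, size_b: int) -> float:
    """Sum of BBH identities over the smaller proteome size."""
    if min(size_a, size_b) < 1:
        raise ValidationError("wGRR undefined for an empty proteome")
    if len(pairs) > min(size_a, size_b):
        raise ValidationError("more BBH pairs than proteins in the smaller genome")
    return sum(p.identity for p in pairs) / min(size_a, size_b)


@dataclasses.dataclass
class WGRRMatrix:
    """Symmetric all-pairs wGRR with per-pair BBH counts."""

    ids: tuple[str, ...]
    values: np.ndarray
    bbh_counts: np.ndarray
    min_sizes: np.ndarray

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "genome_a": a,
                        "genome_b": self.ids[j],
                        "bbh_count": int(self.bbh_counts[i, j]),
                        "min_proteome": int(self.min_sizes[i, j]),
                        "wgrr": self.values[i, j],
                    }
                )
        return pd.DataFrame(
            rows, columns=["genome_a", "genome_b", "bbh_count", "min_proteome", "wgrr"]
        )


def wgrr_matrix(
    proteomes: Mapping[str, Sequence[str]], hits: Sequence[HomologyHit]
) -> WGRRMatrix:
    """All-pairs wGRR over a collection of proteomes.

    ``hits`` should already be filtered (:func:`filter_homology`); each
    genome must encode at least one protein.  The diagonal is 1.
    """
    ids = tuple(sorted(proteomes))
    for gid in ids:
        if len(proteomes[gid]) < 1:
            raise ValidationError(f"genome {gid!r} has no proteins")
    genome_of = {p: gid for gid in ids for p in proteomes[gid]}
    # bucket hits per unordered genome pair to avoid quadratic rescans
    buckets: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        ga, gb = genome_of.get(h.query), genome_of.get(h.target)
        if ga is None or gb is None or ga == gb:
            continue
        key = (ga, gb) if ga < gb else (gb, ga)
        buckets.setdefault(key, []).append(h)
    n = len(ids)
    values = np.eye(n)
    counts = np.zeros((n, n), dtype=int)
    min_sizes = np.zeros((n, n), dtype=int)
    index = {gid: i for i, gid in enumerate(ids)}
    for i, a in enumerate(ids):
        min_sizes[i, i] = len(proteomes[a])
        counts[i, i] = len(proteomes[a])
        for j in range(i + 1, n):
            b = ids[j]
            pair_hits = buckets.get((a, b), [])
            pairs = bbh(pair_hits, proteomes[a], proteomes[b])
            score = wgrr_score(pairs, len(proteomes[a]), len(proteomes[b]))
            values[i, j] = values[j, i] = score
            counts[i, j] = counts[j, i] = len(pairs)
            min_sizes[i, j] = min_sizes[j, i] = min(
                len(proteomes[a]), len(proteomes[b])
            )
    return WGRRMatrix(ids=ids, values=values, bbh_counts=counts, min_sizes=min_sizes)


def upgma_flat_clusters(
    matrix: WGRRMatrix, k: int = 7
) -> tuple[dict[str, int], list[str]]:
    """UPGMA clustering of the wGRR matrix cut into exactly ``k`` flat clusters.

    The dendrogram is built by average linkage on the distance 1 - wGRR;
    labels come from the maxclust criterion and the returned leaf order
    is the dendrogram order used for heatmap export.
    """
    n = len(matrix.ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside 1..{n}")
    if n == 1:
        return {matrix.ids[0]: 1}, list(matrix.ids)
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    order = [matrix.ids[i] for i in leaves_list(z)]
    return {gid: int(lab) for gid, lab in zip(matrix.ids, labels)}, order


def clusters_table(labels: Mapping[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"genome_id": g, "cluster": c} for g, c in sorted(labels.items())],
        columns=["genome_id", "cluster"],
    )
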