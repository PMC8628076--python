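"""Tree-based analyses: patristic distances, cross-component correlation,
monophyly checks and pseudogene scanning.

Patristic distances (sums of branch lengths between leaves) are computed
per component tree; Spearman correlations between the element-paired
distance vectors of two components quantify how coupled their
evolutionary histories are.  Monophyly of a leaf subset is tested in the
unrooted sense: some edge bipartition must separate exactly that subset.
The pseudogene scanner translates a locus in all six frames, chains
local protein matches to the expected component and distinguishes intact
genes from frameshifted or stop-disrupted pseudogenes.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy.stats import spearmanr

from .model import Component, ParseError, PseudogeneCall, ValidationError

logger = logging.getLogger(__name__)


def parse_newick(
    source: str, default_zero: bool = False
) -> dendropy.Tree:
    """Parse a Newick string into a tree, requiring branch lengths.

    Missing edge lengths raise unless ``default_zero`` is set, in which
    case they become 0.  Leaf labels must be unique.
    """
    try:
        tree = dendropy.Tree.get(
            data=source, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            if default_zero:
                edge.length = 0.0
            else:
                raise ValidationError("tree has edges without branch lengths")
        elif edge.length < 0:
            raise ValidationError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclasses.dataclass
class PatristicMatrix:
    """All-pairs leaf path-length sums, leaves sorted by label."""

    ids: tuple[str, ...]
    values: np.ndarray

    def distance(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def patristic_matrix(tree: dendropy.Tree) -> PatristicMatrix:
    """Patristic distances between all leaf pairs of the tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    leaf_taxa = {lf.taxon for lf in tree.leaf_node_iter()}
    taxa = [t for t in taxa if t in leaf_taxa]
    n = len(taxa)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[i], taxa[j])
        values[i, j] = values[j, i] = d
    return PatristicMatrix(ids=tuple(t.label for t in taxa), values=values)


def cross_component_correlation(
    matrices: Mapping[str, PatristicMatrix],
    pairing: Mapping[str, Mapping[str, str]],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of patristic distances between component pairs.

    ``pairing`` maps component -> {element_id -> leaf label}.  For every
    component pair the elements present in both matrices define a common
    set of element pairs; the two distance vectors over those pairs give
    the rank correlation.  Pairs with fewer than ``min_shared`` shared
    elements are reported with a missing rho.
    """
    comps = sorted(matrices)
    rows = []
    for ca, cb in itertools.combinations(comps, 2):
        ma, mb = matrices[ca], matrices[cb]
        pa, pb = pairing[ca], pairing[cb]
        shared = sorted(
            e
            for e in set(pa) & set(pb)
            if pa[e] in ma.ids and pb[e] in mb.ids
        )
        dropped = len(set(pa) | set(pb)) - len(shared)
        if len(shared) < min_shared:
            rows.append(
                {
                    "component_a": ca,
                    "component_b": cb,
                    "rho": np.nan,
                    "n_elements": len(shared),
                    "n_pairs": 0,
                    "elements_dropped": dropped,
                }
            )
            continue
        va, vb = [], []
        for e1, e2 in itertools.combinations(shared, 2):
            va.append(ma.distance(pa[e1], pa[e2]))
            vb.append(mb.distance(pb[e1], pb[e2]))
        rho = spearmanr(va, vb).statistic
        rows.append(
            {
                "component_a": ca,
                "component_b": cb,
                "rho": float(rho),
                "n_elements": len(shared),
                "n_pairs": len(va),
                "elements_dropped": dropped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "component_a",
            "component_b",
            "rho",
            "n_elements",
            "n_pairs",
            "elements_dropped",
        ],
    )


def monophyly_check(
    tree: dendropy.Tree, partition: Mapping[str, Iterable[str]]
) -> dict[str, bool]:
    """Unrooted monophyly verdict for each named leaf subset.

    A subset is monophyletic when some edge bipartition separates
    exactly that subset from the rest (clade sets and their complements
    are both accepted, so the verdict does not depend on rooting).
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    clades: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        clades.add(leaves)
        clades.add(all_leaves - leaves)
    verdicts = {}
    for name, subset in partition.items():
        fs = frozenset(subset)
        if not fs <= all_leaves:
            raise ValidationError(f"subset {name!r} has labels outside the tree")
        verdicts[name] = len(fs) <= 1 or fs in clades
    return verdicts


# --- pseudogene scanning -------------------------------------------------

_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-2.0,
    extend_gap_score=-1.0,
)


@dataclasses.dataclass(frozen=True)
class _Segment:
    """A stop-free translated segment matched to the reference protein."""

    frame: int  # 0-2 forward, 3-5 reverse
    aa_start: int  # position of the segment within the frame translation
    had_upstream_stop: bool
    ref_start: int  # matched reference interval, 0-based half-open
    ref_end: int
    identity: float
    hits_segment_end: bool

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


def _match_segment(reference: str, segment: str) -> Optional[tuple[int, int, float, bool]]:
    """Best local alignment of a translated segment against the reference.

    Returns (ref_start, ref_end, identity over aligned reference columns,
    reaches-segment-end) or None when nothing aligns.
    """
    alignments = _aligner.align(reference, segment)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    blocks_ref, blocks_seg = aln.aligned
    matches = 0
    aligned_ref = 0
    for (rs, re_), (ss, se) in zip(blocks_ref, blocks_seg):
        aligned_ref += re_ - rs
        matches += sum(
            1 for a, b in zip(reference[rs:re_], segment[ss:se]) if a == b
        )
    if aligned_ref == 0:
        return None
    ref_start = int(blocks_ref[0][0])
    ref_end = int(blocks_ref[-1][1])
    seg_end = int(blocks_seg[-1][1])
    return ref_start, ref_end, matches / aligned_ref, seg_end >= len(segment) - 1


def _frame_translations(locus_nt: str) -> list[tuple[int, str]]:
    seqs = [locus_nt.upper(), str(Seq(locus_nt).reverse_complement()).upper()]
    frames = []
    for strand, seq in enumerate(seqs):
        for off in range(3):
            usable = (len(seq) - off) // 3 * 3
            if usable < 3:
                continue
            aa = str(Seq(seq[off : off + usable]).translate())
            frames.append((strand * 3 + off, aa))
    return frames


def pseudogene_scan(
    locus_nt: str,
    reference_aa: str,
    min_segment_identity: float = 0.3,
    pseudogene_coverage: float = 0.4,
    intact_coverage: float = 0.8,
    min_segment_aa: int = 8,
    expected_component: Optional[Component] = None,
    set_id: Optional[str] = None,
) -> PseudogeneCall:
    """Classify the locus at a missing component's expected position.

    The locus is translated in all six frames; stop-free segments are
    locally aligned to the reference protein and segments reaching
    ``min_segment_identity`` are chained.  A single segment covering at
    least ``intact_coverage`` of the reference from its N-terminus gives
    an intact verdict.  Matched segments jointly covering at least
    ``pseudogene_coverage`` that require a frame change, or are broken
    by an internal stop, give a pseudogene verdict with the defect types
    as evidence; anything else is absent.
    """
    reference_aa = reference_aa.rstrip("*")
    if not locus_nt or not reference_aa:
        return PseudogeneCall(
            expected_component=expected_component,
            verdict="absent",
            evidence=(),
            aligned_fraction=0.0,
            set_id=set_id,
        )
    ref_len = len(reference_aa)
    segments: list[_Segment] = []
    for frame, aa in _frame_translations(locus_nt):
        pos = 0
        first = True
        for part in aa.split("*"):
            if len(part) >= min_segment_aa:
                m = _match_segment(reference_aa, part)
                if m is not None:
                    rs, re_, ident, hits_end = m
                    if ident >= min_segment_identity and re_ - rs >= min_segment_aa:
                        segments.append(
                            _Segment(
                                frame=frame,
                                aa_start=pos,
                                had_upstream_stop=not first,
                                ref_start=rs,
                                ref_end=re_,
                                identity=ident,
                                hits_segment_end=hits_end,
                            )
                        )
            pos += len(part) + 1
            first = False
    if not segments:
        return PseudogeneCall(
            expected_component=expected_component,
            verdict="absent",
            evidence=(),
            aligned_fraction=0.0,
            set_id=set_id,
        )
    covered = np.zeros(ref_len, dtype=bool)
    for s in segments:
        covered[s.ref_start : s.ref_end] = True
    union_cov = covered.mean()
    best = max(segments, key=lambda s: s.ref_span)
    nterm_slack = max(2, round(0.05 * ref_len))
    if best.ref_span / ref_len >= intact_coverage and best.ref_start <= nterm_slack:
        return PseudogeneCall(
            expected_component=expected_component,
            verdict="intact",
            evidence=(),
            aligned_fraction=float(union_cov),
            set_id=set_id,
        )
    evidence: list[str] = []
    frames_used = {s.frame for s in segments}
    if len(frames_used) > 1 and _disjoint_ref_intervals(segments):
        evidence.append("frameshift")
    for frame in frames_used:
        in_frame = sorted(
            (s for s in segments if s.frame == frame), key=lambda s: s.aa_start
        )
        if len(in_frame) >= 2 and _disjoint_ref_intervals(in_frame):
            evidence.append("internal_stop")
            break
        if (
            len(in_frame) == 1
            and in_frame[0].had_upstream_stop
            and in_frame[0].ref_start > nterm_slack
        ):
            evidence.append("internal_stop")
            break
    if best.hits_segment_end and best.ref_end < ref_len - 1 and "frameshift" not in evidence:
        # match runs off the end of its reading segment before the reference does
        if evidence:
            evidence.append("truncation")
    if union_cov >= pseudogene_coverage and evidence:
        return PseudogeneCall(
            expected_component=expected_component,
            verdict="pseudogene",
            evidence=tuple(dict.fromkeys(evidence)),
            aligned_fraction=float(union_cov),
            set_id=set_id,
        )
    return PseudogeneCall(
        expected_component=expected_component,
        verdict="absent",
        evidence=(),
        aligned_fraction=float(union_cov),
        set_id=set_id,
    )


def _disjoint_ref_intervals(segments: Sequence[_Segment]) -> bool:
    """True when at least two segments match mostly distinct reference regions."""
    for a, b in itertools.combinations(segments, 2):
        lo = max(a.ref_start, b.ref_start)
        hi = min(a.ref_end, b.ref_end)
        overlap = max(0, hi - lo)
        if overlap < 0.5 * min(a.ref_span, b.ref_span):
            return True
    return False


def pseudogene_table(calls: Iterable[PseudogeneCall]) -> pd.DataFrame:
    rows = [
        {
            "set_id": c.set_id,
            "expected_component": c.expected_component.value
            if c.expected_component
            else None,
            "verdict": c.verdict,
            "evidence": ",".join(c.evidence),
            "aligned_fraction": c.aligned_fraction,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["set_id", "expected_component", "verdict", "evidence", "aligned_fraction"],
    )
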