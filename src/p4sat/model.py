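"""Domain types shared across the P4-like satellite pipeline.

The seven core components of the P4 satellite genome (integrase, psu,
delta, sid, alpA, epsilon, alpha) are the coordinate system for every
downstream stage: detection chains component hits along a replicon,
classification names elements after the components they lack, and
delimitation anchors on the integrase.  All genomic coordinates are
1-based inclusive (GFF3 convention); identities are fractions in [0, 1].
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
from typing import Iterable, Mapping, Optional, Sequence


class SatelliteError(Exception):
    """Base class for pipeline errors."""


class ParseError(SatelliteError):
    """A malformed input line; carries the offending line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(SatelliteError):
    """Input violates a documented invariant."""


class DelimitationError(SatelliteError):
    """A satellite set cannot be delimited (no anchor component)."""


class ClassificationError(SatelliteError):
    """A set with more missing components than the catalogue covers."""


class Component(enum.Enum):
    """One of the seven hallmark P4 genes."""

    INTEGRASE = "integrase"
    PSU = "psu"
    DELTA = "delta"
    SID = "sid"
    ALPA = "alpA"
    EPSILON = "epsilon"
    ALPHA = "alpha"

    @property
    def canonical_rank(self) -> int:
        """1-based position in the canonical P4 gene order."""
        return CANONICAL_ORDER.index(self) + 1

    def __repr__(self) -> str:  # compact in test diffs
        return f"<{self.value}>"


#: Canonical P4 gene order, integrase first.
CANONICAL_ORDER: tuple[Component, ...] = (
    Component.INTEGRASE,
    Component.PSU,
    Component.DELTA,
    Component.SID,
    Component.ALPA,
    Component.EPSILON,
    Component.ALPHA,
)

#: Tyrosine-recombinase PFAM profile: sufficient on its own for an integrase call.
TYROSINE_INTEGRASE_PROFILE = "PF00589.20"
#: Serine-recombinase profiles: a protein must hit BOTH to count as an integrase.
SERINE_INTEGRASE_PROFILES: tuple[str, str] = ("PF00239.19", "PF07508.11")

#: HMM profile -> component mapping used at hit ingestion.
PROFILE_COMPONENTS: dict[str, Component] = {
    "PF07455.12": Component.PSU,
    "PF04606.13": Component.DELTA,
    "SID.custom": Component.SID,
    "PF05930.10": Component.ALPA,
    "PF10554.10": Component.EPSILON,
    "PF03288.17": Component.ALPHA,
    TYROSINE_INTEGRASE_PROFILE: Component.INTEGRASE,
    SERINE_INTEGRASE_PROFILES[0]: Component.INTEGRASE,
    SERINE_INTEGRASE_PROFILES[1]: Component.INTEGRASE,
}

#: Nominal profile lengths (HMM match states) used when emitting synthetic
#: domtblout rows; values are realistic profile sizes, not fitted constants.
PROFILE_LENGTHS: dict[str, int] = {
    "PF07455.12": 190,
    "PF04606.13": 70,
    "SID.custom": 240,
    "PF05930.10": 60,
    "PF10554.10": 50,
    "PF03288.17": 420,
    "PF00589.20": 170,
    "PF00239.19": 140,
    "PF07508.11": 100,
}

#: The profile emitted per component by the synthetic generator.
COMPONENT_DEFAULT_PROFILE: dict[Component, str] = {
    comp: prof
    for prof, comp in PROFILE_COMPONENTS.items()
    if prof not in SERINE_INTEGRASE_PROFILES
}


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A single ORF on a replicon (1-based inclusive coordinates)."""

    replicon_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    protein_id: str
    length_aa: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.protein_id}: bad strand {self.strand!r}")


@dataclasses.dataclass
class Replicon:
    """An ordered list of genes on one chromosome or plasmid."""

    replicon_id: str
    genes: list[GeneRecord]
    length_bp: int
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"bad topology {self.topology!r}")
        for i, g in enumerate(self.genes, start=1):
            if g.gene_index != i:
                raise ValidationError(
                    f"{self.replicon_id}: gene_index not contiguous at rank {i}"
                )
            if g.end > self.length_bp:
                raise ValidationError(
                    f"{self.replicon_id}: gene {g.protein_id} exceeds length_bp"
                )
        self._by_protein = {g.protein_id: g for g in self.genes}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, protein_id: str) -> GeneRecord:
        return self._by_protein[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein


@dataclasses.dataclass(frozen=True)
class RawProfileHit:
    """An unfiltered HMM profile hit for one protein."""

    protein_id: str
    profile_id: str
    evalue: float
    profile_coverage: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.profile_coverage <= 1.0:
            raise ValidationError(
                f"{self.protein_id}/{self.profile_id}: coverage "
                f"{self.profile_coverage} outside [0,1]"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.protein_id}: negative e-value")


@dataclasses.dataclass(frozen=True)
class ComponentHit:
    """A filtered hit tying a gene to one of the seven components."""

    component: Component
    gene: GeneRecord
    evalue: float
    profile_coverage: float
    profile_id: str

    @property
    def gene_index(self) -> int:
        return self.gene.gene_index


@dataclasses.dataclass
class DetectionConfig:
    """Thresholds of the detection stage.

    Defaults are the published values: hits kept at e-value <= 1e-5 and
    profile coverage >= 40%; components chained when less than 10 ORFs
    apart; sets may miss at most two components.
    """

    max_gap_orfs: int = 10
    evalue_max: float = 1e-5
    coverage_min: float = 0.4
    max_missing: int = 2
    #: "intervening": <10 intervening ORFs, i.e. gene_index difference <= 10
    #: "index": strict index distance, gene_index difference < max_gap_orfs
    gap_semantics: str = "intervening"
    #: which side the coverage fraction refers to ("profile" or "target")
    coverage_side: str = "profile"

    def __post_init__(self) -> None:
        if min(self.max_gap_orfs, self.evalue_max, self.coverage_min) <= 0:
            raise ValidationError("detection thresholds must be strictly positive")
        if not 0 <= self.max_missing <= 6:
            raise ValidationError("max_missing must be within 0..6")
        if self.gap_semantics not in ("intervening", "index"):
            raise ValidationError(f"bad gap_semantics {self.gap_semantics!r}")

    def within_gap(self, index_a: int, index_b: int) -> bool:
        """True when two gene indices are co-localizable."""
        d = abs(index_b - index_a)
        if self.gap_semantics == "intervening":
            return d <= self.max_gap_orfs
        return d < self.max_gap_orfs


#: Default Type B numbering: code k is the variant missing ``DEFAULT_B_ORDER[k-1]``.
#: #01=alpha, #02=epsilon, #03=alpA, #04=sid, #05=delta, #06=psu, #07=integrase,
#: i.e. B code = 8 - canonical rank of the missing component.
DEFAULT_B_ORDER: tuple[Component, ...] = tuple(reversed(CANONICAL_ORDER))


class VariantCatalogue:
    """The 29 variant codes: TypeA, 7 Type B codes and C(7,2)=21 Type C codes.

    Type C codes are ordered lexicographically by the Type B codes of the
    two missing components, which anchors {epsilon, alpha} at TypeC#01.
    """

    def __init__(self, b_order: Sequence[Component] = DEFAULT_B_ORDER):
        if sorted(b_order, key=lambda c: c.value) != sorted(
            Component, key=lambda c: c.value
        ):
            raise ValidationError("b_order must be a permutation of the 7 components")
        self._b_order = tuple(b_order)
        self._missing_of: dict[str, frozenset[Component]] = {"TypeA": frozenset()}
        for k, comp in enumerate(self._b_order, start=1):
            self._missing_of[f"TypeB#{k:02d}"] = frozenset({comp})
        b_num = {comp: k for k, comp in enumerate(self._b_order, start=1)}
        pairs = sorted(
            itertools.combinations(self._b_order, 2),
            key=lambda p: tuple(sorted(b_num[c] for c in p)),
        )
        for k, pair in enumerate(pairs, start=1):
            self._missing_of[f"TypeC#{k:02d}"] = frozenset(pair)
        self._code_of = {m: c for c, m in self._missing_of.items()}

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._missing_of)

    def missing_of(self, code: str) -> frozenset[Component]:
        return self._missing_of[code]

    def code_of(self, missing: Iterable[Component]) -> str:
        key = frozenset(missing)
        if key not in self._code_of:
            raise ClassificationError(
                f"no variant code for missing set {sorted(c.value for c in key)}"
            )
        return self._code_of[key]


@dataclasses.dataclass
class SatelliteSet:
    """A chained candidate element: at most one hit per component."""

    set_id: str
    replicon_id: str
    members: dict[Component, ComponentHit]
    set_type: Optional[str] = None
    variant_code: Optional[str] = None
    wrapped: bool = False

    @property
    def present(self) -> frozenset[Component]:
        return frozenset(self.members)

    @property
    def missing(self) -> frozenset[Component]:
        return frozenset(Component) - self.present

    @property
    def span_gene_indices(self) -> tuple[int, int]:
        idx = [h.gene_index for h in self.members.values()]
        return (min(idx), max(idx))

    def members_in_order(self) -> list[ComponentHit]:
        return sorted(self.members.values(), key=lambda h: h.gene_index)


@dataclasses.dataclass
class Fragment:
    """A closed chain missing more than ``max_missing`` components."""

    fragment_id: str
    replicon_id: str
    members: dict[Component, ComponentHit]

    @property
    def span_gene_indices(self) -> tuple[int, int]:
        idx = [h.gene_index for h in self.members.values()]
        return (min(idx), max(idx))


@dataclasses.dataclass(frozen=True)
class HomologyHit:
    """A filtered protein-pair similarity (BLAST-tabular provenance)."""

    query: str
    target: str
    identity: float
    query_coverage: float
    target_coverage: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        for name in ("identity", "query_coverage", "target_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValidationError(f"{self.query}->{self.target}: {name}={v}")

    @property
    def is_self(self) -> bool:
        return self.query == self.target


@dataclasses.dataclass(frozen=True)
class BBHPair:
    """A bidirectional best hit between two proteomes."""

    protein_a: str
    protein_b: str
    identity: float


@dataclasses.dataclass
class SatelliteGenome:
    """A delimited element: full span between the anchor and the furthest component."""

    set_id: str
    replicon_id: str
    span_bp: tuple[int, int]
    gene_list: list[GeneRecord]
    anchor: Component
    furthest: Component
    variant_code: Optional[str] = None

    @property
    def size_bp(self) -> int:
        return self.span_bp[1] - self.span_bp[0] + 1

    @property
    def n_proteins(self) -> int:
        return len(self.gene_list)

    @property
    def protein_ids(self) -> list[str]:
        return [g.protein_id for g in self.gene_list]


@dataclasses.dataclass
class OrganizationSignature:
    """Component order read in gene order starting from the integrase end."""

    set_id: str
    order: tuple[Component, ...]
    gaps: tuple[int, ...]
    canonical: bool
    label: str


@dataclasses.dataclass
class ChromosomePosition:
    """Element position relative to the ordered core genome (N+1 rule)."""

    set_id: str
    upstream_core_family: Optional[str]
    position: int
    flagged: bool = False


@dataclasses.dataclass
class GeneFamily:
    """One protein family of the satellite pangenome (a partition cell)."""

    family_id: str
    members: frozenset[str]
    representative: str
    prevalence: Optional[float] = None


@dataclasses.dataclass
class PseudogeneCall:
    """Verdict for the locus at a missing component's expected position."""

    expected_component: Optional[Component]
    verdict: str  # intact | pseudogene | absent
    evidence: tuple[str, ...]
    aligned_fraction: float
    set_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.verdict == "pseudogene" and not self.evidence:
            raise ValidationError("pseudogene verdict requires evidence")


def restrict_canonical(present: Iterable[Component]) -> tuple[Component, ...]:
    """Canonical P4 order restricted to the given components."""
    present = set(present)
    return tuple(c for c in CANONICAL_ORDER if c in present)
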