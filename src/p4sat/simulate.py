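"""Seeded generator of annotated replicons with planted P4-like satellites.

The generator is the statistical stand-in for a RefSeq-scale dataset: it
emits multi-gene replicons with ordered ORFs, plants satellites of chosen
variant and organization with realistic inter-component gaps, scatters
decoy isolated components away from the elements, builds a protein
universe with controlled pairwise identities (emitted as a similarity
table, since the pipeline consumes tables rather than alignments) and
records a truth table for every planted feature.  All randomness derives
from one master seed through per-artefact streams, so adding replicons
does not shift the placement of previously generated ones.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .model import (
    CANONICAL_ORDER,
    COMPONENT_DEFAULT_PROFILE,
    PROFILE_LENGTHS,
    Component,
    GeneRecord,
    HomologyHit,
    RawProfileHit,
    Replicon,
    ValidationError,
    VariantCatalogue,
    restrict_canonical,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: one codon per amino acid, used for deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_NT = np.array(list("ACGT"))


@dataclasses.dataclass
class SharedAccessory:
    """An accessory family planted at a fixed inter-component interval.

    ``interval`` names the upstream component of the slot (the gene goes
    between it and the next component of the organization); ``prevalence``
    is the probability that any given planted element carries the family.
    """

    family_id: str
    interval: Component
    prevalence: float


@dataclasses.dataclass
class PlantedElement:
    """Specification of one satellite to plant."""

    variant_code: str = "TypeA"
    organization: str = "canonical"  # canonical | psu_delta_swap | reversed | custom
    custom_order: Optional[tuple[Component, ...]] = None
    gap_range: tuple[int, int] = (0, 3)  # intervening ORFs between components
    #: fixed gap after a given component, overriding gap_range (hotspots)
    interval_gaps: Optional[dict[Component, int]] = None
    replicon: Optional[int] = None  # index; round-robin when None
    flank_upstream_family: Optional[str] = None
    flank_downstream_family: Optional[str] = None


@dataclasses.dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    n_replicons: int = 5
    genes_per_replicon: int = 60
    topology: str = "linear"
    elements: Sequence[PlantedElement] = dataclasses.field(
        default_factory=lambda: [PlantedElement()]
    )
    decoys_per_replicon: int = 0
    shared_accessory: Sequence[SharedAccessory] = ()
    #: identity range between homologous core components of different elements
    component_identity: tuple[float, float] = (0.5, 0.9)
    #: identity range within accessory families
    within_family_identity: tuple[float, float] = (0.7, 1.0)
    max_gap_orfs: int = 10  # decoys are placed further than this from elements
    protein_aa_range: tuple[int, int] = (80, 400)
    intergenic_bp_range: tuple[int, int] = (20, 200)


@dataclasses.dataclass
class TruthElement:
    element_id: str
    replicon_id: str
    variant_code: str
    set_type: str
    organization: str
    members: dict[Component, str]  # component -> protein_id
    member_indices: dict[Component, int]
    span_gene_indices: tuple[int, int]
    span_bp: tuple[int, int]


@dataclasses.dataclass
class TruthTable:
    elements: list[TruthElement]
    protein_families: dict[str, str]
    decoys: list[tuple[str, int, Component, str]]  # replicon, index, component, protein

    def census(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.elements:
            counts[e.variant_code] = counts.get(e.variant_code, 0) + 1
        return counts


@dataclasses.dataclass
class SimulatedDataset:
    spec: SimulationSpec
    replicons: list[Replicon]
    raw_hits: list[RawProfileHit]
    similarity: list[HomologyHit]
    protein_lengths: dict[str, int]
    truth: TruthTable

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write the dataset in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "hits": outdir / "hits.domtblout",
            "similarity": outdir / "similarity.tsv",
            "proteins": outdir / "proteins.faa",
            "truth": outdir / "truth.json",
        }
        with open(paths["genes"], "w") as fh:
            fh.write(
                "replicon_id\tprotein_id\tstart\tend\tstrand\tlength_aa"
                "\ttopology\treplicon_length\n"
            )
            for rep in self.replicons:
                for g in rep.genes:
                    fh.write(
                        f"{rep.replicon_id}\t{g.protein_id}\t{g.start}\t{g.end}"
                        f"\t{g.strand}\t{g.length_aa}\t{rep.topology}\t{rep.length_bp}\n"
                    )
        with open(paths["hits"], "w") as fh:
            fh.write("# planted component hits (domtblout dialect)\n")
            for h in self.raw_hits:
                qlen = PROFILE_LENGTHS.get(h.profile_id, 100)
                hmm_to = max(1, round(h.profile_coverage * qlen))
                tlen = self.protein_lengths.get(h.protein_id, 100)
                fh.write(
                    f"{h.protein_id} - {tlen} {h.profile_id} - {qlen} "
                    f"{h.evalue:.3g} {h.score:.1f} 0.0 1 1 "
                    f"{h.evalue:.3g} {h.evalue:.3g} {h.score:.1f} 0.0 "
                    f"1 {hmm_to} 1 {min(tlen, hmm_to)} 1 {tlen} 0.99 -\n"
                )
        with open(paths["similarity"], "w") as fh:
            for h in self.similarity:
                qlen = self.protein_lengths[h.query]
                tlen = self.protein_lengths[h.target]
                qa = max(1, round(h.query_coverage * qlen))
                ta = max(1, round(h.target_coverage * tlen))
                fh.write(
                    f"{h.query}\t{h.target}\t{h.identity * 100:.1f}\t{qa}\t0\t0"
                    f"\t1\t{qa}\t1\t{ta}\t{h.evalue:.3g}\t{h.bitscore:.1f}"
                    f"\t{qlen}\t{tlen}\n"
                )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.spec.seed, spawn_key=(99,))
        )
        with open(paths["proteins"], "w") as fh:
            for pid in sorted(self.protein_lengths):
                aa = "".join(rng.choice(_AA, size=self.protein_lengths[pid]))
                fh.write(f">{pid}\n{aa}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "elements": [
                        {
                            "element_id": e.element_id,
                            "replicon_id": e.replicon_id,
                            "variant_code": e.variant_code,
                            "set_type": e.set_type,
                            "organization": e.organization,
                            "members": {c.value: p for c, p in e.members.items()},
                            "member_indices": {
                                c.value: i for c, i in e.member_indices.items()
                            },
                            "span_gene_indices": list(e.span_gene_indices),
                            "span_bp": list(e.span_bp),
                        }
                        for e in self.truth.elements
                    ],
                    "protein_families": self.truth.protein_families,
                    "decoys": [
                        [rep, idx, comp.value, pid]
                        for rep, idx, comp, pid in self.truth.decoys
                    ],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return paths


def _element_order(spec_e: PlantedElement, catalogue: VariantCatalogue) -> list[Component]:
    missing = catalogue.missing_of(spec_e.variant_code)
    present = [c for c in CANONICAL_ORDER if c not in missing]
    if spec_e.organization == "canonical":
        return present
    if spec_e.organization == "psu_delta_swap":
        order = list(present)
        if Component.PSU in order and Component.DELTA in order:
            i, j = order.index(Component.PSU), order.index(Component.DELTA)
            order[i], order[j] = order[j], order[i]
        return order
    if spec_e.organization == "reversed":
        return [present[0]] + list(reversed(present[1:]))
    if spec_e.organization == "custom":
        if spec_e.custom_order is None:
            raise ValidationError("custom organization requires custom_order")
        return list(spec_e.custom_order)
    raise ValidationError(f"unknown organization {spec_e.organization!r}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate(spec: SimulationSpec, catalogue: Optional[VariantCatalogue] = None) -> SimulatedDataset:
    """Generate a dataset with planted satellites and a full truth table.

    Deterministic under ``spec.seed``.  Raises when an element (with its
    gaps) cannot fit on its replicon at the mandated distance from other
    planted features.
    """
    catalogue = catalogue or VariantCatalogue()
    if spec.n_replicons < 1 or spec.genes_per_replicon < 1:
        raise ValidationError("need at least one replicon and one gene")
    n_rep, n_genes = spec.n_replicons, spec.genes_per_replicon
    rep_ids = [f"REP{r:03d}" for r in range(n_rep)]
    # slot layout per replicon: None or a role tuple
    slots: list[list[Optional[tuple]]] = [[None] * n_genes for _ in range(n_rep)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_rep)]

    def fits(rep: int, start: int, length: int) -> bool:
        if start < 0 or start + length > n_genes:
            return False
        margin = spec.max_gap_orfs + 1
        return all(
            start + length + margin <= lo or start >= hi + margin
            for lo, hi in occupied[rep]
        )

    elements_truth: list[dict] = []
    for e_idx, elem in enumerate(spec.elements):
        rng = _rng(spec.seed, 1, e_idx)
        rep = elem.replicon if elem.replicon is not None else e_idx % n_rep
        if rep >= n_rep:
            raise ValidationError(f"element {e_idx}: replicon {rep} out of range")
        order = _element_order(elem, catalogue)
        gaps = [
            int(rng.integers(elem.gap_range[0], elem.gap_range[1] + 1))
            for _ in range(len(order) - 1)
        ]
        if elem.interval_gaps:
            for i, comp in enumerate(order[:-1]):
                if comp in elem.interval_gaps:
                    gaps[i] = elem.interval_gaps[comp]
        if any(g > spec.max_gap_orfs - 1 for g in gaps):
            raise ValidationError(
                f"element {e_idx}: gap exceeds max_gap_orfs-1; not recoverable"
            )
        # per-slot roles along the element
        layout: list[tuple] = []
        shared_here: dict[int, str] = {}
        for comp, gap in zip(order, gaps + [0]):
            layout.append(("component", e_idx, comp))
            inserted = 0
            for acc in spec.shared_accessory:
                if acc.interval is comp and inserted < gap:
                    if rng.random() < acc.prevalence:
                        layout.append(("accessory", e_idx, acc.family_id))
                        inserted += 1
            for k in range(gap - inserted):
                layout.append(("accessory", e_idx, f"ACC_{e_idx}_{comp.value}_{k}"))
        length = len(layout)
        placed = False
        for _ in range(200):
            start = int(rng.integers(1, max(2, n_genes - length)))
            if fits(rep, start, length):
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"element {e_idx} (len {length}) does not fit on replicon {rep}"
            )
        for k, role in enumerate(layout):
            slots[rep][start + k] = role
        if elem.flank_upstream_family and start >= 1:
            slots[rep][start - 1] = ("flank", e_idx, elem.flank_upstream_family)
        if elem.flank_downstream_family and start + length < n_genes:
            slots[rep][start + length] = ("flank", e_idx, elem.flank_downstream_family)
        lo = start - (1 if elem.flank_upstream_family else 0)
        hi = start + length - 1 + (1 if elem.flank_downstream_family else 0)
        occupied[rep].append((lo, hi))
        elements_truth.append(
            dict(e_idx=e_idx, rep=rep, order=order, start=start, length=length, elem=elem)
        )

    decoys: list[tuple[int, int, Component]] = []
    for rep in range(n_rep):
        rng = _rng(spec.seed, 2, rep)
        for d in range(spec.decoys_per_replicon):
            comp = CANONICAL_ORDER[int(rng.integers(len(CANONICAL_ORDER)))]
            for _ in range(200):
                pos = int(rng.integers(0, n_genes))
                if fits(rep, pos, 1):
                    slots[rep][pos] = ("decoy", rep, comp)
                    occupied[rep].append((pos, pos))
                    decoys.append((rep, pos, comp))
                    break

    # materialize genes with coordinates
    replicons: list[Replicon] = []
    protein_lengths: dict[str, int] = {}
    protein_families: dict[str, str] = {}
    comp_proteins: dict[Component, list[str]] = {c: [] for c in Component}
    fam_proteins: dict[str, list[str]] = {}
    gene_lookup: dict[tuple[int, int], GeneRecord] = {}
    for rep in range(n_rep):
        rng = _rng(spec.seed, 3, rep)
        genes: list[GeneRecord] = []
        pos_bp = 1
        for slot in range(n_genes):
            aa = int(rng.integers(*spec.protein_aa_range))
            gap_bp = int(rng.integers(*spec.intergenic_bp_range))
            strand = "+" if rng.random() < 0.7 else "-"
            pid = f"{rep_ids[rep]}_{slot + 1:05d}"
            start = pos_bp + gap_bp
            end = start + aa * 3 + 2
            role = slots[rep][slot]
            g = GeneRecord(
                replicon_id=rep_ids[rep],
                gene_index=slot + 1,
                start=start,
                end=end,
                strand=strand,
                protein_id=pid,
                length_aa=aa,
            )
            genes.append(g)
            gene_lookup[(rep, slot)] = g
            protein_lengths[pid] = aa
            if role is None:
                protein_families[pid] = f"BG_{pid}"
            elif role[0] == "component":
                comp = role[2]
                fam = f"COMP_{comp.value}"
                protein_families[pid] = fam
                comp_proteins[comp].append(pid)
            elif role[0] == "decoy":
                comp = role[2]
                fam = f"COMP_{comp.value}"
                protein_families[pid] = fam
                comp_proteins[comp].append(pid)
            else:  # accessory or flank family
                fam = role[2]
                protein_families[pid] = fam
                fam_proteins.setdefault(fam, []).append(pid)
            pos_bp = end
        replicons.append(
            Replicon(
                replicon_id=rep_ids[rep],
                genes=genes,
                length_bp=pos_bp + int(rng.integers(*spec.intergenic_bp_range)),
                topology=spec.topology,
            )
        )

    # profile hits: exactly one qualifying hit per planted component gene + decoys
    hit_rng = _rng(spec.seed, 4)
    raw_hits: list[RawProfileHit] = []
    for comp in CANONICAL_ORDER:
        for pid in sorted(comp_proteins[comp]):
            raw_hits.append(
                RawProfileHit(
                    protein_id=pid,
                    profile_id=COMPONENT_DEFAULT_PROFILE[comp],
                    evalue=float(10 ** hit_rng.uniform(-30, -10)),
                    profile_coverage=float(hit_rng.uniform(0.5, 1.0)),
                    score=float(hit_rng.uniform(50, 300)),
                )
            )

    # similarity table realizing the requested identity structure
    sim_rng = _rng(spec.seed, 5)
    similarity: list[HomologyHit] = []

    def add_pair(a: str, b: str, lo: float, hi: float) -> None:
        ident = float(sim_rng.uniform(lo, hi))
        cov_q = float(sim_rng.uniform(0.8, 1.0))
        cov_t = float(sim_rng.uniform(0.8, 1.0))
        bits = ident * min(protein_lengths[a], protein_lengths[b])
        for q, t, cq, ct in ((a, b, cov_q, cov_t), (b, a, cov_t, cov_q)):
            similarity.append(
                HomologyHit(
                    query=q,
                    target=t,
                    identity=ident,
                    query_coverage=cq,
                    target_coverage=ct,
                    evalue=1e-50,
                    bitscore=bits,
                )
            )

    for comp in CANONICAL_ORDER:
        members = sorted(comp_proteins[comp])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                add_pair(a, b, *spec.component_identity)
    for fam in sorted(fam_proteins):
        members = sorted(fam_proteins[fam])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                add_pair(a, b, *spec.within_family_identity)
    for pid in sorted(protein_lengths):
        similarity.append(
            HomologyHit(
                query=pid,
                target=pid,
                identity=1.0,
                query_coverage=1.0,
                target_coverage=1.0,
                evalue=1e-80,
                bitscore=2.0 * protein_lengths[pid],
            )
        )

    truth_elements: list[TruthElement] = []
    for rec in elements_truth:
        order, rep, start = rec["order"], rec["rep"], rec["start"]
        members: dict[Component, str] = {}
        member_indices: dict[Component, int] = {}
        k = start
        for slot in range(start, start + rec["length"]):
            role = slots[rep][slot]
            if role and role[0] == "component" and role[1] == rec["e_idx"]:
                members[role[2]] = gene_lookup[(rep, slot)].protein_id
                member_indices[role[2]] = slot + 1
        idx = sorted(member_indices.values())
        anchor = (
            Component.INTEGRASE if Component.INTEGRASE in members else Component.PSU
        )
        anchor_gene = gene_lookup[(rep, member_indices[anchor] - 1)]
        furthest_comp = max(
            member_indices,
            key=lambda c: (
                abs(member_indices[c] - member_indices[anchor]),
                abs(gene_lookup[(rep, member_indices[c] - 1)].start - anchor_gene.start),
                gene_lookup[(rep, member_indices[c] - 1)].protein_id,
            ),
        )
        furthest_gene = gene_lookup[(rep, member_indices[furthest_comp] - 1)]
        span_bp = (
            min(anchor_gene.start, furthest_gene.start),
            max(anchor_gene.end, furthest_gene.end),
        )
        missing = catalogue.missing_of(rec["elem"].variant_code)
        truth_elements.append(
            TruthElement(
                element_id=f"E{rec['e_idx']:03d}",
                replicon_id=rep_ids[rep],
                variant_code=rec["elem"].variant_code,
                set_type={0: "A", 1: "B", 2: "C"}[len(missing)],
                organization=rec["elem"].organization,
                members=members,
                member_indices=member_indices,
                span_gene_indices=(idx[0], idx[-1]),
                span_bp=span_bp,
            )
        )
    truth = TruthTable(
        elements=truth_elements,
        protein_families=protein_families,
        decoys=[
            (rep_ids[rep], pos + 1, comp, gene_lookup[(rep, pos)].protein_id)
            for rep, pos, comp in decoys
        ],
    )
    return SimulatedDataset(
        spec=spec,
        replicons=replicons,
        raw_hits=raw_hits,
        similarity=similarity,
        protein_lengths=protein_lengths,
        truth=truth,
    )


# --- nucleotide loci for the pseudogene stage ---------------------------


def back_translate(protein_aa: str) -> str:
    """Deterministic coding sequence for a protein (one codon per residue)."""
    try:
        return "".join(_CODON[a] for a in protein_aa) + "TAA"
    except KeyError as exc:
        raise ValidationError(f"cannot back-translate residue {exc}")


def mutate_locus(cds: str, defect: str = "none", position: Optional[int] = None) -> str:
    """Introduce a frameshift or internal stop into a coding sequence.

    ``position`` is the 1-based codon index; a frameshift deletes the
    first base of that codon, an internal stop replaces the codon with
    TAA.  ``defect="none"`` is the identity.
    """
    if len(cds) % 3 != 0:
        raise ValidationError("CDS length must be divisible by 3")
    n_codons = len(cds) // 3
    if defect == "none":
        return cds
    if position is None:
        position = n_codons // 2
    if not 1 <= position <= n_codons:
        raise ValidationError(f"codon position {position} outside 1..{n_codons}")
    i = (position - 1) * 3
    if defect == "frameshift":
        return cds[:i] + cds[i + 1 :]
    if defect == "internal_stop":
        return cds[:i] + "TAA" + cds[i + 3 :]
    raise ValidationError(f"unknown defect {defect!r}")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def random_locus(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def simulate_locus(
    rng: np.random.Generator,
    kind: str,
    protein_aa_range: tuple[int, int] = (100, 250),
    flank_nt: int = 30,
) -> tuple[str, str, str]:
    """One pseudogene-scan test case: (locus_nt, reference_aa, expected verdict).

    ``kind`` is "intact" (exact back-translated CDS), "frameshift" or
    "internal_stop" (the back-translated CDS with a mid-gene defect) or
    "random" (unrelated sequence; expected verdict absent).
    """
    length = int(rng.integers(*protein_aa_range))
    ref = "M" + random_protein(rng, length - 1)
    flank5 = random_locus(rng, flank_nt)
    flank3 = random_locus(rng, flank_nt)
    if kind == "random":
        return random_locus(rng, length * 3 + 2 * flank_nt), ref, "absent"
    cds = back_translate(ref)
    if kind == "intact":
        return flank5 + cds + flank3, ref, "intact"
    if kind in ("frameshift", "internal_stop"):
        return flank5 + mutate_locus(cds, kind) + flank3, ref, "pseudogene"
    raise ValidationError(f"unknown locus kind {kind!r}")


# --- trees for the patristic-correlation stage ---------------------------


@dataclasses.dataclass
class _Node:
    children: list[tuple["_Node", float]] = dataclasses.field(default_factory=list)
    label: Optional[str] = None


def _random_topology(labels: Sequence[str], rng: np.random.Generator) -> _Node:
    labels = [labels[i] for i in rng.permutation(len(labels))]

    def build(ls: list[str]) -> _Node:
        if len(ls) == 1:
            return _Node(label=ls[0])
        k = int(rng.integers(1, len(ls)))
        node = _Node()
        for part in (ls[:k], ls[k:]):
            node.children.append((build(part), float(rng.exponential(0.5)) + 1e-3))
        return node

    return build(labels)


def _to_newick(node: _Node, scale) -> str:
    if node.label is not None:
        return node.label
    parts = [
        f"{_to_newick(child, scale)}:{length * scale(length):.6f}"
        for child, length in node.children
    ]
    return "(" + ",".join(parts) + ")"


def simulate_trees(
    n_elements: int,
    components: Sequence[str] = ("integrase", "psu", "delta", "sid"),
    coupling: str = "shared_history",
    seed: int = 0,
    noise: float = 0.1,
) -> tuple[dict[str, str], dict[str, dict[str, str]]]:
    """Per-component Newick trees plus the element-to-leaf pairing.

    ``shared_history`` draws every component tree from one element
    genealogy, multiplying each branch length by a lognormal factor of
    scale ``noise`` (noise 0 gives identical patristic matrices, hence
    rho = 1 between any two components); ``independent`` draws an
    unrelated topology per component, giving rho near 0 for large
    element counts.  Leaf labels equal element ids, so the pairing maps
    component -> {element -> leaf} with leaf == element.
    """
    if n_elements < 4:
        raise ValidationError("need at least 4 elements")
    if coupling not in ("shared_history", "independent"):
        raise ValidationError(f"unknown coupling {coupling!r}")
    element_ids = [f"E{i:03d}" for i in range(n_elements)]
    newicks: dict[str, str] = {}
    base = None
    if coupling == "shared_history":
        base = _random_topology(element_ids, _rng(seed, 10))
    for k, comp in enumerate(components):
        rng = _rng(seed, 11, k)
        if coupling == "shared_history":
            jitter = lambda L, r=rng: float(np.exp(noise * r.normal())) if noise else 1.0
            newicks[comp] = _to_newick(base, jitter) + ";"
        else:
            topo = _random_topology(element_ids, rng)
            newicks[comp] = _to_newick(topo, lambda L: 1.0) + ";"
    pairing = {comp: {e: e for e in element_ids} for comp in components}
    return newicks, pairing
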