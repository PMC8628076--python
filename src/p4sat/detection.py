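"""Detection of P4-like satellite sets by co-localization chaining.

Filtered component hits are ordered along the replicon and chained: a hit
joins the open chain when it lies within the configured ORF gap of the
chain's nearest member, otherwise the chain closes and a new one opens.
Closed chains keeping at least five distinct components (i.e. missing at
most two) become satellite sets; smaller chains are reported as fragments,
not silently dropped.  Sets are classified as Type A/B/C by the number of
missing components and named after the exact missing combination.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    CANONICAL_ORDER,
    PROFILE_COMPONENTS,
    SERINE_INTEGRASE_PROFILES,
    TYROSINE_INTEGRASE_PROFILE,
    ClassificationError,
    Component,
    ComponentHit,
    DetectionConfig,
    Fragment,
    RawProfileHit,
    Replicon,
    SatelliteSet,
    VariantCatalogue,
)

logger = logging.getLogger(__name__)


def filter_hits(
    raw: Iterable[RawProfileHit], cfg: DetectionConfig
) -> list[RawProfileHit]:
    """Keep hits passing both thresholds (e-value <= max, coverage >= min).

    Hits to profiles outside the component rule table are dropped with a
    warning.  Integrase profile logic (tyrosine profile alone, or both
    serine profiles) is applied afterwards by :func:`resolve_integrases`.
    """
    raw = list(raw)
    kept = []
    for h in raw:
        if h.profile_id not in PROFILE_COMPONENTS:
            logger.warning("dropping hit to unknown profile %r", h.profile_id)
            continue
        if h.evalue <= cfg.evalue_max and h.profile_coverage >= cfg.coverage_min:
            kept.append(h)
    logger.info("filter_hits: %d in, %d out", len(raw), len(kept))
    return kept


def resolve_integrases(filtered: Iterable[RawProfileHit]) -> dict[str, RawProfileHit]:
    """Apply the recombinase rules, returning one merged hit per integrase protein.

    A protein qualifies with a tyrosine-recombinase hit alone, or with
    hits to BOTH serine-recombinase profiles; the merged hit keeps the
    lowest e-value (and highest score) among the contributing profiles.
    """
    by_protein: dict[str, dict[str, RawProfileHit]] = {}
    for h in filtered:
        if PROFILE_COMPONENTS.get(h.profile_id) is Component.INTEGRASE:
            by_protein.setdefault(h.protein_id, {})[h.profile_id] = h
    resolved: dict[str, RawProfileHit] = {}
    ser_a, ser_b = SERINE_INTEGRASE_PROFILES
    for pid, profs in by_protein.items():
        contributing: list[RawProfileHit] = []
        if TYROSINE_INTEGRASE_PROFILE in profs:
            contributing.append(profs[TYROSINE_INTEGRASE_PROFILE])
        if ser_a in profs and ser_b in profs:
            contributing.extend((profs[ser_a], profs[ser_b]))
        if not contributing:
            continue
        best = min(contributing, key=lambda h: (h.evalue, -h.score))
        resolved[pid] = RawProfileHit(
            protein_id=pid,
            profile_id=best.profile_id,
            evalue=min(h.evalue for h in contributing),
            profile_coverage=max(h.profile_coverage for h in contributing),
            score=max(h.score for h in contributing),
        )
    return resolved


def component_hits(
    raw: Iterable[RawProfileHit], replicon: Replicon, cfg: DetectionConfig
) -> list[ComponentHit]:
    """Filter raw hits and label each surviving protein with one component.

    A protein hitting profiles of two different components keeps the
    component with the lowest e-value (single label per gene).
    """
    filtered = [h for h in filter_hits(raw, cfg) if h.protein_id in replicon]
    integrases = resolve_integrases(filtered)
    candidates: dict[str, list[tuple[Component, RawProfileHit]]] = {}
    for h in filtered:
        comp = PROFILE_COMPONENTS[h.profile_id]
        if comp is Component.INTEGRASE:
            continue
        candidates.setdefault(h.protein_id, []).append((comp, h))
    for pid, h in integrases.items():
        candidates.setdefault(pid, []).append((Component.INTEGRASE, h))
    out: list[ComponentHit] = []
    for pid, options in candidates.items():
        # one component per protein: lowest e-value wins, rank breaks ties
        best: dict[Component, RawProfileHit] = {}
        for comp, h in options:
            if comp not in best or h.evalue < best[comp].evalue:
                best[comp] = h
        comp, h = min(
            best.items(), key=lambda kv: (kv[1].evalue, kv[0].canonical_rank)
        )
        out.append(
            ComponentHit(
                component=comp,
                gene=replicon.gene(pid),
                evalue=h.evalue,
                profile_coverage=h.profile_coverage,
                profile_id=h.profile_id,
            )
        )
    out.sort(key=lambda h: h.gene_index)
    return out


def _chain(
    hits: list[ComponentHit], replicon: Replicon, cfg: DetectionConfig
) -> list[tuple[list[ComponentHit], bool]]:
    """Left-to-right sweep chaining; wraps across the origin when circular."""
    chains: list[list[ComponentHit]] = []
    for h in hits:  # hits sorted by gene_index
        if chains and cfg.within_gap(chains[-1][-1].gene_index, h.gene_index):
            chains[-1].append(h)
        else:
            chains.append([h])
    wrapped = [False] * len(chains)
    if (
        replicon.topology == "circular"
        and len(chains) >= 2
        and cfg.within_gap(
            0, replicon.n_genes - chains[-1][-1].gene_index + chains[0][0].gene_index
        )
    ):
        chains[-1].extend(chains[0])
        chains, wrapped = chains[1:], wrapped[1:]
        wrapped[-1] = True
    return list(zip(chains, wrapped))


def dedupe_components(chain: Sequence[ComponentHit]) -> dict[Component, ComponentHit]:
    """Reduce a raw chain to at most one hit per component.

    Duplicate integrases keep the copy closest to psu (first occurrence
    when psu is absent); any other duplicated component keeps the first
    occurrence in gene order.
    """
    ordered = sorted(chain, key=lambda h: h.gene_index)
    members: dict[Component, ComponentHit] = {}
    for h in ordered:
        if h.component is Component.INTEGRASE:
            continue
        members.setdefault(h.component, h)
    integrases = [h for h in ordered if h.component is Component.INTEGRASE]
    if integrases:
        psu = members.get(Component.PSU)
        if psu is not None:
            members[Component.INTEGRASE] = min(
                integrases,
                key=lambda h: (abs(h.gene_index - psu.gene_index), h.gene_index),
            )
        else:
            members[Component.INTEGRASE] = integrases[0]
    return members


def build_sets(
    hits: Sequence[ComponentHit],
    replicon: Replicon,
    cfg: DetectionConfig,
) -> tuple[list[SatelliteSet], list[Fragment]]:
    """Chain component hits into satellite sets and fragments.

    Returns the closed chains with at least ``7 - max_missing`` distinct
    components as :class:`SatelliteSet` (unclassified) and the rest as
    :class:`Fragment`.
    """
    hits = sorted(hits, key=lambda h: h.gene_index)
    sets: list[SatelliteSet] = []
    fragments: list[Fragment] = []
    for chain, wrapped in _chain(hits, replicon, cfg):
        members = dedupe_components(chain)
        if len(members) >= len(Component) - cfg.max_missing:
            sets.append(
                SatelliteSet(
                    set_id=f"{replicon.replicon_id}_S{len(sets) + 1:03d}",
                    replicon_id=replicon.replicon_id,
                    members=members,
                    wrapped=wrapped,
                )
            )
        else:
            fragments.append(
                Fragment(
                    fragment_id=f"{replicon.replicon_id}_F{len(fragments) + 1:03d}",
                    replicon_id=replicon.replicon_id,
                    members=members,
                )
            )
    logger.info(
        "%s: %d sets, %d fragments", replicon.replicon_id, len(sets), len(fragments)
    )
    return sets, fragments


def classify_set(
    s: SatelliteSet, catalogue: Optional[VariantCatalogue] = None
) -> tuple[str, str]:
    """Assign (set_type, variant_code) from the missing-component combination."""
    catalogue = catalogue or VariantCatalogue()
    missing = s.missing
    if len(missing) > 2:
        raise ClassificationError(
            f"{s.set_id}: {len(missing)} missing components; should be a fragment"
        )
    set_type = {0: "A", 1: "B", 2: "C"}[len(missing)]
    code = catalogue.code_of(missing)
    s.set_type, s.variant_code = set_type, code
    return set_type, code


def detect_satellites(
    replicon: Replicon,
    raw: Iterable[RawProfileHit],
    cfg: Optional[DetectionConfig] = None,
    catalogue: Optional[VariantCatalogue] = None,
) -> tuple[list[SatelliteSet], list[Fragment]]:
    """Full per-replicon detection: filter, label, chain, classify."""
    cfg = cfg or DetectionConfig()
    catalogue = catalogue or VariantCatalogue()
    hits = component_hits(raw, replicon, cfg)
    sets, fragments = build_sets(hits, replicon, cfg)
    for s in sets:
        classify_set(s, catalogue)
    return sets, fragments


def census(
    sets: Iterable[SatelliteSet], catalogue: Optional[VariantCatalogue] = None
) -> pd.DataFrame:
    """Abundance per variant code, with zero-count variants listed explicitly."""
    catalogue = catalogue or VariantCatalogue()
    counts = {code: 0 for code in catalogue.codes}
    for s in sets:
        if s.variant_code is None:
            classify_set(s, catalogue)
        counts[s.variant_code] += 1
    rows = [
        {
            "variant_code": code,
            "set_type": "A" if code == "TypeA" else code[4],
            "missing": ",".join(
                sorted(c.value for c in catalogue.missing_of(code))
            ),
            "count": n,
        }
        for code, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["variant_code", "set_type", "missing", "count"])


def sets_table(sets: Iterable[SatelliteSet]) -> pd.DataFrame:
    """Long-form table of detected sets, one row per set."""
    rows = []
    for s in sets:
        ordered = s.members_in_order()
        rows.append(
            {
                "set_id": s.set_id,
                "replicon_id": s.replicon_id,
                "set_type": s.set_type,
                "variant_code": s.variant_code,
                "span_start_index": s.span_gene_indices[0],
                "span_end_index": s.span_gene_indices[1],
                "components": ",".join(h.component.value for h in ordered),
                "gene_indices": ",".join(str(h.gene_index) for h in ordered),
                "protein_ids": ",".join(h.gene.protein_id for h in ordered),
                "evalues": ",".join(format(h.evalue, ".3g") for h in ordered),
            }
        )
    cols = [
        "set_id",
        "replicon_id",
        "set_type",
        "variant_code",
        "span_start_index",
        "span_end_index",
        "components",
        "gene_indices",
        "protein_ids",
        "evalues",
    ]
    return pd.DataFrame(rows, columns=cols)


def fragments_table(fragments: Iterable[Fragment]) -> pd.DataFrame:
    rows = [
        {
            "fragment_id": f.fragment_id,
            "replicon_id": f.replicon_id,
            "n_components": len(f.members),
            "components": ",".join(
                h.component.value
                for h in sorted(f.members.values(), key=lambda h: h.gene_index)
            ),
            "gene_indices": ",".join(
                str(h.gene_index)
                for h in sorted(f.members.values(), key=lambda h: h.gene_index)
            ),
        }
        for f in fragments
    ]
    cols = ["fragment_id", "replicon_id", "n_components", "components", "gene_indices"]
    return pd.DataFrame(rows, columns=cols)
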