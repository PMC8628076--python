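"""Detection stage: hit filtering, integrase rules, chaining, classification."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p4sat.detection import (
    build_sets,
    census,
    classify_set,
    component_hits,
    dedupe_components,
    detect_satellites,
    filter_hits,
    resolve_integrases,
)
from p4sat.model import (
    CANONICAL_ORDER,
    ClassificationError,
    Component,
    DetectionConfig,
    RawProfileHit,
    VariantCatalogue,
)

from conftest import build_replicon, place_hits

CFG = DetectionConfig()


def raw(pid, profile="PF07455.12", evalue=1e-10, cov=0.8):
    return RawProfileHit(protein_id=pid, profile_id=profile, evalue=evalue,
                         profile_coverage=cov, score=50.0)


class TestFilterHits:
    def test_boundary_cases(self):
        keep = raw("a", evalue=1e-6, cov=0.5)
        drop_e = raw("b", evalue=1e-4, cov=0.5)
        drop_c = raw("c", evalue=1e-10, cov=0.39)
        kept = filter_hits([keep, drop_e, drop_c], CFG)
        assert kept == [keep]

    def test_unknown_profile_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = filter_hits([raw("a", profile="PF99999.1")], CFG)
        assert kept == []
        assert "unknown profile" in caplog.text

    def test_matches_bruteforce_two_predicate_filter(self, rng):
        hits = [
            raw(f"p{i}", evalue=10.0 ** rng.uniform(-12, -2),
                cov=float(rng.uniform(0, 1)))
            for i in range(100)
        ]
        oracle = [
            h for h in hits
            if h.evalue <= CFG.evalue_max and h.profile_coverage >= CFG.coverage_min
        ]
        assert filter_hits(hits, CFG) == oracle


class TestResolveIntegrases:
    def test_tyrosine_profile_alone_qualifies(self):
        out = resolve_integrases([raw("p", profile="PF00589.20")])
        assert set(out) == {"p"}

    def test_single_serine_profile_does_not_qualify(self):
        assert resolve_integrases([raw("p", profile="PF00239.19")]) == {}
        assert resolve_integrases([raw("p", profile="PF07508.11")]) == {}

    def test_serine_pair_merges_best_evalue(self):
        out = resolve_integrases(
            [raw("p", profile="PF00239.19", evalue=1e-10),
             raw("p", profile="PF07508.11", evalue=1e-8)]
        )
        assert out["p"].evalue == 1e-10


class TestBuildSets:
    def test_seven_hits_chain_into_one_type_a_set(self, replicon):
        placements = list(zip([5, 8, 9, 10, 12, 14, 15], CANONICAL_ORDER))
        hits = place_hits(replicon, placements)
        sets, frags = build_sets(hits, replicon, CFG)
        assert len(sets) == 1 and not frags
        assert sets[0].span_gene_indices == (5, 15)
        assert classify_set(sets[0]) == ("A", "TypeA")

    def test_distant_pair_yields_two_fragments(self, replicon):
        hits = place_hits(replicon, [(5, Component.PSU), (30, Component.DELTA)])
        sets, frags = build_sets(hits, replicon, CFG)
        assert sets == [] and len(frags) == 2

    def test_empty_input(self, replicon):
        assert build_sets([], replicon, CFG) == ([], [])

    def test_equals_connected_component_enumeration(self, rng):
        """Chains must match the exhaustive co-localization graph oracle."""
        rep = build_replicon(n_genes=120)
        for _ in range(30):
            n = int(rng.integers(1, 26))
            idx = sorted(rng.choice(np.arange(1, 121), size=n, replace=False))
            comps = [CANONICAL_ORDER[i] for i in rng.integers(0, 7, size=n)]
            hits = place_hits(rep, list(zip(idx, comps)))
            sets, frags = build_sets(hits, rep, CFG)
            got = sorted(
                frozenset(h.gene_index for h in chain)
                for chain in ([s.members_in_order() for s in sets]
                              + [sorted(f.members.values(), key=lambda h: h.gene_index)
                                 for f in frags])
            )
            g = nx.Graph()
            g.add_nodes_from(idx)
            for a in idx:
                for b in idx:
                    if a < b and b - a <= CFG.max_gap_orfs:
                        g.add_edge(a, b)
            # oracle components, deduplicated the same way (one gene per component)
            oracle = []
            for comp_set in nx.connected_components(g):
                members = dedupe_components(
                    [h for h in hits if h.gene_index in comp_set]
                )
                oracle.append(frozenset(h.gene_index for h in members.values()))
            assert sorted(got, key=min) == sorted(oracle, key=min)

    def test_components_per_set_monotone_in_gap_threshold(self, rng):
        """Raising max_gap_orfs never decreases the components of a recovered set."""
        rep = build_replicon(n_genes=200)
        idx = sorted(rng.choice(np.arange(1, 201), size=25, replace=False))
        comps = [CANONICAL_ORDER[i] for i in rng.integers(0, 7, size=25)]
        hits = place_hits(rep, list(zip(idx, comps)))

        def chains(gap):
            cfg = DetectionConfig(max_gap_orfs=gap)
            sets, frags = build_sets(hits, rep, cfg)
            return [
                (s.span_gene_indices, len(s.present)) for s in sets
            ] + [(f.span_gene_indices, len(f.members)) for f in frags]

        small, big = chains(5), chains(15)
        for (lo, hi), n_small in small:
            containing = [
                n_big for (blo, bhi), n_big in big if blo <= lo and hi <= bhi
            ]
            assert containing and max(containing) >= n_small

    def test_circular_replicon_wraps_across_origin(self):
        rep = build_replicon(n_genes=40, topology="circular")
        placements = [(37, Component.INTEGRASE), (39, Component.PSU),
                      (2, Component.DELTA), (4, Component.SID), (6, Component.ALPA)]
        hits = place_hits(rep, placements)
        sets, frags = build_sets(hits, rep, CFG)
        assert len(sets) == 1 and not frags
        assert sets[0].present == {Component.INTEGRASE, Component.PSU,
                                   Component.DELTA, Component.SID, Component.ALPA}
        assert sets[0].wrapped
        # the same layout on a linear replicon splits in two
        rep_lin = build_replicon(n_genes=40, topology="linear")
        sets_lin, frags_lin = build_sets(place_hits(rep_lin, placements), rep_lin, CFG)
        assert len(sets_lin) == 0 and len(frags_lin) == 2


class TestDedupe:
    def test_integrase_closest_to_psu_kept(self, replicon):
        hits = place_hits(replicon, [(2, Component.INTEGRASE), (9, Component.INTEGRASE),
                                     (11, Component.PSU)])
        members = dedupe_components(hits)
        assert members[Component.INTEGRASE].gene_index == 9

    def test_first_occurrence_for_duplicates(self, replicon):
        hits = place_hits(replicon, [(8, Component.PSU), (13, Component.PSU)])
        assert dedupe_components(hits)[Component.PSU].gene_index == 8

    def test_integrase_first_occurrence_without_psu(self, replicon):
        hits = place_hits(replicon, [(3, Component.INTEGRASE), (7, Component.INTEGRASE)])
        assert dedupe_components(hits)[Component.INTEGRASE].gene_index == 3

    def test_single_hit_identity(self, replicon):
        hits = place_hits(replicon, [(5, Component.SID)])
        assert dedupe_components(hits) == {Component.SID: hits[0]}


class TestClassify:
    @pytest.mark.parametrize(
        "missing, expected",
        [
            (set(), ("A", "TypeA")),
            ({Component.ALPA}, ("B", "TypeB#03")),
            ({Component.ALPHA}, ("B", "TypeB#01")),
            ({Component.PSU}, ("B", "TypeB#06")),
            ({Component.INTEGRASE}, ("B", "TypeB#07")),
            ({Component.EPSILON, Component.ALPHA}, ("C", "TypeC#01")),
        ],
    )
    def test_variant_codes(self, replicon, missing, expected):
        present = [c for c in CANONICAL_ORDER if c not in missing]
        hits = place_hits(replicon, list(zip(range(5, 5 + len(present)), present)))
        sets, _ = build_sets(hits, replicon, CFG)
        assert classify_set(sets[0]) == expected

    def test_over_missing_raises(self, replicon):
        hits = place_hits(replicon, [(5, c) for c in CANONICAL_ORDER])
        sets, _ = build_sets(
            place_hits(replicon, list(zip(range(5, 12), CANONICAL_ORDER))),
            replicon, CFG,
        )
        s = sets[0]
        for comp in (Component.SID, Component.ALPA, Component.EPSILON):
            del s.members[comp]
        with pytest.raises(ClassificationError):
            classify_set(s)


class TestCensus:
    def test_empty_input_lists_all_29_variants_at_zero(self):
        table = census([])
        assert len(table) == 29
        assert table["count"].sum() == 0
        assert (table[table.set_type == "C"].shape[0]) == 21

    def test_counts_match_planted_and_conserve(self, replicon):
        sets = []
        for k, missing in enumerate([set(), set(), set(), {Component.ALPA}, {Component.ALPA}]):
            rep = build_replicon(replicon_id=f"R{k}")
            present = [c for c in CANONICAL_ORDER if c not in missing]
            hits = place_hits(rep, list(zip(range(5, 5 + len(present)), present)))
            s, _ = build_sets(hits, rep, CFG)
            classify_set(s[0])
            sets.extend(s)
        table = census(sets)
        by_code = dict(zip(table.variant_code, table["count"]))
        assert by_code["TypeA"] == 3 and by_code["TypeB#03"] == 2
        assert table["count"].sum() == len(sets)


def test_component_hits_single_label_per_gene(replicon):
    # one protein hitting two different component profiles keeps the lower e-value
    pid = replicon.genes[4].protein_id
    raw_hits = [raw(pid, profile="PF07455.12", evalue=1e-20),
                raw(pid, profile="PF04606.13", evalue=1e-8)]
    out = component_hits(raw_hits, replicon, CFG)
    assert len(out) == 1
    assert out[0].component is Component.PSU


@given(
    indices=st.lists(
        st.integers(min_value=1, max_value=100), min_size=1, max_size=20, unique=True
    ),
    gap=st.integers(min_value=1, max_value=20),
)
@settings(deadline=None, derandomize=True, max_examples=50)
def test_chain_spans_respect_gap_predicate(indices, gap):
    """Within any chain consecutive members are within the gap; across chains not."""
    rep = build_replicon(n_genes=100, replicon_id="H")
    cfg = DetectionConfig(max_gap_orfs=gap)
    comps = [CANONICAL_ORDER[i % 7] for i in range(len(indices))]
    hits = place_hits(rep, list(zip(sorted(indices), comps)))
    sets, frags = build_sets(hits, rep, cfg)
    spans = sorted(
        x.span_gene_indices for x in [*sets, *frags]
    )
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        assert lo2 - hi1 > gap  # distinct chains are separated beyond the gap


def test_variant_catalogue_structure():
    cat = VariantCatalogue()
    codes = cat.codes
    assert len(codes) == 29
    assert sum(1 for c in codes if c.startswith("TypeC")) == 21
    # bijection: no two codes share a missing set
    seen = {cat.missing_of(c) for c in codes}
    assert len(seen) == 29
    assert [c.canonical_rank for c in CANONICAL_ORDER] == list(range(1, 8))
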