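"""Pangenome: family clustering, spectra, rarefaction, enrichment."""

import math

import numpy as np
import pytest

from p4sat.architecture import delimit_genome
from p4sat.detection import build_sets, classify_set
from p4sat.model import CANONICAL_ORDER, Component, DetectionConfig, HomologyHit, ValidationError
from p4sat.pangenome import (
    cluster_proteins,
    family_index,
    frequency_spectrum,
    genome_family_sets,
    hypergeom_enrichment_p,
    local_pangenome,
    rarefaction,
    variant_accessory_association,
)

from conftest import build_replicon, place_hits


def hh(q, t, ident, qcov=0.9, tcov=0.9):
    return HomologyHit(query=q, target=t, identity=ident, query_coverage=qcov,
                       target_coverage=tcov, evalue=1e-30, bitscore=100.0)


class TestClustering:
    def test_single_linkage_transitivity(self):
        hits = [hh("A", "B", 0.45), hh("B", "C", 0.45), hh("A", "C", 0.10)]
        fams = cluster_proteins(hits, ["A", "B", "C"])
        assert len(fams) == 1 and fams[0].members == {"A", "B", "C"}

    def test_no_edges_all_singletons(self):
        hits = [hh("A", "B", 0.39)]
        fams = cluster_proteins(hits, ["A", "B", "C"])
        assert sorted(len(f.members) for f in fams) == [1, 1, 1]

    def test_complete_graph_single_family(self):
        prots = [f"p{i}" for i in range(5)]
        hits = [hh(a, b, 1.0) for a in prots for b in prots if a < b]
        fams = cluster_proteins(hits, prots)
        assert len(fams) == 1

    def test_coverage_gate(self):
        hits = [hh("A", "B", 0.9, qcov=0.5)]
        assert len(cluster_proteins(hits, ["A", "B"])) == 2

    def test_partition_property_random_graph(self, rng):
        prots = [f"p{i}" for i in range(40)]
        hits = [
            hh(prots[i], prots[j], float(rng.uniform(0, 1)))
            for i, j in rng.integers(0, 40, size=(120, 2))
            if i != j
        ]
        fams = cluster_proteins(hits, prots)
        all_members = [p for f in fams for p in f.members]
        assert sorted(all_members) == sorted(prots)  # exact partition
        # thresholds out of range collapse to the two extremes
        assert len(cluster_proteins(hits, prots, min_id=1.01)) == len(prots)
        complete = [hh(a, b, 1.0, qcov=1.0, tcov=1.0)
                    for a in prots for b in prots if a < b]
        assert len(cluster_proteins(complete, prots, min_id=0.0)) == 1

    def test_matches_union_find_oracle(self, rng):
        prots = [f"p{i}" for i in range(30)]
        hits = [
            hh(prots[i], prots[j], float(rng.uniform(0.2, 0.8)))
            for i, j in rng.integers(0, 30, size=(80, 2))
            if i != j
        ]
        parent = {p: p for p in prots}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h in hits:
            if h.identity >= 0.4 and min(h.query_coverage, h.target_coverage) >= 0.8:
                parent[find(h.query)] = find(h.target)
        oracle = {}
        for p in prots:
            oracle.setdefault(find(p), set()).add(p)
        got = {frozenset(f.members) for f in cluster_proteins(hits, prots)}
        assert got == {frozenset(s) for s in oracle.values()}


def _corpus(n_genomes=4, shared_family_all=True):
    """Delimited genomes with one shared accessory family and unique ones."""
    genomes, sets, hits, proteins = [], {}, [], []
    for i in range(n_genomes):
        rep = build_replicon(replicon_id=f"R{i}")
        placements = list(zip([5, 7, 8, 9, 11, 13, 15], CANONICAL_ORDER))
        ss, _ = build_sets(place_hits(rep, placements), rep, DetectionConfig())
        classify_set(ss[0])
        g = delimit_genome(ss[0], rep)
        genomes.append(g)
        sets[g.set_id] = ss[0]
        proteins.extend(g.protein_ids)
    # component families across genomes
    for comp_i in [5, 7, 8, 9, 11, 13, 15]:
        members = [f"R{i}_{comp_i:05d}" for i in range(n_genomes)]
        hits += [hh(a, b, 0.8) for a in members for b in members if a < b]
    if shared_family_all:  # the accessory gene at slot 6 shared by all genomes
        members = [f"R{i}_{6:05d}" for i in range(n_genomes)]
        hits += [hh(a, b, 0.9) for a in members for b in members if a < b]
    return genomes, sets, hits, sorted(set(proteins))


class TestSpectrum:
    def test_shared_family_counted_in_all_genomes(self):
        genomes, sets, hits, proteins = _corpus(3)
        fams = cluster_proteins(hits, proteins)
        spectrum = frequency_spectrum(fams, genomes)
        fam_of = family_index(fams)
        shared = fam_of["R0_00006"]
        assert spectrum.counts[shared] == 3

    def test_exclude_core_removes_component_families(self):
        genomes, sets, hits, proteins = _corpus(3)
        fams = cluster_proteins(hits, proteins)
        core = frozenset(
            h.gene.protein_id for s in sets.values() for h in s.members.values()
        )
        spectrum = frequency_spectrum(fams, genomes, exclude_core=True,
                                      core_proteins=core)
        fam_of = family_index(fams)
        core_fams = {fam_of[p] for p in core}
        assert not core_fams & set(spectrum.counts)
        full = frequency_spectrum(fams, genomes)
        assert set(full.counts) - set(spectrum.counts) == core_fams

    def test_planted_histogram(self):
        genomes, sets, hits, proteins = _corpus(3)
        fams = cluster_proteins(hits, proteins)
        spectrum = frequency_spectrum(fams, genomes)
        hist = dict(zip(spectrum.histogram()["genomes"],
                        spectrum.histogram()["n_families"]))
        # 8 shared families (7 components + 1 accessory) in all 3 genomes,
        # the remaining in-span genes are unique singletons
        assert hist[3] == 8
        unique_per_genome = len(genomes[0].protein_ids) - 8
        assert hist[1] == 3 * unique_per_genome


class TestRarefaction:
    def test_identical_genomes_flat_curve(self):
        gf = {f"g{i}": {"f1", "f2"} for i in range(5)}
        curve = rarefaction(gf, n_permutations=10, seed=0)
        assert (curve.curves == 2).all()

    def test_disjoint_genomes_linear_curve(self):
        gf = {f"g{i}": {f"f{i}_a", f"f{i}_b", f"f{i}_c"} for i in range(4)}
        curve = rarefaction(gf, n_permutations=5, seed=0)
        assert (curve.curves == np.arange(3, 13, 3)).all()

    def test_nondecreasing_and_endpoint_invariant(self, rng):
        gf = {
            f"g{i}": {f"f{int(k)}" for k in rng.integers(0, 30, size=8)}
            for i in range(12)
        }
        total = len(set().union(*gf.values()))
        curve = rarefaction(gf, n_permutations=50, seed=1)
        assert (np.diff(curve.curves, axis=1) >= 0).all()
        assert (curve.curves[:, -1] == total).all()

    def test_validation(self):
        with pytest.raises(ValidationError):
            rarefaction({"g": {"f"}}, n_permutations=0)


class TestLocalPangenome:
    def test_hotspot_interval_has_max_count(self):
        genomes, sets, hits, proteins = _corpus(4)
        fam_of = {p: f"F_{p}" for p in proteins}
        table = local_pangenome(genomes, sets, fam_of)
        counts = dict(zip(zip(table.component_a, table.component_b),
                          table.n_families))
        # layout 5,7,8,9,11,13,15: one accessory gene slot in int-psu,
        # sid-alpA, alpA-eps and eps-alpha; none inside the psu-delta-sid operon
        assert counts[("psu", "delta")] == 0 and counts[("delta", "sid")] == 0
        assert counts[("integrase", "psu")] == 4  # unique family per genome
        total = table.n_families.sum()
        assert total == 4 * 4  # 4 accessory slots x 4 genomes, all unique

    def test_no_accessory_genes_all_zero(self):
        rep = build_replicon(replicon_id="RZ")
        ss, _ = build_sets(
            place_hits(rep, list(zip(range(5, 12), CANONICAL_ORDER))),
            rep, DetectionConfig())
        classify_set(ss[0])
        g = delimit_genome(ss[0], rep)
        table = local_pangenome([g], {g.set_id: ss[0]},
                                {p: f"F_{p}" for p in g.protein_ids})
        assert (table.n_families == 0).all()


class TestEnrichment:
    def test_p_equals_direct_hypergeometric_summation(self, rng):
        for _ in range(200):
            big_n = int(rng.integers(2, 60))
            big_k = int(rng.integers(0, big_n + 1))
            n = int(rng.integers(0, big_n + 1))
            k = int(rng.integers(max(0, big_k + n - big_n), min(big_k, n) + 1))
            p = hypergeom_enrichment_p(k, big_k, n, big_n)
            if big_k in (0, big_n) or n in (0, big_n):
                assert p == 1.0
                continue
            direct = sum(
                math.comb(big_k, x) * math.comb(big_n - big_k, n - x)
                for x in range(k, min(big_k, n) + 1)
            ) / math.comb(big_n, n)
            assert p == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_transposition_invariance(self, rng):
        for _ in range(50):
            big_n = int(rng.integers(4, 40))
            big_k = int(rng.integers(1, big_n))
            n = int(rng.integers(1, big_n))
            k = int(rng.integers(max(0, big_k + n - big_n), min(big_k, n) + 1))
            assert hypergeom_enrichment_p(k, big_k, n, big_n) == pytest.approx(
                hypergeom_enrichment_p(k, n, big_k, big_n), rel=1e-9
            )

    def test_exclusive_family_strongly_enriched(self):
        genomes, sets, hits, proteins = _corpus(4)
        # variant labels: first genome TypeB#03-like, rest TypeA (synthetic relabel)
        fam_of = family_index(cluster_proteins(hits, proteins))
        sets[genomes[0].set_id].variant_code = "TypeB#03"
        table = variant_accessory_association(genomes, sets, fam_of)
        assert not table.empty
        # family unique to genome 0 is maximally enriched in its variant
        uniq_fam = fam_of["R0_00010"]
        row = table[(table.variant == "TypeB#03") & (table.family_id == uniq_fam)]
        expected = hypergeom_enrichment_p(1, 1, 1, 4)
        assert row["p"].iloc[0] == pytest.approx(expected)

    def test_uniform_family_not_enriched(self):
        genomes, sets, hits, proteins = _corpus(4)
        fam_of = family_index(cluster_proteins(hits, proteins))
        sets[genomes[0].set_id].variant_code = "TypeB#03"
        table = variant_accessory_association(genomes, sets, fam_of)
        shared = family_index(cluster_proteins(hits, proteins))["R0_00006"]
        rows = table[table.family_id == shared]
        assert (rows["p"] == 1.0).all() and not rows["enriched"].any()

    def test_single_variant_corpus_empty_table(self):
        genomes, sets, hits, proteins = _corpus(3)
        fam_of = family_index(cluster_proteins(hits, proteins))
        table = variant_accessory_association(genomes, sets, fam_of)
        assert table.empty
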