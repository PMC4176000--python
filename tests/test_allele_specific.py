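"""Haplotype assignment, ASE/ASAS tests, bias filters, extrapolation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isohap as ih
from isohap.allele_specific import asas_table, exon_blocks


def _sites(*positions, chrom="chr1"):
    return ih.SiteIndex([
        ih.PhasedSite(chrom, p, "A", "A", "G") for p in positions
    ])


def _frag(calls, junctions=(), chrom="chr1"):
    return ih.fragment_from_positions("f", chrom, dict(calls), junctions)


class TestAssignHaplotype:
    def test_single_maternal_site(self):
        frag = _frag({100: "A", 101: "C"})
        assert ih.assign_haplotype(frag, _sites(100)).status == "maternal"

    def test_single_paternal_site(self):
        frag = _frag({100: "G"})
        assert ih.assign_haplotype(frag, _sites(100)).status == "paternal"

    def test_mixed_sites_conflict(self):
        frag = _frag({100: "A", 200: "G"})
        assert ih.assign_haplotype(frag, _sites(100, 200)).status == \
            "conflicting"

    def test_non_allelic_base_conflicts(self):
        frag = _frag({100: "T"})
        assert ih.assign_haplotype(frag, _sites(100)).status == "conflicting"

    def test_no_covered_site(self):
        frag = _frag({100: "A"})
        assert ih.assign_haplotype(frag, _sites(500)).status == "no_site"

    def test_site_in_uncovered_gap_ignored(self):
        frag = _frag({100: "A", 300: "C"})  # gap covers (101..299)
        assert ih.assign_haplotype(frag, _sites(200)).status == "no_site"


class TestAssignableFraction:
    def test_zero_density_means_zero(self):
        frags = [_frag({i: "A", i + 1: "C"}) for i in range(0, 100, 10)]
        df = ih.assignable_fraction(frags, _sites())
        assert (df.fraction == 0).all()

    def test_stratified_fractions(self):
        assigned = [_frag({100: "A", 101: "C"})] * 3
        unassigned = [_frag({300: "C"})] * 1
        df = ih.assignable_fraction(assigned + unassigned, _sites(100))
        assert df.fraction.iloc[0] == pytest.approx(0.75)


class TestPoissonModel:
    def test_parameter_recovery_within_ten_percent(self, rng):
        lam = 1e-3
        lengths = rng.integers(100, 501, size=10_000)
        y = rng.random(10_000) < -np.expm1(-lam * lengths)
        model = ih.fit_poisson_model(lengths, y)
        assert abs(model.lambda_ - lam) / lam < 0.10

    def test_predict_at_zero_is_zero(self, rng):
        lengths = rng.integers(100, 501, size=200)
        y = rng.random(200) < 0.3
        model = ih.fit_poisson_model(lengths, y)
        assert model.predict(0.0) == 0.0
        assert model.predict(np.inf) == pytest.approx(1.0)

    def test_quarter_at_kilobase_inversion(self):
        lam = -math.log(0.75) / 1000
        model = ih.PoissonAssignmentModel()
        model.lambda_ = lam
        assert float(model.predict(1000)) == pytest.approx(0.25)

    def test_monotone_in_length(self, rng):
        lengths = rng.integers(100, 501, size=500)
        y = rng.random(500) < 0.4
        model = ih.fit_poisson_model(lengths, y)
        grid = model.predict(np.array([75, 150, 262, 524, 1000]))
        assert (np.diff(grid) > 0).all()

    def test_boundary_inputs_flagged(self, rng):
        lengths = rng.integers(100, 501, size=200)
        model = ih.fit_poisson_model(lengths, np.ones(200, dtype=bool))
        assert model.boundary_
        model = ih.fit_poisson_model(lengths, np.zeros(200, dtype=bool))
        assert model.boundary_ and model.lambda_ == 0.0

    def test_needs_enough_fragments(self):
        with pytest.raises(ValueError):
            ih.fit_poisson_model([100] * 50, [True] * 50)

    def test_full_pipeline_recovers_density(self, default_sim):
        """Fitting on simulated fragments returns a rate close to the
        generating het density (exactly equal only in expectation)."""
        cfg, _g, _a, sites, lib = default_sim
        site_index = ih.SiteIndex(sites)
        lengths = [f.effective_length for f in lib.fragments]
        flags = [
            ih.assign_haplotype(f, site_index).assigned
            for f in lib.fragments
        ]
        model = ih.fit_poisson_model(lengths, flags)
        assert 0.1 * cfg.het_density < model.lambda_ < 3 * cfg.het_density


class TestAseTest:
    def test_balanced_counts(self):
        assert ih.ase_test(10, 10) == 1.0

    def test_total_imbalance_closed_form(self):
        assert ih.ase_test(20, 0) == pytest.approx(2 * 0.5 ** 20)

    def test_known_two_sided_value(self):
        assert ih.ase_test(15, 5) == pytest.approx(0.041389, abs=1e-6)

    def test_min_total_exclusion(self):
        assert ih.ase_test(10, 9) is None
        assert ih.ase_test(0, 0) is None

    def test_per_locus_values(self):
        df = ih.per_locus_ase_test({
            ("chr1", 1): (5, 5),
            ("chr1", 2): (12, 0),
        })
        by = df.set_index("pos").p
        assert by[1] == 1.0
        assert by[2] == pytest.approx(2 * 0.5 ** 12)

    def test_per_locus_null_calibration(self, rng):
        m = rng.binomial(30, 0.5, size=500)
        counts = {("chr1", i): (int(k), int(30 - k)) for i, k in enumerate(m)}
        df = ih.per_locus_ase_test(counts)
        frac = (df.p < 0.05).mean()
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 500)


class TestExonBlocks:
    def test_single_isoform_blocks_are_exons(self, make_gene):
        g = make_gene("G1", [[(100, 200), (300, 400)]])
        blocks = exon_blocks(g)
        assert [(b.start, b.end) for b in blocks] == [(100, 200), (300, 400)]

    def test_nested_exon_boundary_projection(self, make_gene):
        g = make_gene("G1", [[(100, 200)], [(150, 200)]])
        blocks = exon_blocks(g)
        assert [(b.start, b.end) for b in blocks] == [(100, 150), (150, 200)]

    def test_blocks_never_cross_boundaries(self, default_sim):
        _cfg, _g, ann, _s, _lib = default_sim
        for gene in ann:
            blocks = exon_blocks(gene)
            boundaries = {
                b for t in gene.transcripts for s, e in t.exons
                for b in (s, e)
            }
            union = gene.exonic_union
            covered = sum(b.end - b.start for b in blocks)
            assert covered == sum(e - s for s, e in union)
            for b in blocks:
                assert not any(b.start < x < b.end for x in boundaries)
            # ordered, disjoint
            for b1, b2 in zip(blocks, blocks[1:]):
                assert b1.end <= b2.start


class TestAsasTest:
    def _calls(self, spec):
        return [ih.HaplotypeCall(s) for s in spec]

    def test_uniform_table_is_null(self):
        block = ih.ExonBlock("G1", 0, 100, 200)
        frags = [_frag({150: "A"})] * 20 + [_frag({300: "A"})] * 20
        calls = self._calls(
            ["maternal"] * 10 + ["paternal"] * 10
            + ["maternal"] * 10 + ["paternal"] * 10
        )
        table, p = ih.asas_test(block, frags, calls, min_total=40)
        assert (table.a, table.b, table.c, table.d) == (10, 10, 10, 10)
        assert p == 1.0

    def test_known_chi_square_value(self):
        block = ih.ExonBlock("G1", 0, 100, 200)
        frags = [_frag({150: "A"})] * 40 + [_frag({300: "A"})] * 40
        calls = self._calls(
            ["maternal"] * 30 + ["paternal"] * 10
            + ["maternal"] * 10 + ["paternal"] * 30
        )
        table, p = ih.asas_test(block, frags, calls, min_total=40)
        assert (table.a, table.b, table.c, table.d) == (30, 10, 10, 30)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_margin_skipped(self):
        block = ih.ExonBlock("G1", 0, 100, 200)
        frags = [_frag({150: "A"})] * 40
        calls = self._calls(["maternal"] * 20 + ["paternal"] * 20)
        _t, p = ih.asas_test(block, frags, calls, min_total=40)
        assert p is None  # no non-overlapping reads

    def test_min_total_enforced(self):
        block = ih.ExonBlock("G1", 0, 100, 200)
        frags = [_frag({150: "A"})] * 10 + [_frag({300: "A"})] * 10
        calls = self._calls(["maternal"] * 10 + ["paternal"] * 10)
        _t, p = ih.asas_test(block, frags, calls, min_total=40)
        assert p is None

    def test_planted_skipping_power(self, rng):
        """Inclusion 0.9 vs 0.1 with 200 reads: p < 1e-6 in >95% of seeds."""
        block = ih.ExonBlock("G1", 0, 100, 200)
        hits = 0
        n_seeds = 40
        for _ in range(n_seeds):
            a = rng.binomial(100, 0.9)
            c = rng.binomial(100, 0.1)
            frags = [_frag({150: "A"})] * (a + c) + \
                [_frag({300: "A"})] * (200 - a - c)
            calls = [ih.HaplotypeCall("maternal")] * a + \
                [ih.HaplotypeCall("paternal")] * c + \
                [ih.HaplotypeCall("maternal")] * (100 - a) + \
                [ih.HaplotypeCall("paternal")] * (100 - c)
            _t, p = ih.asas_test(block, frags, calls, min_total=40)
            hits += p < 1e-6
        assert hits / n_seeds > 0.95


class TestBhFdr:
    def test_step_up_walkthrough(self):
        sig = ih.bh_fdr([0.001, 0.01, 0.2, 0.9], q=0.1)
        assert sig.tolist() == [True, True, False, False]

    def test_all_ones_none_significant(self):
        assert not ih.bh_fdr([1.0] * 10, q=0.1).any()

    def test_all_zeros_all_significant(self):
        assert ih.bh_fdr([0.0] * 10, q=0.1).all()

    def test_empty_input(self):
        assert ih.bh_fdr([], q=0.1).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ih.bh_fdr([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_on_random_vectors(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 60)) ** 2
        ours = ih.bh_fdr(p, q=0.1)
        theirs = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        assert (ours == theirs).all()


class TestAlleleFlip:
    def test_flip_swaps_alleles(self):
        frag = _frag({100: "A", 101: "C"})
        flipped, flagged = ih.allele_flip(frag, _sites(100))
        assert flipped.base_at(100) == "G"
        assert flipped.base_at(101) == "C"
        assert flagged == ()

    def test_involution(self):
        frag = _frag({100: "A", 150: "G", 151: "T"})
        sites = _sites(100, 150)
        once, _ = ih.allele_flip(frag, sites)
        twice, _ = ih.allele_flip(once, sites)
        assert twice.block_seqs == frag.block_seqs

    def test_locality(self, default_sim):
        _cfg, _g, _a, sites, lib = default_sim
        site_index = ih.SiteIndex(sites)
        positions = {s.pos for s in sites}
        flipped_any = 0
        for frag in lib.fragments:
            covered = [p for p in positions if frag.covers(p)]
            if not covered:
                continue
            call = ih.assign_haplotype(frag, site_index)
            flipped, _ = ih.allele_flip(
                frag, site_index,
                call.status if call.assigned else None,
            )
            for pos in frag.positions():
                if pos in positions:
                    continue
                assert flipped.base_at(pos) == frag.base_at(pos)
            flipped_any += 1
            if flipped_any >= 50:
                break
        assert flipped_any == 50

    def test_non_allelic_base_flagged_and_opposed(self):
        frag = _frag({100: "T"})
        flipped, flagged = ih.allele_flip(frag, _sites(100), "maternal")
        assert flagged == (100,)
        assert flipped.base_at(100) == "G"  # paternal allele

    def test_requires_a_covered_site(self):
        with pytest.raises(ValueError):
            ih.allele_flip(_frag({100: "A"}), _sites(500))


class TestRetentionRate:
    def test_unique_locus_retains_everything(self, make_gene, rng):
        from isohap.seq import random_seq

        seq = random_seq(rng, 2000)
        site = ih.PhasedSite("chr1", 500, seq[500], seq[500],
                             "A" if seq[500] != "A" else "C")
        genome = ih.ReferenceGenome({"chr1": seq})
        gene = make_gene("G1", [[(400, 700)]])
        sites = ih.SiteIndex([site])
        frags = [
            ih.fragment_from_positions(
                f"r{i}", "chr1",
                {p: seq[p] for p in range(450, 560)},
            )
            for i in range(10)
        ]
        calls = [ih.assign_haplotype(f, sites) for f in frags]
        assert all(c.status == "maternal" for c in calls)
        aligner = ih.ToyAligner(genome, max_mismatches=4)
        res = ih.retention_rate(gene, frags, calls, sites, aligner.align)
        assert res.rate == 1.0
        assert res.testable

    def test_near_duplicate_locus_loses_flipped_reads(self, make_gene):
        """A duplicate differing only at the het site captures flipped
        reads, so retention drops below 1."""
        from isohap.seq import random_seq

        rng = np.random.default_rng(33)
        core = random_seq(rng, 300)
        # copy B carries 'G' where locus A carries 'A' at offset 150
        locus_a = core[:150] + "A" + core[151:]
        locus_b = core[:150] + "G" + core[151:]
        pad = random_seq(rng, 100)
        seq = locus_a + pad + locus_b
        genome = ih.ReferenceGenome({"chr1": seq})
        gene = make_gene("G1", [[(0, 300)]])
        sites = ih.SiteIndex([ih.PhasedSite("chr1", 150, "A", "A", "G")])
        frags = [
            ih.fragment_from_positions(
                f"r{i}", "chr1",
                {p: seq[p] for p in range(100, 220)},
            )
            for i in range(5)
        ]
        calls = [ih.assign_haplotype(f, sites) for f in frags]
        aligner = ih.ToyAligner(genome, max_mismatches=4)
        res = ih.retention_rate(gene, frags, calls, sites, aligner.align)
        assert res.n_flipped == 5
        assert res.rate < 1.0
        assert not res.testable


class TestFiltersAndEnrichment:
    def test_exclusion_reasons(self):
        counts = {"g1": 100, "g2": 19, "g3": 39, "g4": 100}
        names = {"g1": "HLA-A", "g2": "X", "g3": "Y", "g4": "Z"}
        retention = {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 0.5}
        testable, log = ih.exclusion_filters(
            counts, names, min_reads=20, retention=retention
        )
        assert testable == {"g3"}
        reasons = dict(zip(log.gene_id, log.reasons))
        assert "excluded_name" in reasons["g1"]
        assert "low_count" in reasons["g2"]
        assert "low_retention" in reasons["g4"]
        # the 39-read gene passes ASE (min 20) but fails ASAS (min 40)
        testable_asas, _ = ih.exclusion_filters(
            counts, names, min_reads=40, retention=retention
        )
        assert "g3" not in testable_asas

    def test_enrichment_closed_form(self):
        assert ih.enrichment_test(0, 5, 4, 10) == 1.0
        assert ih.enrichment_test(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_enrichment_matches_enumeration_at_the_mean(self):
        N, K, n = 100, 40, 20
        k = int(n * K / N)  # expected overlap
        p = ih.enrichment_test(k, K, n, N)
        brute = sum(
            math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
            for j in range(k, min(K, n) + 1)
        )
        assert p == pytest.approx(brute)
        assert 0.3 < p < 0.8

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ih.enrichment_test(6, 5, 4, 10)


def test_ase_scan_pools_and_calls(default_sim):
    cfg = ih.SimulationConfig(n_fragments=3000, het_density=3e-3,
                              allelic_ratio={"G0003": 0.95}, seed=17,
                              isoforms_per_gene=(1, 1),
                              duplicate_locus_fraction=0.0)
    _g, ann, sites, lib = ih.simulate(cfg)
    site_index = ih.SiteIndex(sites)
    calls = [ih.assign_haplotype(f, site_index) for f in lib.fragments]
    gene_ids = list(lib.truth.gene_id)
    counts = ih.gene_haplotype_counts(lib.fragments, calls, gene_ids)
    result = ih.ase_scan(counts)
    if "G0003" in set(result.gene_id):
        row = result[result.gene_id == "G0003"].iloc[0]
        frac = row.maternal / (row.maternal + row.paternal)
        assert frac > 0.8
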