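"""Consistent-feature assignment and quantification."""

import numpy as np
import pandas as pd
import pytest

import isohap as ih
from isohap.experiments import brute_force_consistent


@pytest.fixture
def three_isoform_gene(make_gene):
    # shared exon [100,200); isoform-specific structure downstream
    return make_gene("G1", [
        [(100, 200), (300, 400), (500, 600)],
        [(100, 200), (500, 600)],
        [(100, 200), (300, 400)],
    ])


class TestBaseIndex:
    def test_single_exon_gene(self, make_gene, make_annotation):
        ann = make_annotation(make_gene("G1", [[(100, 200)]]))
        idx = ih.build_base_index(ann, "isoform")
        assert idx.features_at("chr1", 100) == {"G1.1"}
        assert idx.features_at("chr1", 199) == {"G1.1"}
        assert idx.features_at("chr1", 200) == frozenset()
        assert idx.features_at("chr1", 99) == frozenset()

    def test_gene_level_covers_introns(self, make_gene, make_annotation):
        ann = make_annotation(make_gene("G1", [[(100, 200), (300, 400)]]))
        idx = ih.build_base_index(ann, "gene")
        assert idx.features_at("chr1", 250) == {"G1"}

    def test_overlapping_genes_share_bases(self, make_gene, make_annotation):
        ann = make_annotation(
            make_gene("G1", [[(100, 300)]]),
            make_gene("G2", [[(250, 400)]]),
        )
        idx = ih.build_base_index(ann, "gene")
        assert idx.features_at("chr1", 260) == {"G1", "G2"}
        assert idx.features_at("chr1", 150) == {"G1"}

    def test_rejects_unknown_level(self, make_annotation):
        with pytest.raises(ValueError):
            ih.build_base_index(make_annotation(), "exon")


class TestConsistentFeatures:
    def test_constitutive_exon_matches_all_isoforms(
        self, three_isoform_gene, make_annotation
    ):
        ann = make_annotation(three_isoform_gene)
        idx = ih.build_base_index(ann, "isoform")
        frag = ih.fragment_from_positions(
            "f", "chr1", {p: "A" for p in range(120, 180)}
        )
        a = ih.consistent_features(frag, idx, ann)
        assert a.consistent_features == {"G1.1", "G1.2", "G1.3"}
        assert not a.unambiguous

    def test_junction_restricts_to_one_isoform(
        self, three_isoform_gene, make_annotation
    ):
        ann = make_annotation(three_isoform_gene)
        idx = ih.build_base_index(ann, "isoform")
        # spliced read over the exon-skipping junction (200, 500)
        calls = {p: "A" for p in list(range(180, 200)) + list(range(500, 520))}
        frag = ih.fragment_from_positions("f", "chr1", calls, [(200, 500)])
        a = ih.consistent_features(frag, idx, ann)
        assert a.consistent_features == {"G1.2"}
        assert a.unambiguous

    def test_unknown_junction_means_unassigned(
        self, three_isoform_gene, make_annotation
    ):
        ann = make_annotation(three_isoform_gene)
        idx = ih.build_base_index(ann, "isoform")
        calls = {p: "A" for p in list(range(180, 200)) + list(range(510, 530))}
        frag = ih.fragment_from_positions("f", "chr1", calls, [(200, 510)])
        assert ih.consistent_features(frag, idx, ann).unassigned

    def test_intergenic_fragment_unassigned(
        self, three_isoform_gene, make_annotation
    ):
        ann = make_annotation(three_isoform_gene)
        idx = ih.build_base_index(ann, "isoform")
        frag = ih.fragment_from_positions(
            "f", "chr1", {p: "A" for p in range(700, 760)}
        )
        assert ih.consistent_features(frag, idx, ann).unassigned

    def test_bases_outside_annotation_do_not_veto(
        self, three_isoform_gene, make_annotation
    ):
        ann = make_annotation(three_isoform_gene)
        idx = ih.build_base_index(ann, "isoform")
        calls = {p: "A" for p in range(150, 230)}  # runs past exon end
        frag = ih.fragment_from_positions("f", "chr1", calls)
        a = ih.consistent_features(frag, idx, ann)
        assert a.consistent_features == {"G1.1", "G1.2", "G1.3"}

    def test_agrees_with_brute_force_oracle(self, default_sim):
        _cfg, _g, annotation, _s, lib = default_sim
        idx = ih.build_base_index(annotation, "isoform")
        for frag in lib.fragments[:300]:
            fast = ih.consistent_features(frag, idx, annotation)
            slow = brute_force_consistent(frag, annotation, "isoform")
            assert fast.consistent_features == slow

    def test_monotone_in_covered_bases(self, default_sim):
        """A sub-fragment's consistent set contains the full fragment's."""
        _cfg, _g, annotation, _s, lib = default_sim
        idx = ih.build_base_index(annotation, "isoform")
        for frag in lib.fragments[:100]:
            full = ih.consistent_features(frag, idx, annotation)
            if frag.effective_length < 40:
                continue
            s, e = frag.blocks[0]
            e = min(e, s + 30)
            sub = ih.fragment_from_positions(
                frag.name, frag.chrom,
                {p: frag.base_at(p) for p in range(s, e)},
            )
            subset = ih.consistent_features(sub, idx, annotation)
            if not full.unassigned:
                assert full.consistent_features <= subset.consistent_features


class TestConsistencyDistribution:
    def test_single_isoform_annotation_is_all_unambiguous(self):
        cfg = ih.SimulationConfig(n_fragments=200, isoforms_per_gene=(1, 1),
                                  duplicate_locus_fraction=0.0, seed=13)
        _g, ann, _s, lib = ih.simulate(cfg)
        idx = ih.build_base_index(ann, "isoform")
        assignments = ih.assign_fragments(lib.fragments, idx, ann)
        df = ih.consistency_distribution(lib.fragments, assignments)
        assert df[df["size"] == 1].cum_fraction.iloc[0] == 1.0
        assert ih.unambiguous_rate(assignments) == 1.0

    def test_longer_strata_are_less_ambiguous(self, default_sim):
        _cfg, _g, ann, _s, lib = default_sim
        idx = ih.build_base_index(ann, "isoform")
        assignments = ih.assign_fragments(lib.fragments, idx, ann)
        df = ih.consistency_distribution(
            lib.fragments, assignments, strata_edges=[260]
        )
        lo = df[(df.stratum == "[0,260)") & (df["size"] == 1)]
        hi = df[(df.stratum == ">=260") & (df["size"] == 1)]
        assert hi.cum_fraction.iloc[0] > lo.cum_fraction.iloc[0]


class TestGeneQuantification:
    def test_fractions_normalize(self):
        a = [ih.FeatureAssignment(frozenset({"G1"}))] * 75 + \
            [ih.FeatureAssignment(frozenset({"G2"}))] * 25 + \
            [ih.FeatureAssignment(frozenset({"G1", "G2"}))] * 10
        df = ih.gene_read_fractions(a)
        by = df.set_index("gene_id")
        assert by.loc["G1", "fraction"] == pytest.approx(0.75)
        assert by.loc["G2", "fraction"] == pytest.approx(0.25)
        assert df["fraction"].sum() == pytest.approx(1.0)

    def test_min_fraction_flags_unobserved(self):
        df = ih.gene_read_fractions(
            [ih.FeatureAssignment(frozenset({"G1"}))] * 999999
            + [ih.FeatureAssignment(frozenset({"G2"}))]
        )
        by = df.set_index("gene_id")
        assert bool(by.loc["G1", "observed"])
        assert by.loc["G2", "fraction"] == pytest.approx(1e-6)

    def test_fold_change_flags(self):
        df = ih.fold_change_flags(
            {"A": 1e-3, "B": 0.5, "C": 0.2},
            {"A": 1e-5, "B": 0.5, "C": 0.2 / 15},
            fold=10,
        )
        by = df.set_index("gene_id").flag
        assert by["A"] == "A-enriched"
        assert by["B"] == "neither"
        assert by["C"] == "A-enriched"

    def test_planted_pseudogene_fraction(self):
        cfg = ih.SimulationConfig(n_fragments=2000,
                                  pseudogene_expression=0.05, seed=14)
        _g, ann, _s, lib = ih.simulate(cfg)
        idx = ih.build_base_index(ann, "gene")
        assignments = ih.assign_fragments(lib.fragments, idx)
        bt = ih.biotype_breakdown(assignments, ann)
        assert bt.sum() == pytest.approx(1.0)
        sd = (0.05 * 0.95 / 2000) ** 0.5
        assert abs(bt.get("pseudogene", 0.0) - 0.05) < 4 * sd


class TestMappability:
    def test_group_sizes_differ_by_at_most_one(self, default_sim):
        _cfg, genome, ann, _s, lib = default_sim
        genes = [g for g in ann]
        scores = {g.id: 1.0 for g in genes}
        frac = {g.id: 0.1 for g in genes}
        frac_b = {g.id: 0.2 for g in genes}
        df = ih.mappability_stratify(genes, scores, frac, frac_b, n_groups=5)
        assert df.n_genes.max() - df.n_genes.min() <= 1
        assert df.n_genes.sum() == len(genes)

    def test_length_weighted_mean_score(self, make_gene):
        g = make_gene("G1", [[(0, 100)]])
        track = [("chr1", 0, 50, 1.0), ("chr1", 50, 100, 0.5)]
        scores = ih.gene_mean_mappability([g], track)
        assert scores["G1"] == pytest.approx(0.75)

    def test_gene_without_track_coverage_scores_zero(self, make_gene):
        g = make_gene("G1", [[(1000, 1100)]])
        scores = ih.gene_mean_mappability([g], [("chr1", 0, 50, 1.0)])
        assert scores["G1"] == 0.0


class TestUniqueBases:
    def test_single_isoform_gene_is_fully_unique(self, make_gene):
        g = make_gene("G1", [[(0, 100), (200, 260)]])
        assert ih.unique_bases(g.transcripts[0], g) == 160

    def test_identical_isoforms_have_none(self, make_gene):
        g = make_gene("G1", [[(0, 100)], [(0, 100)]])
        for t in g.transcripts:
            assert ih.unique_bases(t, g) == 0

    def test_skipped_exon_pair(self, make_gene):
        g = make_gene("G1", [
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
        ])
        inclusion, exclusion = g.transcripts
        assert ih.unique_bases(inclusion, g) == 100  # the skipped exon
        assert ih.unique_bases(exclusion, g) == 0  # junction-only evidence

    def test_matches_per_base_brute_force(self, default_sim):
        _cfg, _g, ann, _s, _lib = default_sim
        for gene in ann:
            for t in gene.transcripts:
                own = {p for s, e in t.exons for p in range(s, e)}
                others = {
                    p for sib in gene.transcripts if sib.id != t.id
                    for s, e in sib.exons for p in range(s, e)
                }
                assert ih.unique_bases(t, gene) == len(own - others)


class TestTranscriptAbundance:
    def test_count_over_unique_bases(self, make_gene, make_annotation):
        g = make_gene("G1", [
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
        ])
        ann = make_annotation(g)
        a = [ih.FeatureAssignment(frozenset({"G1.1"}))] * 50
        df = ih.transcript_abundance(a, ann, min_unique=10)
        by = df.set_index("transcript_id")
        assert by.loc["G1.1", "abundance"] == pytest.approx(50 / 100)
        # exclusion isoform has 0 unique bases -> filtered out
        assert "G1.2" not in by.index

    def test_min_unique_threshold(self, make_gene, make_annotation):
        g = make_gene("G1", [
            [(0, 100), (200, 209)],  # 9 unique bases
            [(0, 100)],
        ])
        ann = make_annotation(g)
        df = ih.transcript_abundance([], ann, min_unique=10)
        assert "G1.1" not in set(df.transcript_id)

    def test_single_isoform_genes_excluded_by_default(
        self, make_gene, make_annotation
    ):
        ann = make_annotation(make_gene("G1", [[(0, 100)]]))
        assert len(ih.transcript_abundance([], ann)) == 0

    def test_tracks_truth_on_simulated_data(self):
        cfg = ih.SimulationConfig(n_fragments=4000, isoforms_per_gene=(2, 3),
                                  duplicate_locus_fraction=0.0,
                                  het_density=0.0, seed=15)
        _g, ann, _s, lib = ih.simulate(cfg)
        idx = ih.build_base_index(ann, "isoform")
        assignments = ih.assign_fragments(lib.fragments, idx, ann)
        df = ih.transcript_abundance(assignments, ann, min_unique=10)
        truth_counts = lib.truth.transcript_id.value_counts()
        df = df[df["count"] >= 5]
        merged = df.assign(truth=df.transcript_id.map(truth_counts)).dropna()
        assert len(merged) >= 5
        from scipy.stats import spearmanr

        rho = spearmanr(merged["abundance"] * merged["unique_bases"],
                        merged["truth"]).statistic
        assert rho > 0.6


class TestAmbiguityAndEstimatorComparison:
    def test_ambiguity_rate_counts(self, make_gene, make_annotation):
        g = make_gene("G1", [[(0, 100), (200, 300)], [(0, 100)]])
        ann = make_annotation(g)
        a = [ih.FeatureAssignment(frozenset({"G1.1"}))] * 7 + \
            [ih.FeatureAssignment(frozenset({"G1.1", "G1.2"}))] * 3
        assert ih.ambiguity_rate(g, a, ann) == pytest.approx(0.3)
        assert ih.ambiguity_rate(g, [], ann) is None
        assert ih.ambiguity_rate(
            g, [ih.FeatureAssignment(frozenset({"G1.1"}))], ann
        ) == 0.0

    def test_spearman_limits_and_known_value(self):
        gene_of = {f"T{i}": f"G{i}" for i in range(4)}
        amb = {f"G{i}": 0.0 for i in range(4)}
        internal = {f"T{i}": float(i + 1) for i in range(4)}
        same = ih.compare_abundance_estimates(
            internal, internal, gene_of, amb, thresholds=[1.0]
        )
        assert same.rho.iloc[0] == pytest.approx(1.0)
        reverse = {f"T{i}": float(4 - i) for i in range(4)}
        rev = ih.compare_abundance_estimates(
            reverse, internal, gene_of, amb, thresholds=[1.0]
        )
        assert rev.rho.iloc[0] == pytest.approx(-1.0)
        swapped = {"T0": 1.0, "T1": 2.0, "T2": 4.0, "T3": 3.0}
        near = ih.compare_abundance_estimates(
            swapped, internal, gene_of, amb, thresholds=[1.0]
        )
        assert near.rho.iloc[0] == pytest.approx(0.8)

    def test_too_few_shared_transcripts_is_nan(self):
        df = ih.compare_abundance_estimates(
            {"T0": 1.0}, {"T0": 1.0}, {"T0": "G0"}, {"G0": 0.0},
            thresholds=[1.0],
        )
        assert np.isnan(df.rho.iloc[0])

    def test_correlation_difference_bootstrap(self, rng):
        gene_of = {f"T{i}": f"G{i}" for i in range(30)}
        truth = {f"T{i}": float(i) for i in range(30)}
        good = {t: v + rng.normal(0, 1) for t, v in truth.items()}
        bad = {t: float(rng.normal()) for t in truth}
        diff, p = ih.compare_abundance_estimates, None
        from isohap.feature_assignment import correlation_difference_test

        observed, p = correlation_difference_test(
            good, bad, truth, gene_of, n_boot=300, seed=0
        )
        assert observed > 0.5
        assert p < 0.05
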