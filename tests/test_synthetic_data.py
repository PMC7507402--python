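"""Generators: determinism, invariants, planted-truth closure, calibration."""

import numpy as np
import pandas as pd
import pytest

from bypassnet import synthetic_data as sd
from bypassnet.enrichment_stats import compare_gene_properties
from bypassnet.functional_standards import relatedness_vector


class TestGenome:
    def test_essential_fraction_within_one_gene(self):
        genes, _ = sd.generate_genome(n_genes=6000, frac_essential=0.18, seed=0)
        assert abs(genes["essential"].sum() - 1080) <= 1

    def test_same_seed_is_byte_identical(self):
        a = sd.generate_genome(n_genes=500, n_chromosomes=6,
                               genome_bp=3_000_000, seed=42)
        b = sd.generate_genome(n_genes=500, n_chromosomes=6,
                               genome_bp=3_000_000, seed=42)
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_one_gene_per_chromosome_degenerate_case(self):
        genes, chroms = sd.generate_genome(
            n_genes=16, n_chromosomes=16, genome_bp=1_600_000, seed=1
        )
        assert len(genes) == 16
        assert genes["chromosome"].nunique() == 16
        assert (genes["start_bp"] < genes["end_bp"]).all()
        assert genes["gene_id"].is_unique

    def test_invariants_hold(self):
        genes, chroms = sd.generate_genome(
            n_genes=800, n_chromosomes=8, genome_bp=4_000_000, seed=3
        )
        lengths = dict(zip(chroms["chromosome"], chroms["length_bp"]))
        # unequal, size-ordered chromosomes
        assert list(chroms["length_bp"]) == sorted(chroms["length_bp"], reverse=True)
        assert chroms["length_bp"].nunique() == len(chroms)
        for chrom, sub in genes.groupby("chromosome"):
            sub = sub.sort_values("start_bp")
            assert (sub["end_bp"] <= lengths[chrom]).all()
            # non-overlapping, sorted
            assert (sub["start_bp"].to_numpy()[1:]
                    >= sub["end_bp"].to_numpy()[:-1]).all()
        assert genes["rdna"].sum() == 1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sd.generate_genome(n_genes=5, n_chromosomes=10)
        with pytest.raises(ValueError):
            sd.generate_genome(n_genes=0, n_chromosomes=0)


class TestCompendium:
    def test_zero_density_means_no_coexpression(self, small_genome):
        comp = sd.generate_compendium(
            small_genome[0], n_complexes=40, n_pathways=20,
            coexpr_density=0.0, seed=2,
        )
        assert len(comp.coexpression) == 0

    def test_single_minimal_complex_forces_three_pairs(self, small_genome):
        comp = sd.generate_compendium(
            small_genome[0], n_complexes=1, complex_size_mean=3.0, seed=7,
        )
        # exactly one complex; all its member pairs are cocomplex-true
        (members,) = comp.complexes.values()
        pairs = [(a, b) for i, a in enumerate(sorted(members))
                 for b in sorted(members)[i + 1:]]
        for a, b in pairs:
            assert relatedness_vector(a, b, comp).cocomplex is True

    def test_determinism(self, small_genome):
        a = sd.generate_compendium(small_genome[0], n_complexes=40,
                                   n_pathways=20, seed=9)
        b = sd.generate_compendium(small_genome[0], n_complexes=40,
                                   n_pathways=20, seed=9)
        assert a.complexes == b.complexes
        assert a.coexpression == b.coexpression
        assert a.localization == b.localization

    def test_too_many_complexes_rejected(self, small_genome):
        with pytest.raises(ValueError):
            sd.generate_compendium(small_genome[0], n_complexes=10_000)


class TestSuppressionStudy:
    def test_truth_closure(self, small_genome, small_compendium):
        genes, _ = small_genome
        _, variants, experiments, truth = sd.generate_suppression_study(
            genes, small_compendium, n_queries=50, frac_dispensable=0.5, seed=11
        )
        universe = set(genes["gene_id"])
        for st in truth.strains.values():
            assert st.query_gene in universe
            for g in st.true_suppressor_genes:
                assert g in universe
            if st.mechanism == "snp":
                planted_genes = {v["gene_id"] for v in st.planted_variants
                                 if v["nonsynonymous"]}
                assert set(st.true_suppressor_genes) & planted_genes
        # every logged suppressor resolves
        sups = experiments["suppressor_gene"].dropna()
        assert set(sups) <= universe

    def test_zero_passengers_leaves_only_planted_variant(self, small_genome,
                                                         small_compendium):
        genes, _ = small_genome
        _, variants, _, truth = sd.generate_suppression_study(
            genes, small_compendium, n_queries=40, frac_dispensable=1.0,
            passenger_rate=0.0, mechanism_mix={"snp": 1.0}, seed=12,
        )
        per_strain = variants.groupby("strain_id").size()
        assert (per_strain == 1).all()
        for sid, st in truth.strains.items():
            v = variants.loc[variants["strain_id"] == sid].iloc[0]
            assert v["gene_id"] == st.true_suppressor_genes[0]

    def test_wgd_only_mix(self, small_genome, small_compendium):
        genes, _ = small_genome
        strains, _, _, truth = sd.generate_suppression_study(
            genes, small_compendium, n_queries=30, frac_dispensable=1.0,
            mechanism_mix={"wgd": 1.0}, seed=13,
        )
        assert (strains["ploidy"] == 2).all()
        for st in truth.strains.values():
            assert st.true_suppressor_genes == []
            assert not any(v["nonsynonymous"] and v["gene_id"] in
                           st.true_suppressor_genes
                           for v in st.planted_variants)

    def test_aneuploidy_mechanism_plants_disomy(self, small_genome,
                                                small_compendium):
        genes, _ = small_genome
        gene_chrom = dict(zip(genes["gene_id"], genes["chromosome"]))
        _, _, _, truth = sd.generate_suppression_study(
            genes, small_compendium, n_queries=30, frac_dispensable=1.0,
            mechanism_mix={"aneuploidy": 1.0}, seed=14,
        )
        for st in truth.strains.values():
            sup = st.true_suppressor_genes[0]
            assert st.copy_numbers[gene_chrom[sup]] == 2
            assert st.ploidy == 1

    def test_empty_compendium_with_coupling_rejected(self, small_genome):
        from bypassnet.functional_standards import FunctionalCompendium
        with pytest.raises(ValueError):
            sd.generate_suppression_study(
                small_genome[0], FunctionalCompendium(), n_queries=5,
                functional_coupling=0.5,
            )

    def test_marginal_calibration_over_seeds(self, small_genome,
                                             small_compendium):
        # realized dispensable fraction and per-strain variant medians track
        # the requested parameters within 2 standard errors over many seeds
        genes, _ = small_genome
        frac = 0.17
        n_queries = 40
        realized, medians, aneuploid = [], [], []
        for seed in range(100):
            strains, variants, _, truth = sd.generate_suppression_study(
                genes, small_compendium, n_queries=n_queries,
                frac_dispensable=frac, seed=seed,
            )
            realized.append(len(truth.dispensable_queries) / n_queries)
            if len(variants):
                per_strain = variants.loc[variants["nonsynonymous"]].groupby(
                    "strain_id").size()
                medians.append(float(per_strain.median()))
            changed = [s.mechanism != "snp" for s in truth.strains.values()]
            if changed:
                aneuploid.append(np.mean(changed))
        se = np.sqrt(frac * (1 - frac) / n_queries) / np.sqrt(len(realized))
        assert abs(np.mean(realized) - frac) <= 2 * se
        # a median of 2-3 unique nonsynonymous variants per strain
        assert 2.0 <= np.mean(medians) <= 3.0
        # ~49% of strains carry genome-content changes
        se_mech = np.std(aneuploid, ddof=1) / np.sqrt(len(aneuploid))
        assert abs(np.mean(aneuploid) - 0.49) <= max(2 * se_mech, 0.02)


class TestDepthProfiles:
    @pytest.fixture()
    def disomy_truth(self, small_genome, small_compendium):
        genes, chroms = small_genome
        _, _, _, truth = sd.generate_suppression_study(
            genes, small_compendium, n_queries=20, frac_dispensable=1.0,
            mechanism_mix={"aneuploidy": 1.0}, seed=21,
        )
        return truth, chroms

    def test_noise_free_disomy_is_exactly_double(self, disomy_truth,
                                                 small_genome):
        truth, chroms = disomy_truth
        depth = sd.generate_depth_profiles(truth, chroms, noise_cv=0.0, seed=0)
        sid, st = next(iter(truth.strains.items()))
        gene_chrom = dict(zip(small_genome[0]["gene_id"],
                              small_genome[0]["chromosome"]))
        c = gene_chrom[st.true_suppressor_genes[0]]
        prof = depth.loc[depth["strain_id"] == sid]
        on = prof.loc[prof["chromosome"] == c, "depth"]
        off = prof.loc[prof["chromosome"] != c, "depth"]
        assert (on == 2 * off.iloc[0]).all()
        assert off.nunique() == 1

    def test_partial_segment_elevates_expected_bin_count(self):
        truth = sd.SyntheticTruth()
        truth.strains["s1"] = sd.StrainTruth(
            strain_id="s1", query_gene="q", true_suppressor_genes=["g"],
            mechanism="partial_amplification", ploidy=1,
            copy_numbers={1: 1}, partial_segments=[(1, 100_000, 200_000, 2)],
            planted_variants=[], coupling_tier=None, fitness=1.0,
        )
        chroms = pd.DataFrame({"chromosome": [1], "length_bp": [500_000]})
        depth = sd.generate_depth_profiles(
            truth, chroms, bin_bp=10_000, noise_cv=0.0, seed=0
        )
        elevated = depth.loc[depth["depth"] > depth["depth"].min()]
        assert len(elevated) == int(np.ceil(100_000 / 10_000))

    def test_bin_larger_than_smallest_chromosome_rejected(self, disomy_truth):
        truth, chroms = disomy_truth
        with pytest.raises(ValueError):
            sd.generate_depth_profiles(truth, chroms, bin_bp=10**9)


class TestFeatureTable:
    def test_planted_paralog_rates_detectable(self, small_genome):
        genes, _ = sd.generate_genome(
            n_genes=4000, n_chromosomes=8, genome_bp=8_000_000,
            frac_essential=0.5, seed=31,
        )
        table, _ = sd.generate_feature_table(
            genes, n_dispensable=300, n_indispensable=300, seed=31
        )
        disp = table.loc[table["label"] == "dispensable"]
        indisp = table.loc[table["label"] == "indispensable"]
        out = compare_gene_properties(
            disp, indisp, binary_features=["has_paralog"],
            continuous_features=["coexpression_degree"],
        ).set_index("feature")
        assert out.loc["has_paralog", "p_value"] < 1e-4
        assert out.loc["has_paralog", "direction"] == 1
        assert out.loc["coexpression_degree", "direction"] == -1

    def test_zero_effect_controls_stay_null(self, small_genome):
        genes, _ = sd.generate_genome(
            n_genes=4000, n_chromosomes=8, genome_bp=8_000_000,
            frac_essential=0.5, seed=33,
        )
        table, _ = sd.generate_feature_table(
            genes, n_dispensable=300, n_indispensable=300, seed=33
        )
        disp = table.loc[table["label"] == "dispensable"]
        indisp = table.loc[table["label"] == "indispensable"]
        out = compare_gene_properties(
            disp, indisp, continuous_features=["control_continuous"]
        )
        assert abs(out.loc[0, "auroc"] - 0.5) < 0.05

    def test_unknown_feature_kind_rejected(self, small_genome):
        with pytest.raises(ValueError):
            sd.generate_feature_table(
                small_genome[0], planted_effects={"bad": {"kind": "mystery"}}
            )

    def test_determinism(self, small_genome):
        a, _ = sd.generate_feature_table(small_genome[0], seed=8)
        b, _ = sd.generate_feature_table(small_genome[0], seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestSpeciesPanel:
    def test_no_absence_when_probability_zero(self, small_genome):
        orth, _, _ = sd.generate_species_panel(
            small_genome[0],
            status_probs={"dispensable": (0, 0.5, 0.5),
                          "indispensable": (0, 0.5, 0.5)},
            seed=41,
        )
        assert set(orth["status"]) <= {"duplicated", "one_to_one"}

    def test_planted_indispensable_like_classified(self, small_genome):
        from bypassnet.dispensability import classify_cell_line_essentiality
        genes = small_genome[0]
        essential = genes.loc[genes["essential"], "gene_id"].tolist()
        planted = essential[:20]
        _, ceres, truth = sd.generate_species_panel(
            genes, indispensable_like=planted, n_cell_lines=100, seed=42
        )
        out = classify_cell_line_essentiality(ceres)
        assert (out.loc[planted, "class"] == "indispensable").all()
        others = out.drop(index=planted)
        assert not (others["class"] == "indispensable").any()

    def test_determinism(self, small_genome):
        a = sd.generate_species_panel(small_genome[0], n_cell_lines=20, seed=5)
        b = sd.generate_species_panel(small_genome[0], n_cell_lines=20, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestScreenGenerator:
    def test_zero_effect_gives_no_expected_shift(self):
        df, _ = sd.generate_overexpression_screen(
            "Q", [f"g{i}" for i in range(20)], "g3", effect_size=0.0,
            noise_sd=0.05, seed=6,
        )
        genes = df.loc[~df["is_empty_vector"]]
        means = genes.groupby("array_gene")["colony_size"].mean()
        assert (means - 1.0).abs().max() < 0.1

    def test_vanishing_noise_isolates_suppressor_and_flyers(self):
        df, _ = sd.generate_overexpression_screen(
            "Q", [f"g{i}" for i in range(20)], "g3", effect_size=0.5,
            noise_sd=1e-9, frequent_flyer_genes=["FLY"], seed=6,
        )
        genes = df.loc[~df["is_empty_vector"]]
        means = genes.groupby("array_gene")["colony_size"].mean()
        elevated = set(means.index[means > 1.25])
        assert elevated == {"g3", "FLY"}

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_overexpression_screen("Q", ["g"], None, effect_size=-1)

    def test_stable_keyed_substreams(self, small_genome, small_compendium):
        # generating a superset of queries leaves shared queries untouched
        genes, _ = small_genome
        essential = genes.loc[genes["essential"], "gene_id"]
        _, v1, e1, t1 = sd.generate_suppression_study(
            genes, small_compendium, n_queries=20, frac_dispensable=0.6, seed=77
        )
        _, v2, e2, t2 = sd.generate_suppression_study(
            genes, small_compendium, n_queries=40, frac_dispensable=0.6, seed=77
        )
        shared = set(e1["query_gene"]) & set(e2["query_gene"])
        assert shared
        for q in shared:
            a = e1.loc[e1["query_gene"] == q, ["outcome", "suppressor_gene"]]
            b = e2.loc[e2["query_gene"] == q, ["outcome", "suppressor_gene"]]
            assert a.reset_index(drop=True).equals(b.reset_index(drop=True))
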