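"""Copy-number calling, segmentation, genome size, variant filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bypassnet.functional_standards import FunctionalCompendium
from bypassnet.genome_calls import (
    AmplifiedSegment,
    StrainCall,
    call_chromosome_copy_numbers,
    compute_genome_size,
    detect_linkage_locus,
    filter_recurrent_variants,
    nominate_suppressor_candidates,
    segment_partial_amplifications,
)


def flat_profile(depths_per_chrom: dict[int, float], n_bins: int = 20,
                 bin_bp: int = 10_000) -> pd.DataFrame:
    rows = []
    for chrom, depth in depths_per_chrom.items():
        for i in range(n_bins):
            rows.append(
                {"chromosome": chrom, "bin_start": i * bin_bp,
                 "bin_end": (i + 1) * bin_bp, "depth": depth}
            )
    return pd.DataFrame(rows)


class TestCopyNumberCalls:
    def test_disomy_in_haploid_doubles_depth(self):
        # 2x depth on one chromosome of a haploid -> copy 2
        prof = flat_profile({1: 30, 2: 30, 3: 60})
        calls = call_chromosome_copy_numbers(prof, ploidy=1)
        assert calls.loc[3, "copy_number"] == 2
        assert calls.loc[3, "aneuploid"]
        assert list(calls.loc[[1, 2], "copy_number"]) == [1, 1]

    def test_trisomy_in_diploid_is_1_5x(self):
        prof = flat_profile({1: 30, 2: 30, 3: 45})
        calls = call_chromosome_copy_numbers(prof, ploidy=2)
        assert calls.loc[3, "copy_number"] == 3

    def test_euploid_ratio_one_any_ploidy(self):
        prof = flat_profile({1: 30, 2: 30})
        for ploidy in (1, 2, 3):
            calls = call_chromosome_copy_numbers(prof, ploidy)
            assert (calls["copy_number"] == ploidy).all()
            assert not calls["aneuploid"].any()

    def test_low_confidence_flag_and_tie_rounds_up(self):
        # ratio * ploidy = 1.5 exactly: rounds up to 2, flagged low-confidence
        prof = flat_profile({1: 30, 2: 30, 3: 30, 4: 45})
        calls = call_chromosome_copy_numbers(prof, ploidy=1)
        assert calls.loc[4, "copy_number"] == 2
        assert calls.loc[4, "low_confidence"]
        assert not calls.loc[1, "low_confidence"]

    def test_all_zero_depth_is_degenerate(self):
        prof = flat_profile({1: 0, 2: 0})
        with pytest.raises(ValueError):
            call_chromosome_copy_numbers(prof, ploidy=1)


def brute_force_two_changepoint(y: np.ndarray):
    """Oracle: exhaustive least-squares search over all (i, j) segmentations."""
    best, best_cost = None, np.inf
    n = len(y)
    for i, j in itertools.combinations(range(1, n), 2):
        cost = sum(
            float(((seg - seg.mean()) ** 2).sum())
            for seg in (y[:i], y[i:j], y[j:])
        )
        if cost < best_cost - 1e-12:
            best, best_cost = (i, j), cost
    return best


class TestSegmentation:
    def test_noise_free_planted_segment_recovered_exactly(self):
        prof = flat_profile({1: 30, 2: 30, 3: 30}, n_bins=60)
        mask = (prof["chromosome"] == 2) & (prof["bin_start"] >= 200_000) & (
            prof["bin_start"] < 400_000
        )
        prof.loc[mask, "depth"] = 60.0
        segs = segment_partial_amplifications(prof, 2, ploidy=1)
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_bp, seg.end_bp, seg.copy_number) == (200_000, 400_000, 2)
        # agrees with the exhaustive two-changepoint oracle
        y = prof.loc[prof["chromosome"] == 2, "depth"].to_numpy()
        i, j = brute_force_two_changepoint(y)
        assert (i * 10_000, j * 10_000) == (seg.start_bp, seg.end_bp)

    def test_flat_chromosome_yields_no_segments(self):
        prof = flat_profile({1: 30, 2: 30}, n_bins=50)
        assert segment_partial_amplifications(prof, 1, ploidy=1) == []

    def test_whole_chromosome_gain_is_not_a_segment(self):
        prof = flat_profile({1: 30, 2: 30, 3: 60}, n_bins=50)
        assert segment_partial_amplifications(prof, 3, ploidy=1) == []

    def test_noisy_flat_chromosomes_rarely_segment(self):
        rng = np.random.default_rng(5)
        false_calls = 0
        for _ in range(100):
            prof = flat_profile({1: 30, 2: 30, 3: 30}, n_bins=40)
            prof["depth"] *= rng.normal(1, 0.1, size=len(prof))
            false_calls += bool(segment_partial_amplifications(prof, 2, ploidy=1))
        assert false_calls <= 1

    def test_min_bins_larger_than_chromosome_rejected(self):
        prof = flat_profile({1: 30, 2: 30}, n_bins=5)
        with pytest.raises(ValueError):
            segment_partial_amplifications(prof, 1, ploidy=1, min_bins=10)


class TestGenomeSize:
    lengths = {c: 750_000 for c in range(1, 17)}

    def test_whole_chromosome_gain_arithmetic(self):
        lengths = dict(self.lengths)
        lengths[16] = 500_000
        lengths[1] = 1_000_000  # total 12.0 Mb
        copies = {c: 1 for c in lengths}
        copies[16] = 2
        call = StrainCall("s", ploidy=1, copy_numbers=copies)
        assert compute_genome_size(call, lengths) == 12_500_000

    def test_partial_segment_adds_extra_copies(self):
        copies = {c: 1 for c in self.lengths}
        call = StrainCall(
            "s", 1, copies,
            partial_amplifications=[AmplifiedSegment(3, 100_000, 200_000, 2)],
        )
        base = sum(self.lengths.values())
        assert compute_genome_size(call, self.lengths) == base + 100_000

    def test_rdna_flagged_amplification_ignored(self):
        copies = {c: 1 for c in self.lengths}
        call = StrainCall(
            "s", 1, copies,
            partial_amplifications=[AmplifiedSegment(12, 100_000, 200_000, 3)],
        )
        size = compute_genome_size(
            call, self.lengths, excluded_regions=[(12, 150_000, 160_000)]
        )
        assert size == sum(self.lengths.values())

    def test_additivity_over_independent_gains(self):
        copies = {c: 1 for c in self.lengths}
        segs = [
            AmplifiedSegment(2, 0, 50_000, 2),
            AmplifiedSegment(5, 100_000, 300_000, 3),
        ]
        base = compute_genome_size(StrainCall("s", 1, dict(copies)), self.lengths)
        total = compute_genome_size(
            StrainCall("s", 1, dict(copies), partial_amplifications=segs),
            self.lengths,
        )
        gains = sum(
            compute_genome_size(
                StrainCall("s", 1, dict(copies), partial_amplifications=[s]),
                self.lengths,
            )
            - base
            for s in segs
        )
        assert total == base + gains

    def test_segment_outside_chromosome_rejected(self):
        call = StrainCall(
            "s", 1, {1: 1},
            partial_amplifications=[AmplifiedSegment(1, 0, 2_000_000, 2)],
        )
        with pytest.raises(ValueError):
            compute_genome_size(call, {1: 750_000})


class TestRecurrenceFilter:
    @staticmethod
    def variants(site_strains: dict[int, int]) -> pd.DataFrame:
        rows = []
        for pos, n in site_strains.items():
            for s in range(n):
                rows.append(
                    {"strain_id": f"s{pos}_{s}", "position_bp": pos,
                     "gene_id": f"g{pos}", "nonsynonymous": True}
                )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("n_strains,kept", [(5, False), (4, True), (1, True)])
    def test_boundary(self, n_strains, kept):
        df = self.variants({100: n_strains})
        out = filter_recurrent_variants(df)
        assert (len(out) > 0) is kept
        if not kept:
            assert len(out) == 0  # removed from all carrying strains

    def test_idempotent_and_order_independent(self):
        df = self.variants({1: 6, 2: 4, 3: 1})
        once = filter_recurrent_variants(df)
        twice = filter_recurrent_variants(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = df.sample(frac=1, random_state=0)
        out = filter_recurrent_variants(shuffled).sort_index()
        pd.testing.assert_frame_equal(out, once.loc[out.index])


class TestNomination:
    comp = FunctionalCompendium(complexes={"X": frozenset(["Q", "SUP"])})

    @staticmethod
    def variant(strain, gene, nonsyn=True, pos=100):
        return {"strain_id": strain, "gene_id": gene, "nonsynonymous": nonsyn,
                "position_bp": pos, "kind": "missense" if nonsyn else "synonymous"}

    def test_recurrent_cocomplex_gene_ranks_first(self):
        rows = [self.variant(f"s{i}", "SUP", pos=100 + i) for i in range(3)]
        rows += [self.variant("s1", "OTHER", pos=500)]
        out = nominate_suppressor_candidates(pd.DataFrame(rows), "Q", self.comp)
        top = out.loc[(out["strain_id"] == "s1") & (out["gene_id"] == "SUP")].iloc[0]
        assert top["recurrent"] and top["functional_connection"]
        assert top["rank"] == 1
        other = out.loc[(out["strain_id"] == "s1") & (out["gene_id"] == "OTHER")].iloc[0]
        assert other["rank"] > 1

    def test_synonymous_only_gene_is_not_a_candidate(self):
        rows = [self.variant("s1", "SYN", nonsyn=False)]
        out = nominate_suppressor_candidates(pd.DataFrame(rows), "Q", self.comp)
        assert len(out) == 0

    def test_locus_membership_breaks_ties(self):
        rows = [self.variant("s1", "IN", pos=1), self.variant("s1", "OUT", pos=2)]
        out = nominate_suppressor_candidates(
            pd.DataFrame(rows), "Q", self.comp, locus_genes={"s1": {"IN"}}
        )
        by_gene = out.set_index("gene_id")
        assert not by_gene.loc["OUT", "in_locus"]
        assert by_gene.loc["IN", "rank"] < by_gene.loc["OUT", "rank"]


class TestLinkageLocus:
    @staticmethod
    def scores(values, chromosome=1):
        return pd.DataFrame(
            {"chromosome": chromosome, "gene_id": [f"g{i}" for i in range(len(values))],
             "score": values}
        )

    def test_planted_run_recovered_exactly(self):
        vals = [0.0] * 30 + [-1.0] * 20 + [0.0] * 30
        locus = detect_linkage_locus(self.scores(vals), window=10, threshold=-0.2)
        assert (locus.start_index, locus.end_index) == (30, 49)
        # oracle: exhaustive scan over all qualifying runs
        runs = []
        arr = np.array(vals)
        i = 0
        while i < len(arr):
            if arr[i] <= -0.2:
                j = i
                while j < len(arr) and arr[j] <= -0.2:
                    j += 1
                if j - i >= 10:
                    runs.append((i, j - 1))
                i = j
            else:
                i += 1
        assert runs == [(locus.start_index, locus.end_index)]

    def test_no_qualifying_run_returns_none(self):
        assert detect_linkage_locus(self.scores([0.0] * 50), threshold=-0.2) is None

    def test_lowest_mean_run_wins(self):
        vals = [-0.5] * 12 + [0.0] * 5 + [-1.0] * 12 + [0.0] * 5
        locus = detect_linkage_locus(self.scores(vals), window=10, threshold=-0.2)
        assert (locus.start_index, locus.end_index) == (17, 28)

    def test_runs_do_not_cross_chromosomes(self):
        df = pd.concat(
            [self.scores([-1.0] * 6, chromosome=1),
             self.scores([-1.0] * 6, chromosome=2)],
            ignore_index=True,
        )
        assert detect_linkage_locus(df, window=10, threshold=-0.2) is None

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            detect_linkage_locus(self.scores([0.0]), window=1)
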