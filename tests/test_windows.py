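"""Window construction, mismatch counting and rank-sum tests."""

import itertools
import logging
from math import comb

import numpy as np
import pytest
from scipy import stats

from refbias import freqstats as fs
from refbias.alleles import ConsensusSequence
from refbias.windows import (
    bias_mechanism_report,
    build_windows,
    count_window_mismatches,
    mannwhitney_one_tailed,
    windows_with_mismatches,
)


def _random_seq(rng, L):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, L))


class TestBuildWindows:
    def test_one_window_per_copy_and_classes(self):
        ref = "A" * 101
        seqs = [ref, ref[:50] + "T" + ref[51:], ref]
        ws = build_windows(seqs, site=51, ref_base="A")
        assert len(ws) == 3
        assert [w.central_class for w in ws] == ["REF", "ALT", "REF"]
        assert all(len(w) == 51 for w in ws)

    def test_edge_truncation(self):
        seqs = ["A" * 60]
        (w,) = build_windows(seqs, site=1, ref_base="A")
        assert len(w) == 26  # no upstream flank
        (w,) = build_windows(seqs, site=60, ref_base="A")
        assert len(w) == 26

    def test_interior_window_is_full_width(self):
        (w,) = build_windows(["C" * 546], site=300, ref_base="C")
        assert len(w) == 51
        assert w.start == 275

    def test_ambiguous_central_site_excluded(self):
        amb = ConsensusSequence.from_sequences(["A" * 60, "A" * 30 + "T" + "A" * 29])
        ws = build_windows([amb, "A" * 60], site=31, ref_base="A")
        assert len(ws) == 1  # only the unambiguous copy contributes

    def test_site_out_of_range(self):
        with pytest.raises(ValueError):
            build_windows(["A" * 60], site=61, ref_base="A")


class TestMismatchCounting:
    def test_identical_window_counts_zero(self):
        ref = "ACGT" * 20
        ws = windows_with_mismatches([ref], 40, ref[39], index_seq=ref)
        assert ws[0].mismatch_count == 0

    def test_central_mismatch_excluded(self):
        ref = "A" * 80
        seq = ref[:39] + "T" + ref[40:]
        ws = windows_with_mismatches([seq], 40, "A", index_seq=ref)
        assert ws[0].central_class == "ALT"
        assert ws[0].mismatch_count == 0

    def test_flanking_differences_counted(self):
        ref = "A" * 80
        seq = list(ref)
        seq[39] = "T"          # central (site 40)
        seq[30] = seq[50] = "G"  # two flanking differences
        ws = windows_with_mismatches(["".join(seq)], 40, "A", index_seq=ref)
        assert ws[0].mismatch_count == 2

    def test_ambiguous_flank_matches_when_index_base_possible(self):
        ref = "A" * 60
        amb = ConsensusSequence.from_sequences([ref, ref[:10] + "T" + ref[11:]])
        ws = windows_with_mismatches([amb], 20, "A", index_seq=ref)
        assert ws[0].mismatch_count == 0  # {A,T} contains the index base A

    def test_index_length_disagreement(self):
        ws = build_windows(["A" * 80], 60, "A")
        with pytest.raises(ValueError):
            count_window_mismatches(ws[0], "A" * 70)

    def test_brute_force_hamming_oracle(self):
        rng = np.random.default_rng(8)
        L = 120
        for _ in range(200):
            ref = _random_seq(rng, L)
            seq = _random_seq(rng, L)
            site = int(rng.integers(1, L + 1))
            (w,) = windows_with_mismatches([seq], site, ref[site - 1], index_seq=ref)
            lo, hi = max(1, site - 25), min(L, site + 25)
            expected = sum(
                1
                for p in range(lo, hi + 1)
                if p != site and seq[p - 1] != ref[p - 1]
            )
            assert w.mismatch_count == expected


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        # exact: the most extreme of C(6,3)=20 assignments
        assert mannwhitney_one_tailed([5, 6, 7], [1, 2, 3]) == pytest.approx(0.05)

    def test_identical_groups_not_significant(self):
        assert mannwhitney_one_tailed([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_one_tailed([], [1])

    def test_exact_equals_permutation_enumeration(self):
        """Tie-aware exact p equals brute-force enumeration for sizes <= 8."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            na, nb = rng.integers(2, 9, size=2)
            pooled = rng.integers(0, 5, size=na + nb).astype(float)  # heavy ties
            a, b = pooled[:na], pooled[na:]
            ranks = stats.rankdata(pooled)
            obs = ranks[:na].sum()
            count = sum(
                1
                for idx in itertools.combinations(range(na + nb), na)
                if ranks[list(idx)].sum() >= obs - 1e-9
            )
            expected = count / comb(na + nb, na)
            assert mannwhitney_one_tailed(a, b) == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(10)
        a = rng.permutation(40)[:12].astype(float)
        b = (rng.permutation(40)[:10] + 0.5).astype(float)
        ours = mannwhitney_one_tailed(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_large_shifted_samples_underflow(self):
        rng = np.random.default_rng(11)
        a = rng.normal(2.0, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        assert mannwhitney_one_tailed(a, b) < 1e-16


class TestBiasReport:
    def test_deterministic_construction_recovers_differential(self):
        """ALT haplotype carrying exactly 3 extra flanking variants gives a
        mean(ALT) - mean(REF) differential of exactly 3."""
        ref = "A" * 101
        alt_hap = list(ref)
        alt_hap[50] = "T"                   # central site 51
        for p in (30, 40, 60):              # three linked flanking variants
            alt_hap[p] = "C"
        seqs = ["".join(alt_hap)] * 10 + [ref] * 10
        ws = windows_with_mismatches(seqs, 51, "A", index_seq=ref)
        report = bias_mechanism_report(ws, {51: fs.OVERESTIMATED})
        row = report.iloc[0]
        assert row["mean_alt"] - row["mean_ref"] == 3.0
        assert row["n_ref"] == row["n_alt"] == 10
        assert row["p_alt_greater"] < 0.01

    def test_class_without_alt_windows_omitted(self, caplog):
        ref = "A" * 101
        ws = windows_with_mismatches([ref] * 4, 51, "A", index_seq=ref)
        with caplog.at_level(logging.WARNING, logger="refbias.windows"):
            report = bias_mechanism_report(ws, {51: fs.WELL_ESTIMATED})
        assert report.empty
        assert "lacks" in caplog.text

    def test_missing_counts_rejected(self):
        ws = build_windows(["A" * 60], 30, "A")
        with pytest.raises(ValueError):
            bias_mechanism_report(ws, {30: fs.WELL_ESTIMATED})
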