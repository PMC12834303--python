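"""Alignment-rate computation and the available/disposable partition."""

import numpy as np
import pytest

from gapfill import (ScaffoldRecord, align_candidate, compare_assemblies,
                     detect_gaps, filter_predictions, patch_scaffold,
                     truth_homolog_provider)
from gapfill.filtering import _baseline_region, fasta_homolog_provider
from gapfill.gaps import GapRecord
from gapfill.search import GapFill


def _rand_seq(n, seed=0):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def _fill(gap, seq, direction="left"):
    return GapFill(gap=gap, sequence=seq, direction=direction, f=0.0, g=0.0,
                   mean_step_prob=0.5)


class TestAlignCandidate:
    def test_exact_substring_rate_one(self):
        hom = _rand_seq(200, 1)
        assert align_candidate(hom[50:90], hom).rate == 1.0

    def test_all_n_rate_zero(self):
        assert align_candidate("N" * 40, _rand_seq(200, 2)).rate == 0.0

    def test_k_mismatches_rate_matches_edlib(self):
        """A candidate with k substitutions at its best placement scores
        (L-k)/L; the edit distance from an independent routine agrees."""
        import edlib

        hom = _rand_seq(300, 3)
        cand = list(hom[100:160])
        rng = np.random.default_rng(4)
        k = 5
        pos = rng.choice(60, size=k, replace=False)
        for p in pos:
            cand[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cand[p]]
        cand = "".join(cand)
        report = align_candidate(cand, hom)
        assert report.rate == pytest.approx((60 - k) / 60)
        assert report.edit_distance == edlib.align(cand, hom, mode="HW")["editDistance"]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            align_candidate("", "ACGT")


class TestFilterPredictions:
    def _setup(self, gap_len=30, margin_seq=60):
        truth_seq = _rand_seq(1000, 7)
        gap = GapRecord("t", 400, 400 + gap_len,
                        left_flank=truth_seq[300:400],
                        right_flank=truth_seq[400 + gap_len : 500 + gap_len])
        truth = [ScaffoldRecord("t", truth_seq)]
        provider = truth_homolog_provider(truth, margin=50)
        return gap, truth_seq[400 : 400 + gap_len], provider

    def test_perfect_candidate_available(self):
        gap, truth_fill, provider = self._setup()
        avail, disp, verdicts = filter_predictions(
            [_fill(gap, truth_fill)], provider, tau=0.9
        )
        assert len(avail) == 1 and not disp
        assert verdicts[0].label == "available"
        assert verdicts[0].report.rate == 1.0
        assert verdicts[0].report.rate > verdicts[0].baseline_rate

    def test_low_rate_candidate_disposable(self):
        gap, truth_fill, provider = self._setup()
        garbage = _rand_seq(len(truth_fill), 99)
        avail, disp, verdicts = filter_predictions([_fill(gap, garbage)], provider)
        assert not avail and len(disp) == 1
        assert verdicts[0].report.rate < 0.9

    def test_partition_exhaustive_and_disjoint(self):
        gap, truth_fill, provider = self._setup()
        pool = [_fill(gap, truth_fill, "left"),
                _fill(gap, _rand_seq(len(truth_fill), 5), "right")]
        avail, disp, verdicts = filter_predictions(pool, provider)
        assert len(avail) + len(disp) == len(pool) == len(verdicts)
        assert not (set(map(id, avail)) & set(map(id, disp)))

    def test_threshold_monotonicity(self):
        gap, truth_fill, provider = self._setup()
        half_bad = truth_fill[: len(truth_fill) // 2] + _rand_seq(
            len(truth_fill) - len(truth_fill) // 2, 3
        )
        pool = [_fill(gap, truth_fill), _fill(gap, half_bad, "right")]
        sizes = []
        for tau in (0.1, 0.5, 0.9, 0.99):
            avail, _, _ = filter_predictions(pool, provider, tau=tau)
            sizes.append(len(avail))
        assert sizes == sorted(sizes, reverse=True)

    def test_available_mean_rate_dominates_pool(self):
        gap, truth_fill, provider = self._setup()
        rng = np.random.default_rng(0)
        pool = []
        for i in range(10):
            n_bad = int(rng.integers(0, len(truth_fill)))
            cand = truth_fill[: len(truth_fill) - n_bad] + _rand_seq(n_bad, i)
            pool.append(_fill(gap, cand, f"c{i}"))
        avail, _, verdicts = filter_predictions(pool, provider, tau=0.5)
        rates = {v.candidate_id: v.report.rate for v in verdicts}
        if avail:
            mean_avail = np.mean([rates[f"{f.gap_id}/{f.direction}"] for f in avail])
            assert mean_avail >= np.mean(list(rates.values()))

    def test_missing_homolog_pass_through_and_strict(self):
        gap, truth_fill, _ = self._setup()
        none_provider = lambda g: None
        avail, disp, verdicts = filter_predictions([_fill(gap, truth_fill)],
                                                   none_provider)
        assert not avail and verdicts[0].label == "disposable"
        with pytest.raises(ValueError, match="no homolog"):
            filter_predictions([_fill(gap, truth_fill)], none_provider, strict=True)

    def test_baseline_region_includes_flank_margin(self):
        gap, _, _ = self._setup(gap_len=20)
        region = _baseline_region(gap, margin=30)
        assert region == gap.left_flank[-30:] + "N" * 20 + gap.right_flank[:30]

    def test_fasta_provider_keys_by_gap_id(self):
        gap, truth_fill, _ = self._setup()
        provider = fasta_homolog_provider(
            [ScaffoldRecord(gap.gap_id, "ACGT" * 30)]
        )
        assert provider(gap) == "ACGT" * 30


class TestCompareAssemblies:
    def _scenario(self):
        truth_seq = _rand_seq(5000, 11)
        scaffold_seq = truth_seq[:2000] + "N" * 50 + truth_seq[2050:]
        scaffold = ScaffoldRecord("t", scaffold_seq)
        truth = ScaffoldRecord("t", truth_seq)
        (gap,) = detect_gaps(scaffold, flank_len=100)
        good = truth_seq[2000:2050]
        corrupt = _rand_seq(50, 13)
        return scaffold, truth, gap, good, corrupt

    def test_filter_removes_corrupted_candidate(self):
        scaffold, truth, gap, good, corrupt = self._scenario()
        provider = truth_homolog_provider([truth])
        pool = [_fill(gap, corrupt)]
        avail, _, _ = filter_predictions(pool, provider)
        unfiltered = [patch_scaffold(scaffold, gap, corrupt)]
        filtered = [patch_scaffold(scaffold, gap, f.sequence) for f in avail] or [scaffold]
        m_unf, m_fil = compare_assemblies(unfiltered, filtered, [truth], [gap])
        assert m_fil.mismatches_per_100kb <= m_unf.mismatches_per_100kb

    def test_noop_filter_identical_scaffolds(self):
        scaffold, truth, gap, good, _ = self._scenario()
        patched = [patch_scaffold(scaffold, gap, good)]
        m_unf, m_fil = compare_assemblies(patched, patched, [truth], [gap])
        assert m_unf == m_fil

    def test_all_disposable_leaves_original(self):
        scaffold, truth, gap, _, corrupt = self._scenario()
        provider = truth_homolog_provider([truth])
        avail, _, _ = filter_predictions([_fill(gap, corrupt)], provider)
        assert avail == []
        # nothing applied: the filtered assembly is the unpatched scaffold
        m_unf, m_fil = compare_assemblies(
            [patch_scaffold(scaffold, gap, corrupt)], [scaffold], [truth], [gap]
        )
        assert m_fil.gaps_filled == 0 and m_unf.gaps_filled == 1

    def test_length_mismatch_rejected(self):
        scaffold, truth, gap, good, _ = self._scenario()
        shorter = patch_scaffold(scaffold, gap, good[:-1])
        with pytest.raises(ValueError, match="length bookkeeping"):
            compare_assemblies([scaffold], [shorter], [truth], [gap])
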