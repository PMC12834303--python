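"""Cost function closed forms and beam-search behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapfill import (BeamSchedule, HeuristicWeights, beam_width_at,
                     bscea_search, entropy_term, fill_gap, gc_ratio_impact,
                     markov_oracle, norm_rem_len, path_cost_g)
from gapfill.gaps import GapRecord
from gapfill.search import BeamNode, OracleContractError, _merge_candidates, heuristic_cost
from helpers import brute_force_best, reference_beam_search

simplex4 = st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4).map(
    lambda v: np.array(v) / sum(v)
)


class TestCostClosedForms:
    def test_path_cost_g(self):
        assert path_cost_g(0.0, [1.0, 1.0]) == 0.0
        assert path_cost_g(0.0, [0.5]) == pytest.approx(math.log(2), abs=1e-9)
        assert path_cost_g(1.0, [0.25, 0.25]) == pytest.approx(
            1 + 2 * math.log(4), abs=1e-9
        )

    def test_path_cost_domain(self):
        with pytest.raises(ValueError):
            path_cost_g(0.0, [1.5])
        # a hard zero is floored, not fatal
        assert math.isfinite(path_cost_g(0.0, [0.0]))

    def test_entropy_term(self):
        uniform = np.full(4, 0.25)
        assert entropy_term([uniform] * 5) == pytest.approx(1.0, abs=1e-9)
        onehot = np.array([1.0, 0, 0, 0])
        assert entropy_term([onehot] * 3) == pytest.approx(0.0, abs=1e-9)
        half = np.array([0.5, 0.5, 0, 0])
        assert entropy_term([half]) == pytest.approx(0.5, abs=1e-9)
        assert entropy_term([]) == 0.0

    def test_norm_rem_len(self):
        assert norm_rem_len(100, 99) == pytest.approx(0.0, abs=1e-9)
        assert norm_rem_len(100, 0) == pytest.approx(1.0, abs=1e-9)
        assert norm_rem_len(100, 50) == pytest.approx(
            math.log(50) / math.log(100), abs=1e-9
        )
        assert norm_rem_len(100, 100) == 0.0  # terminating convention

    def test_gc_ratio_impact(self):
        assert gc_ratio_impact("ATAT", "ATATG") == pytest.approx(0.2, abs=1e-9)
        assert gc_ratio_impact("ACGT", "ACGT") == 0.0
        assert gc_ratio_impact("GGCC", "GGCCA") == pytest.approx(0.2, abs=1e-9)
        with pytest.raises(ValueError):
            gc_ratio_impact("", "A")

    def test_heuristic_combination(self):
        """Unit weights: h = -entropy + remaining + GC shift, each at its
        worked closed form."""
        node = BeamNode(sequence="ATAT")
        half = np.array([0.5, 0.5, 0.0, 0.0])
        # one prior step at entropy 0.5 plus this uniform candidate step
        h = heuristic_cost(
            BeamNode(sequence="ATAT"), "G", half, target_length=2,
            weights=HeuristicWeights(1, 1, 1),
        )
        # trace = [half]: ent 0.5; n_new=1 of 2 -> ln1/ln2 = 0; gc shift 0.2
        assert h == pytest.approx(-0.5 + 0.0 + 0.2, abs=1e-9)
        assert heuristic_cost(node, "G", half, 2, HeuristicWeights(0, 0, 0)) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(dists=st.lists(simplex4, min_size=1, max_size=8))
    def test_component_ranges(self, dists):
        assert 0.0 <= entropy_term(dists) <= 1.0 + 1e-12
        assert 0.0 <= norm_rem_len(len(dists) + 1, len(dists)) <= 1.0


class TestBeamWidth:
    SCHED = BeamSchedule(w_init=4, w_max=16, w_final=4, contract_at=0.5)

    def test_endpoints(self):
        assert beam_width_at(0, 100, self.SCHED) == 4
        assert beam_width_at(99, 100, self.SCHED) == 4

    def test_interpolation(self):
        assert beam_width_at(25, 100, self.SCHED) == 10
        assert beam_width_at(50, 100, self.SCHED) == 16  # peak at the pivot

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            BeamSchedule(w_init=0, w_max=4, w_final=2, contract_at=0.5)
        with pytest.raises(ValueError):
            BeamSchedule(w_init=8, w_max=4, w_final=2, contract_at=0.5)


class TestSearch:
    def test_deterministic_oracle_forces_sequence(self):
        """An oracle that puts ~all mass on one base per context yields the
        forced continuation with near-zero g."""
        def oracle(contexts):
            rows = []
            for c in contexts:
                j = "ACGT".index(c[-1])
                row = np.full(4, 0.001)
                row[(j + 1) % 4] = 0.997
                rows.append(row)
            return np.stack(rows)

        res = bscea_search(oracle, "A", 6, HeuristicWeights(0, 0, 0),
                           BeamSchedule.constant(4))
        assert res.predicted == "CGTACG"
        assert res.best.g == pytest.approx(6 * abs(math.log(0.997)), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exhaustive_oracle_equivalence(self, seed):
        """With the beam wide enough to hold every hypothesis, the search must
        return the brute-force minimum-f completion exactly."""
        oracle = markov_oracle(2, rng_seed=seed)
        res = bscea_search(oracle, "ACG", 6, HeuristicWeights(1, 1, 1),
                           BeamSchedule.constant(4096))
        best_seq, best_f = brute_force_best(oracle, "ACG", 6)
        assert res.predicted == best_seq
        assert res.best.f == pytest.approx(best_f, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nested_beam_monotonicity(self, seed):
        oracle = markov_oracle(2, rng_seed=seed)
        fs = [
            bscea_search(oracle, "ACG", 8, HeuristicWeights(1, 1, 1),
                         BeamSchedule.constant(w)).best.f
            for w in (1, 4, 16, 64)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(fs, fs[1:]))

    @pytest.mark.parametrize("seed,width", [(0, 1), (0, 4), (1, 8), (2, 4)])
    def test_null_heuristic_reduces_to_plain_beam_search(self, seed, width):
        oracle = markov_oracle(2, rng_seed=seed)
        res = bscea_search(oracle, "ACG", 8, HeuristicWeights(0, 0, 0),
                           BeamSchedule.constant(width))
        assert res.best.sequence == reference_beam_search(oracle, "ACG", 8, width)

    def test_cost_recomputable_from_trace(self):
        oracle = markov_oracle(1, rng_seed=5)
        res = bscea_search(oracle, "AC", 10, schedule=BeamSchedule.constant(8))
        for node in res.candidates:
            assert node.recompute_g() == pytest.approx(node.g, abs=1e-9)
        assert res.best.f == res.best.g + res.best.h

    def test_result_invariants(self):
        oracle = markov_oracle(1, rng_seed=9)
        res = bscea_search(oracle, "A", 5, schedule=BeamSchedule.constant(4))
        assert len(res.predicted) == 5
        assert res.best.f == min(c.f for c in res.candidates)

    def test_non_simplex_oracle_rejected(self):
        bad = lambda contexts: np.full((len(contexts), 4), 0.5)
        with pytest.raises(OracleContractError):
            bscea_search(bad, "A", 3)

    def test_seed_validation(self):
        oracle = markov_oracle(0, rng_seed=0)
        with pytest.raises(ValueError):
            bscea_search(oracle, "", 3)
        with pytest.raises(ValueError):
            bscea_search(oracle, "ANA", 3)


class TestFillGap:
    @staticmethod
    def _periodic_oracle(motif="ACGGTCA"):
        """Deterministic continuation of a tandem motif, given >=len(motif)
        context (an idealized converged model)."""
        from gapfill import reverse_complement

        strands = (motif, reverse_complement(motif))  # both strands known

        def oracle(contexts):
            rows = []
            for c in contexts:
                # locate phase by matching the last motif-length slice
                tail = c[-len(motif):]
                nxt = motif[0]
                if len(tail) == len(motif):
                    for m in strands:
                        idx = (m * 2).find(tail)
                        if idx >= 0:
                            nxt = (m * 2)[idx + len(motif)]
                            break
                row = np.full(4, 0.001)
                row["ACGT".index(nxt)] = 0.997
                rows.append(row)
            return np.stack(rows)

        return oracle

    def _gap(self, motif="ACGGTCA", gap_len=14):
        tandem = motif * 30
        left = tandem[:70]
        right = tandem[70 + gap_len : 70 + gap_len + 70]
        truth = tandem[70 : 70 + gap_len]
        return (
            GapRecord("s", 70, 70 + gap_len, left_flank=left, right_flank=right),
            truth,
        )

    def test_left_mode_recovers_periodic_truth(self):
        gap, truth = self._gap()
        fill = fill_gap(self._periodic_oracle(), gap, mode="left", min_flank=10)
        assert fill.sequence == truth

    def test_bidirectional_agreeing_candidates_returned_unchanged(self):
        gap, truth = self._gap()
        fill = fill_gap(self._periodic_oracle(), gap, mode="bidirectional",
                        min_flank=10)
        assert fill.sequence == truth
        assert fill.direction == "bidirectional"

    def test_right_mode_equals_left_on_mirrored_gap(self):
        """Right-flank prediction is defined as left-flank prediction on the
        reverse-complemented strand, so the two must mirror exactly."""
        from gapfill import reverse_complement

        oracle = markov_oracle(3, rng_seed=4)
        gap, _ = self._gap(gap_len=10)
        mirrored = GapRecord(
            "s", 70, 80,
            left_flank=reverse_complement(gap.right_flank),
            right_flank=reverse_complement(gap.left_flank),
        )
        right = fill_gap(oracle, gap, mode="right", min_flank=10)
        left = fill_gap(oracle, mirrored, mode="left", min_flank=10)
        assert right.sequence == reverse_complement(left.sequence)

    def test_unusable_flanks_skip_gap(self):
        gap = GapRecord("s", 5, 10, left_flank="ACG", right_flank="T")
        assert fill_gap(markov_oracle(0), gap, min_flank=50) is None

    def test_merge_identity(self):
        assert _merge_candidates("ACGTACGTACGT", "ACGTACGTACGT", 10, 0.9) == \
            "ACGTACGTACGT"

    def test_merge_disagreement_returns_none(self):
        assert _merge_candidates("A" * 20, "C" * 20, 10, 0.9) is None
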