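"""The contraction-expansion beam search on a seeded Markov oracle.

Shows the cost decomposition f = g + h, the beam-width schedule, and how
widening the beam can only improve (never worsen) the best final cost.
"""

from gapfill import (BeamSchedule, HeuristicWeights, beam_width_at,
                     bscea_search, markov_oracle)

oracle = markov_oracle(order=2, rng_seed=7)
weights = HeuristicWeights(alpha=1.0, beta=1.0, gamma=1.0)

schedule = BeamSchedule.from_peak(16)  # 8 -> 16 -> 8, contraction at 75%
print("beam width over a 20-step search:",
      [beam_width_at(s, 20, schedule) for s in range(20)])

for width in (1, 4, 16, 64):
    res = bscea_search(oracle, seed="ACG", target_length=12, weights=weights,
                       schedule=BeamSchedule.constant(width))
    print(f"width {width:>3}: predicted {res.predicted} "
          f"f={res.best.f:.4f} (g={res.best.g:.4f}, h={res.best.h:.4f}), "
          f"{res.nodes_expanded} nodes expanded")
# f is non-increasing as the beam widens: a wider beam searches a superset
# of hypotheses under the same deterministic tie-breaking.
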