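"""Independent reference implementations used as oracles in tests.

These deliberately avoid the package's search/cost code paths: costs are
recomputed from first principles with plain ``math`` so that agreement
with the package is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"


def ref_final_cost(seed: str, completion: str, probs: list[float],
                   dists: list[list[float]], alpha: float, beta: float,
                   gamma: float, p_min: float = 1e-9) -> float:
    """f of a full-length candidate, from scratch.

    g = sum |ln p_i| over chosen bases; at the final step the heuristic is
    -alpha * normalized entropy of all step distributions (remaining-length
    term is 0 at the target) + gamma * GC shift of the last extension.
    """
    g = sum(abs(math.log(max(p, p_min))) for p in probs)
    n = len(dists)
    ent = 0.0
    for dist in dists:
        ent -= sum(p * math.log(p) for p in dist if p > 0)
    ent /= n * math.log(4)
    full = seed + completion
    prev = full[:-1]
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    return g - alpha * ent + gamma * abs(gc(full) - gc(prev))


def brute_force_best(oracle, seed: str, target: int, alpha: float = 1.0,
                     beta: float = 1.0, gamma: float = 1.0) -> tuple[str, float]:
    """Enumerate all 4^target completions; return (best completion, best f).

    Tie-break mirrors the package's rule: lower f, then channel order of
    the last base, then lexicographic sequence.
    """
    best = None
    for combo in itertools.product(BASES, repeat=target):
        completion = "".join(combo)
        probs, dists = [], []
        ctx = seed
        for base in completion:
            dist = [float(x) for x in oracle([ctx])[0]]
            probs.append(dist[BASES.index(base)])
            dists.append(dist)
            ctx += base
        f = ref_final_cost(seed, completion, probs, dists, alpha, beta, gamma)
        key = (f, BASES.index(completion[-1]), seed + completion)
        if best is None or key < best[0]:
            best = (key, completion, f)
    return best[1], best[2]


def reference_beam_search(oracle, seed: str, target: int, width: int,
                          p_min: float = 1e-9) -> str:
    """Textbook fixed-width beam search minimizing accumulated |ln p|.

    Deterministic tie-break: (score, channel of last base, sequence).
    """
    beam = [(0.0, seed)]
    for _ in range(target):
        children = []
        for score, seq in beam:
            dist = oracle([seq])[0]
            for j, base in enumerate(BASES):
                p = max(float(dist[j]), p_min)
                children.append((score + abs(math.log(p)), seq + base))
        children.sort(key=lambda c: (c[0], BASES.index(c[1][-1]), c[1]))
        beam = children[:width]
    return min(beam, key=lambda c: (c[0], BASES.index(c[1][-1]), c[1]))[1]


def identity(a: str, b: str) -> float:
    """Positional identity of two same-length strings."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)
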