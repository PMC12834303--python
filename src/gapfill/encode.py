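"""One-hot encoding of nucleotide strings and strand utilities.

The channel order is the module constant ``CHANNEL_ORDER`` = "ACGT" and
is serialized into every model file; a trained model refuses to load
under a different convention, so the mapping can never silently drift
between training and inference.

N rows follow an explicit policy: all-zero by default (an N carries no
evidence, and a zero input is neutral for the convolution), or uniform
0.25 per channel.
"""

from __future__ import annotations

import numpy as np

CHANNEL_ORDER = "ACGT"
_INDEX = {b: i for i, b in enumerate(CHANNEL_ORDER)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class EncodingError(ValueError):
    pass


def one_hot_encode(seq: str, n_policy: str = "zero") -> np.ndarray:
    """Encode a sequence over {A,C,G,T,N} as a (len, 4) float matrix."""
    if n_policy not in ("zero", "uniform"):
        raise ValueError(f"unknown n_policy {n_policy!r}")
    m = np.zeros((len(seq), 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch == "N":
            if n_policy == "uniform":
                m[i] = 0.25
        else:
            j = _INDEX.get(ch)
            if j is None:
                raise EncodingError(f"illegal character {ch!r} at offset {i}")
            m[i, j] = 1.0
    return m


def one_hot_decode(m: np.ndarray) -> str:
    """Map each row back to its argmax base (ties break in channel order)."""
    m = np.asarray(m)
    if m.size == 0:
        return ""
    if m.ndim != 2 or m.shape[1] != 4:
        raise EncodingError(f"expected shape (n, 4), got {m.shape}")
    return "".join(CHANNEL_ORDER[j] for j in np.argmax(m, axis=1))


def reverse_complement(seq: str) -> str:
    """Reverse-complement over {A,C,G,T,N}; an involution."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise EncodingError(f"illegal characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]
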