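"""Assembly-quality metrics: fill counts/rates, N's per 100 kb,
truth-based mismatch rates, and GC-content profiles.

A gap counts as *filled* when its (coordinate-tracked) interval in the
patched scaffold contains no N; partially reduced N-runs are reported
separately. Mismatch metrics require a truth sequence and use direct
positional comparison when lengths agree (the pipeline's fills are
length-preserving), falling back to an edit-distance alignment walk
otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .gaps import GapRecord
from .io import ScaffoldRecord


@dataclass
class GCProfile:
    """GC fraction per non-overlapping window (windows containing N excluded),
    binned at 1% resolution, plus the global GC percent over non-N bases."""

    window: int
    global_gc_percent: float
    window_fractions: list[float]
    histogram: np.ndarray  # 101 bins: 0..100 percent

    @property
    def n_windows(self) -> int:
        return len(self.window_fractions)


@dataclass
class AssemblyMetrics:
    gaps_total: int
    gaps_filled: int
    fill_rate: float | None  # percent; None when gaps_total == 0
    n_count: int
    total_length: int
    ns_per_100kb: float
    gc_fraction: float  # percent of non-N bases
    mismatches_per_100kb: float | None = None
    gc_profile: GCProfile | None = None


def fill_rate(gaps_filled: int, gaps_total: int) -> float | None:
    """Percent of gaps filled, to 2 decimals; None (not applicable) for 0 gaps."""
    if not 0 <= gaps_filled <= gaps_total:
        raise ValueError("require 0 <= gaps_filled <= gaps_total")
    if gaps_total == 0:
        return None
    return round(100.0 * gaps_filled / gaps_total, 2)


def ns_per_100kb(records: ScaffoldRecord | Sequence[ScaffoldRecord]) -> float:
    """Undetermined bases per 100 000 bases of assembly."""
    if isinstance(records, ScaffoldRecord):
        records = [records]
    total = sum(len(r.sequence) for r in records)
    if total == 0:
        raise ValueError("empty assembly")
    n = sum(r.sequence.count("N") for r in records)
    return n / total * 100_000


def _mismatches_aligned(assembly: str, truth: str) -> tuple[int, int]:
    """(mismatches, aligned non-N length) via an edit-distance alignment walk."""
    res = edlib.align(assembly, truth, task="path", mode="NW")
    mism = 0
    aligned = 0
    i = j = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        count = int(count)
        if op in "=XM":
            for k in range(count):
                a, t = assembly[i + k], truth[j + k]
                if a != "N":
                    aligned += 1
                    if a != t:
                        mism += 1
            i += count
            j += count
        elif op == "I":  # present in assembly only
            i += count
        else:  # deletion from assembly
            j += count
    return mism, aligned


def mismatches_per_100kb(assembly: ScaffoldRecord, truth: ScaffoldRecord) -> float:
    """Substituted bases per 100 kb of aligned, non-N assembly sequence."""
    a, t = assembly.sequence, truth.sequence
    if len(a) == len(t):
        arr_a = np.frombuffer(a.encode(), dtype="S1")
        arr_t = np.frombuffer(t.encode(), dtype="S1")
        non_n = arr_a != b"N"
        aligned = int(non_n.sum())
        mism = int(((arr_a != arr_t) & non_n).sum())
    else:
        mism, aligned = _mismatches_aligned(a, t)
    if aligned == 0:
        raise ValueError("no aligned non-N positions between assembly and truth")
    return mism / aligned * 100_000


def gc_fraction_percent(records: ScaffoldRecord | Sequence[ScaffoldRecord]) -> float:
    if isinstance(records, ScaffoldRecord):
        records = [records]
    gc = sum(r.sequence.count("G") + r.sequence.count("C") for r in records)
    acgt = sum(len(r.sequence) - r.sequence.count("N") for r in records)
    return 100.0 * gc / acgt if acgt else 0.0


def gc_profile(record: ScaffoldRecord, window: int = 1000) -> GCProfile:
    """Windowed GC composition; windows overlapping an N are excluded."""
    if window < 100:
        raise ValueError("window must be >= 100")
    fracs = []
    seq = record.sequence
    for lo in range(0, len(seq) - window + 1, window):
        win = seq[lo : lo + window]
        if "N" in win:
            continue
        fracs.append((win.count("G") + win.count("C")) / window)
    hist = np.zeros(101, dtype=int)
    for frac in fracs:
        hist[int(round(frac * 100))] += 1
    return GCProfile(
        window=window,
        global_gc_percent=gc_fraction_percent(record),
        window_fractions=fracs,
        histogram=hist,
    )


def _gap_states(after: dict[str, ScaffoldRecord], gaps: Sequence[GapRecord]):
    """Classify each gap interval in the patched assembly: filled / partial / open."""
    states = {}
    for g in gaps:
        rec = after.get(g.scaffold_id)
        if rec is None:
            raise ValueError(f"gap {g.gap_id}: scaffold {g.scaffold_id!r} missing")
        if g.end > len(rec.sequence):
            raise ValueError(
                f"gap {g.gap_id} extends past scaffold end; length bookkeeping mismatch"
            )
        n_in = rec.sequence[g.start : g.end].count("N")
        states[g.gap_id] = (
            "filled" if n_in == 0 else "open" if n_in == g.length else "partial"
        )
    return states


def compute_metrics(
    records: Sequence[ScaffoldRecord],
    gaps: Sequence[GapRecord],
    truth: Sequence[ScaffoldRecord] | None = None,
    gc_window: int | None = None,
) -> AssemblyMetrics:
    """Metrics for one scaffold set against its original gap inventory."""
    by_id = {r.id: r for r in records}
    states = _gap_states(by_id, gaps)
    filled = sum(1 for s in states.values() if s == "filled")
    mism = None
    if truth is not None:
        truth_by_id = {t.id: t for t in truth}
        total_m = total_a = 0
        for r in records:
            t = truth_by_id.get(r.id)
            if t is None:
                raise ValueError(f"truth missing for scaffold {r.id!r}")
            rate = mismatches_per_100kb(r, t)
            aligned = len(r.sequence) - r.sequence.count("N")
            total_m += rate * aligned / 100_000
            total_a += aligned
        mism = total_m / total_a * 100_000 if total_a else 0.0
    profile = None
    if gc_window is not None and records:
        profile = gc_profile(records[0], gc_window)
    return AssemblyMetrics(
        gaps_total=len(gaps),
        gaps_filled=filled,
        fill_rate=fill_rate(filled, len(gaps)),
        n_count=sum(r.sequence.count("N") for r in records),
        total_length=sum(len(r.sequence) for r in records),
        ns_per_100kb=ns_per_100kb(list(records)),
        gc_fraction=gc_fraction_percent(list(records)),
        mismatches_per_100kb=mism,
    )


def evaluate_run(
    before: Sequence[ScaffoldRecord],
    after: Sequence[ScaffoldRecord],
    gaps: Sequence[GapRecord],
    truth: Sequence[ScaffoldRecord] | None = None,
) -> tuple[AssemblyMetrics, AssemblyMetrics, dict]:
    """Before/after metrics plus a delta report over the shared gap inventory."""
    before_ids = {r.id for r in before}
    after_ids = {r.id for r in after}
    if before_ids != after_ids:
        raise ValueError(f"scaffold id mismatch: {before_ids ^ after_ids}")
    m_before = compute_metrics(before, gaps, truth)
    m_after = compute_metrics(after, gaps, truth)
    states = _gap_states({r.id: r for r in after}, gaps)
    delta = {
        "gaps_filled": m_after.gaps_filled - m_before.gaps_filled,
        "gaps_partial": sum(1 for s in states.values() if s == "partial"),
        "n_count": m_after.n_count - m_before.n_count,
        "ns_per_100kb": m_after.ns_per_100kb - m_before.ns_per_100kb,
        "fill_rate": (
            None
            if m_after.fill_rate is None
            else round(m_after.fill_rate - (m_before.fill_rate or 0.0), 2)
        ),
    }
    if m_before.mismatches_per_100kb is not None:
        delta["mismatches_per_100kb"] = (
            m_after.mismatches_per_100kb - m_before.mismatches_per_100kb
        )
    return m_before, m_after, delta
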