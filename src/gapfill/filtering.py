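"""The prediction filter: keep only candidate fills that demonstrably
improve on the unfilled scaffold.

Each candidate is aligned (local pairwise, unit match/mismatch with
affine gaps) against a homologous region spanning its gap, giving an
alignment rate = identical aligned bases / candidate length. The same
region is also aligned against the *baseline* — the original N-run plus
a short flank margin — and a candidate is labelled ``available`` only
when its rate clears the threshold tau AND beats that baseline;
everything else is ``disposable`` and never patched in. Homologous
regions come either from a user-supplied FASTA keyed by gap id or from
the simulator's truth genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import edlib
from Bio import Align

from .gaps import GapRecord
from .io import ScaffoldRecord
from .metrics import AssemblyMetrics, compute_metrics
from .search import GapFill

log = logging.getLogger(__name__)

HomologProvider = Callable[[GapRecord], "str | None"]


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentReport:
    rate: float  # identical aligned bases / candidate length, in [0, 1]
    aligned_span: tuple[int, int]  # matched interval on the homolog region
    edit_distance: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")


@dataclass(frozen=True)
class FilterVerdict:
    gap_id: str
    candidate_id: str
    report: AlignmentReport
    baseline_rate: float
    label: str  # "available" | "disposable"


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def align_candidate(
    candidate: str,
    homolog_region: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignmentReport:
    """Best local alignment of candidate against the homolog region.

    N never counts as a match (an undetermined base is evidence of
    nothing). An unalignable candidate reports rate 0 rather than
    raising.
    """
    if not candidate or not homolog_region:
        raise ValueError("candidate and homolog region must be non-empty")
    ed = edlib.align(candidate, homolog_region, mode="HW")["editDistance"]
    aln = _aligner(scoring).align(candidate, homolog_region)
    try:
        best = aln[0]
    except IndexError:
        return AlignmentReport(rate=0.0, aligned_span=(0, 0), edit_distance=ed)
    matches = 0
    for (q0, q1), (t0, t1) in zip(*best.aligned):
        for qc, tc in zip(candidate[q0:q1], homolog_region[t0:t1]):
            if qc == tc and qc != "N":
                matches += 1
    t_blocks = best.aligned[1]
    span = (int(t_blocks[0][0]), int(t_blocks[-1][1])) if len(t_blocks) else (0, 0)
    return AlignmentReport(
        rate=matches / len(candidate), aligned_span=span, edit_distance=ed
    )


def truth_homolog_provider(
    truth: Sequence[ScaffoldRecord], margin: int = 50
) -> HomologProvider:
    """Homolog regions cut from the simulator's truth genome around each gap."""
    by_id = {t.id: t for t in truth}

    def provider(gap: GapRecord) -> str | None:
        t = by_id.get(gap.scaffold_id)
        if t is None:
            return None
        return t.sequence[max(0, gap.start - margin) : gap.end + margin]

    return provider


def fasta_homolog_provider(records: Sequence[ScaffoldRecord]) -> HomologProvider:
    """Homolog regions from a FASTA whose entry ids are gap ids
    (``scaffold:start-end``)."""
    by_id = {r.id: r.sequence for r in records}
    return lambda gap: by_id.get(gap.gap_id)


def _baseline_region(gap: GapRecord, margin: int) -> str:
    left = gap.left_flank[-margin:] if margin else ""
    right = gap.right_flank[:margin] if margin else ""
    return left + "N" * gap.length + right


def filter_predictions(
    candidates: Sequence[GapFill],
    homolog_provider: HomologProvider,
    tau: float = 0.9,
    scoring: AlignmentScoring = AlignmentScoring(),
    baseline_margin: int = 50,
    strict: bool = False,
) -> tuple[list[GapFill], list[GapFill], list[FilterVerdict]]:
    """Partition candidates into (available, disposable) with verdicts.

    available iff rate >= tau AND rate > baseline_rate, where the
    baseline aligns the original N-run plus ``baseline_margin`` bases of
    flank each side against the same region. Candidates without a
    homolog are disposable by default; ``strict`` raises instead.
    """
    available: list[GapFill] = []
    disposable: list[GapFill] = []
    verdicts: list[FilterVerdict] = []
    missing: list[str] = []
    for i, cand in enumerate(candidates):
        region = homolog_provider(cand.gap)
        cid = f"{cand.gap_id}/{cand.direction}"
        if region is None:
            missing.append(cand.gap_id)
            verdicts.append(
                FilterVerdict(
                    gap_id=cand.gap_id,
                    candidate_id=cid,
                    report=AlignmentReport(0.0, (0, 0), len(cand.sequence)),
                    baseline_rate=0.0,
                    label="disposable",
                )
            )
            disposable.append(cand)
            continue
        report = align_candidate(cand.sequence, region, scoring)
        baseline = align_candidate(_baseline_region(cand.gap, baseline_margin),
                                   region, scoring)
        ok = report.rate >= tau and report.rate > baseline.rate
        verdicts.append(
            FilterVerdict(
                gap_id=cand.gap_id,
                candidate_id=cid,
                report=report,
                baseline_rate=baseline.rate,
                label="available" if ok else "disposable",
            )
        )
        (available if ok else disposable).append(cand)
    if missing:
        if strict:
            raise ValueError(f"no homolog region for gaps: {sorted(set(missing))}")
        log.warning("no homolog region for %d gap(s); marked disposable", len(missing))
    return available, disposable, verdicts


def compare_assemblies(
    unfiltered_patch: Sequence[ScaffoldRecord],
    filtered_patch: Sequence[ScaffoldRecord],
    truth: Sequence[ScaffoldRecord],
    gaps: Sequence[GapRecord],
) -> tuple[AssemblyMetrics, AssemblyMetrics]:
    """Metrics for the patched-with-everything vs patched-with-available
    scaffolds against truth — the filter's effect, measured at scaffold level."""
    for a, b in zip(sorted(unfiltered_patch, key=lambda r: r.id),
                    sorted(filtered_patch, key=lambda r: r.id)):
        if a.id != b.id:
            raise ValueError(f"scaffold id mismatch: {a.id!r} vs {b.id!r}")
        if len(a.sequence) != len(b.sequence):
            raise ValueError(f"scaffold {a.id!r}: length bookkeeping mismatch")
    return (
        compute_metrics(list(unfiltered_patch), gaps, truth=list(truth)),
        compute_metrics(list(filtered_patch), gaps, truth=list(truth)),
    )
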