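"""Gap detection, flank extraction, scaffold patching, and BED inventories.

Coordinates are 0-based half-open throughout; BED output matches. A gap
is a maximal run of N of at least ``min_gap_len`` bases. Flanks are the
up-to-``flank_len`` non-N bases immediately adjacent to the run; they
never cross another N-run and are truncated at scaffold ends. Gaps whose
flanks are shorter than a configurable minimum carry too little context
for the predictor and are flagged unusable by callers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .io import ScaffoldRecord

log = logging.getLogger(__name__)

_N_RUN = re.compile(r"N+")

GAP_STATUSES = ("unclassified", "fixed", "unfixed")


@dataclass(frozen=True)
class GapRecord:
    """One N-run in a scaffold with its extracted flanking context."""

    scaffold_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    left_flank: str = ""
    right_flank: str = ""
    status: str = "unclassified"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gap [{self.start},{self.end}): end must exceed start")
        if "N" in self.left_flank or "N" in self.right_flank:
            raise ValueError("flanks must not contain N")
        if self.status not in GAP_STATUSES:
            raise ValueError(f"unknown gap status {self.status!r}")

    @property
    def gap_id(self) -> str:
        return f"{self.scaffold_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_gaps(
    record: ScaffoldRecord, min_gap_len: int = 1, flank_len: int = 500
) -> list[GapRecord]:
    """Locate every maximal N-run of length >= min_gap_len, with flanks.

    Flanks stop at scaffold ends and at neighbouring N-runs, so they are
    always N-free. Output is sorted by start coordinate.
    """
    if min_gap_len < 1 or flank_len < 1:
        raise ValueError("min_gap_len and flank_len must be positive")
    seq = record.sequence
    gaps = []
    for m in _N_RUN.finditer(seq):
        if m.end() - m.start() < min_gap_len:
            continue
        left_lo = m.start() - flank_len
        left = seq[max(0, left_lo) : m.start()]
        if (cut := left.rfind("N")) != -1:
            left = left[cut + 1 :]
        right = seq[m.end() : m.end() + flank_len]
        if (cut := right.find("N")) != -1:
            right = right[:cut]
        gaps.append(
            GapRecord(
                scaffold_id=record.id,
                start=m.start(),
                end=m.end(),
                left_flank=left,
                right_flank=right,
            )
        )
    return gaps


def patch_scaffold(record: ScaffoldRecord, gap: GapRecord, fill: str) -> ScaffoldRecord:
    """Replace the gap's N-run with ``fill``; bases outside it are untouched."""
    if gap.scaffold_id != record.id:
        raise ValueError(f"gap {gap.gap_id} does not belong to scaffold {record.id!r}")
    if gap.end > len(record.sequence) or set(
        record.sequence[gap.start : gap.end]
    ) != {"N"}:
        raise ValueError(f"gap {gap.gap_id} coordinates do not match an N-run")
    if "N" in fill:
        raise ValueError("fill must not contain N")
    seq = record.sequence[: gap.start] + fill + record.sequence[gap.end :]
    return ScaffoldRecord(id=record.id, sequence=seq)


def classify_gaps(
    gaps: Sequence[GapRecord], fixed_gap_list: Iterable[str] | None = None
) -> list[GapRecord]:
    """Set gap status: ids on the fixed list -> ``fixed`` (routed to external
    tools), everything else -> ``unfixed`` (routed to the predictor)."""
    fixed: set[str] = set()
    if fixed_gap_list is not None:
        seen = list(fixed_gap_list)
        fixed = set(seen)
        if len(seen) != len(fixed):
            log.warning("fixed gap list contains duplicates; deduplicated")
        unknown = fixed - {g.gap_id for g in gaps}
        if unknown:
            raise ValueError(f"fixed gap list names unknown gaps: {sorted(unknown)}")
    return [
        replace(g, status="fixed" if g.gap_id in fixed else "unfixed") for g in gaps
    ]


def write_gap_bed(gaps: Iterable[GapRecord], path: str | Path) -> None:
    """Write gaps as BED3+1 (scaffold, start, end, status)."""
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{g.scaffold_id}\t{g.start}\t{g.end}\t{g.status}\n")


def read_gap_bed(path: str | Path) -> list[GapRecord]:
    """Read a BED3+1 gap inventory written by :func:`write_gap_bed`.

    Flanks are not stored in BED; re-extract them with :func:`detect_gaps`
    or attach them from the source scaffold as needed.
    """
    gaps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            status = parts[3] if len(parts) > 3 else "unclassified"
            gaps.append(
                GapRecord(
                    scaffold_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    status=status,
                )
            )
    return gaps


def attach_flanks(
    gaps: Sequence[GapRecord], record: ScaffoldRecord, flank_len: int = 500
) -> list[GapRecord]:
    """Re-extract flanks for BED-loaded gaps from their source scaffold."""
    by_coord = {
        (g.start, g.end): g for g in detect_gaps(record, 1, flank_len)
    }
    out = []
    for g in gaps:
        if g.scaffold_id != record.id:
            out.append(g)
            continue
        src = by_coord.get((g.start, g.end))
        if src is None:
            raise ValueError(f"gap {g.gap_id} not found as an N-run in {record.id!r}")
        out.append(replace(g, left_flank=src.left_flank, right_flank=src.right_flank))
    return out
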