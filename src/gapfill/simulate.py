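"""Seeded synthetic genomes, gapped scaffolds, truth tables and oracles.

The generator emulates the two sequence regimes that matter for gap
filling: *repeat blocks* (tandem copies of a short motif — the regime a
context model can actually learn and extrapolate into a gap) and
*unique blocks* (i.i.d. bases at a target GC — essentially
unpredictable, so fills there exercise the prediction filter). Blocks
alternate along the genome; gaps are then punched as N-runs with every
masked base recorded in a truth table, so recovery is exactly scorable.

All randomness flows through ``numpy.random.default_rng(seed)``; every
generator is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gaps import GapRecord, detect_gaps
from .io import ScaffoldRecord


@dataclass(frozen=True)
class GenomeSpec:
    length: int = 50_000
    gc_content: float = 0.45
    repeat_motif_len: int = 21
    repeat_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("length must be >= 1000")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if self.repeat_motif_len < 1:
            raise ValueError("repeat_motif_len must be >= 1")


@dataclass(frozen=True)
class TruthEntry:
    scaffold_id: str
    start: int
    end: int
    truth_sequence: str
    region: str = ""  # "repeat" | "unique" | "" when unknown

    def __post_init__(self) -> None:
        if len(self.truth_sequence) != self.end - self.start:
            raise ValueError("truth_sequence length must equal end - start")
        if "N" in self.truth_sequence:
            raise ValueError("truth_sequence must not contain N")


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, gap: GapRecord) -> TruthEntry | None:
        for e in self.entries:
            if (e.scaffold_id, e.start, e.end) == (gap.scaffold_id, gap.start, gap.end):
                return e
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.scaffold_id, e.start, e.end, e.truth_sequence, e.region)
             for e in self.entries],
            columns=["scaffold_id", "start", "end", "truth_sequence", "region"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(
            [TruthEntry(r.scaffold_id, int(r.start), int(r.end),
                        r.truth_sequence, str(r.region))
             for r in df.itertuples()]
        )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    return _BASES[rng.choice(4, size=n, p=_base_probs(gc))].tobytes().decode()


def generate_genome_with_layout(
    spec: GenomeSpec, scaffold_id: str = "sim", block_len: int = 5000
) -> tuple[ScaffoldRecord, list[tuple[int, int, str]]]:
    """Genome plus its block layout [(start, end, "repeat"|"unique"), ...].

    Unique and repeat blocks alternate in ~``block_len`` pieces, with the
    repeat share set by ``repeat_fraction``. Each repeat block is tandem
    copies of one motif drawn once per genome.
    """
    rng = np.random.default_rng(spec.rng_seed)
    motif = _random_bases(rng, spec.repeat_motif_len, spec.gc_content)
    pieces: list[str] = []
    layout: list[tuple[int, int, str]] = []
    pos = 0
    want_repeat = spec.repeat_fraction >= 0.5  # start with the majority regime
    while pos < spec.length:
        remaining = spec.length - pos
        # target sizes keep the realized repeat share near the spec
        rep_so_far = sum(e - s for s, e, k in layout if k == "repeat")
        rep_deficit = spec.repeat_fraction * spec.length - rep_so_far
        kind = "repeat" if (want_repeat and rep_deficit > 0) or rep_deficit >= remaining else "unique"
        size = min(block_len, remaining)
        if kind == "repeat":
            size = min(size, int(np.ceil(rep_deficit)))
            # phase-lock tandem copies to the absolute position so that a
            # fully repetitive genome is exactly periodic across blocks
            phase = pos % spec.repeat_motif_len
            reps = int(np.ceil((size + phase) / spec.repeat_motif_len)) + 1
            block = (motif * reps)[phase : phase + size]
        else:
            block = _random_bases(rng, size, spec.gc_content)
        pieces.append(block)
        layout.append((pos, pos + size, kind))
        pos += size
        want_repeat = not want_repeat
    return ScaffoldRecord(id=scaffold_id, sequence="".join(pieces)), layout


def generate_genome(spec: GenomeSpec, scaffold_id: str = "sim") -> ScaffoldRecord:
    """Seeded genome: i.i.d. bases at the target GC in unique blocks,
    tandem motif copies in repeat blocks."""
    return generate_genome_with_layout(spec, scaffold_id)[0]


def introduce_gaps(
    genome: ScaffoldRecord,
    n_gaps: int,
    gap_len_range: tuple[int, int] = (20, 100),
    min_spacing: int = 200,
    rng_seed: int = 0,
    edge_margin: int = 500,
    regions: Sequence[tuple[int, int]] | None = None,
    region_labels: Callable[[int], str] | None = None,
    max_tries: int = 10_000,
) -> tuple[ScaffoldRecord, TruthTable]:
    """Mask ``n_gaps`` non-overlapping intervals with N and record the truth.

    Gaps keep ``min_spacing`` bases between each other and never sit
    within ``edge_margin`` of the scaffold ends (the predictor needs full
    flanks). ``regions`` restricts placement to given intervals.
    """
    lo, hi = gap_len_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid gap_len_range")
    rng = np.random.default_rng(rng_seed)
    L = len(genome.sequence)
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < n_gaps:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_gaps} gaps after {max_tries} tries; "
                "relax spacing or gap count"
            )
        tries += 1
        glen = int(rng.integers(lo, hi + 1))
        if regions is not None:
            rs, re_ = regions[int(rng.integers(len(regions)))]
            rs, re_ = max(rs, edge_margin), min(re_, L - edge_margin)
            if re_ - rs < glen:
                continue
            start = int(rng.integers(rs, re_ - glen + 1))
        else:
            if L - edge_margin - glen <= edge_margin:
                raise ValueError("genome too short for the requested edge margin")
            start = int(rng.integers(edge_margin, L - edge_margin - glen + 1))
        end = start + glen
        if any(start < pe + min_spacing and ps - min_spacing < end for ps, pe in placed):
            continue
        placed.append((start, end))
    placed.sort()
    seq = list(genome.sequence)
    entries = []
    for start, end in placed:
        truth_seq = genome.sequence[start:end]
        label = region_labels(start) if region_labels else ""
        entries.append(TruthEntry(genome.id, start, end, truth_seq, label))
        seq[start:end] = "N" * (end - start)
    return ScaffoldRecord(id=genome.id, sequence="".join(seq)), TruthTable(entries)


def markov_oracle(order: int, rng_seed: int = 0):
    """A seeded random Markov next-base oracle over 4^order contexts.

    Rows are Dirichlet(1,1,1,1) simplexes; contexts shorter than the
    order are left-padded with A. Stands in for a trained model in
    search tests and supports brute-force enumeration of completions.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    from .encode import CHANNEL_ORDER

    rng = np.random.default_rng(rng_seed)
    table = rng.dirichlet(np.ones(4), size=max(1, 4**order))
    idx = {b: i for i, b in enumerate(CHANNEL_ORDER)}

    def row_for(context: str) -> np.ndarray:
        ctx = ("A" * order + context)[-order:] if order else ""
        code = 0
        for ch in ctx:
            code = code * 4 + idx[ch]
        return table[code]

    def oracle(contexts: Sequence[str]) -> np.ndarray:
        return np.stack([row_for(c) for c in contexts])

    return oracle


@dataclass
class Fixture:
    """A complete simulated study: genome, gapped scaffold, truth, layout."""

    genome: ScaffoldRecord
    scaffold: ScaffoldRecord
    truth_table: TruthTable
    layout: list[tuple[int, int, str]]
    gaps: list[GapRecord]


def make_fixture(
    seed: int = 0,
    spec: GenomeSpec | None = None,
    n_gaps: int = 20,
    gap_len_range: tuple[int, int] = (20, 100),
    flank_len: int = 500,
) -> Fixture:
    """The standard end-to-end fixture: a 50 kb genome at GC 0.45, half
    tandem 21-mers, with gaps split evenly between repeat blocks
    (recoverable) and unique blocks (hard)."""
    spec = spec or GenomeSpec(rng_seed=seed)
    genome, layout = generate_genome_with_layout(spec)
    repeat_regions = [(s, e) for s, e, k in layout if k == "repeat"]
    unique_regions = [(s, e) for s, e, k in layout if k == "unique"]

    def label(pos: int) -> str:
        for s, e, k in layout:
            if s <= pos < e:
                return k
        return ""

    half = n_gaps // 2
    scaffold_a, truth_a = introduce_gaps(
        genome, half, gap_len_range, rng_seed=seed * 2 + 1,
        regions=repeat_regions or None, region_labels=label, edge_margin=flank_len,
    )
    # punch the unique-block gaps into the already-gapped scaffold, spacing
    # against the repeat gaps by restricting to unique regions
    scaffold, truth_b = introduce_gaps(
        ScaffoldRecord(genome.id, scaffold_a.sequence),
        n_gaps - half, gap_len_range, rng_seed=seed * 2 + 2,
        regions=unique_regions or None, region_labels=label, edge_margin=flank_len,
    )
    # truth for the second round must come from the ungapped genome
    entries = list(truth_a.entries)
    for e in truth_b.entries:
        entries.append(
            TruthEntry(e.scaffold_id, e.start, e.end,
                       genome.sequence[e.start : e.end], e.region)
        )
    entries.sort(key=lambda e: e.start)
    truth = TruthTable(entries)
    gaps = detect_gaps(scaffold, min_gap_len=1, flank_len=flank_len)
    return Fixture(genome=genome, scaffold=scaffold, truth_table=truth,
                   layout=layout, gaps=gaps)
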