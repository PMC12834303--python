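"""End-to-end orchestration: detect -> classify -> predict -> filter ->
patch -> evaluate, with a manifest that makes the run reproducible.

Every tunable consumed by any stage is echoed into the manifest after
resolution, and all randomness is derived from the run seed, so an
identical config + seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filtering import (FilterVerdict, fasta_homolog_provider, filter_predictions,
                        truth_homolog_provider)
from .gaps import (GapRecord, classify_gaps, detect_gaps, patch_scaffold,
                   write_gap_bed)
from .io import ScaffoldRecord, read_fasta, write_fasta
from .metrics import AssemblyMetrics, evaluate_run
from .model import NextBaseModel, load_model
from .search import BeamSchedule, GapFill, HeuristicWeights, fill_gap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    scaffold_path: str
    model_path: str
    out_dir: str
    truth_path: str | None = None  # simulator truth genome for the filter
    homolog_path: str | None = None  # or user-supplied homolog FASTA by gap id
    flank_len: int = 500
    min_gap_len: int = 1
    min_flank: int = 50
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    beam_width: int = 16  # peak width; schedule is w/2 -> w -> w/2
    contract_at: float = 0.75
    p_min: float = 1e-9
    tau: float = 0.9
    baseline_margin: int = 50
    mode: str = "bidirectional"
    rng_seed: int = 0
    fixed_gap_list: tuple[str, ...] = ()


@dataclass
class RunOutput:
    patched: list[ScaffoldRecord]
    unfiltered_patched: list[ScaffoldRecord]
    gaps: list[GapRecord]
    fills: list[GapFill]
    available: list[GapFill]
    verdicts: list[FilterVerdict]
    metrics_before: AssemblyMetrics
    metrics_after: AssemblyMetrics
    delta: dict
    manifest: dict


def _apply_fills(
    scaffolds: Sequence[ScaffoldRecord], fills: Sequence[GapFill]
) -> list[ScaffoldRecord]:
    by_id = {r.id: r for r in scaffolds}
    # patch right-to-left so earlier coordinates stay valid even if a fill
    # ever changes the length
    for f in sorted(fills, key=lambda f: (f.gap.scaffold_id, -f.gap.start)):
        by_id[f.gap.scaffold_id] = patch_scaffold(by_id[f.gap.scaffold_id], f.gap, f.sequence)
    return [by_id[r.id] for r in scaffolds]


def run_pipeline_in_memory(
    model: NextBaseModel,
    scaffolds: Sequence[ScaffoldRecord],
    config: RunConfig,
    truth: Sequence[ScaffoldRecord] | None = None,
    homologs: Sequence[ScaffoldRecord] | None = None,
) -> RunOutput:
    """The full run on in-memory objects; `run_pipeline` adds file I/O."""
    weights = HeuristicWeights(config.alpha, config.beta, config.gamma)
    schedule = BeamSchedule.from_peak(config.beam_width, config.contract_at)

    gaps: list[GapRecord] = []
    for rec in scaffolds:
        gaps.extend(detect_gaps(rec, config.min_gap_len, config.flank_len))
    gaps = classify_gaps(gaps, config.fixed_gap_list or None)

    fills: list[GapFill] = []
    for gap in gaps:
        if gap.status == "fixed":
            continue
        fill = fill_gap(
            model, gap, weights, schedule, mode=config.mode,
            min_flank=config.min_flank, p_min=config.p_min,
        )
        if fill is not None:
            fills.append(fill)
            log.info("gap %s: %s fill f=%.3f g=%.3f mean_p=%.3f", gap.gap_id,
                     fill.direction, fill.f, fill.g, fill.mean_step_prob)

    if truth is not None:
        provider = truth_homolog_provider(truth, margin=config.baseline_margin)
    elif homologs is not None:
        provider = fasta_homolog_provider(homologs)
    else:
        provider = None

    if provider is not None:
        available, _, verdicts = filter_predictions(
            fills, provider, tau=config.tau, baseline_margin=config.baseline_margin
        )
    else:
        log.warning("no homolog/truth source; applying all fills unfiltered")
        available, verdicts = list(fills), []

    patched = _apply_fills(scaffolds, available)
    unfiltered_patched = _apply_fills(scaffolds, fills)
    m_before, m_after, delta = evaluate_run(list(scaffolds), patched, gaps, truth)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "model_fingerprint": model.training_fingerprint,
        "n_gaps": len(gaps),
        "n_fills_predicted": len(fills),
        "n_fills_available": len(available),
    }
    return RunOutput(
        patched=patched, unfiltered_patched=unfiltered_patched, gaps=gaps,
        fills=fills, available=available, verdicts=verdicts,
        metrics_before=m_before, metrics_after=m_after, delta=delta,
        manifest=manifest,
    )


def write_outputs(out: RunOutput, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out.patched, out_dir / "patched.fasta")
    write_gap_bed(out.gaps, out_dir / "gaps.bed")
    pd.DataFrame(
        [(f.gap_id, f.direction, f.f, f.g, f.mean_step_prob, f.sequence)
         for f in out.fills],
        columns=["gap_id", "direction", "f", "g", "mean_step_prob", "sequence"],
    ).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(v.gap_id, v.candidate_id, v.report.rate, v.baseline_rate,
          v.report.edit_distance, v.label) for v in out.verdicts],
        columns=["gap_id", "candidate_id", "rate", "baseline_rate",
                 "edit_distance", "label"],
    ).to_csv(out_dir / "verdicts.tsv", sep="\t", index=False)
    rows = []
    for name, m in (("before", out.metrics_before), ("after", out.metrics_after)):
        rows.append((name, m.gaps_total, m.gaps_filled, m.fill_rate, m.n_count,
                     m.ns_per_100kb, m.mismatches_per_100kb, m.gc_fraction))
    pd.DataFrame(rows, columns=[
        "stage", "gaps_total", "gaps_filled", "fill_rate", "n_count",
        "ns_per_100kb", "mismatches_per_100kb", "gc_fraction",
    ]).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    with open(out_dir / "delta.json", "w") as fh:
        json.dump(out.delta, fh, indent=2, sort_keys=True)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(out.manifest, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunOutput:
    """Load inputs, run every stage, write outputs + manifest to out_dir."""
    scaffolds = read_fasta(config.scaffold_path)
    model = load_model(config.model_path)
    truth = read_fasta(config.truth_path) if config.truth_path else None
    homologs = read_fasta(config.homolog_path) if config.homolog_path else None
    out = run_pipeline_in_memory(model, scaffolds, config, truth, homologs)
    write_outputs(out, config.out_dir)
    return out
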