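"""End-to-end orchestration: simulate/ingest, preprocess, peaks, classify, report.

`run_full_pipeline` wires the stages together and writes plain-text
artifacts (manifest, rejection log, peak tables, metric tables, run log)
into one directory, so a whole run is reproducible from its embedded
configuration and seed.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .catalogue import default_catalogue
from .classify import LOPO, LOSO, EvaluationReport, MetricReport, ModelConfig, round_half_away, run_two_step
from .core import SpectraCohort
from .difference import assign_peaks, detect_signed_peaks, difference_spectrum, group_mean
from .errors import SersdxError
from .io import read_cohort, write_cohort
from .preprocess import PreprocessConfig, preprocess_cohort
from .synthetic import SyntheticConfig, generate_cohort

_TUMOR_PAIRS = (("PA", "Normal"), ("WT", "Normal"), ("MEC", "Normal"))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed is recorded in all outputs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    manifest: str | None = None  # when set, ingest this cohort instead of simulating
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    peak_min_prominence: float | None = None  # None: 2x robust noise estimate
    peak_min_separation: float = 8.0
    assignment_tolerance: float = 3.0
    schemes: tuple[str, ...] = (LOSO, LOPO)
    seed: int = 0


def _fmt_pct(x: float) -> str:
    return f"{round_half_away(1000.0 * x) / 10:.1f} %"


def _fmt_mcc(x: float) -> str:
    return f"{round_half_away(1000.0 * x) / 1000:.3f}"


def render_tables(report: EvaluationReport) -> str:
    """Render metric tables, one per (step, scheme), in publication layout.

    Percentages to one decimal, MCC to three decimals, rounding half away
    from zero.
    """
    blocks = []
    for step in (1, 2):
        for scheme in (LOSO, LOPO):
            rows = [r for r in report.reports if r.step == step and r.scheme == scheme]
            title = f"Step {step} - {scheme}"
            header = ["Parameter"] + [f"{r.task[0]} vs {r.task[1]}" for r in rows]
            lines = [title, "\t".join(header)]
            for name, getter, fmt in (
                ("SP", lambda r: r.sp, _fmt_pct),
                ("SE", lambda r: r.se, _fmt_pct),
                ("ACC", lambda r: r.acc, _fmt_pct),
                ("MCC", lambda r: r.mcc, _fmt_mcc),
            ):
                lines.append("\t".join([name] + [fmt(getter(r)) for r in rows]))
            blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def _write_metrics_csv(report: EvaluationReport, path: Path) -> int:
    rows = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["step", "scheme", "positive", "negative", "SP", "SE", "ACC", "MCC",
             "tp", "fn", "tn", "fp"]
        )
        for r in report.reports:
            c = r.counts
            writer.writerow(
                [r.step, r.scheme, r.task[0], r.task[1],
                 f"{r.sp:.6f}", f"{r.se:.6f}", f"{r.acc:.6f}", f"{r.mcc:.6f}",
                 c.tp, c.fn, c.tn, c.fp]
            )
            rows += 1
    return rows


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run simulate/ingest -> preprocess -> difference peaks -> two-step SVM.

    Returns the output directory.  Any stage failure aborts with a
    stage-named error; artifacts written before the failure are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"sersdx {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"seed {config.seed}",
    ]

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate with the failing stage
            (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at {name}: {exc}\n")
            raise SersdxError(f"stage {name!r} failed: {exc}") from exc
        log_lines.append(f"stage {name} ok")
        return result

    def _acquire() -> SpectraCohort:
        if config.manifest is not None:
            return read_cohort(config.manifest)
        cfg = config.synthetic
        return generate_cohort(cfg, seed=config.seed)

    raw = stage("acquire", _acquire)
    stage("write-manifest", lambda: write_cohort(raw, out / "cohort"))

    def _preprocess():
        return preprocess_cohort(raw, config.preprocess, return_rejected=True)

    processed, rejected = stage("preprocess", _preprocess)
    with open(out / "rejections.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["spectrum_id", "reason"])
        writer.writerows(rejected)

    catalogue = config.synthetic.catalogue or default_catalogue()

    def _peaks():
        n_tables = 0
        for tumor, normal in _TUMOR_PAIRS:
            if not processed.group_spectra(tumor) or not processed.group_spectra(normal):
                continue
            diff = difference_spectrum(group_mean(processed, tumor), group_mean(processed, normal))
            hits = assign_peaks(
                detect_signed_peaks(diff, config.peak_min_prominence, config.peak_min_separation),
                catalogue,
                config.assignment_tolerance,
            )
            with open(out / f"peaks_{tumor}_vs_{normal}.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["position", "sign", "magnitude", "assignment"])
                for h in hits:
                    writer.writerow([h.position, h.sign, f"{h.magnitude:.6g}", h.assignment])
            n_tables += 1
        return n_tables

    n_tables = stage("difference-peaks", _peaks)
    log_lines.append(f"peak tables: {n_tables}")

    report = stage("classify", lambda: run_two_step(processed, config.model, config.schemes))
    n_rows = _write_metrics_csv(report, out / "metrics.csv")
    (out / "metrics.txt").write_text(render_tables(report))
    log_lines.append(f"metric rows: {n_rows}")
    for w in report.warnings:
        log_lines.append(f"warning: {w}")
    log_lines.append(f"finished {datetime.datetime.now().isoformat(timespec='seconds')}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


__all__ = ["RunConfig", "run_full_pipeline", "render_tables"]
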