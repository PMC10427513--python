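"""Orchestration: per-subject analysis runs and cohort comparisons.

`analyze_session` is the in-memory core: given one session's Dixon set,
label mask and airway landmarks it produces the long-format metric table
(one row per structure and metric) and the per-structure fat-fraction
histograms. `run_subject` / `run_cohort` wrap it with file I/O, manifest
writing and error context. Outputs are deterministic given inputs, options
and seed; nothing is written unless the whole computation succeeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import DEFAULT_N_BOOT, PairedCohortTable, summarize_comparisons
from .errors import AirwayFatError, ConfigError
from .fat_fraction import (
    DEFAULT_N_BINS,
    compute_fat_fraction_map,
    tissue_fat_metrics,
)
from .volume_io import DixonSet, LabelMask, load_dixon_set, load_label_mask, read_volume
from .volumetrics import AirwayLandmarks, airway_region_metrics

METRIC_SEP = "/"


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis parameters shared across subjects of one run."""

    background_threshold: float = 0.0
    n_bins: int = DEFAULT_N_BINS
    effect_variant: str = "d_rm"
    ci_method: str = "nct"
    n_boot: int = DEFAULT_N_BOOT
    seed: int = 0


@dataclass(frozen=True)
class SubjectSessionConfig:
    """File inputs for one subject's scan session."""

    subject: str
    session: str
    in_phase: Path
    out_phase: Path
    fat: Path
    water: Path
    mask: Path
    label_table: Path
    landmarks: Path

    def paths(self) -> dict[str, Path]:
        return {
            name: Path(getattr(self, name))
            for name in ("in_phase", "out_phase", "fat", "water", "mask", "label_table", "landmarks")
        }

    def validate(self) -> None:
        for name, path in self.paths().items():
            if not Path(path).exists():
                raise ConfigError(
                    f"subject {self.subject!r} session {self.session!r}: "
                    f"{name} file not found: {path}"
                )


def read_landmarks(path: str | Path) -> AirwayLandmarks:
    """Read airway landmark slice indices from a YAML/JSON mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: landmark file must be a mapping")
    try:
        return AirwayLandmarks(
            hard_palate_slice=int(raw["hard_palate_slice"]),
            uvula_tip_slice=int(raw["uvula_tip_slice"]),
            epiglottis_base_slice=int(raw["epiglottis_base_slice"]),
            vocal_fold_slice=int(raw["vocal_fold_slice"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing landmark key {exc}") from exc


def write_landmarks(landmarks: AirwayLandmarks, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump(
            {
                "hard_palate_slice": landmarks.hard_palate_slice,
                "uvula_tip_slice": landmarks.uvula_tip_slice,
                "epiglottis_base_slice": landmarks.epiglottis_base_slice,
                "vocal_fold_slice": landmarks.vocal_fold_slice,
            },
            sort_keys=False,
        )
    )
    return path


def analyze_session(
    dixon: DixonSet,
    mask: LabelMask,
    landmarks: AirwayLandmarks,
    options: AnalysisOptions = AnalysisOptions(),
    subject: str = "",
    session: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute every per-structure metric for one session.

    Returns (metrics, histograms): metrics is long-format with columns
    subject, session, structure, metric, value; histograms has columns
    subject, session, structure, bin_left, bin_right, count.
    """
    ffmap = compute_fat_fraction_map(dixon, options.background_threshold)
    metric_rows: list[dict] = []
    hist_rows: list[dict] = []

    def add(structure: str, metric: str, value: float) -> None:
        metric_rows.append(
            {
                "subject": subject,
                "session": session,
                "structure": structure,
                "metric": metric,
                "value": float(value),
            }
        )

    for structure in mask.structures():
        if structure == "airway":
            continue
        tfm = tissue_fat_metrics(ffmap, mask, structure, n_bins=options.n_bins)
        add(structure, "tissue_volume_cm3", tfm.tissue_volume_cm3)
        add(structure, "fat_volume_cm3", tfm.fat_volume_cm3)
        add(structure, "fat_percent", tfm.fat_percent)
        add(structure, "median_fat_percent", tfm.median_fat_percent)
        for left, right, count in zip(
            tfm.histogram.bin_edges[:-1], tfm.histogram.bin_edges[1:], tfm.histogram.counts
        ):
            hist_rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "structure": structure,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "count": int(count),
                }
            )

    if "airway" in mask.label_table:
        for region, metrics in airway_region_metrics(mask, landmarks).items():
            add("airway", f"{region}_volume_cm3", metrics.volume_cm3)
            add("airway", f"{region}_mean_csa_mm2", metrics.mean_csa_mm2)
            add("airway", f"{region}_min_csa_mm2", metrics.min_csa_mm2)
            add("airway", f"{region}_length_mm", metrics.length_mm)

    return pd.DataFrame(metric_rows), pd.DataFrame(hist_rows)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _write_manifest(out_dir: Path, stem: str, payload: dict) -> Path:
    manifest = {
        "airwayfat_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": _config_hash(payload),
        **payload,
    }
    path = out_dir / f"{stem}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path


def run_subject(
    config: SubjectSessionConfig,
    out_dir: str | Path,
    options: AnalysisOptions = AnalysisOptions(),
) -> dict[str, Path]:
    """Analyse one subject session from files and write its outputs.

    Writes ``<subject>_<session>_metrics.csv``, ``..._histograms.csv`` and
    a JSON run manifest. All computation happens before any file is
    written, so a failure leaves no partial outputs.
    """
    config.validate()
    try:
        dixon = load_dixon_set(config.in_phase, config.out_phase, config.fat, config.water)
        reference = read_volume(config.in_phase)
        mask = load_label_mask(config.mask, reference, config.label_table)
        landmarks = read_landmarks(config.landmarks)
        metrics, histograms = analyze_session(
            dixon, mask, landmarks, options, subject=config.subject, session=config.session
        )
    except AirwayFatError as exc:
        raise type(exc)(
            f"subject {config.subject!r} session {config.session!r}: {exc}"
        ) from exc

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{config.subject}_{config.session}"
    paths = {
        "metrics": out_dir / f"{stem}_metrics.csv",
        "histograms": out_dir / f"{stem}_histograms.csv",
    }
    metrics.to_csv(paths["metrics"], index=False)
    histograms.to_csv(paths["histograms"], index=False)
    paths["manifest"] = _write_manifest(
        out_dir,
        stem,
        {
            "subject": config.subject,
            "session": config.session,
            "inputs": {k: str(v) for k, v in config.paths().items()},
            "options": asdict(options),
        },
    )
    return paths


def cohort_table_from_metrics(metrics: pd.DataFrame) -> PairedCohortTable:
    """Fold per-session structure metrics into a paired cohort table.

    Metric keys are ``structure/metric`` (e.g. ``tongue/fat_percent``).
    """
    data = metrics.assign(metric=metrics["structure"] + METRIC_SEP + metrics["metric"])
    return PairedCohortTable(data[["subject", "session", "metric", "value"]])


def run_cohort(
    metrics_csvs: list[str | Path],
    out_dir: str | Path,
    options: AnalysisOptions = AnalysisOptions(),
    histogram_csvs: list[str | Path] | None = None,
) -> dict[str, object]:
    """Paired cohort comparison from per-subject metric CSVs.

    Requires at least two complete subject pairs. Unpaired subjects are
    reported and excluded. Writes ``comparison.csv``, a rendered plain-text
    table, per-subject histogram overlay figures when histogram CSVs are
    supplied, and a manifest.
    """
    from .report import plot_session_histograms, render_comparison_text

    if not metrics_csvs:
        raise ConfigError("no metrics CSVs supplied")
    metrics = pd.concat([pd.read_csv(p) for p in sorted(map(str, metrics_csvs))], ignore_index=True)
    cohort = cohort_table_from_metrics(metrics)
    sessions_per_subject = cohort.data.groupby("subject")["session"].nunique()
    paired = sorted(sessions_per_subject[sessions_per_subject == 2].index)
    unpaired = sorted(sessions_per_subject[sessions_per_subject < 2].index)
    if len(paired) < 2:
        raise ConfigError(
            f"cohort statistics need >= 2 complete subject pairs, found {len(paired)} "
            f"(unpaired subjects: {unpaired or 'none'})"
        )
    cohort = PairedCohortTable(cohort.data[cohort.data["subject"].isin(paired)])
    summary = summarize_comparisons(
        cohort,
        variant=options.effect_variant,
        ci_method=options.ci_method,
        n_boot=options.n_boot,
        seed=options.seed,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}
    summary.to_csv(out_dir / "comparison.csv", index=False)
    (out_dir / "comparison.txt").write_text(render_comparison_text(summary))
    paths["comparison_csv"] = out_dir / "comparison.csv"
    paths["comparison_txt"] = out_dir / "comparison.txt"
    if unpaired:
        (out_dir / "unpaired_subjects.txt").write_text("\n".join(unpaired) + "\n")
        paths["unpaired"] = out_dir / "unpaired_subjects.txt"

    if histogram_csvs:
        hist = pd.concat([pd.read_csv(p) for p in sorted(map(str, histogram_csvs))], ignore_index=True)
        figures = []
        for subject in paired:
            sub = hist[hist["subject"] == subject]
            if set(sub["session"].unique()) == {"baseline", "followup"}:
                fig_path = out_dir / f"{subject}_fat_histograms.png"
                plot_session_histograms(sub, fig_path, title=f"Subject {subject}")
                figures.append(fig_path)
        paths["figures"] = figures

    paths["manifest"] = _write_manifest(
        out_dir,
        "cohort",
        {
            "metrics_csvs": sorted(map(str, metrics_csvs)),
            "n_paired_subjects": len(paired),
            "unpaired_subjects": unpaired,
            "options": asdict(options),
        },
    )
    paths["summary"] = summary
    return paths
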