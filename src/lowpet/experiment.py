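"""End-to-end experiment orchestration: simulate -> truncate -> fit -> summarise.

A single :class:`ExperimentConfig` drives the whole pipeline
deterministically: cohort simulation under every requested truncation
scheme, SRTM/SUVR quantification per subject and region, and the
scheme-versus-full agreement statistics.  All tabular outputs are plain
CSV (UTF-8, '.' decimal separator) and manifests are JSON, so every stage
is re-ingestable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .framing import SCHEME_LABELS
from .kinetics import SRTMBasis, SuvrWindow, compute_suvr, fit_srtm
from .simulate import (
    TRACER_PRESETS,
    CohortConfig,
    KineticParams,
    NoiseModel,
    SubjectDataset,
    TimeActivityCurve,
    make_cohort,
)
from .stats import pivot_bias_table, summarise

logger = logging.getLogger("lowpet")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "quantify_dataset",
    "write_cohort",
    "write_dataset",
    "read_dataset",
    "ingest_tacs",
]


@dataclass
class ExperimentConfig:
    """Full configuration of one low-activity experiment."""

    seed: int
    tracer: str = "UCBJ"
    n_subjects: int = 5
    scheme_labels: list[str] = field(default_factory=lambda: list(SCHEME_LABELS))
    outcomes: list[str] = field(default_factory=lambda: ["BPnd", "SUVR"])
    midtime_convention: str = "retained_window"
    noise_mode: str = "poisson"  # poisson | expected | none
    sensitivity: float = 0.05
    weights_mode: str = "uniform"
    k2a_min: float = 0.006
    k2a_max: float = 0.6
    k2a_n: int = 100
    suvr_window_s: tuple[float, float] = (3600.0, 5400.0)
    bp_jitter_cv: float = 0.10
    r1_jitter_cv: float = 0.05
    k2_jitter_cv: float = 0.05
    vary_injected_activity: bool = True
    alpha: float = 0.05
    out_dir: str | None = None
    write_tacs: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.tracer not in TRACER_PRESETS:
            raise ValueError(f"unknown tracer {self.tracer!r}; available: {sorted(TRACER_PRESETS)}")
        bad = [s for s in self.scheme_labels if s not in SCHEME_LABELS]
        if bad:
            raise ValueError(f"unknown scheme labels {bad}; valid: {list(SCHEME_LABELS)}")
        if "full" not in self.scheme_labels:
            raise ValueError("scheme_labels must include 'full' (the comparison anchor)")
        bad_out = [o for o in self.outcomes if o not in ("BPnd", "SUVR")]
        if bad_out:
            raise ValueError(f"unknown outcomes {bad_out}; valid: ['BPnd', 'SUVR']")

    @property
    def k2a_grid(self) -> np.ndarray:
        return np.geomspace(self.k2a_min, self.k2a_max, self.k2a_n)

    @property
    def suvr_window(self) -> SuvrWindow:
        return SuvrWindow(*self.suvr_window_s)

    def noise_model(self) -> NoiseModel:
        return NoiseModel(sensitivity=self.sensitivity, mode=self.noise_mode, seed=self.seed)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            bp_jitter_cv=self.bp_jitter_cv,
            r1_jitter_cv=self.r1_jitter_cv,
            k2_jitter_cv=self.k2_jitter_cv,
            vary_injected_activity=self.vary_injected_activity,
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["suvr_window_s"] = list(self.suvr_window_s)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        if "suvr_window_s" in d:
            d["suvr_window_s"] = tuple(d["suvr_window_s"])
        return cls(**d)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    outcomes: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.10g")
        self.outcomes.to_csv(out / "outcomes.csv", **kw)
        self.summary.to_csv(out / "summary_long.csv", **kw)
        for outcome in sorted(self.outcomes["outcome"].unique()):
            wide = pivot_bias_table(self.summary, outcome)
            wide.to_csv(out / f"bias_{outcome}_wide.csv", float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _analysis_targets(dataset: SubjectDataset) -> list[str]:
    """Regions to quantify: the tracer's analysis list, else all non-reference."""
    preset = TRACER_PRESETS.get(dataset.tracer)
    if preset is not None and set(preset.regions) <= set(dataset.tacs):
        return list(preset.regions)
    return [r for r in dataset.tacs if r != dataset.reference_region]


def quantify_dataset(
    dataset: SubjectDataset,
    outcomes=("BPnd", "SUVR"),
    weights_mode: str = "uniform",
    k2a_grid: np.ndarray | None = None,
    suvr_window: SuvrWindow | None = None,
    basis: SRTMBasis | None = None,
) -> list[dict]:
    """Quantify one subject dataset; returns tidy outcome records."""
    reference = dataset.tacs[dataset.reference_region]
    if basis is None and "BPnd" in outcomes:
        basis = SRTMBasis(reference, k2a_grid)
    records = []
    for region in _analysis_targets(dataset):
        target = dataset.tacs[region]
        base = {
            "subject": dataset.subject_id,
            "region": region,
            "scheme_label": dataset.scheme_label,
        }
        if "BPnd" in outcomes:
            res = fit_srtm(target, reference, weights_mode=weights_mode, basis=basis)
            records.append(
                {
                    **base,
                    "outcome": "BPnd",
                    "value": res.bp_nd,
                    "r1": res.r1,
                    "k2_per_min": res.k2,
                    "wrss": res.wrss,
                    "converged": res.converged,
                    "negative_bp_flag": res.negative_bp_flag,
                }
            )
        if "SUVR" in outcomes:
            records.append(
                {
                    **base,
                    "outcome": "SUVR",
                    "value": compute_suvr(target, reference, suvr_window),
                }
            )
    return records


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full experiment; deterministic given (config, seed)."""
    manifest: dict = {
        "software": f"lowpet {__version__}",
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    t0 = time.perf_counter()
    try:
        cohort = make_cohort(
            tracer=config.tracer,
            n_subjects=config.n_subjects,
            scheme_labels=config.scheme_labels,
            nm=config.noise_model(),
            config=config.cohort_config(),
            midtime_convention=config.midtime_convention,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    n_ds = sum(len(v) for v in cohort.values())
    manifest["stages"]["simulate"] = {"datasets": n_ds, "elapsed_s": round(time.perf_counter() - t0, 3)}
    logger.info("stage=simulate datasets=%d elapsed=%.2fs", n_ds, time.perf_counter() - t0)

    if config.out_dir and config.write_tacs:
        write_cohort(cohort, Path(config.out_dir) / "tacs")

    t0 = time.perf_counter()
    records = []
    for lab in config.scheme_labels:
        for ds in cohort[lab]:
            try:
                records.extend(
                    quantify_dataset(
                        ds,
                        outcomes=config.outcomes,
                        weights_mode=config.weights_mode,
                        k2a_grid=config.k2a_grid,
                        suvr_window=config.suvr_window,
                    )
                )
            except Exception as e:
                raise RuntimeError(
                    f"stage 'fit' failed on subject={ds.subject_id} scheme={lab}: {e}"
                ) from e
    outcomes = pd.DataFrame(records)
    manifest["stages"]["fit"] = {
        "records": len(outcomes),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    logger.info("stage=fit records=%d elapsed=%.2fs", len(outcomes), time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        summary = summarise(outcomes, alpha=config.alpha)
    except Exception as e:
        raise RuntimeError(f"stage 'stats' failed: {e}") from e
    manifest["stages"]["stats"] = {
        "records": len(summary),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    logger.info("stage=stats records=%d elapsed=%.2fs", len(summary), time.perf_counter() - t0)

    result = ExperimentResult(config=config, outcomes=outcomes, summary=summary, manifest=manifest)
    if config.out_dir:
        result.write(config.out_dir)
    return result


# ---------------------------------------------------------------------------
# Dataset I/O: one directory per (scheme, subject) with per-region TAC CSVs
# and a JSON manifest.
# ---------------------------------------------------------------------------

def _sanitize(label: str) -> str:
    return label.replace("/", "_")


def write_dataset(dataset: SubjectDataset, directory) -> None:
    """Write one subject dataset as per-region CSVs plus ``manifest.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for region, tac in dataset.tacs.items():
        tac.to_frame().to_csv(d / f"{region}.csv", index=False, float_format="%.10g")
    manifest = {
        "subject_id": dataset.subject_id,
        "tracer": dataset.tracer,
        "injected_activity_MBq": dataset.injected_activity_MBq,
        "reference_region": dataset.reference_region,
        "scheme_label": dataset.scheme_label,
        "midtime_convention": dataset.midtime_convention,
        "units": {"conc": "kBq/mL", "time": "s"},
        "truth": {
            r: {"r1": k.r1, "k2_per_min": k.k2, "bp_nd": k.bp_nd}
            for r, k in dataset.truth.items()
        },
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_cohort(cohort: dict[str, list[SubjectDataset]], root) -> None:
    for lab, datasets in cohort.items():
        for ds in datasets:
            write_dataset(ds, Path(root) / _sanitize(lab) / ds.subject_id)


def _read_tac_csv(path: Path, region: str) -> TimeActivityCurve:
    df = pd.read_csv(path)
    required = {"frame_index", "midtime_s", "duration_s", "conc_kBq_per_mL"}
    if not required <= set(df.columns):
        raise ValueError(
            f"{path}: malformed TAC CSV, missing columns {sorted(required - set(df.columns))}"
        )
    mid = df["midtime_s"].to_numpy(float)
    bad = np.where(np.diff(mid) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: frame mid-times not strictly increasing at rows "
            f"{[int(b) + 2 for b in bad]} (1-based data rows, after header)"
        )
    counts = df["counts"].to_numpy(float) if "counts" in df.columns else None
    return TimeActivityCurve(
        region=region,
        midtimes_s=mid,
        durations_s=df["duration_s"].to_numpy(float),
        conc=df["conc_kBq_per_mL"].to_numpy(float),
        counts=counts,
    )


def read_dataset(directory) -> SubjectDataset:
    """Read one subject dataset written by :func:`write_dataset`."""
    d = Path(directory)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise ValueError(f"{d}: missing manifest.json")
    m = json.loads(mpath.read_text())
    tacs = {}
    for csv_path in sorted(d.glob("*.csv")):
        region = csv_path.stem
        tacs[region] = _read_tac_csv(csv_path, region)
    ref = m["reference_region"]
    if ref not in tacs:
        raise ValueError(f"{d}: missing TAC file for reference region '{ref}'")
    truth = {
        r: KineticParams(r1=v["r1"], k2=v["k2_per_min"], bp_nd=v["bp_nd"])
        for r, v in m.get("truth", {}).items()
    }
    return SubjectDataset(
        subject_id=m["subject_id"],
        tracer=m.get("tracer", "unknown"),
        injected_activity_MBq=float(m.get("injected_activity_MBq", float("nan"))),
        reference_region=ref,
        scheme_label=m.get("scheme_label", "full"),
        midtime_convention=m.get("midtime_convention", "retained_window"),
        tacs=tacs,
        truth=truth,
    )


def ingest_tacs(path) -> list[SubjectDataset]:
    """Load every subject dataset below ``path`` (any directory that holds a
    ``manifest.json``); datasets are validated on read."""
    root = Path(path)
    if not root.exists():
        raise ValueError(f"no such directory: {root}")
    dirs = sorted({p.parent for p in root.rglob("manifest.json")})
    if not dirs:
        raise ValueError(f"{root}: no datasets found (no manifest.json anywhere below)")
    return [read_dataset(d) for d in dirs]
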