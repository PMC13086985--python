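"""Synthetic dynamic PET cohorts with activity-fraction-scaled count noise.

The simulator produces regional time-activity curves (TACs) with the
statistical structure a low-injected-activity frame-truncation study relies
on:

* an analytic tri-exponential plasma input (the study design needs no
  arterial input; it exists only to generate a realistic reference-region
  curve),
* a one-tissue reference region ``C_R = K1' * (Cp (x) exp(-k2' t))``,
* SRTM-consistent target regions
  ``C_T = R1*C_R + (k2 - R1*k2a) * (C_R (x) exp(-k2a t))`` with
  ``k2a = k2 / (1 + BP_ND)``,
* Poisson count noise at the frame level: expected counts are the integral
  of the *decayed* activity over the retained frame window times a scanner
  sensitivity, so reducing the retained window reduces counts and inflates
  the variance of the decay-corrected concentration estimate exactly as a
  reduced injected activity would.

Activity fractions are paired within subject: one Poisson draw is made per
subject and region on a 1-s micro-grid spanning the full acquisition, and
every truncation scheme sums the *same* draws over its retained windows.
Events rejected by a delay are rejected consistently, mirroring list-mode
re-binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .framing import (
    SCHEME_LABELS,
    FrameSchedule,
    TruncatedFrame,
    apply_scheme,
    make_full_schedule,
    make_scheme,
)

__all__ = [
    "C11_HALF_LIFE_S",
    "C11_LAMBDA_PER_S",
    "InputFunctionParams",
    "ReferenceKinetics",
    "KineticParams",
    "NoiseModel",
    "TimeActivityCurve",
    "SubjectDataset",
    "TracerPreset",
    "CohortConfig",
    "TRACER_PRESETS",
    "plasma_input",
    "exp_conv",
    "fine_grid_s",
    "reference_tac",
    "srtm_forward",
    "bin_counts",
    "thin_counts",
    "make_cohort",
]

#: C-11 half-life (s) and decay constant.
C11_HALF_LIFE_S = 1223.0
C11_LAMBDA_PER_S = math.log(2.0) / C11_HALF_LIFE_S

#: Quadrature step for all convolutions / integrals (s).
FINE_DT_S = 1.0
TOTAL_DURATION_S = 5400.0


def fine_grid_s(total_s: float = TOTAL_DURATION_S, dt_s: float = FINE_DT_S) -> np.ndarray:
    """Uniform fine time grid in seconds, 0..total inclusive."""
    n = int(round(total_s / dt_s))
    return np.linspace(0.0, n * dt_s, n + 1)


# ---------------------------------------------------------------------------
# Continuous models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionParams:
    """Tri-exponential plasma input ``Cp(t)``.

    ``Cp(t) = (A1*(t-t0) - A2 - A3) e^{l1 (t-t0)} + A2 e^{l2 (t-t0)}
    + A3 e^{l3 (t-t0)}`` for ``t >= t0`` and 0 before the appearance
    delay ``t0``; all rates are negative so ``Cp(t0) = 0`` and
    ``Cp -> 0`` at late times.  Defaults are a conventional bolus shape
    (amplitudes in kBq/mL, rates per min).
    """

    A1: float = 851.1  # kBq mL^-1 min^-1
    A2: float = 21.9   # kBq mL^-1
    A3: float = 20.8   # kBq mL^-1
    l1: float = -4.1339  # min^-1
    l2: float = -0.1191  # min^-1
    l3: float = -0.01043  # min^-1
    t0: float = 0.5    # min

    def __post_init__(self) -> None:
        if not (self.l1 < 0 and self.l2 < 0 and self.l3 < 0):
            raise ValueError("all input-function rates must be negative")
        if self.A1 <= 0:
            raise ValueError("A1 must be positive")

    def scaled(self, factor: float) -> "InputFunctionParams":
        """Amplitude-scaled copy (e.g. for injected-activity variation)."""
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor, A3=self.A3 * factor)


@dataclass(frozen=True)
class ReferenceKinetics:
    """One-tissue kinetics of the reference region (K1' in mL cm^-3 min^-1)."""

    K1p: float = 0.35
    k2p: float = 0.15

    def __post_init__(self) -> None:
        if self.K1p < 0 or self.k2p < 0:
            raise ValueError("reference kinetic constants must be non-negative")


@dataclass(frozen=True)
class KineticParams:
    """SRTM parameters of one region.

    ``k2a = k2 / (1 + BP_ND)`` is the apparent efflux constant.  Truth values
    carry ``bp_nd >= 0``; fitted values may be negative (and are flagged by
    the fitting code), so only ``bp_nd > -1`` is enforced here.
    """

    r1: float
    k2: float  # min^-1
    bp_nd: float

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp_nd <= -1:
            raise ValueError("BP_ND must exceed -1 (k2a must stay positive)")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


def plasma_input(t_min, p: InputFunctionParams | None = None) -> np.ndarray:
    """Evaluate the tri-exponential plasma input at times ``t_min`` (minutes)."""
    p = p or InputFunctionParams()
    t = np.asarray(t_min, dtype=float)
    tau = t - p.t0
    with np.errstate(over="ignore"):
        cp = (
            (p.A1 * tau - p.A2 - p.A3) * np.exp(p.l1 * tau)
            + p.A2 * np.exp(p.l2 * tau)
            + p.A3 * np.exp(p.l3 * tau)
        )
    # The three terms cancel exactly at onset; clamp the float residue.
    return np.maximum(np.where(tau >= 0, cp, 0.0), 0.0)


def exp_conv(f: np.ndarray, k_per_min: float, dt_min: float) -> np.ndarray:
    """``(f (x) exp(-k t))(t_i)`` on a uniform grid, exact for piecewise-linear f.

    Uses the one-step recursion ``y_{i+1} = E y_i + I_i`` with
    ``E = exp(-k dt)`` and the closed-form integral of a linear segment
    against the exponential kernel; the recursion is evaluated as a linear
    filter, so the cost is O(n) and no large exponentials appear.
    """
    f = np.asarray(f, dtype=float)
    h = float(dt_min)
    if abs(k_per_min) < 1e-12:
        seg = 0.5 * h * (f[:-1] + f[1:])
        return np.concatenate(([0.0], np.cumsum(seg)))
    k = float(k_per_min)
    E = math.exp(-k * h)
    g = (1.0 - E) / k  # ∫_0^h e^{-k(h-s)} ds
    slope = (f[1:] - f[:-1]) / h
    seg = f[:-1] * g + slope * (h - g) / k
    y = lfilter([1.0], [1.0, -E], seg)
    return np.concatenate(([0.0], y))


def reference_tac(
    p: InputFunctionParams,
    rk: ReferenceKinetics,
    times_min,
    dt_s: float = FINE_DT_S,
) -> np.ndarray:
    """Reference-region concentration ``K1' * (Cp (x) e^{-k2' t})`` at ``times_min``.

    Computed on the fine grid then linearly sampled.
    """
    times = np.asarray(times_min, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    t_end = max(TOTAL_DURATION_S, float(times.max(initial=0.0)) * 60.0)
    t_fine = fine_grid_s(t_end, dt_s) / 60.0
    cr_fine = rk.K1p * exp_conv(plasma_input(t_fine, p), rk.k2p, t_fine[1] - t_fine[0])
    return np.interp(times, t_fine, cr_fine)


def srtm_forward(C_R: np.ndarray, kp: KineticParams, times_min) -> np.ndarray:
    """Target-region curve from the SRTM operational equation.

    ``C_T = R1*C_R + (k2 - R1*k2a) * (C_R (x) e^{-k2a t})`` with ``C_R``
    sampled on the (uniform) ``times_min`` grid.
    """
    times = np.asarray(times_min, dtype=float)
    C_R = np.asarray(C_R, dtype=float)
    if C_R.shape != times.shape:
        raise ValueError("C_R and times must share a grid")
    if times.size < 2:
        raise ValueError("need at least two time points")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("srtm_forward requires a uniform, increasing time grid")
    conv = exp_conv(C_R, kp.k2a, dt[0])
    return kp.r1 * C_R + (kp.k2 - kp.r1 * kp.k2a) * conv


# ---------------------------------------------------------------------------
# Count noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Frame-count statistics.

    ``sensitivity`` converts (kBq/mL x s) of *decayed* activity into expected
    detected counts for a region-of-interest TAC.  ``mode`` selects Poisson
    draws (``"poisson"``), deterministic expected counts (``"expected"``), or
    idealised noise-free TACs sampled at the frame mid-times (``"none"``).
    """

    sensitivity: float = 0.05  # counts per (kBq mL^-1 s)
    decay_lambda_per_s: float = C11_LAMBDA_PER_S
    mode: str = "poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        # lambda = 0 is allowed: it turns decay weighting off, which makes
        # count expectations exactly proportional to retained time.
        if self.decay_lambda_per_s < 0:
            raise ValueError("decay constant must be non-negative")
        if self.mode not in ("poisson", "expected", "none"):
            raise ValueError("mode must be 'poisson', 'expected' or 'none'")


@dataclass
class TimeActivityCurve:
    """Per-frame decay-corrected concentrations for one region."""

    region: str
    midtimes_s: np.ndarray
    durations_s: np.ndarray
    conc: np.ndarray  # kBq/mL, decay-corrected
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.midtimes_s = np.asarray(self.midtimes_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.midtimes_s.shape:
                raise ValueError("counts length must match frames")
        if not (self.midtimes_s.shape == self.durations_s.shape == self.conc.shape):
            raise ValueError("midtimes, durations and conc must have equal length")
        if np.any(self.durations_s <= 0):
            raise ValueError("durations must be positive")
        if np.any(np.diff(self.midtimes_s) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("concentrations must be finite")

    @property
    def n_frames(self) -> int:
        return self.midtimes_s.size

    def to_frame(self):
        import pandas as pd

        d = {
            "frame_index": np.arange(self.n_frames),
            "midtime_s": self.midtimes_s,
            "duration_s": self.durations_s,
            "conc_kBq_per_mL": self.conc,
        }
        if self.counts is not None:
            d["counts"] = self.counts
        return pd.DataFrame(d)


def _micro_weights(frames: Sequence[TruncatedFrame], t_end_s: float, dt_s: float = 1.0):
    """Per-frame overlap weights of 1-s micro-bins with the retained windows."""
    n_bins = int(math.ceil(t_end_s / dt_s))
    centers = (np.arange(n_bins) + 0.5) * dt_s
    weights = []
    for fr in frames:
        a, b = fr.retained_start_s, fr.retained_end_s
        lo = np.clip(centers - dt_s / 2, a, b)
        hi = np.clip(centers + dt_s / 2, a, b)
        weights.append(np.maximum(hi - lo, 0.0))
    return centers, weights


def _eval_conc(conc, t_s: np.ndarray) -> np.ndarray:
    if callable(conc):
        vals = np.asarray(conc(t_s), dtype=float)
    else:
        grid_t, grid_v = conc
        vals = np.interp(t_s, np.asarray(grid_t, dtype=float), np.asarray(grid_v, dtype=float))
    return vals


def bin_counts(
    conc,
    frames: Sequence[TruncatedFrame],
    nm: NoiseModel,
    rng: np.random.Generator | None = None,
    region: str = "region",
) -> TimeActivityCurve:
    """Bin a continuous decay-corrected concentration into noisy frame counts.

    ``conc`` is either a callable of time (s) or a ``(t_s, values)`` sample
    pair.  Expected counts per frame are
    ``S * ∫_window conc(t) e^{-lambda t} dt`` over the *retained* window;
    the decay-corrected concentration is recovered as
    ``counts / (S * ∫_window e^{-lambda t} dt)``, which is unbiased for the
    decay-weighted mean concentration over the window.  With
    ``nm.mode == "none"`` the model concentration is sampled directly at the
    frame mid-times and no counts are produced.
    """
    midtimes = np.array([fr.midtime_s for fr in frames], dtype=float)
    durations = np.array([fr.retained_duration_s for fr in frames], dtype=float)

    if nm.mode == "none":
        sample_t = np.array(
            [fr.retained_start_s + fr.retained_duration_s / 2 for fr in frames], dtype=float
        )
        vals = _eval_conc(conc, sample_t)
        if np.any(vals < 0):
            raise ValueError("negative concentration encountered")
        return TimeActivityCurve(region=region, midtimes_s=midtimes, durations_s=durations, conc=vals)

    t_end = max(fr.retained_end_s for fr in frames)
    centers, weights = _micro_weights(frames, t_end)
    vals = _eval_conc(conc, centers)
    scale = float(np.max(np.abs(vals), initial=0.0))
    if np.any(vals < -1e-9 * max(scale, 1e-300)):
        raise ValueError("negative concentration encountered")
    vals = np.maximum(vals, 0.0)
    decay = np.exp(-nm.decay_lambda_per_s * centers)
    rate = vals * decay  # decayed activity per micro-bin (kBq/mL)
    mu = np.array([nm.sensitivity * np.sum(w * rate) for w in weights])
    norm = np.array([nm.sensitivity * np.sum(w * decay) for w in weights])
    if nm.mode == "poisson":
        rng = rng if rng is not None else np.random.default_rng(nm.seed)
        counts = rng.poisson(mu).astype(float)
    else:
        counts = mu
    return TimeActivityCurve(
        region=region,
        midtimes_s=midtimes,
        durations_s=durations,
        conc=counts / norm,
        counts=counts,
    )


def thin_counts(counts, f: float, seed=None) -> np.ndarray:
    """Binomially thin frame counts by fraction ``f`` (count-thinning oracle).

    Each count is replaced by a Binomial(count, f) draw; ``f = 1`` is the
    identity and ``f = 0`` zeroes everything.
    """
    if not (0 <= f <= 1):
        raise ValueError("thinning fraction must be in [0, 1]")
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    ci = np.round(c).astype(np.int64)
    if f == 1:
        return ci.astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(ci, f).astype(float)


# ---------------------------------------------------------------------------
# Tracer presets and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerPreset:
    """Region list, reference region and plausible truth kinetics for a tracer.

    The truth values are implementer-chosen plausible defaults (documented in
    the methods note); nothing downstream value-matches against them — all
    validation is recovery- and property-based.
    """

    name: str
    regions: tuple[str, ...]
    reference_region: str
    truth: Mapping[str, KineticParams]
    ref_kinetics: ReferenceKinetics
    injected_activity_mean_MBq: float
    injected_activity_sd_MBq: float


_PHNO_TRUTH = {
    "striatum": KineticParams(1.00, 0.35, 2.40),
    "caudate": KineticParams(1.00, 0.35, 2.20),
    "putamen": KineticParams(1.05, 0.36, 2.50),
    "globus_pallidus": KineticParams(0.95, 0.34, 1.90),
    "thalamus": KineticParams(0.95, 0.32, 0.45),
    "substantia_nigra": KineticParams(0.85, 0.30, 1.50),
    "accumbens": KineticParams(1.00, 0.34, 2.30),
}

_UCBJ_TRUTH = {
    "brainstem": KineticParams(1.15, 0.28, 1.60),
    "substantia_nigra": KineticParams(1.20, 0.30, 2.00),
    "thalamus": KineticParams(1.35, 0.32, 3.00),
    "striatum": KineticParams(1.40, 0.33, 3.20),
    "caudate": KineticParams(1.35, 0.32, 2.90),
    "putamen": KineticParams(1.45, 0.34, 3.40),
    "hippocampus": KineticParams(1.25, 0.30, 2.70),
    "insular_cortex": KineticParams(1.40, 0.32, 3.20),
    "temporal_lobe": KineticParams(1.35, 0.31, 3.00),
    "parietal_lobe": KineticParams(1.40, 0.32, 3.10),
    "frontal_cortex": KineticParams(1.45, 0.33, 3.30),
    "cerebellum": KineticParams(1.40, 0.34, 3.00),
    "accumbens": KineticParams(1.35, 0.32, 3.20),
}

TRACER_PRESETS: dict[str, TracerPreset] = {
    "PHNO": TracerPreset(
        name="PHNO",
        regions=(
            "striatum",
            "caudate",
            "putamen",
            "globus_pallidus",
            "thalamus",
            "substantia_nigra",
            "accumbens",
            "cerebellum",
        ),
        reference_region="cerebellum",
        truth=_PHNO_TRUTH,
        ref_kinetics=ReferenceKinetics(K1p=0.35, k2p=0.15),
        injected_activity_mean_MBq=134.2,
        injected_activity_sd_MBq=20.3,
    ),
    "UCBJ": TracerPreset(
        name="UCBJ",
        regions=(
            "brainstem",
            "substantia_nigra",
            "thalamus",
            "striatum",
            "caudate",
            "putamen",
            "hippocampus",
            "insular_cortex",
            "temporal_lobe",
            "parietal_lobe",
            "frontal_cortex",
            "cerebellum",
            "accumbens",
        ),
        reference_region="centrum_semiovale",
        truth=_UCBJ_TRUTH,
        # White-matter pseudo-reference: lower flow than cerebellar grey matter.
        ref_kinetics=ReferenceKinetics(K1p=0.15, k2p=0.12),
        injected_activity_mean_MBq=228.6,
        injected_activity_sd_MBq=58.3,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Between-subject variability settings for cohort generation."""

    bp_jitter_cv: float = 0.10
    r1_jitter_cv: float = 0.05
    k2_jitter_cv: float = 0.05
    vary_injected_activity: bool = True
    input_params: InputFunctionParams = field(default_factory=InputFunctionParams)


@dataclass
class SubjectDataset:
    """All regional TACs of one subject under one truncation scheme."""

    subject_id: str
    tracer: str
    injected_activity_MBq: float
    reference_region: str
    scheme_label: str
    midtime_convention: str
    tacs: dict[str, TimeActivityCurve]
    truth: dict[str, KineticParams]

    def __post_init__(self) -> None:
        if self.reference_region not in self.tacs:
            raise ValueError(
                f"reference region '{self.reference_region}' missing from TACs "
                f"(have: {sorted(self.tacs)})"
            )

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.tacs)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def make_cohort(
    tracer: str,
    n_subjects: int,
    scheme_labels: Sequence[str] = SCHEME_LABELS,
    nm: NoiseModel | None = None,
    config: CohortConfig | None = None,
    midtime_convention: str = "retained_window",
    schedule: FrameSchedule | None = None,
) -> dict[str, list[SubjectDataset]]:
    """Simulate a paired cohort: one dataset list per truncation scheme.

    Every subject has ONE underlying continuous noise-free dataset and one
    micro-grid Poisson draw per region; each scheme's TACs sum the same draws
    over that scheme's retained windows, so datasets are paired within
    subject exactly as a within-scan list-mode re-binning pairs them.
    """
    if tracer not in TRACER_PRESETS:
        raise ValueError(f"unknown tracer {tracer!r}; available: {sorted(TRACER_PRESETS)}")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for cohort statistics")
    preset = TRACER_PRESETS[tracer]
    nm = nm or NoiseModel()
    config = config or CohortConfig()
    schedule = schedule or make_full_schedule()

    truncations = {
        lab: apply_scheme(schedule, make_scheme(lab), midtime_convention) for lab in scheme_labels
    }

    t_end = schedule.starts_s[-1] + schedule.durations_s[-1]
    t_fine = fine_grid_s(t_end)
    t_fine_min = t_fine / 60.0
    dt_min = (t_fine[1] - t_fine[0]) / 60.0

    # Precompute micro-bin geometry once per scheme (shared by all subjects).
    centers, _ = _micro_weights(truncations[list(scheme_labels)[0]], t_end)
    decay = np.exp(-nm.decay_lambda_per_s * centers)
    scheme_weights = {lab: _micro_weights(trunc, t_end)[1] for lab, trunc in truncations.items()}
    scheme_midtimes = {
        lab: np.array([fr.midtime_s for fr in trunc]) for lab, trunc in truncations.items()
    }
    scheme_sample_t = {
        lab: np.array([fr.retained_start_s + fr.retained_duration_s / 2 for fr in trunc])
        for lab, trunc in truncations.items()
    }
    scheme_durations = {
        lab: np.array([fr.retained_duration_s for fr in trunc]) for lab, trunc in truncations.items()
    }
    scheme_norms = {
        lab: np.array([nm.sensitivity * np.sum(w * decay) for w in ws])
        for lab, ws in ((l, scheme_weights[l]) for l in scheme_labels)
    }

    master = np.random.SeedSequence(nm.seed if nm.seed is not None else 0)
    subject_seqs = master.spawn(n_subjects)

    out: dict[str, list[SubjectDataset]] = {lab: [] for lab in scheme_labels}
    for i in range(n_subjects):
        seqs = subject_seqs[i].spawn(2 + len(preset.regions))
        subj_rng = np.random.default_rng(seqs[0])
        subject_id = f"sub-{i + 1:02d}"

        ia = preset.injected_activity_mean_MBq
        if config.vary_injected_activity:
            ia = max(
                1e-3,
                float(
                    subj_rng.normal(
                        preset.injected_activity_mean_MBq, preset.injected_activity_sd_MBq
                    )
                ),
            )
        amp = ia / preset.injected_activity_mean_MBq
        p_in = config.input_params.scaled(amp)

        cr_fine = preset.ref_kinetics.K1p * exp_conv(
            plasma_input(t_fine_min, p_in), preset.ref_kinetics.k2p, dt_min
        )

        # Per-subject truth with mild biological jitter; the reference region
        # itself is its own curve (BP 0 relative to itself by construction).
        truth: dict[str, KineticParams] = {}
        curves: dict[str, np.ndarray] = {preset.reference_region: cr_fine}
        for region in preset.regions:
            if region == preset.reference_region:
                truth[region] = KineticParams(r1=1.0, k2=preset.ref_kinetics.k2p, bp_nd=0.0)
                continue
            base = preset.truth[region]
            kp = KineticParams(
                r1=base.r1 * _lognormal_factor(subj_rng, config.r1_jitter_cv),
                k2=base.k2 * _lognormal_factor(subj_rng, config.k2_jitter_cv),
                bp_nd=base.bp_nd * _lognormal_factor(subj_rng, config.bp_jitter_cv),
            )
            truth[region] = kp
            curves[region] = srtm_forward(cr_fine, kp, t_fine_min)
        truth[preset.reference_region] = KineticParams(
            r1=1.0, k2=preset.ref_kinetics.k2p, bp_nd=0.0
        )

        region_order = list(dict.fromkeys(list(preset.regions) + [preset.reference_region]))
        region_tacs: dict[str, dict[str, TimeActivityCurve]] = {lab: {} for lab in scheme_labels}
        for j, region in enumerate(region_order):
            ct_fine = curves[region]
            scale = float(np.max(np.abs(ct_fine), initial=0.0))
            if np.any(ct_fine < -1e-9 * scale):
                raise ValueError(f"negative concentration generated for region {region}")
            vals_center = np.maximum(np.interp(centers, t_fine, ct_fine), 0.0)
            mu_micro = nm.sensitivity * vals_center * decay
            micro = None
            if nm.mode == "poisson":
                region_rng = np.random.default_rng(seqs[1 + j])
                micro = region_rng.poisson(mu_micro).astype(float)
            for lab in scheme_labels:
                if nm.mode == "none":
                    conc = np.interp(scheme_sample_t[lab], t_fine, ct_fine)
                    tac = TimeActivityCurve(
                        region=region,
                        midtimes_s=scheme_midtimes[lab],
                        durations_s=scheme_durations[lab],
                        conc=conc,
                    )
                else:
                    ws = scheme_weights[lab]
                    if nm.mode == "poisson":
                        counts = np.array([np.sum(w * micro) for w in ws])
                    else:
                        counts = np.array([np.sum(w * mu_micro) for w in ws])
                    tac = TimeActivityCurve(
                        region=region,
                        midtimes_s=scheme_midtimes[lab],
                        durations_s=scheme_durations[lab],
                        conc=counts / scheme_norms[lab],
                        counts=counts,
                    )
                region_tacs[lab][region] = tac

        for lab in scheme_labels:
            out[lab].append(
                SubjectDataset(
                    subject_id=subject_id,
                    tracer=tracer,
                    injected_activity_MBq=ia,
                    reference_region=preset.reference_region,
                    scheme_label=lab,
                    midtime_convention=midtime_convention,
                    tacs=region_tacs[lab],
                    truth=truth,
                )
            )
    return out
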