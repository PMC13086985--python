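"""Agreement and significance statistics for outcome tables.

Each low-activity dataset is compared against the full-activity dataset per
region: coefficient of variation across subjects, mean paired bias,
Bland-Altman limits of agreement, and a normality-gated significance test
(one-way ANOVA with Bonferroni-corrected pairwise scheme-vs-full
comparisons when every group passes Shapiro-Wilk and Levene; otherwise
Kruskal-Wallis with Bonferroni-corrected rank-sum follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .framing import SCHEME_LABELS

__all__ = [
    "BlandAltman",
    "ComparisonResult",
    "compute_cv",
    "compute_bias",
    "bland_altman",
    "compare_to_full",
    "summarise",
    "pivot_bias_table",
]

OUTCOME_COLUMNS = ("subject", "region", "scheme_label", "outcome", "value")


def compute_cv(values) -> float:
    """Coefficient of variation in percent: ``100 * sample SD / mean``.

    Sample SD uses the n-1 denominator.  Requires ``n >= 2`` and a non-zero
    mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def compute_bias(sim_values, full_values) -> float:
    """Mean paired difference ``mean(sim - full)`` (signed, outcome units)."""
    s = np.asarray(sim_values, dtype=float)
    f = np.asarray(full_values, dtype=float)
    if s.shape != f.shape:
        raise ValueError(f"paired series length mismatch: {s.shape} vs {f.shape}")
    return float(np.mean(s - f))


class BlandAltman(NamedTuple):
    mean_diff: float
    loa_low: float
    loa_high: float


def bland_altman(sim_values, full_values) -> BlandAltman:
    """Bland-Altman mean difference and 1.96-SD limits of agreement."""
    s = np.asarray(sim_values, dtype=float)
    f = np.asarray(full_values, dtype=float)
    if s.shape != f.shape:
        raise ValueError(f"paired series length mismatch: {s.shape} vs {f.shape}")
    if s.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = s - f
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd)


@dataclass
class ComparisonResult:
    """Gated group-comparison outcome for one region."""

    test_used: str  # "ANOVA_Bonferroni" or "KruskalWallis"
    overall_p: float
    table: pd.DataFrame  # per scheme: raw_p, adj_p, significant
    gate: dict


def _safe_p(p, default=1.0) -> float:
    p = float(p)
    return p if np.isfinite(p) else default


def _pairwise_p(a: np.ndarray, b: np.ndarray, parametric: bool) -> float:
    scale = max(np.abs(np.concatenate([a, b])).max(), 1.0)
    if a.std(ddof=1) + b.std(ddof=1) < 1e-12 * scale:
        # Degenerate: both groups essentially constant.
        return 1.0 if abs(a.mean() - b.mean()) < 1e-12 * scale else 0.0
    if parametric:
        return _safe_p(sps.ttest_ind(a, b, equal_var=True).pvalue)
    return _safe_p(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_to_full(
    groups: Mapping[str, Sequence[float]],
    full_label: str = "full",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare every scheme's outcome values against the full-activity group.

    Gate: if every group passes Shapiro-Wilk (p > 0.05) AND Levene's test
    across groups passes (p > 0.05), use one-way ANOVA with
    Bonferroni-adjusted pairwise scheme-vs-full t-tests; otherwise
    Kruskal-Wallis with Bonferroni-adjusted pairwise rank-sum follow-up.
    Non-normality in ANY group or variance heterogeneity routes to the
    nonparametric branch.
    """
    if full_label not in groups:
        raise ValueError(f"groups must contain the reference label {full_label!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for k, a in arrays.items():
        if a.size < 3:
            raise ValueError(f"group {k!r} has n={a.size} < 3; tests undefined")

    scale = max(max(np.abs(a).max() for a in arrays.values()), 1.0)
    degenerate = all(np.ptp(a) < 1e-12 * scale for a in arrays.values())

    shapiro_p = {}
    for k, a in arrays.items():
        if np.ptp(a) < 1e-12 * scale:
            shapiro_p[k] = 1.0  # constant group: normality cannot be rejected
        else:
            shapiro_p[k] = _safe_p(sps.shapiro(a).pvalue)
    if degenerate:
        levene_p = 1.0
    else:
        levene_p = _safe_p(sps.levene(*arrays.values()).pvalue)
    parametric = all(p > 0.05 for p in shapiro_p.values()) and levene_p > 0.05

    labels = [k for k in arrays if k != full_label]
    m = len(labels)
    full = arrays[full_label]

    if degenerate:
        overall_p = 1.0
    elif parametric:
        overall_p = _safe_p(sps.f_oneway(*arrays.values()).pvalue)
    else:
        overall_p = _safe_p(sps.kruskal(*arrays.values()).pvalue)

    rows = []
    for lab in labels:
        raw = _pairwise_p(arrays[lab], full, parametric)
        adj = min(1.0, m * raw)
        rows.append(
            {
                "scheme_label": lab,
                "raw_p": raw,
                "adj_p": adj,
                "significant": bool(adj < alpha),
            }
        )
    return ComparisonResult(
        test_used="ANOVA_Bonferroni" if parametric else "KruskalWallis",
        overall_p=overall_p,
        table=pd.DataFrame(rows),
        gate={"shapiro_p": shapiro_p, "levene_p": levene_p, "parametric": parametric},
    )


def _scheme_order(labels) -> list[str]:
    known = [s for s in SCHEME_LABELS if s in labels]
    return known + sorted(set(labels) - set(known))


def summarise(
    outcomes: pd.DataFrame,
    full_label: str = "full",
    alpha: float = 0.05,
    run_tests: bool = True,
) -> pd.DataFrame:
    """Per (outcome, region, scheme) agreement summary versus full activity.

    ``outcomes`` is the tidy outcome table with columns
    ``subject, region, scheme_label, outcome, value`` and one record per
    combination (subjects paired across schemes).  Returns a tidy frame with
    CV, signed bias, Bland-Altman triple and the gated test result.
    """
    missing_cols = set(OUTCOME_COLUMNS) - set(outcomes.columns)
    if missing_cols:
        raise ValueError(f"outcome table is missing columns {sorted(missing_cols)}")
    rows = []
    for (outcome, region), grp in outcomes.groupby(["outcome", "region"], sort=True):
        pivot = grp.pivot_table(
            index="subject", columns="scheme_label", values="value", aggfunc="first"
        )
        if pivot.isna().any().any():
            bad = sorted(pivot.index[pivot.isna().any(axis=1)])
            raise ValueError(
                f"incomplete pairing for outcome={outcome!r} region={region!r}: "
                f"subjects {bad} lack at least one scheme"
            )
        if full_label not in pivot.columns:
            raise ValueError(f"outcome table lacks the '{full_label}' scheme for {region!r}")
        schemes = _scheme_order(pivot.columns)
        full = pivot[full_label].to_numpy()
        # Significance tests need n >= 3 per group; smaller cohorts still get
        # CV / bias / Bland-Altman.
        comp = (
            compare_to_full({s: pivot[s].to_numpy() for s in schemes}, full_label, alpha)
            if run_tests and len(pivot) >= 3
            else None
        )
        comp_by_scheme = (
            {} if comp is None else comp.table.set_index("scheme_label").to_dict("index")
        )
        for s in schemes:
            vals = pivot[s].to_numpy()
            try:
                cv = compute_cv(vals)
            except ValueError:
                cv = np.nan
            if s == full_label:
                bias, ba = 0.0, BlandAltman(0.0, 0.0, 0.0)
                p_adj, sig = np.nan, False
            else:
                bias = compute_bias(vals, full)
                ba = bland_altman(vals, full)
                if comp is None:
                    p_adj, sig = np.nan, False
                else:
                    p_adj = comp_by_scheme[s]["adj_p"]
                    sig = comp_by_scheme[s]["significant"]
            rows.append(
                {
                    "outcome": outcome,
                    "region": region,
                    "scheme_label": s,
                    "n": vals.size,
                    "cv_percent": cv,
                    "bias": bias,
                    "ba_mean_diff": ba.mean_diff,
                    "ba_loa_low": ba.loa_low,
                    "ba_loa_high": ba.loa_high,
                    "test_used": None if comp is None else comp.test_used,
                    "p_value": p_adj,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows)


def pivot_bias_table(summary: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Wide bias table (region rows x scheme columns) for one outcome."""
    sub = summary[(summary["outcome"] == outcome) & (summary["scheme_label"] != "full")]
    wide = sub.pivot(index="region", columns="scheme_label", values="bias")
    return wide[[c for c in _scheme_order(wide.columns)]]
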