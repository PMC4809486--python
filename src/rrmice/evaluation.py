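"""Accuracy analysis of corrected estimates: ME, RMSE, F-ratios.

Residuals are (estimate - unrestricted-sample truth).  The mean error
measures trueness (a positive ME is overestimation), the root mean square
error measures precision, and the F-ratio of mean squared errors compares
the precision of two methods on identical samples: an F of 2 means one
method is twice as precise as the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResidualRecord",
    "mean_error",
    "rmse",
    "f_ratio_test",
    "partition_by_strength",
    "aggregate",
    "records_to_frame",
]

MIN_STABLE_CELL = 100  # cells with fewer usable iterations are flagged


@dataclass(frozen=True)
class ResidualRecord:
    """One estimator's residual on one iteration x SR cell (or its exclusion)."""

    scenario: str
    kind: str
    sr: float
    method: str  # "mice" | "thorndike"
    estimator: str  # "r_pb" | "r_b" | "br"
    iteration: int
    residual: float | None = None
    true_value: float | None = None
    excluded: bool = False
    reason: str | None = None
    true_zx: float | None = None  # unrestricted Z-X correlation, IRR only


def mean_error(residuals: np.ndarray) -> float:
    """Arithmetic mean of residuals (trueness; positive = overestimation)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("no residuals")
    return float(residuals.mean())


def rmse(residuals: np.ndarray) -> float:
    """Root mean square of residuals (precision)."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("no residuals")
    return float(np.sqrt(np.mean(residuals**2)))


def f_ratio_test(
    res_thorndike: np.ndarray, res_mice: np.ndarray
) -> tuple[float, float]:
    """F-ratio of mean squared errors, Thorndike over MICE, with one-sided p.

    Both residual vectors must come from identical (paired) iterations so
    the comparison is on the same samples.  p is the upper-tail F
    probability with the per-group counts as degrees of freedom — the
    one-sided test that the MI correction is the more precise one.  A zero
    MICE MSE yields an infinite F.
    """
    res_t = np.asarray(res_thorndike, dtype=float)
    res_m = np.asarray(res_mice, dtype=float)
    if res_t.size == 0 or res_m.size == 0:
        raise ValueError("empty residual vector")
    mse_t = float(np.mean(res_t**2))
    mse_m = float(np.mean(res_m**2))
    if mse_m == 0.0:
        return float("inf"), 0.0
    f = mse_t / mse_m
    p = float(stats.f.sf(f, res_t.size, res_m.size))
    return f, p


def partition_by_strength(true_r: float) -> str:
    """Bin a true correlation: weak [.1,.4), moderate [.4,.7), strong [.7,.9]."""
    if not 0.1 <= true_r <= 0.9:
        raise ValueError(f"true correlation {true_r} outside [.1, .9]")
    if true_r < 0.4:
        return "weak"
    if true_r < 0.7:
        return "moderate"
    return "strong"


def records_to_frame(records: list[ResidualRecord]) -> pd.DataFrame:
    """Residual records as a flat DataFrame (the audit archive layout)."""
    df = pd.DataFrame(
        {
            "scenario": [r.scenario for r in records],
            "kind": [r.kind for r in records],
            "sr": [r.sr for r in records],
            "method": [r.method for r in records],
            "estimator": [r.estimator for r in records],
            "iteration": [r.iteration for r in records],
            "residual": [r.residual for r in records],
            "true_value": [r.true_value for r in records],
            "excluded": [r.excluded for r in records],
            "reason": [r.reason for r in records],
            "true_zx": [r.true_zx for r in records],
        }
    )
    for col in ("residual", "true_value", "true_zx"):
        df[col] = pd.to_numeric(df[col])
    return df


def aggregate(
    records: list[ResidualRecord] | pd.DataFrame,
    by_strength: bool = False,
    strength_of: str = "xy",
) -> pd.DataFrame:
    """Accuracy table: one row per condition x SR x method x estimator cell.

    Each cell reports ME, RMSE, usable and excluded counts; for the
    correlation estimators the F-ratio (Thorndike MSE over MICE MSE on the
    paired usable iterations) and its one-sided p are attached to both
    methods' rows.  Cells with no usable records are emitted with blank
    statistics; cells with fewer than ``MIN_STABLE_CELL`` usable records
    are flagged unstable.  With ``by_strength`` the partition of the true
    correlation (X-Y, or Z-X via ``strength_of="zx"``) is an extra facet.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    keys = ["scenario", "kind", "method", "estimator", "sr"]
    if by_strength:
        col = "true_value" if strength_of == "xy" else "true_zx"
        df["strength"] = [
            partition_by_strength(min(max(abs(v), 0.1), 0.9)) if np.isfinite(v) else None
            for v in pd.to_numeric(df[col]).to_numpy(float)
        ]
        keys.append("strength")
    rows = []
    for key_vals, grp in df.groupby(keys, dropna=False):
        used = grp[~grp["excluded"]]["residual"].dropna().to_numpy(float)
        n_used = used.size
        n_excluded = len(grp) - n_used
        row = dict(zip(keys, key_vals))
        row.update(
            me=mean_error(used) if n_used else np.nan,
            rmse=rmse(used) if n_used else np.nan,
            n_used=n_used,
            n_excluded=n_excluded,
            unstable=n_used < MIN_STABLE_CELL,
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    # attach paired F-ratios for correlation estimators
    table["f_ratio"] = np.nan
    table["p"] = np.nan
    facet_keys = [k for k in keys if k != "method"]
    usable = df[~df["excluded"]].dropna(subset=["residual"])
    for key_vals, grp in usable.groupby(facet_keys, dropna=False):
        est = dict(zip(facet_keys, key_vals))["estimator"]
        if est == "br":
            continue
        t = grp[grp["method"] == "thorndike"]
        m = grp[grp["method"] == "mice"]
        common = np.intersect1d(t["iteration"], m["iteration"])
        if common.size == 0:
            continue
        res_t = t.set_index("iteration").loc[common, "residual"].to_numpy(float)
        res_m = m.set_index("iteration").loc[common, "residual"].to_numpy(float)
        f, p = f_ratio_test(res_t, res_m)
        mask = np.ones(len(table), dtype=bool)
        for k, v in zip(facet_keys, key_vals):
            mask &= table[k].to_numpy() == v
        table.loc[mask, "f_ratio"] = f
        table.loc[mask, "p"] = p
    return table
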