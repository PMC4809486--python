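"""Top-down selection: the missingness mechanism under range restriction.

Selection keeps the top ``round(N * sr)`` applicants by the selection
variable (X under direct range restriction, Z under indirect) and deletes
the criterion for everyone else.  Because the missing indicator is a
deterministic function of a fully observed variable, the resulting pattern
is missing-at-random by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import UnrestrictedDataset

__all__ = [
    "RestrictedDataset",
    "apply_selection",
    "passes_marginal_condition",
    "write_restricted",
    "read_restricted",
]


@dataclass
class RestrictedDataset:
    """An applicant pool after selection: Y observed for selected cases only."""

    x: np.ndarray
    y_obs: np.ndarray  # float array, NaN where unselected
    selected: np.ndarray  # boolean mask
    sr: float
    scenario: str
    kind: str
    z: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selection_variable(self) -> np.ndarray:
        """X for DRR, Z for IRR."""
        return self.x if self.scenario == "drr" else self.z

    def observed_y(self) -> np.ndarray:
        """Observed criterion values as an integer vector."""
        return self.y_obs[self.selected].astype(np.int64)


def _n_selected(n: int, sr: float) -> int:
    # round half away from zero; np.round would round half to even
    return int(np.floor(n * sr + 0.5))


def apply_selection(
    dataset: UnrestrictedDataset, sr: float, scenario: str | None = None
) -> RestrictedDataset:
    """Select the top ``round(N*sr)`` cases and delete unselected criteria.

    Cases are ranked in descending order of X (DRR) or Z (IRR); ties break
    by original row index (probability zero under continuous draws).  X and
    Z remain observed for all applicants; only Y is made missing.
    """
    if not 0.0 < sr <= 1.0:
        raise ValueError(f"selection ratio must be in (0, 1], got {sr}")
    scenario = scenario or dataset.scenario
    key = dataset.x if scenario == "drr" else dataset.z
    if key is None:
        raise ValueError("IRR selection requires a z variable")
    k = _n_selected(dataset.n, sr)
    order = np.argsort(-key, kind="stable")
    selected = np.zeros(dataset.n, dtype=bool)
    selected[order[:k]] = True
    y_obs = dataset.y.astype(float)
    y_obs[~selected] = np.nan
    return RestrictedDataset(
        x=dataset.x,
        y_obs=y_obs,
        selected=selected,
        sr=sr,
        scenario=scenario,
        kind=dataset.kind,
        z=dataset.z,
    )


def passes_marginal_condition(
    restricted: RestrictedDataset, min_per_category: int = 5
) -> bool:
    """True iff the observed criterion has enough cases in both categories.

    The exclusion rule requires at least ``min_per_category`` observed
    successes and failures (default 5, the contingency-table rule of
    thumb); samples failing it are excluded from accuracy aggregation.
    """
    y = restricted.observed_y()
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    return n1 >= min_per_category and n0 >= min_per_category


def write_restricted(restricted: RestrictedDataset, path: str | Path) -> None:
    """Write the restricted dataset as CSV, empty fields for missing Y."""
    cols = {"id": np.arange(restricted.n), "x": restricted.x}
    if restricted.z is not None:
        cols["z"] = restricted.z
    cols["y"] = [
        "" if not sel else str(int(v))
        for sel, v in zip(restricted.selected, restricted.y_obs)
    ]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_restricted(
    path: str | Path, scenario: str | None = None, kind: str = "natural"
) -> RestrictedDataset:
    """Read a rectangular CSV with x, optional z, and y blank where unselected."""
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"CSV is missing required column '{col}'")
    z = df["z"].to_numpy(float) if "z" in df.columns else None
    if scenario is None:
        scenario = "irr" if z is not None else "drr"
    if scenario == "irr" and z is None:
        raise ValueError("IRR requires a z column")
    y_obs = pd.to_numeric(df["y"], errors="coerce").to_numpy(float)
    selected = ~np.isnan(y_obs)
    bad = y_obs[selected][~np.isin(y_obs[selected], (0.0, 1.0))]
    if bad.size:
        raise ValueError(f"y must be 0/1 or blank; found {bad[:5]}")
    return RestrictedDataset(
        x=df["x"].to_numpy(float),
        y_obs=y_obs,
        selected=selected,
        sr=float(selected.mean()),
        scenario=scenario,
        kind=kind,
        z=z,
    )
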