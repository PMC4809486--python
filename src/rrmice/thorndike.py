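"""Thorndike's classical range-restriction corrections (Cases 2 and 3).

Case 2 (direct restriction on X) rescales the restricted correlation by
the ratio ``k = S_X / s_X`` of unrestricted to restricted predictor
standard deviations:

    rho = k r / sqrt(1 + r^2 (k^2 - 1))

Case 3 (indirect restriction on a third variable Z) uses the restricted
correlations of Z with X and Y and the ratio ``k = S_Z / s_Z``:

    rho = [r_xy + r_zx r_zy (k^2-1)]
          / [sqrt(1 + r_zx^2 (k^2-1)) sqrt(1 + r_zy^2 (k^2-1))]

Both are exact for multivariate normal data truncated on the selection
variable with a continuous criterion.  Applied to a dichotomous criterion
they correct the correlation appropriate to the criterion type computed
on the selected sample: the point-biserial for a natural dichotomy, or
the biserial formed with the selected sample's success proportion for an
artificial one.  That success proportion is the only proportion this
method can see, and it is a biased estimate of the base rate — which is
what leaves the corrected biserial exposed to base-rate bias.
Thorndike's approach yields no estimate of the base rate itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlations import biserial, point_biserial
from .selection import RestrictedDataset, passes_marginal_condition

__all__ = [
    "ThorndikeInputs",
    "CorrectionResult",
    "case2_correction",
    "case3_correction",
    "correct_drr",
    "correct_irr",
    "thorndike_estimate",
]


class DegenerateRestrictionError(ValueError):
    """Restricted sd of the selection variable is zero."""


@dataclass(frozen=True)
class ThorndikeInputs:
    """Restricted-sample correlations and the sd ratio ingredients.

    ``s_sel``/``S_sel`` are the restricted and unrestricted standard
    deviations of the selection variable (X for DRR, Z for IRR); the
    unrestricted sd is computable because the selection variable is
    observed for all applicants.
    """

    r_xy: float
    s_sel: float
    S_sel: float
    r_zx: float | None = None
    r_zy: float | None = None

    @property
    def k(self) -> float:
        if self.s_sel <= 0:
            raise DegenerateRestrictionError("restricted sd must be positive")
        return self.S_sel / self.s_sel


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected estimates from one method on one restricted sample."""

    method: str  # "thorndike" | "mice"
    r_pb: float | None = None
    r_b: float | None = None  # artificial kind only
    br: float | None = None  # MICE only; Thorndike provides none
    clipped: bool = False


def case2_correction(r: float, k: float) -> float:
    """Case-2 formula on raw ingredients: ``k r / sqrt(1 + r^2(k^2-1))``."""
    if k <= 0:
        raise ValueError(f"sd ratio must be positive, got {k}")
    return float(k * r / np.sqrt(1.0 + r * r * (k * k - 1.0)))


def case3_correction(r_xy: float, r_zx: float, r_zy: float, k: float) -> float:
    """Case-3 formula on raw ingredients (may fall outside [-1, 1] in finite samples)."""
    if k <= 0:
        raise ValueError(f"sd ratio must be positive, got {k}")
    u = k * k - 1.0
    num = r_xy + r_zx * r_zy * u
    den = np.sqrt(1.0 + r_zx * r_zx * u) * np.sqrt(1.0 + r_zy * r_zy * u)
    return float(num / den)


def correct_drr(inputs: ThorndikeInputs) -> float:
    """Case-2 corrected correlation; always in [-1, 1] for |r| <= 1."""
    return case2_correction(inputs.r_xy, inputs.k)


def correct_irr(inputs: ThorndikeInputs) -> tuple[float, bool]:
    """Case-3 corrected correlation, clipped to [-1, 1] with a flag."""
    if inputs.r_zx is None or inputs.r_zy is None:
        raise ValueError("Case 3 requires r_zx and r_zy")
    raw = case3_correction(inputs.r_xy, inputs.r_zx, inputs.r_zy, inputs.k)
    clipped = abs(raw) > 1.0
    return float(np.clip(raw, -1.0, 1.0)), bool(clipped)


def thorndike_estimate(
    restricted: RestrictedDataset,
    kind: str | None = None,
    scenario: str | None = None,
) -> CorrectionResult:
    """Full Thorndike correction of a restricted sample.

    Restricted correlations are computed on selected cases only (Eq-style
    restricted-dataset definitions, including r_zx and r_zy for IRR even
    though X and Z are observed for everyone); the unrestricted sd of the
    selection variable comes from all applicants.  For an artificial
    dichotomy the correlation appropriate to the criterion type is formed
    first — the restricted point-biserial is converted to a biserial with
    the selected sample's success proportion (the only proportion this
    method can see, and a biased one under selection) — and the correction
    formula is then applied to that coefficient; for IRR the Z-criterion
    correlation is converted the same way.
    """
    kind = kind or restricted.kind
    scenario = scenario or restricted.scenario
    if not passes_marginal_condition(restricted):
        raise ValueError("marginal condition not met (need >=5 per category)")
    sel = restricted.selected
    y_sel = restricted.observed_y()
    sel_var = restricted.selection_variable
    s_sel = float(sel_var[sel].std())
    S_sel = float(sel_var.std())
    r_xy = point_biserial(restricted.x[sel], y_sel)
    clipped = False
    if kind == "artificial":
        conv = biserial(r_xy.value, r_xy.q)
        r_crit = conv.value
        clipped = conv.clipped
    else:
        r_crit = r_xy.value
    if scenario == "drr":
        inputs = ThorndikeInputs(r_xy=r_crit, s_sel=s_sel, S_sel=S_sel)
        corrected = correct_drr(inputs)
    else:
        r_zx = float(np.corrcoef(restricted.z[sel], restricted.x[sel])[0, 1])
        r_zy = point_biserial(restricted.z[sel], y_sel)
        r_zy_val = (
            biserial(r_zy.value, r_zy.q).value if kind == "artificial" else r_zy.value
        )
        inputs = ThorndikeInputs(
            r_xy=r_crit, s_sel=s_sel, S_sel=S_sel, r_zx=r_zx, r_zy=r_zy_val
        )
        corrected, clip3 = correct_irr(inputs)
        clipped = clipped or clip3
    if kind == "artificial":
        return CorrectionResult(method="thorndike", r_b=corrected, clipped=clipped)
    return CorrectionResult(method="thorndike", r_pb=corrected, clipped=clipped)
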