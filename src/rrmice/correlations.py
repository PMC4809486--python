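"""Correlation estimators for a continuous variable paired with a dichotomy.

Two coefficients are distinguished by the nature of the dichotomous
variable.  For a *naturally* dichotomous criterion (e.g. graduated vs. not
graduated) the point-biserial correlation

    r_pb = (M1 - M0) * sqrt(p * q) / sigma_x

is the appropriate measure; it is numerically identical to the Pearson
product-moment correlation of ``x`` with the 0/1 coding.  For an
*artificially* dichotomous criterion — a continuous trait split at a
cut-off — the point-biserial systematically underestimates the latent
Pearson correlation, and the biserial coefficient

    r_b = r_pb * sqrt(p * q) / h

is used instead, where ``h`` is the standard normal ordinate at the split.
Both coefficients shrink as the split proportions ``p, q`` become extreme,
which is why an estimator's implicit success proportion matters under
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrEstimate",
    "UndefinedCorrelationError",
    "point_biserial",
    "normal_ordinate_at_split",
    "biserial",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant input)."""


@dataclass(frozen=True)
class CorrEstimate:
    """A correlation estimate with the split proportions that produced it.

    Attributes
    ----------
    value : float
        The coefficient, clipped to [-1, 1] if ``clipped`` is true.
    kind : str
        One of ``"pearson"``, ``"point_biserial"``, ``"biserial"``.
    p : float
        Proportion of the sample with criterion value 0.
    q : float
        Proportion with criterion value 1 (success); ``p + q == 1``.
    clipped : bool
        True if the raw value fell outside [-1, 1] (possible for the
        biserial in finite samples) and was clipped.
    """

    value: float
    kind: str
    p: float
    q: float
    clipped: bool = False


def point_biserial(x: np.ndarray, y: np.ndarray) -> CorrEstimate:
    """Point-biserial correlation between continuous ``x`` and 0/1 ``y``.

    Computed as ``(M1 - M0) * sqrt(p*q) / sigma_x`` with the
    population-denominator standard deviation, which makes it exactly the
    Pearson product-moment correlation of ``x`` with the 0/1 coding.

    Raises
    ------
    UndefinedCorrelationError
        If either variable is constant (one criterion group empty, or
        ``x`` without variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    n1 = int(np.sum(y == 1))
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedCorrelationError("criterion is constant: correlation undefined")
    sigma = x.std()  # population denominator: identity with Pearson r holds exactly
    if sigma == 0.0:
        raise UndefinedCorrelationError("predictor is constant: correlation undefined")
    q = n1 / n
    p = 1.0 - q
    m1 = x[y == 1].mean()
    m0 = x[y == 0].mean()
    value = (m1 - m0) * np.sqrt(p * q) / sigma
    return CorrEstimate(value=float(value), kind="point_biserial", p=p, q=q)


def normal_ordinate_at_split(q: float) -> float:
    """Standard normal density at the cut leaving upper-tail mass ``q``.

    This is the ``h`` in the biserial formula: the ordinate of the standard
    normal distribution at the dichotomization point.  Symmetric in
    ``q <-> 1 - q``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"split proportion must be in (0, 1), got {q}")
    return float(stats.norm.pdf(stats.norm.ppf(1.0 - q)))


def biserial(r_pb: float, q: float) -> CorrEstimate:
    """Biserial correlation from a point-biserial and the success proportion.

    ``r_b = r_pb * sqrt(p*q) / h`` estimates the latent Pearson correlation
    when the dichotomy is an artificial split of a normal variable.  Since
    ``sqrt(p*q)/h >= 1``, the biserial is never smaller in magnitude than
    the point-biserial.  Finite-sample values beyond +-1 are clipped and
    flagged.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"split proportion must be in (0, 1), got {q}")
    p = 1.0 - q
    h = normal_ordinate_at_split(q)
    raw = r_pb * np.sqrt(p * q) / h
    clipped = bool(abs(raw) > 1.0)
    value = float(np.clip(raw, -1.0, 1.0))
    return CorrEstimate(value=value, kind="biserial", p=p, q=q, clipped=clipped)
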