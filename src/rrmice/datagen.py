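"""Synthetic applicant populations for the selection scenarios.

Generates unrestricted datasets of a continuous predictor ``X``, a
dichotomous criterion ``Y`` (1 = successful), and — for indirect range
restriction — a continuous selection variable ``Z``, under two data models:

* ``artificial``: a bivariate (DRR) or trivariate (IRR) standard normal
  with target correlations; the latent criterion is dichotomized at the
  cut-off ``c = Phi^-1(1 - BR)`` so the expected success proportion equals
  the base rate.
* ``natural``: ``Y ~ Bernoulli(BR)``; within each criterion group ``X``
  (and ``Z``) are unit-variance normals whose group mean difference ``d``
  is chosen to hit a target point-biserial correlation.  This is the
  two-component mixture design underlying the Taylor-Russell tables.

The "true" parameters attached to each dataset are the *sample* statistics
of the unrestricted data; downstream accuracy analysis measures every
corrected estimate against these.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .correlations import biserial, point_biserial, UndefinedCorrelationError

__all__ = [
    "FactorDraw",
    "UnrestrictedDataset",
    "TrueParams",
    "MixtureSpec",
    "InfeasibleFactorsError",
    "mixture_sd",
    "pb_from_mixture",
    "d_from_pb",
    "solve_within_corr",
    "gen_artificial",
    "gen_natural",
    "generate",
    "draw_factors",
    "true_params",
    "write_dataset",
    "read_dataset",
]

SCENARIOS = ("drr", "irr")
KINDS = ("artificial", "natural")


class InfeasibleFactorsError(ValueError):
    """A factor draw implies an impossible correlation structure.

    Raised when the implied latent correlation matrix is not positive
    definite (artificial kind) or the implied within-group correlation
    falls outside (-1, 1) (natural kind).  Callers doing factorial draws
    resample on this error.
    """


@dataclass(frozen=True)
class FactorDraw:
    """Target population parameters for one simulated applicant pool.

    ``rho_xy`` is the target predictor-criterion association (latent
    Pearson for the artificial kind, point-biserial for the natural kind),
    ``br`` the base rate of success.  ``rho_zx``/``rho_zy`` are present for
    IRR only: the Z-X Pearson correlation and the Z-criterion association.
    """

    rho_xy: float
    br: float
    rho_zx: float | None = None
    rho_zy: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho_xy", "br", "rho_zx", "rho_zy"):
            v = getattr(self, name)
            if v is not None and not 0.1 <= v <= 0.9:
                raise ValueError(f"{name}={v} outside [.1, .9]")


@dataclass(frozen=True)
class TrueParams:
    """Sample statistics of the unrestricted dataset (the accuracy truth)."""

    rho_pb: float
    br: float
    rho_b: float | None = None  # artificial kind only
    r_zx: float | None = None  # IRR only
    r_zy: float | None = None  # IRR only


@dataclass
class UnrestrictedDataset:
    """A complete applicant population: no missing criterion values."""

    x: np.ndarray
    y: np.ndarray
    kind: str
    scenario: str
    z: np.ndarray | None = None
    factors: FactorDraw | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")
        if (self.z is not None) != (self.scenario == "irr"):
            raise ValueError("z must be present iff scenario is 'irr'")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of the two-component mixture for the natural kind.

    Group standard deviations are fixed at 1; the mixture sd of X is
    ``sqrt(1 + br(1-br) d_x^2)``.
    """

    d_x: float
    br: float
    d_z: float | None = None
    rho_w: float | None = None  # within-group X-Z correlation, IRR only


# ---------------------------------------------------------------------------
# Mixture algebra


def mixture_sd(d: float, br: float) -> float:
    """Standard deviation of a two-component unit-variance normal mixture.

    With group mean difference ``d`` and mixing proportion ``br`` for the
    upper group, the mixture variance is ``1 + br(1-br) d^2``.
    """
    if not 0.0 < br < 1.0:
        raise ValueError(f"base rate must be in (0, 1), got {br}")
    if d < 0:
        raise ValueError(f"mean difference must be >= 0, got {d}")
    return float(np.sqrt(1.0 + br * (1.0 - br) * d * d))


def pb_from_mixture(d: float, br: float) -> float:
    """Point-biserial correlation implied by the mixture parameters.

    ``rho_pb = d * sqrt(br(1-br)) / sigma_X``, e.g. d=1.5 at BR=.5 gives
    1.5 * .25 / 1.25 = .60.
    """
    return float(d * np.sqrt(br * (1.0 - br)) / mixture_sd(d, br))


def d_from_pb(rho_pb: float, br: float) -> float:
    """Group mean difference that yields a target point-biserial.

    Inverse of :func:`pb_from_mixture` for fixed ``br``; needed because the
    simulation factors are drawn as target correlations.
    """
    if not 0.0 < br < 1.0:
        raise ValueError(f"base rate must be in (0, 1), got {br}")
    if not 0.0 <= rho_pb < 1.0:
        raise ValueError(f"no finite mean difference for rho_pb={rho_pb}")
    pq = br * (1.0 - br)
    return float(np.sqrt(rho_pb * rho_pb / (pq * (1.0 - rho_pb * rho_pb))))


def solve_within_corr(
    rho_zx_target: float, d_x: float, d_z: float, br: float
) -> float:
    """Within-group X-Z correlation hitting a target marginal correlation.

    In the mixture model the marginal covariance of X and Z decomposes as
    ``rho_w + br(1-br) d_x d_z`` (within-group part plus the between-group
    mean shift), so ``rho_w = rho_zx_target * sigma_X * sigma_Z -
    br(1-br) d_x d_z``.  Targets implying ``|rho_w| >= 1`` are infeasible.
    """
    rho_w = rho_zx_target * mixture_sd(d_x, br) * mixture_sd(d_z, br) - br * (
        1.0 - br
    ) * d_x * d_z
    if not -1.0 < rho_w < 1.0:
        raise InfeasibleFactorsError(
            f"implied within-group correlation {rho_w:.4f} outside (-1, 1)"
        )
    return float(rho_w)


# ---------------------------------------------------------------------------
# Generators


def gen_artificial(
    n: int, factors: FactorDraw, scenario: str, rng: np.random.Generator
) -> UnrestrictedDataset:
    """Draw latent multivariate normals and dichotomize the criterion.

    The latent (X, Y*, Z) are standard normal with the target correlations;
    ``Y = 1`` where the latent criterion exceeds ``c = Phi^-1(1 - br)``, so
    values above the cut are coded successful and the expected proportion
    of successes equals the base rate.
    """
    if scenario == "drr":
        corr = np.array([[1.0, factors.rho_xy], [factors.rho_xy, 1.0]])
    elif scenario == "irr":
        if factors.rho_zx is None or factors.rho_zy is None:
            raise ValueError("IRR requires rho_zx and rho_zy")
        # variable order: X, Y*, Z
        corr = np.array(
            [
                [1.0, factors.rho_xy, factors.rho_zx],
                [factors.rho_xy, 1.0, factors.rho_zy],
                [factors.rho_zx, factors.rho_zy, 1.0],
            ]
        )
    else:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise InfeasibleFactorsError(
            "target correlation matrix is not positive definite"
        ) from None
    draws = rng.standard_normal((n, corr.shape[0])) @ chol.T
    x = draws[:, 0]
    cut = stats.norm.ppf(1.0 - factors.br)
    y = (draws[:, 1] > cut).astype(np.int64)
    z = draws[:, 2] if scenario == "irr" else None
    return UnrestrictedDataset(
        x=x, y=y, z=z, kind="artificial", scenario=scenario, factors=factors
    )


def gen_natural(
    n: int,
    factors: FactorDraw,
    scenario: str,
    rng: np.random.Generator,
    fixed_counts: bool = False,
) -> UnrestrictedDataset:
    """Draw the two-component mixture design for a natural dichotomy.

    Group membership is i.i.d. Bernoulli(br) by default, modelling a
    random applicant population in which the realized base rate is itself
    a random variable; ``fixed_counts=True`` instead fixes the success
    count at ``round(n * br)`` in a random arrangement.  Conditional on
    the group, ``X ~ N(d_x * Y, 1)``.  For IRR, (X, Z) within each group
    are bivariate normal with unit variances and within-group correlation
    chosen by :func:`solve_within_corr` so the marginal Z-X correlation
    matches the target.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    d_x = d_from_pb(factors.rho_xy, factors.br)
    if fixed_counts:
        n1 = int(np.floor(n * factors.br + 0.5))
        y = np.zeros(n, dtype=np.int64)
        y[rng.permutation(n)[:n1]] = 1
    else:
        y = (rng.random(n) < factors.br).astype(np.int64)
    eps_x = rng.standard_normal(n)
    x = d_x * y + eps_x
    z = None
    if scenario == "irr":
        if factors.rho_zx is None or factors.rho_zy is None:
            raise ValueError("IRR requires rho_zx and rho_zy")
        d_z = d_from_pb(factors.rho_zy, factors.br)
        rho_w = solve_within_corr(factors.rho_zx, d_x, d_z, factors.br)
        eps_z = rho_w * eps_x + np.sqrt(1.0 - rho_w * rho_w) * rng.standard_normal(n)
        z = d_z * y + eps_z
    return UnrestrictedDataset(
        x=x, y=y, z=z, kind="natural", scenario=scenario, factors=factors
    )


def generate(
    n: int, factors: FactorDraw, scenario: str, kind: str, rng: np.random.Generator
) -> UnrestrictedDataset:
    """Dispatch to the generator for ``kind``."""
    if kind == "artificial":
        return gen_artificial(n, factors, scenario, rng)
    if kind == "natural":
        return gen_natural(n, factors, scenario, rng)
    raise ValueError(f"kind must be one of {KINDS}")


def draw_factors(
    scenario: str,
    kind: str,
    rng: np.random.Generator,
    low: float = 0.1,
    high: float = 0.9,
    max_tries: int = 1000,
) -> tuple[FactorDraw, int]:
    """Draw uniform factors, rejecting infeasible combinations.

    All correlations and the base rate are uniform on [low, high].
    Infeasible draws (non-positive-definite latent matrix for the
    artificial kind, out-of-range within-group correlation for the natural
    kind) are rejected and redrawn; returns the accepted draw and the
    number of rejections.
    """
    rejections = 0
    for _ in range(max_tries):
        if scenario == "drr":
            f = FactorDraw(rho_xy=rng.uniform(low, high), br=rng.uniform(low, high))
            return f, rejections
        f = FactorDraw(
            rho_xy=rng.uniform(low, high),
            br=rng.uniform(low, high),
            rho_zx=rng.uniform(low, high),
            rho_zy=rng.uniform(low, high),
        )
        try:
            if kind == "artificial":
                corr = np.array(
                    [
                        [1.0, f.rho_xy, f.rho_zx],
                        [f.rho_xy, 1.0, f.rho_zy],
                        [f.rho_zx, f.rho_zy, 1.0],
                    ]
                )
                np.linalg.cholesky(corr)
            else:
                solve_within_corr(
                    f.rho_zx, d_from_pb(f.rho_xy, f.br), d_from_pb(f.rho_zy, f.br), f.br
                )
            return f, rejections
        except (np.linalg.LinAlgError, InfeasibleFactorsError):
            rejections += 1
    raise InfeasibleFactorsError(f"no feasible factor draw in {max_tries} tries")


def true_params(dataset: UnrestrictedDataset) -> TrueParams:
    """Sample "true" parameters of the unrestricted dataset.

    These are the targets that corrected estimates are measured against:
    the sample point-biserial r(x, y), the sample base rate, and — for the
    artificial kind — the sample biserial.  IRR adds the sample Z-X and
    Z-criterion correlations.
    """
    if dataset.y.min() == dataset.y.max():
        raise UndefinedCorrelationError("criterion is constant in the dataset")
    est = point_biserial(dataset.x, dataset.y)
    br = float(dataset.y.mean())
    rho_b = None
    if dataset.kind == "artificial":
        rho_b = biserial(est.value, br).value
    r_zx = r_zy = None
    if dataset.scenario == "irr":
        r_zx = float(np.corrcoef(dataset.z, dataset.x)[0, 1])
        r_zy = point_biserial(dataset.z, dataset.y).value
    return TrueParams(rho_pb=est.value, br=br, rho_b=rho_b, r_zx=r_zx, r_zy=r_zy)


# ---------------------------------------------------------------------------
# Dataset I/O: CSV with a JSON metadata sidecar


def write_dataset(
    dataset: UnrestrictedDataset, path: str | Path, seed: int | None = None
) -> None:
    """Write a dataset to CSV (columns id, x[, z], y) with a JSON sidecar."""
    path = Path(path)
    cols = {"id": np.arange(dataset.n), "x": dataset.x}
    if dataset.z is not None:
        cols["z"] = dataset.z
    cols["y"] = dataset.y
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "scenario": dataset.scenario,
        "kind": dataset.kind,
        "n": dataset.n,
        "seed": seed,
        "factors": asdict(dataset.factors) if dataset.factors else None,
        "true_params": asdict(true_params(dataset)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def read_dataset(path: str | Path) -> UnrestrictedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    scenario, kind, factors = "drr", "natural", None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        scenario, kind = meta["scenario"], meta["kind"]
        if meta.get("factors"):
            factors = FactorDraw(**meta["factors"])
    elif "z" in df.columns:
        scenario = "irr"
    return UnrestrictedDataset(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(np.int64),
        z=df["z"].to_numpy(float) if "z" in df.columns else None,
        kind=kind,
        scenario=scenario,
        factors=factors,
    )
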