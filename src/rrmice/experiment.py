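"""Monte Carlo orchestration of the correction-accuracy study.

A condition is one of the four crossings of selection scenario (DRR/IRR)
and criterion kind (artificial/natural).  Per iteration the experiment
draws uniform factors, generates an unrestricted applicant pool, records
its sample statistics as the truth, and — for every selection ratio on
the grid — applies top-down selection and runs both corrections
(Thorndike and multiple imputation) on the *same* restricted sample.  A
sample excluded for one method (marginal condition, non-convergence) is
excluded for both, so the F-ratio precision comparison is paired on
identical samples.

Randomness is governed by one master seed; each iteration x SR cell gets
a deterministic child stream, so any single cell is reproducible in
isolation and the whole pipeline is a pure function of its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlations import UndefinedCorrelationError
from .datagen import TrueParams, draw_factors, generate, true_params
from .evaluation import ResidualRecord, aggregate, records_to_frame, rmse, mean_error
from .mi_logreg import ConvergenceError, mice_estimate, multiple_impute, pool_estimates
from .selection import (
    RestrictedDataset,
    apply_selection,
    passes_marginal_condition,
    read_restricted,
)
from .thorndike import thorndike_estimate

__all__ = [
    "ExperimentConfig",
    "load_config",
    "run_condition",
    "preliminary_m_study",
    "correct_user_dataset",
]

DEFAULT_SR_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass(frozen=True)
class ExperimentConfig:
    """One Monte Carlo condition and its execution parameters.

    Defaults follow the study design: applicant pools of N = 500, factors
    (correlations and base rate) uniform on [.1, .9], nine selection
    ratios from .1 to .9, m = 20 imputations, 5000 iterations (scale
    ``iterations`` down for quicker runs).
    """

    scenario: str = "drr"
    kind: str = "natural"
    n: int = 500
    iterations: int = 5000
    sr_grid: tuple[float, ...] = DEFAULT_SR_GRID
    m: int = 20
    factor_low: float = 0.1
    factor_high: float = 0.9
    master_seed: int = 0
    ridge: float = 1e-5
    min_per_category: int = 5
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.m < 1:
            raise ValueError("iterations and m must be >= 1")
        for sr in self.sr_grid:
            if not 0.0 < sr <= 1.0:
                raise ValueError(f"selection ratio {sr} outside (0, 1]")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if "sr_grid" in data:
        data["sr_grid"] = tuple(data["sr_grid"])
    return ExperimentConfig(**data)


def _cell_records(
    restricted: RestrictedDataset,
    truth: TrueParams,
    iteration: int,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> list[ResidualRecord]:
    """Paired residual (or exclusion) records for one iteration x SR cell."""
    kind, scenario, sr = restricted.kind, restricted.scenario, restricted.sr
    est_name = "r_b" if kind == "artificial" else "r_pb"
    true_corr = truth.rho_b if kind == "artificial" else truth.rho_pb
    common = dict(scenario=scenario, kind=kind, sr=sr, iteration=iteration)

    def excluded(reason: str) -> list[ResidualRecord]:
        return [
            ResidualRecord(
                method=meth, estimator=est, excluded=True, reason=reason,
                true_zx=truth.r_zx, **common,
            )
            for meth, est in (
                ("thorndike", est_name),
                ("mice", est_name),
                ("mice", "br"),
            )
        ]

    if not passes_marginal_condition(restricted, config.min_per_category):
        return excluded("marginal_condition")
    try:
        pooled = mice_estimate(
            restricted, m=config.m, kind=kind, scenario=scenario, rng=rng,
            ridge=config.ridge,
        )
        thorn = thorndike_estimate(restricted, kind=kind, scenario=scenario)
    except (ConvergenceError, UndefinedCorrelationError) as exc:
        return excluded(type(exc).__name__)
    thorn_est = thorn.r_b if kind == "artificial" else thorn.r_pb
    mice_est = pooled.r_b if kind == "artificial" else pooled.r_pb
    return [
        ResidualRecord(
            method="thorndike", estimator=est_name,
            residual=thorn_est - true_corr, true_value=true_corr,
            true_zx=truth.r_zx, **common,
        ),
        ResidualRecord(
            method="mice", estimator=est_name,
            residual=mice_est - true_corr, true_value=true_corr,
            true_zx=truth.r_zx, **common,
        ),
        ResidualRecord(
            method="mice", estimator="br",
            residual=pooled.br - truth.br, true_value=truth.br,
            true_zx=truth.r_zx, **common,
        ),
    ]


def run_condition(
    config: ExperimentConfig, return_records: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one full Monte Carlo condition.

    Returns the accuracy table (one row per method x estimator x SR cell,
    with ME, RMSE, paired F-ratios, and exclusion counts) and the flat
    residual-record archive.  Fully reproducible from ``master_seed``.
    """
    records: list[ResidualRecord] = []
    for it in range(config.iterations):
        gen_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, it])
        )
        factors, _ = draw_factors(
            config.scenario, config.kind, gen_rng,
            low=config.factor_low, high=config.factor_high,
        )
        dataset = generate(config.n, factors, config.scenario, config.kind, gen_rng)
        truth = true_params(dataset)
        for j, sr in enumerate(config.sr_grid):
            restricted = apply_selection(dataset, sr)
            cell_rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, it, j])
            )
            records.extend(_cell_records(restricted, truth, it, config, cell_rng))
    frame = records_to_frame(records)
    table = aggregate(frame)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"{config.scenario}_{config.kind}"
        table.to_csv(out / f"accuracy_{tag}.csv", index=False)
        if return_records:
            frame.to_csv(out / f"residuals_{tag}.csv", index=False)
        (out / f"config_{tag}.json").write_text(json.dumps(asdict(config), indent=2))
    return table, frame


def preliminary_m_study(
    config: ExperimentConfig,
    m_values: tuple[int, ...] = (5, 20, 50),
    missing_rates: tuple[float, ...] = (0.7, 0.5, 0.3),
    kinds: tuple[str, ...] = ("artificial", "natural"),
) -> pd.DataFrame:
    """The how-many-imputations study (DRR, N = 500).

    For each criterion kind and missing-value rate (selection ratio
    ``1 - rate``), computes the RMSE and ME of the pooled correlation
    estimate for each number of imputations m — the biserial for the
    artificial kind, the point-biserial for the natural kind.  To keep the
    m comparison paired, one set of ``max(m_values)`` imputations is drawn
    per sample and each m pools its first m members (statistically
    identical to independent runs, since imputations are i.i.d.).
    """
    max_m = max(m_values)
    rows = []
    for kind in kinds:
        est_name = "r_b" if kind == "artificial" else "r_pb"
        residuals: dict[tuple[float, int], list[float]] = {
            (rate, m): [] for rate in missing_rates for m in m_values
        }
        excluded = {rate: 0 for rate in missing_rates}
        for it in range(config.iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.master_seed, {"artificial": 1, "natural": 2}[kind], it]
                )
            )
            factors, _ = draw_factors(
                config.scenario, kind, rng,
                low=config.factor_low, high=config.factor_high,
            )
            dataset = generate(config.n, factors, config.scenario, kind, rng)
            truth = true_params(dataset)
            true_corr = truth.rho_b if kind == "artificial" else truth.rho_pb
            for rate in missing_rates:
                restricted = apply_selection(dataset, 1.0 - rate)
                if not passes_marginal_condition(restricted, config.min_per_category):
                    excluded[rate] += 1
                    continue
                try:
                    completed = multiple_impute(
                        restricted, m=max_m, rng=rng, ridge=config.ridge
                    )
                except (ConvergenceError, UndefinedCorrelationError):
                    excluded[rate] += 1
                    continue
                for m in m_values:
                    pooled = pool_estimates(restricted.x, completed[:m], kind)
                    est = pooled.r_b if kind == "artificial" else pooled.r_pb
                    residuals[(rate, m)].append(est - true_corr)
        for rate in missing_rates:
            for m in m_values:
                res = np.array(residuals[(rate, m)])
                rows.append(
                    dict(
                        kind=kind, estimator=est_name, missing_rate=rate, m=m,
                        rmse=rmse(res) if res.size else np.nan,
                        me=mean_error(res) if res.size else np.nan,
                        n_used=res.size, n_excluded=excluded[rate],
                    )
                )
    return pd.DataFrame(rows)


def correct_user_dataset(
    path: str | Path,
    scenario: str | None = None,
    kind: str = "natural",
    m: int = 20,
    seed: int = 0,
    ridge: float = 1e-5,
) -> dict:
    """Correct a user-supplied restricted dataset with both methods.

    The CSV must have columns ``x`` and ``y`` (``y`` blank for unselected
    cases) and optionally ``z``; with a ``z`` column the scenario defaults
    to IRR.  Returns a report with both methods' corrected estimates, the
    selected-sample success rate, the restricted/unrestricted sds of the
    selection variable, and the m per-imputation estimates.
    """
    restricted = read_restricted(path, scenario=scenario, kind=kind)
    if not passes_marginal_condition(restricted):
        raise ValueError(
            "observed criterion needs at least 5 cases in each category"
        )
    rng = np.random.default_rng(seed)
    thorn = thorndike_estimate(restricted)
    pooled = mice_estimate(restricted, m=m, rng=rng, ridge=ridge)
    sel_var = restricted.selection_variable
    report = {
        "scenario": restricted.scenario,
        "kind": restricted.kind,
        "n": restricted.n,
        "n_selected": restricted.n_selected,
        "selection_ratio": restricted.sr,
        "success_rate": float(restricted.observed_y().mean()),
        "sd_restricted": float(sel_var[restricted.selected].std()),
        "sd_unrestricted": float(sel_var.std()),
        "thorndike": {"r_pb": thorn.r_pb, "r_b": thorn.r_b},
        "mice": {
            "r_pb": pooled.r_pb,
            "r_b": pooled.r_b,
            "br": pooled.br,
            "m": pooled.m,
            "per_imputation": pooled.per_imputation,
        },
    }
    return report
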