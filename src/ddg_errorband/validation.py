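"""Leave-one-system-out cross-validation and coverage statistics.

Mutations from the same protein are not independent, so model performance is
assessed by holding out one whole system per fold: the model (including
subset selection, unless a fixed formula is requested) is fit on the other
systems and each held-out mutation j receives an error bound B_j — the upper
end of its out-of-sample prediction interval.  Overall coverage is

    Coverage = (1/N) Σ_i Σ_j I(Error_j < B_j)

with a strict inequality.  Mutations not captured by their bound are
*outliers*; whether outliers concentrate in particular systems is tested
with a chi-squared goodness of fit against counts proportional to system
size (Monte-Carlo p-value by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import PredictorTable
from .regression import (
    DEFAULT_BOUND_KIND,
    ErrorModel,
    best_subset_select,
    error_bound,
    fit_ols,
    predict,
    stepwise_select,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectorConfig",
    "LOSOResult",
    "GOFResult",
    "coverage",
    "loso_cv",
    "summarize_by_system",
    "outlier_gof_test",
]


@dataclass(frozen=True)
class SelectorConfig:
    """How the model is chosen inside each training fold.

    ``method`` is one of ``best_subset``, ``stepwise`` or ``fixed``; a fixed
    formula evaluates one pre-chosen predictor list across folds (no
    selection re-run).  Selection is always performed on the training fold
    only, so no information from the held-out system leaks into the model.
    """

    method: str = "best_subset"
    predictors: tuple[str, ...] | None = None  # fixed-formula mode
    max_size: int = 12
    d_convention: str = "paper"
    rss_floor: bool = False

    def __post_init__(self):
        if self.method not in ("best_subset", "stepwise", "fixed"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.method == "fixed" and self.predictors is None:
            raise ValueError("fixed-formula mode needs an explicit predictor list")


@dataclass
class LOSOResult:
    """Per-mutation, per-system and overall leave-one-system-out metrics."""

    rows: pd.DataFrame        # system_id, error, point, upper (bound B), width, captured, warn_unseen
    per_system: pd.DataFrame  # indexed by system: n, coverage, median_error, median_width, n_outliers
    fold_models: dict[str, ErrorModel]
    fold_predictors: dict[str, tuple[str, ...]]
    level: float
    width_kind: str

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def overall_coverage(self) -> float:
        return float(self.rows["captured"].mean())

    @property
    def median_width(self) -> float:
        return float(self.rows["width"].median())

    @property
    def median_error(self) -> float:
        return float(self.rows["error"].median())

    @property
    def outliers(self) -> pd.DataFrame:
        return self.rows.loc[~self.rows["captured"]]


@dataclass
class GOFResult:
    """Chi-squared goodness of fit of outlier counts vs system sizes."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    p_value: float
    method: str
    reps: int | None = None


def coverage(errors, bounds) -> float:
    """Fraction of observations with Error strictly below its bound."""
    e = np.asarray(errors, dtype=float)
    b = np.asarray(bounds, dtype=float)
    if e.size == 0:
        raise ValueError("empty input to coverage")
    if e.shape != b.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {b.shape}")
    return float(np.mean(e < b))


def _select_fold(train: PredictorTable, selector: SelectorConfig) -> tuple[tuple[str, ...], ErrorModel]:
    if selector.method == "fixed":
        model = fit_ols(train, list(selector.predictors), rss_floor=selector.rss_floor)
        return tuple(selector.predictors), model
    if selector.method == "best_subset":
        res = best_subset_select(
            train, max_size=selector.max_size, d_convention=selector.d_convention
        )
    else:
        res = stepwise_select(train, d_convention=selector.d_convention)
    chosen_cols = tuple(c for b in res.chosen_blocks for c in train.blocks[b])
    return chosen_cols, res.model


def loso_cv(
    table: PredictorTable,
    selector: SelectorConfig | None = None,
    level: float = 0.95,
    width_kind: str = "upper",
    bound_kind: str = DEFAULT_BOUND_KIND,
) -> LOSOResult:
    """Leave-one-system-out cross-validation with per-fold selection.

    Each held-out mutation receives the error bound B at capture probability
    ``level`` (see :func:`ddg_errorband.regression.error_bound` for
    ``bound_kind``).  ``width_kind='upper'`` reports the interpretable
    "± B kcal/mol" margin (the bound itself); ``'full'`` reports the full
    symmetric interval width 2·(B − point) instead.  A held-out row carrying
    a nonzero value in a column the training fold dropped as aliased (e.g.
    an unseen secondary-structure level) is predicted with the
    reference-level contribution and flagged, not aborted.
    """
    if selector is None:
        selector = SelectorConfig()
    if width_kind not in ("upper", "full"):
        raise ValueError(f"unknown width_kind {width_kind!r}")
    systems = sorted(pd.unique(table.systems))
    if len(systems) < 2:
        raise ValueError("leave-one-system-out requires at least 2 systems")

    records = []
    fold_models: dict[str, ErrorModel] = {}
    fold_predictors: dict[str, tuple[str, ...]] = {}
    for sys_id in systems:
        held = table.systems == sys_id
        train = table.subset_rows(~held)
        chosen, model = _select_fold(train, selector)
        fold_models[sys_id] = model
        fold_predictors[sys_id] = chosen
        kept = set(model.predictor_names)
        dropped = [c for c in chosen if c not in kept]
        test_df = table.df.loc[held]
        for _, row in test_df.iterrows():
            warn = any(float(row[c]) != 0.0 for c in dropped)
            point = predict(model, row)
            b = error_bound(model, row, level=level, kind=bound_kind)
            err = float(row[table.response])
            records.append(
                {
                    "system_id": sys_id,
                    "error": err,
                    "point": point,
                    "upper": b,
                    "width": b if width_kind == "upper" else 2.0 * (b - point),
                    "captured": err < b,
                    "warn_unseen": warn,
                }
            )
    rows = pd.DataFrame.from_records(records)
    per_system = (
        rows.groupby("system_id")
        .agg(
            n=("error", "size"),
            coverage=("captured", "mean"),
            median_error=("error", "median"),
            median_width=("width", "median"),
            n_outliers=("captured", lambda c: int((~c).sum())),
        )
        .loc[systems]
    )
    return LOSOResult(
        rows=rows,
        per_system=per_system,
        fold_models=fold_models,
        fold_predictors=fold_predictors,
        level=level,
        width_kind=width_kind,
    )


def summarize_by_system(result: LOSOResult) -> pd.DataFrame:
    """System-by-system performance table plus a Total row.

    Columns: n, median Error (kcal/mol), coverage (%), median width
    (kcal/mol) — the per-system breakdown layout.
    """
    if result.n == 0:
        raise ValueError("empty LOSO result")
    tab = result.per_system.copy()
    out = pd.DataFrame(
        {
            "n": tab["n"].astype(int),
            "median_error": tab["median_error"],
            "coverage_pct": 100.0 * tab["coverage"],
            "median_width": tab["median_width"],
        }
    )
    out.loc["Total"] = [
        result.n,
        result.median_error,
        100.0 * result.overall_coverage,
        result.median_width,
    ]
    out["n"] = out["n"].astype(int)
    return out


def outlier_gof_test(
    observed,
    n_i,
    method: str = "monte_carlo",
    reps: int = 2000,
    seed: int | None = None,
) -> GOFResult:
    """Do outliers concentrate in particular systems?

    Expected counts are proportional to system sizes: E_i = T·n_i/N with T
    the total outlier count.  The statistic is Σ(O−E)²/E.  ``monte_carlo``
    draws ``reps`` multinomial tables under proportionality and reports
    p = (b + 1)/(reps + 1) with b the number of draws at least as extreme;
    ``asymptotic`` uses the χ² distribution with (#systems − 1) df.
    """
    obs = np.asarray(observed, dtype=float)
    sizes = np.asarray(n_i, dtype=float)
    if obs.shape != sizes.shape:
        raise ValueError("observed and n_i must have equal length")
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one outlier")
    probs = sizes / sizes.sum()
    expected = total * probs
    if np.any(expected == 0):
        raise ValueError("a system has expected outlier count 0")
    statistic = float(np.sum((obs - expected) ** 2 / expected))

    if method == "asymptotic":
        p = float(stats.chi2.sf(statistic, df=len(obs) - 1))
        return GOFResult(obs, expected, statistic, p, method)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(total), probs, size=reps)
    sim_stats = np.sum((draws - expected) ** 2 / expected, axis=1)
    b = int(np.sum(sim_stats >= statistic - 1e-12))
    p = (b + 1) / (reps + 1)
    return GOFResult(obs, expected, statistic, float(p), method, reps=reps)
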