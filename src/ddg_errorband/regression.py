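"""Ordinary-least-squares core with BIC model selection and error bounds.

The fitted object is deliberately self-contained: it stores the coefficient
vector, the residual variance s², and the inverse normal-equations matrix
(XᵀX)⁻¹, which is everything needed to emit an out-of-sample prediction
interval for a new mutation x₀:

    ŷ₀ ± t(1 − α/2, n − p) · s · sqrt(1 + x₀ᵀ (XᵀX)⁻¹ x₀)

The upper end of that interval is the per-mutation error bound B.  Model
search minimises BIC = −2·loglike + ln(n)·d where loglike is the Gaussian
maximum log-likelihood and d counts fitted slope coefficients (dummy columns
counted individually, intercept excluded).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .features import PredictorTable

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel",
    "PredictionBound",
    "SelectionResult",
    "fit_ols",
    "bic",
    "predict",
    "predict_interval",
    "error_bound",
    "best_subset_select",
    "stepwise_select",
    "effect_on_interval_width",
    "DEFAULT_BOUND_KIND",
]

#: How the scalar error bound B is derived from the fitted model.
#: ``one_sided`` targets P(Error < B) = level (the calibrated choice for the
#: capture statistic); ``two_sided_upper`` is the upper limit of the central
#: two-sided interval at the same level (capture probability (1+level)/2 on
#: correctly specified data).
DEFAULT_BOUND_KIND = "one_sided"

#: Condition-number ceiling beyond which a candidate design is treated as
#: numerically singular and skipped during search.
COND_MAX = 1e10

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ErrorModel:
    """A fitted linear Error model with interval machinery.

    ``params`` holds the intercept first, then one coefficient per entry of
    ``predictor_names`` (post aliased-column drop).  ``xtx_inv`` is the
    inverse Gram matrix of the design including the intercept column.
    """

    predictor_names: list[str]
    params: np.ndarray
    xtx_inv: np.ndarray
    s2: float
    df_resid: int
    n: int
    rss: float
    loglik: float
    adj_r2: float
    dropped: list[str] = field(default_factory=list)
    response: str = "error_abs"

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.predictor_names, self.params[1:]))

    @property
    def bic_value(self) -> float:
        return bic(self)

    def design_row(self, x0) -> np.ndarray:
        """Build [1, x...] in model order from a mapping/Series/array."""
        if isinstance(x0, (pd.Series, dict)):
            try:
                vals = [float(x0[name]) for name in self.predictor_names]
            except KeyError as exc:
                raise ValueError(f"x0 missing predictor {exc.args[0]!r}") from None
        else:
            arr = np.asarray(x0, dtype=float).ravel()
            if arr.size != len(self.predictor_names):
                raise ValueError(
                    f"x0 has {arr.size} values, model expects {len(self.predictor_names)}"
                )
            vals = list(arr)
        return np.concatenate(([1.0], vals))


@dataclass(frozen=True)
class PredictionBound:
    """Out-of-sample interval for the Error of one mutation (kcal/mol).

    ``upper`` is the error bound B; the lower end is reported raw (the
    response is a magnitude but downstream uses the upper bound only).
    """

    point: float
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must satisfy lower <= point <= upper")


@dataclass
class SelectionResult:
    """Outcome of a model search over predictor blocks."""

    method: str
    model: ErrorModel
    chosen_blocks: tuple[str, ...]
    best_by_size: dict[int, tuple[tuple[str, ...], float]]
    trace: list[tuple[tuple[str, ...], float]]
    n_steps: int = 0


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (_LOG2PI + math.log(rss / n) + 1.0)


def _independent_columns(X: np.ndarray, names: list[str]) -> tuple[list[int], list[str]]:
    """Greedy keep-first scan dropping exactly aliased (dependent) columns."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    return keep, dropped


def fit_ols(
    table: PredictorTable,
    predictors: list[str] | None = None,
    rss_floor: bool = False,
) -> ErrorModel:
    """Fit Error ~ intercept + predictors by least squares.

    Exactly aliased columns are dropped with a logged warning (keep-first
    policy).  A zero RSS makes the Gaussian log-likelihood infinite and is an
    error unless ``rss_floor`` is set, which floors RSS at 1e−12·n·var(y).
    """
    if predictors is None:
        predictors = list(table.predictors)
    unknown = [p for p in predictors if p not in table.df.columns]
    if unknown:
        raise ValueError(f"unknown predictor(s): {unknown}")
    y = table.y
    n = len(y)
    Xp = table.df[list(predictors)].to_numpy(dtype=float) if predictors else np.empty((n, 0))
    X = np.column_stack([np.ones(n), Xp])
    names = ["const"] + list(predictors)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep, dropped = _independent_columns(X, names)
        if 0 not in keep:  # intercept always kept; it is scanned first
            raise RuntimeError("intercept column unexpectedly dropped")
        logger.warning("dropping aliased column(s): %s", dropped)
        X = X[:, keep]
        kept_names = [names[j] for j in keep]
    else:
        dropped = []
        kept_names = names

    p = X.shape[1]
    if n <= p:
        raise ValueError(f"n={n} must exceed number of fitted columns p={p}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    s2 = rss / df_resid
    if rss <= 0 or (tss > 0 and rss < 1e-14 * tss):
        if not rss_floor:
            raise ValueError(
                "RSS is (numerically) zero: log-likelihood undefined; "
                "pass rss_floor=True to floor it"
            )
        rss = max(rss, 1e-12 * n * float(np.var(y)))
        s2 = rss / df_resid
    loglik = _gaussian_loglik(rss, n)
    adj_r2 = 1.0 - (rss / df_resid) / (tss / (n - 1)) if tss > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return ErrorModel(
        predictor_names=kept_names[1:],
        params=beta,
        xtx_inv=xtx_inv,
        s2=s2,
        df_resid=df_resid,
        n=n,
        rss=rss,
        loglik=loglik,
        adj_r2=float(adj_r2),
        dropped=dropped,
        response=table.response,
    )


def bic(model: ErrorModel, d_convention: str = "paper") -> float:
    """BIC = −2·loglike + ln(n)·d.

    ``d_convention='paper'`` counts the fitted slope coefficients (the number
    of predictor variables, dummies individually); ``'plus_intercept'`` adds
    one.  At fixed n the choice shifts every model equally and never changes
    rankings.
    """
    if not math.isfinite(model.loglik):
        raise ValueError("log-likelihood is not finite")
    d = len(model.predictor_names)
    if d_convention == "plus_intercept":
        d += 1
    elif d_convention != "paper":
        raise ValueError(f"unknown d_convention {d_convention!r}")
    return -2.0 * model.loglik + math.log(model.n) * d


def predict(model: ErrorModel, x0) -> float:
    return float(model.design_row(x0) @ model.params)


def predict_interval(model: ErrorModel, x0, level: float = 0.95) -> PredictionBound:
    """Out-of-sample prediction interval for a new observation at x0.

    Uses the t-based interval with the "1 +" leverage term; the upper bound
    is the per-mutation error bound B.  The lower end is not clamped at 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    x = model.design_row(x0)
    point = float(x @ model.params)
    if model.s2 == 0.0:
        return PredictionBound(point=point, lower=point, upper=point, level=level)
    alpha = 1.0 - level
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, model.df_resid)
    half = tcrit * math.sqrt(model.s2 * (1.0 + float(x @ model.xtx_inv @ x)))
    return PredictionBound(point=point, lower=point - half, upper=point + half, level=level)


def error_bound(
    model: ErrorModel, x0, level: float = 0.95, kind: str = DEFAULT_BOUND_KIND
) -> float:
    """Per-mutation error bound B (kcal/mol).

    ``one_sided`` (default): B = x̂β + t(level, n−p)·s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀),
    so a new Error from the fitted model falls below B with probability
    ``level`` exactly.  ``two_sided_upper``: the upper limit of the central
    two-sided interval at ``level`` (the quantile used is (1+level)/2).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if kind == "one_sided":
        q = level
    elif kind == "two_sided_upper":
        q = (1.0 + level) / 2.0
    else:
        raise ValueError(f"unknown bound kind {kind!r}")
    x = model.design_row(x0)
    point = float(x @ model.params)
    if model.s2 == 0.0:
        return point
    tcrit = stats.t.ppf(q, model.df_resid)
    return point + tcrit * math.sqrt(model.s2 * (1.0 + float(x @ model.xtx_inv @ x)))


class _RSSEngine:
    """Cached Gram-matrix RSS evaluations over column subsets."""

    def __init__(self, table: PredictorTable, columns: list[str]):
        y = table.y
        n = len(y)
        X = np.column_stack(
            [np.ones(n)] + [table.df[c].to_numpy(dtype=float) for c in columns]
        )
        self.columns = columns
        self.n = n
        self.G = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.tss = float(np.sum((y - y.mean()) ** 2))
        self.cache: dict[tuple[int, ...], float | None] = {}

    def rss(self, col_idx: tuple[int, ...]) -> float | None:
        """RSS of intercept + the given candidate columns; None if singular."""
        key = col_idx
        if key in self.cache:
            return self.cache[key]
        idx = np.concatenate(([0], np.asarray(col_idx, dtype=int) + 1))
        G = self.G[np.ix_(idx, idx)]
        xty = self.Xty[idx]
        try:
            c, low = linalg.cho_factor(G)
            beta = linalg.cho_solve((c, low), xty)
            if np.linalg.cond(G) > COND_MAX:
                out = None
            else:
                out = max(self.yty - float(xty @ beta), 0.0)
        except linalg.LinAlgError:
            out = None
        self.cache[key] = out
        return out


def _bic_from_rss(rss: float, n: int, d: int) -> float:
    if rss <= 0:
        raise ValueError("zero RSS during selection: log-likelihood undefined")
    return -2.0 * _gaussian_loglik(rss, n) + math.log(n) * d


def _block_layout(table: PredictorTable, blocks: dict[str, list[str]] | None):
    if blocks is None:
        blocks = table.blocks
    names = sorted(blocks)
    all_cols: list[str] = []
    col_idx: dict[str, list[int]] = {}
    for b in names:
        col_idx[b] = []
        for c in blocks[b]:
            col_idx[b].append(len(all_cols))
            all_cols.append(c)
    return names, blocks, all_cols, col_idx


def _forward_order(engine: _RSSEngine, names: list[str], col_idx, k: int) -> list[str]:
    """Greedy forward RSS ordering of blocks (screening for large pools)."""
    chosen: list[str] = []
    cols: tuple[int, ...] = ()
    remaining = list(names)
    while remaining and len(chosen) < k:
        best = None
        for b in remaining:
            rss = engine.rss(cols + tuple(col_idx[b]))
            if rss is not None and (best is None or rss < best[0]):
                best = (rss, b)
        if best is None:
            break
        chosen.append(best[1])
        cols = cols + tuple(col_idx[best[1]])
        remaining.remove(best[1])
    return chosen


def best_subset_select(
    table: PredictorTable,
    blocks: dict[str, list[str]] | None = None,
    max_size: int = 12,
    d_convention: str = "paper",
    exact_limit: int = 15,
) -> SelectionResult:
    """Minimum-BIC subset search over predictor blocks.

    For pools of up to ``exact_limit`` blocks the search is exact: branch and
    bound in which the RSS of the relaxed model (current blocks plus
    everything still available) lower-bounds the RSS of every completion, so
    a node is pruned when even that relaxed RSS combined with the smallest
    reachable penalty cannot beat the incumbent BIC.  Larger pools are first
    screened to their ``exact_limit`` best blocks by a greedy forward-RSS
    pass (exhaustive search over tens of blocks is combinatorially
    infeasible), then searched exactly within the screened set; the result is
    exact conditional on the screen.  The intercept-only model is always a
    candidate.  Ties in BIC break toward fewer blocks, then lexicographic
    block order.
    """
    names, blocks, all_cols, col_idx = _block_layout(table, blocks)
    engine = _RSSEngine(table, all_cols)
    if len(names) > exact_limit:
        screened = sorted(_forward_order(engine, names, col_idx, exact_limit))
        logger.info(
            "screened %d candidate blocks to %d by forward RSS: %s",
            len(names), len(screened), screened,
        )
        names = screened
    max_size = min(max_size, len(names))
    n = engine.n

    def cols_of(block_set: tuple[str, ...]) -> tuple[int, ...]:
        return tuple(i for b in block_set for i in col_idx[b])

    trace: list[tuple[tuple[str, ...], float]] = []
    best_by_size: dict[int, tuple[tuple[str, ...], float]] = {}
    null_rss = engine.tss
    best_bic = _bic_from_rss(null_rss, n, 0)
    best_set: tuple[str, ...] = ()
    best_by_size[0] = ((), null_rss)
    trace.append(((), best_bic))

    def consider(block_set: tuple[str, ...]) -> None:
        nonlocal best_bic, best_set
        rss = engine.rss(cols_of(block_set))
        if rss is None:
            logger.info("skipping numerically singular subset %s", block_set)
            return
        if rss <= 0.0:
            logger.info("skipping zero-RSS (degenerate) subset %s", block_set)
            return
        k = len(block_set)
        if k not in best_by_size or rss < best_by_size[k][1]:
            best_by_size[k] = (block_set, rss)
        value = _bic_from_rss(rss, n, len(cols_of(block_set)))
        trace.append((block_set, value))
        better = value < best_bic - 1e-10
        tie = abs(value - best_bic) <= 1e-10
        if better or (tie and (len(block_set) < len(best_set))):
            best_bic, best_set = value, block_set

    def descend(i: int, chosen: tuple[str, ...]) -> None:
        if len(chosen) >= max_size or i == len(names):
            return
        remaining = names[i:]
        # relaxed bound: all remaining blocks added (capped at max_size is
        # still valid since more columns can only lower RSS further)
        relaxed = engine.rss(cols_of(chosen + tuple(remaining)))
        if relaxed is not None and relaxed > 0:
            d_min = len(cols_of(chosen)) + min(len(col_idx[b]) for b in remaining)
            if _bic_from_rss(relaxed, n, d_min) >= best_bic - 1e-10:
                return
        for j in range(i, len(names)):
            nxt = chosen + (names[j],)
            consider(nxt)
            descend(j + 1, nxt)

    descend(0, ())

    chosen_cols = [c for b in best_set for c in blocks[b]]
    model = fit_ols(table, chosen_cols)
    return SelectionResult(
        method="best_subset",
        model=model,
        chosen_blocks=best_set,
        best_by_size=best_by_size,
        trace=trace,
    )


def stepwise_select(
    table: PredictorTable,
    blocks: dict[str, list[str]] | None = None,
    start: str = "null",
    d_convention: str = "paper",
) -> SelectionResult:
    """Greedy bidirectional stepwise search on BIC.

    One block is added or removed per step, taking the move with the largest
    BIC decrease; the search stops when every move makes the fit poorer.
    Deterministic given the table and start.
    """
    names, blocks, all_cols, col_idx = _block_layout(table, blocks)
    engine = _RSSEngine(table, all_cols)
    n = engine.n

    def cols_of(block_set: frozenset[str]) -> tuple[int, ...]:
        return tuple(i for b in names if b in block_set for i in col_idx[b])

    def bic_of(block_set: frozenset[str]) -> float | None:
        cols = cols_of(block_set)
        rss = engine.rss(cols) if cols else engine.tss
        if rss is None:
            return None
        return _bic_from_rss(rss, n, len(cols))

    if start == "null":
        current: frozenset[str] = frozenset()
    elif start == "full":
        current = frozenset(names)
    else:
        raise ValueError(f"unknown start {start!r}")
    current_bic = bic_of(current)
    if current_bic is None:
        raise ValueError("starting model is numerically singular")

    trace = [(tuple(b for b in names if b in current), current_bic)]
    n_steps = 0
    while True:
        moves: list[tuple[float, int, tuple[str, ...], frozenset[str]]] = []
        for b in names:
            cand = current - {b} if b in current else current | {b}
            value = bic_of(cand)
            if value is not None:
                ordered = tuple(x for x in names if x in cand)
                moves.append((value, len(cand), ordered, cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_value, _, ordered, cand = moves[0]
        if best_value >= current_bic - 1e-10:
            break
        current, current_bic = cand, best_value
        trace.append((ordered, best_value))
        n_steps += 1

    chosen = tuple(b for b in names if b in current)
    chosen_cols = [c for b in chosen for c in blocks[b]]
    model = fit_ols(table, chosen_cols)
    return SelectionResult(
        method="stepwise",
        model=model,
        chosen_blocks=chosen,
        best_by_size={},
        trace=trace,
        n_steps=n_steps,
    )


def effect_on_interval_width(
    model: ErrorModel,
    table: PredictorTable,
    predictor: str,
    quantile: float = 0.10,
    level: float = 0.95,
    on_constant: str = "error",
    bound_kind: str = DEFAULT_BOUND_KIND,
) -> float:
    """Rescale a coefficient to an interval-width effect (kcal/mol).

    Builds two hypothetical mutations: the target predictor is set to the
    mean of its values within the top ``quantile`` fraction vs within the
    bottom fraction (for a 0/1 flag: 1 vs 0), all other predictors at their
    dataset-wide means; returns the difference of the predicted upper bounds.
    """
    if predictor not in model.predictor_names:
        raise ValueError(f"{predictor!r} is not in the fitted model")
    vals = table.df[predictor].to_numpy(dtype=float)
    if np.ptp(vals) == 0.0:
        if on_constant == "zero":
            return 0.0
        raise ValueError(f"predictor {predictor!r} is constant in the data")
    base = {name: float(table.df[name].mean()) for name in model.predictor_names}
    uniq = np.unique(vals)
    if set(uniq) <= {0.0, 1.0}:
        hi_val, lo_val = 1.0, 0.0
    else:
        hi_thr = np.quantile(vals, 1.0 - quantile)
        lo_thr = np.quantile(vals, quantile)
        hi_val = float(vals[vals >= hi_thr].mean())
        lo_val = float(vals[vals <= lo_thr].mean())
    hi_row = dict(base, **{predictor: hi_val})
    lo_row = dict(base, **{predictor: lo_val})
    upper_hi = error_bound(model, hi_row, level=level, kind=bound_kind)
    upper_lo = error_bound(model, lo_row, level=level, kind=bound_kind)
    return upper_hi - upper_lo
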