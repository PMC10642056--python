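"""Model-ladder orchestration: build, select, cross-validate, report.

Runs the five predictor pools (single-structure terms; + biochemistry; MD
means; + biochemistry; + snapshot SDs) on a folding and/or binding table and
emits a machine-readable report with, per model: the selected predictors,
leave-one-system-out coverage and median bound width, adjusted R² and BIC of
the all-data fit, per-system breakdowns, and coefficient / interval-width
effect tables.  The report is a pure function of (inputs, config).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import POOLS, build_predictor_table
from .regression import (
    best_subset_select,
    bic,
    effect_on_interval_width,
    stepwise_select,
)
from .validation import SelectorConfig, loso_cv, summarize_by_system

logger = logging.getLogger(__name__)

__all__ = ["LadderReport", "run_model_ladder", "write_report"]


@dataclass
class LadderReport:
    """Comparison metrics and reporting tables for the model ladder."""

    comparison: pd.DataFrame            # rows: dataset × model; Table-4-style metrics
    per_system: dict[str, pd.DataFrame]  # key "dataset/model"
    coefficients: dict[str, pd.DataFrame]  # key "dataset/model"
    selected: dict[str, dict[str, tuple[str, ...]]]
    skipped: list[str]
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "skipped": self.skipped,
            "comparison": self.comparison.to_dict(orient="records"),
            "selected": {
                k: {m: list(v) for m, v in d.items()} for k, d in self.selected.items()
            },
            "per_system": {k: v.reset_index().to_dict(orient="records") for k, v in self.per_system.items()},
            "coefficients": {k: v.to_dict(orient="records") for k, v in self.coefficients.items()},
        }


def _coefficient_table(model, table, level):
    rows = []
    # classical OLS t-test p-values for reporting
    from scipy import stats

    se = np.sqrt(np.diag(model.xtx_inv) * model.s2)
    tvals = model.params / se
    pvals = 2 * stats.t.sf(np.abs(tvals), model.df_resid)
    names = ["const"] + model.predictor_names
    for name, est, p in zip(names, model.params, pvals):
        effect = None
        if name != "const":
            try:
                effect = effect_on_interval_width(model, table, name, level=level)
            except ValueError:
                effect = None
        rows.append(
            {"predictor": name, "coefficient": float(est), "p_value": float(p),
             "effect_on_interval_width": effect}
        )
    return pd.DataFrame(rows)


def run_model_ladder(
    tables: dict[str, pd.DataFrame],
    method: str = "best_subset",
    max_size: int = 12,
    level: float = 0.95,
    compare_methods: bool = False,
) -> LadderReport:
    """Run the five-pool ladder on named tidy tables (e.g. folding/binding).

    Pools needing single-structure columns are skipped with a note when those
    columns are absent.  Selection is re-run inside every LOSO training fold
    (no leakage); the all-data fit provides the reported coefficients, BIC
    and adjusted R².  With ``compare_methods`` both search methods are run on
    the full data and their chosen subsets recorded; the headline metrics use
    ``method``.
    """
    comparison_rows = []
    per_system: dict[str, pd.DataFrame] = {}
    coefficients: dict[str, pd.DataFrame] = {}
    selected: dict[str, dict[str, tuple[str, ...]]] = {}
    skipped: list[str] = []

    for ds_name, df in tables.items():
        selected[ds_name] = {}
        for pool in POOLS:
            tag = f"{ds_name}/{pool}"
            if pool in ("model1", "model2") and "total_single" not in df.columns:
                logger.info("skipping %s: no single-structure columns", tag)
                skipped.append(tag)
                continue
            table = build_predictor_table(df, pool)
            logger.info("%s: %d rows, %d candidate columns", tag, len(table.df), len(table.predictors))

            searches = {}
            for m in {method} | ({"best_subset", "stepwise"} if compare_methods else set()):
                if m == "best_subset":
                    searches[m] = best_subset_select(table, max_size=max_size)
                else:
                    searches[m] = stepwise_select(table)
            res = searches[method]
            chosen_cols = tuple(c for b in res.chosen_blocks for c in table.blocks[b])
            for m, r in searches.items():
                selected[ds_name][f"{pool}/{m}"] = r.chosen_blocks
            logger.info("%s: selected %s", tag, list(res.chosen_blocks))

            selector = SelectorConfig(method=method, max_size=max_size)
            cv = loso_cv(table, selector=selector, level=level)
            per_system[tag] = summarize_by_system(cv)
            coefficients[tag] = _coefficient_table(res.model, table, level)
            comparison_rows.append(
                {
                    "dataset": ds_name,
                    "model": pool,
                    "coverage_pct": 100.0 * cv.overall_coverage,
                    "median_width": cv.median_width,
                    "adj_r2": res.model.adj_r2,
                    "bic": bic(res.model),
                    "n": cv.n,
                    "n_predictors": len(chosen_cols),
                }
            )

    comparison = pd.DataFrame(comparison_rows)
    return LadderReport(
        comparison=comparison,
        per_system=per_system,
        coefficients=coefficients,
        selected=selected,
        skipped=skipped,
        config={"method": method, "max_size": max_size, "level": level},
    )


def write_report(report: LadderReport, out_dir: str | Path) -> None:
    """Write report.json plus CSV tables mirroring the comparison layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2, default=str))
    report.comparison.to_csv(out / "comparison.csv", index=False)
    for key, tab in report.per_system.items():
        tab.to_csv(out / f"per_system_{key.replace('/', '_')}.csv")
    for key, tab in report.coefficients.items():
        tab.to_csv(out / f"coefficients_{key.replace('/', '_')}.csv", index=False)
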