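"""Response and predictor construction.

The response of every model is the *Error* — the absolute difference between
the FoldX-predicted and the experimentally measured stability change,

    Error = |ΔΔG_FoldX − ΔΔG_exp|   (kcal/mol),

modelled as a linear function of predictors drawn from three pools: FoldX
energy-term ΔΔG values, their snapshot SDs, and biochemical properties of
the mutated residue (proline involvement, absolute changes in van der Waals
volume / hydrophobicity / side-chain charge, DSSP secondary-structure class,
and relative solvent accessibility).

Five predictor pools of increasing complexity are defined:

========  =====================  =========================================
pool      ΔΔG_FoldX source        candidate predictors
========  =====================  =========================================
model1    single structure        17 energy terms
model2    single structure        + 6 biochemical properties
model3    MD snapshot mean        17 energy-term means
model4    MD snapshot mean        + 6 biochemical properties
model5    MD snapshot mean        + 17 energy-term SDs (full model)
========  =====================  =========================================
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .data_model import (
    BIOCHEM_COLUMNS,
    CANONICAL_TERMS,
    DsspResidue,
    MutationRecord,
    SS_LEVELS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PropertyTables",
    "BiochemProps",
    "PredictorTable",
    "load_property_tables",
    "compute_error",
    "compute_biochem_props",
    "pool_columns",
    "build_predictor_table",
    "SS_REFERENCE",
]

#: Reference level for secondary-structure dummy coding (isolated β-bridge).
SS_REFERENCE = "B"

POOLS = ("model1", "model2", "model3", "model4", "model5")

SCALAR_BIOCHEM = ("is_proline", "volume_change", "hydrophobicity_change", "charge_change")


@dataclass(frozen=True)
class PropertyTables:
    """Frozen per-residue physical property lookups (20 entries each)."""

    volume: dict[str, float]           # van der Waals volume, Å³
    hydrophobicity: dict[str, float]   # index at pH 7
    charge: dict[str, float]           # side-chain formal charge
    max_asa_theoretical: dict[str, float]  # Å²
    max_asa_empirical: dict[str, float]    # Å²


@dataclass(frozen=True)
class BiochemProps:
    """Mutation-level biochemical predictors; change fields are absolute."""

    is_proline: int
    volume_change: float
    hydrophobicity_change: float
    charge_change: float
    ss_class: str
    rsa: float


def load_property_tables(his_charge: float = 0.0) -> PropertyTables:
    """Load the packaged amino-acid property tables.

    ``his_charge`` overrides the histidine side-chain charge (default 0 at
    pH 7; a fractional +0.1 convention can be selected).
    """
    with resources.files("ddg_errorband.data").joinpath("aa_properties.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    if len(df) != 20:
        raise ValueError("property table must have exactly 20 amino-acid rows")
    charge = dict(zip(df["aa"], df["charge"].astype(float)))
    charge["H"] = float(his_charge)
    return PropertyTables(
        volume=dict(zip(df["aa"], df["volume_a3"].astype(float))),
        hydrophobicity=dict(zip(df["aa"], df["hydrophobicity_ph7"].astype(float))),
        charge=charge,
        max_asa_theoretical=dict(zip(df["aa"], df["max_asa_theoretical"].astype(float))),
        max_asa_empirical=dict(zip(df["aa"], df["max_asa_empirical"].astype(float))),
    )


def compute_error(ddg_foldx, ddg_exp):
    """Error = |ΔΔG_FoldX − ΔΔG_exp| (kcal/mol); accepts scalars or arrays."""
    a = np.asarray(ddg_foldx, dtype=float)
    b = np.asarray(ddg_exp, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite ΔΔG input to compute_error")
    out = np.abs(a - b)
    return float(out) if out.ndim == 0 else out


def compute_biochem_props(
    mutation: MutationRecord,
    dssp_record: DsspResidue,
    tables: PropertyTables,
    max_asa_kind: str = "theoretical",
    strict: bool = True,
) -> BiochemProps:
    """Derive the six biochemical predictors for one mutation.

    RSA is the DSSP absolute accessibility of the wild-type residue divided
    by its maximum ASA, clipped to [0, 1] (over-unity ratios occur for
    distorted or terminal residues and are clipped with a warning).
    """
    if max_asa_kind not in ("theoretical", "empirical"):
        raise ValueError(f"unknown max_asa_kind {max_asa_kind!r}")
    if (dssp_record.chain, dssp_record.position) != (mutation.chain, mutation.position):
        raise ValueError(
            f"DSSP record {dssp_record.chain}{dssp_record.position} does not match "
            f"mutation site {mutation.chain}{mutation.position}"
        )
    if dssp_record.aa.upper() != mutation.wt_aa:
        msg = (
            f"DSSP residue {dssp_record.aa!r} != wild-type {mutation.wt_aa!r} at "
            f"{mutation.chain}{mutation.position}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    wt, mut = mutation.wt_aa, mutation.mut_aa
    max_asa = (
        tables.max_asa_theoretical if max_asa_kind == "theoretical" else tables.max_asa_empirical
    )
    rsa = dssp_record.acc / max_asa[wt]
    if rsa > 1.0:
        logger.warning(
            "RSA %.3f > 1 at %s%s; clipping to 1", rsa, mutation.chain, mutation.position
        )
        rsa = 1.0
    if dssp_record.ss_class not in SS_LEVELS:
        raise ValueError(f"unknown secondary-structure class {dssp_record.ss_class!r}")
    return BiochemProps(
        is_proline=int(wt == "P" or mut == "P"),
        volume_change=abs(tables.volume[wt] - tables.volume[mut]),
        hydrophobicity_change=abs(tables.hydrophobicity[wt] - tables.hydrophobicity[mut]),
        charge_change=abs(tables.charge[wt] - tables.charge[mut]),
        ss_class=dssp_record.ss_class,
        rsa=float(rsa),
    )


@dataclass
class PredictorTable:
    """Design table for one pool: response, predictors and system labels.

    ``df`` holds one row per mutation with columns ``error_abs`` (response),
    ``system_id``, and every predictor; ``blocks`` groups columns that enter
    or leave selection together (the secondary-structure dummies form one
    block, everything else is a singleton).
    """

    df: pd.DataFrame
    predictors: list[str]
    blocks: dict[str, list[str]]
    pool: str
    response: str = "error_abs"

    @property
    def y(self) -> np.ndarray:
        return self.df[self.response].to_numpy(dtype=float)

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.predictors]

    @property
    def systems(self) -> np.ndarray:
        return self.df["system_id"].to_numpy()

    def subset_rows(self, mask) -> "PredictorTable":
        return PredictorTable(
            df=self.df.loc[mask].reset_index(drop=True),
            predictors=list(self.predictors),
            blocks={k: list(v) for k, v in self.blocks.items()},
            pool=self.pool,
            response=self.response,
        )


def pool_columns(pool: str) -> dict[str, list[str]]:
    """Raw (pre-dummy) column requirements of a predictor pool."""
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}; expected one of {POOLS}")
    suffix = "_single" if pool in ("model1", "model2") else "_mean"
    cols: dict[str, list[str]] = {"terms": [f"{t}{suffix}" for t in CANONICAL_TERMS]}
    if pool in ("model2", "model4", "model5"):
        cols["biochem"] = list(BIOCHEM_COLUMNS)
    if pool == "model5":
        cols["sd"] = [f"{t}_sd" for t in CANONICAL_TERMS]
    return cols


def build_predictor_table(
    df: pd.DataFrame,
    pool: str,
    response_source: str | None = None,
    drop_constant_dummies: bool = True,
) -> PredictorTable:
    """Assemble the design table for one pool from a tidy mutation table.

    The response is computed from the pool's designated ΔΔG_FoldX source
    (``total_single`` for models 1–2, ``total_mean`` for models 3–5, unless
    overridden).  ``ss_class`` is expanded to dummies against reference level
    ``B``; dummy levels absent from the data are dropped (logged) so the
    design stays full rank.  Column order is deterministic.
    """
    cols = pool_columns(pool)
    if response_source is None:
        response_source = "single_structure" if pool in ("model1", "model2") else "md_mean"
    total_col = {"single_structure": "total_single", "md_mean": "total_mean"}.get(response_source)
    if total_col is None:
        raise ValueError(f"unknown response_source {response_source!r}")

    needed = [c for group in cols.values() for c in group] + [total_col, "ddg_exp", "system_id"]
    missing = [c for c in dict.fromkeys(needed) if c not in df.columns]
    if missing:
        raise ValueError(f"pool {pool} requires missing column(s): {', '.join(missing)}")
    if df["ddg_exp"].isna().any():
        raise ValueError("response requires ddg_exp on every row")

    out = pd.DataFrame({"system_id": df["system_id"].astype(str).to_numpy()})
    out["error_abs"] = compute_error(df[total_col].to_numpy(), df["ddg_exp"].to_numpy())

    predictors: list[str] = []
    blocks: dict[str, list[str]] = {}
    for c in cols["terms"]:
        out[c] = df[c].astype(float).to_numpy()
        predictors.append(c)
        blocks[c] = [c]
    if "biochem" in cols:
        for c in SCALAR_BIOCHEM:
            out[c] = df[c].astype(float).to_numpy()
            predictors.append(c)
            blocks[c] = [c]
        ss = df["ss_class"].astype(str)
        bad = set(ss) - set(SS_LEVELS)
        if bad:
            raise ValueError(f"unknown ss_class level(s): {sorted(bad)}")
        dummy_cols = []
        for level in SS_LEVELS:
            if level == SS_REFERENCE:
                continue
            col = f"ss_{level}"
            vals = (ss == level).astype(float).to_numpy()
            if drop_constant_dummies and not vals.any():
                logger.info("dropping all-zero dummy %s (level absent from data)", col)
                continue
            out[col] = vals
            dummy_cols.append(col)
        if dummy_cols:
            predictors.extend(dummy_cols)
            blocks["ss_class"] = dummy_cols
        out["rsa"] = df["rsa"].astype(float).to_numpy()
        predictors.append("rsa")
        blocks["rsa"] = ["rsa"]
    if "sd" in cols:
        for c in cols["sd"]:
            out[c] = df[c].astype(float).to_numpy()
            predictors.append(c)
            blocks[c] = [c]

    if out[predictors].isna().any().any():
        bad_cols = out[predictors].columns[out[predictors].isna().any()].tolist()
        raise ValueError(f"missing values in predictor column(s): {bad_cols}")
    if out["system_id"].nunique() < 2:
        raise ValueError("need at least 2 systems (leave-one-system-out requires it)")
    return PredictorTable(df=out, predictors=predictors, blocks=blocks, pool=pool)
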