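"""Synthetic mutation datasets with known error structure.

The generator emulates the statistical shape of a multi-system ΔΔG
benchmark — ten protein systems of 19–190 mutations, 16 constituent FoldX
energy terms plus the total (snapshot means and SDs), biochemical properties
derived from real residue property tables, and a destabilizing-skewed
ΔΔG_exp distribution — with a known linear ground truth for the Error:

    Error_j = intercept + x_jᵀβ + u_system(j) + ε_j,   ε ~ N(0, σ²)

Negative Error draws are resampled (the response is a magnitude); the
experimental value is then placed at ΔΔG_exp = ΔΔG_FoldX − s_j·Error_j with
the sign s_j chosen to skew the resulting ΔΔG_exp classes toward
destabilizing.  Every pipeline stage (pool assembly, selection, intervals,
LOSO coverage, classification) can therefore be exercised against known
parameters without any external download.  It reproduces the *statistical*
structure only — not FoldX physics, MD dynamics, or the real correlations
among energy terms (a hook for a correlation matrix is a non-goal here).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CANONICAL_TERMS, CONSTITUENT_TERMS, FOLDX4_COLUMN_MAP
from .features import load_property_tables

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "sample_mutation_features",
    "generate_dataset",
    "make_fixture_suite",
    "write_fxout",
    "format_dssp",
]

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
NON_PROLINE = tuple(a for a in AA_ORDER if a != "P")

#: Per-term sampling parameters for snapshot-mean ΔΔG values (kcal/mol).
#: Clash-like terms are nonnegative (log-normal, parameters in log space);
#: the rest are Gaussian.  Locations skew the total toward destabilizing.
DEFAULT_TERM_PARAMS: dict[str, tuple[str, float, float]] = {
    "electrostatic": ("gaussian", 0.0, 0.3),
    "electrostatic_kon": ("gaussian", 0.0, 0.05),
    "entropy_mainchain": ("gaussian", 0.1, 0.4),
    "entropy_sidechain": ("gaussian", 0.3, 0.5),
    "helix_dipole": ("gaussian", 0.0, 0.15),
    "hbond_backbone": ("gaussian", 0.2, 0.6),
    "hbond_sidechain": ("gaussian", 0.1, 0.5),
    "ionization": ("gaussian", 0.0, 0.05),
    "solvation_hydrophobic": ("gaussian", -0.4, 0.7),
    "solvation_polar": ("gaussian", 0.5, 0.8),
    "vdw": ("gaussian", 0.5, 0.9),
    "backbone_vdw_clash": ("lognormal", math.log(0.15), 0.8),
    "cis_bond": ("lognormal", -4.0, 1.0),
    "disulfide": ("lognormal", -4.0, 1.0),
    "torsional_clash": ("lognormal", math.log(0.2), 0.8),
    "vdw_clash": ("lognormal", math.log(0.4), 0.9),
}

DEFAULT_SS_PROBS: dict[str, float] = {
    "H": 0.35,
    "E": 0.20,
    "T": 0.12,
    "S": 0.10,
    "G": 0.06,
    "B": 0.02,
    "none": 0.15,
}

#: True Error coefficients (kcal/mol per unit) on predictor-table columns.
DEFAULT_BETA: dict[str, float] = {
    "vdw_mean": 0.631,
    "vdw_clash_mean": 0.431,
    "entropy_sidechain_mean": 0.531,
    "total_sd": 0.569,
    "is_proline": 0.724,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the generator; defaults mirror the benchmark scale."""

    n_systems: int = 10
    n_per_system: int | tuple[int, int] = (19, 190)
    # the intercept keeps the linear predictor ~3.5 noise-SDs above zero, so
    # the Error >= 0 resampling guard is an O(1e-4) event and OLS recovery of
    # the coefficients stays unbiased
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = 2.0
    noise_sd: float = 0.5
    system_effect_sd: float = 0.0
    proline_prob: float = 0.05
    ss_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SS_PROBS))
    rsa_beta: tuple[float, float] = (0.9, 1.8)
    term_params: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TERM_PARAMS)
    )
    total_resid_sd: float = 0.3      # total = Σ constituents + this noise
    sd_log_loc: float = math.log(0.25)   # per-term snapshot-SD, log space
    sd_log_scale: float = 0.5
    total_sd_log_loc: float = math.log(0.6)
    row_variability_log_sd: float = 0.35  # shared per-row SD scaling factor
    snapshot_count: int = 100
    single_structure: bool = True
    single_noise_sd: float = 0.6     # extra noise of single-structure terms
    class_skew: tuple[float, float, float] = (0.1, 0.2, 0.7)  # stab/neutral/destab
    clamp_negative_error: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.noise_sd < 0 or self.system_effect_sd < 0:
            raise ValueError("noise/system-effect SDs must be >= 0")
        if not 0 <= self.proline_prob <= 1:
            raise ValueError("proline_prob must be in [0, 1]")
        if abs(sum(self.ss_probs.values()) - 1.0) > 1e-9:
            raise ValueError("ss_probs must sum to 1")
        if abs(sum(self.class_skew) - 1.0) > 1e-9:
            raise ValueError("class_skew must sum to 1")
        if self.snapshot_count < 2:
            raise ValueError("snapshot_count must be >= 2")
        missing = set(self.term_params) ^ set(CONSTITUENT_TERMS)
        if missing:
            raise ValueError(f"term_params must cover constituent terms; mismatch: {missing}")


@dataclass
class SyntheticDataset:
    """Generated records plus the ground truth used to make them."""

    df: pd.DataFrame
    beta: dict[str, float]
    intercept: float
    noise_sd: float
    system_effects: dict[str, float]
    error: np.ndarray
    config: SyntheticConfig
    seed: int | None


def _sample_features(config: SyntheticConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Draw n rows of mutation-level predictors (no response yet)."""
    tables = load_property_tables()
    vol = np.array([tables.volume[a] for a in AA_ORDER])
    hyd = np.array([tables.hydrophobicity[a] for a in AA_ORDER])
    chg = np.array([tables.charge[a] for a in AA_ORDER])
    aa = np.array(AA_ORDER)
    nonp_idx = np.array([AA_ORDER.index(a) for a in NON_PROLINE])
    p_idx = AA_ORDER.index("P")

    has_p = rng.random(n) < config.proline_prob
    wt = np.empty(n, dtype=int)
    mut = np.empty(n, dtype=int)
    # non-proline pairs: ordered distinct draws from the 19 non-P residues
    n_free = int((~has_p).sum())
    wt_free = nonp_idx[rng.integers(0, len(nonp_idx), size=n_free)]
    shift = rng.integers(1, len(nonp_idx), size=n_free)
    mut_free = nonp_idx[(np.searchsorted(nonp_idx, wt_free) + shift) % len(nonp_idx)]
    wt[~has_p], mut[~has_p] = wt_free, mut_free
    # proline-involving pairs: P on a random side, partner uniform non-P
    n_pro = int(has_p.sum())
    side = rng.random(n_pro) < 0.5
    partner = nonp_idx[rng.integers(0, len(nonp_idx), size=n_pro)]
    wt[has_p] = np.where(side, p_idx, partner)
    mut[has_p] = np.where(side, partner, p_idx)

    ss_levels = list(config.ss_probs)
    ss = rng.choice(ss_levels, size=n, p=[config.ss_probs[k] for k in ss_levels])
    rsa = rng.beta(*config.rsa_beta, size=n)

    out = pd.DataFrame(
        {
            "wt_aa": aa[wt],
            "mut_aa": aa[mut],
            "is_proline": has_p.astype(int),
            "volume_change": np.abs(vol[wt] - vol[mut]),
            "hydrophobicity_change": np.abs(hyd[wt] - hyd[mut]),
            "charge_change": np.abs(chg[wt] - chg[mut]),
            "ss_class": ss,
            "rsa": rsa,
        }
    )

    v_row = np.exp(rng.normal(0.0, config.row_variability_log_sd, size=n))
    for term in CONSTITUENT_TERMS:
        kind, loc, scale = config.term_params[term]
        if kind == "gaussian":
            out[f"{term}_mean"] = rng.normal(loc, scale, size=n)
        elif kind == "lognormal":
            out[f"{term}_mean"] = np.exp(rng.normal(loc, scale, size=n))
        else:
            raise ValueError(f"unknown distribution kind {kind!r} for term {term}")
        out[f"{term}_sd"] = (
            np.exp(rng.normal(config.sd_log_loc, config.sd_log_scale, size=n)) * v_row
        )
    const = out[[f"{t}_mean" for t in CONSTITUENT_TERMS]].to_numpy()
    out["total_mean"] = const.sum(axis=1) + rng.normal(0.0, config.total_resid_sd, size=n)
    out["total_sd"] = (
        np.exp(rng.normal(config.total_sd_log_loc, config.sd_log_scale, size=n)) * v_row
    )
    if config.single_structure:
        for term in CONSTITUENT_TERMS:
            out[f"{term}_single"] = out[f"{term}_mean"] + rng.normal(
                0.0, config.single_noise_sd, size=n
            )
        singles = out[[f"{t}_single" for t in CONSTITUENT_TERMS]].to_numpy()
        out["total_single"] = singles.sum(axis=1) + rng.normal(
            0.0, config.total_resid_sd, size=n
        )
    return out


def sample_mutation_features(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    """One row of mutation-level predictors."""
    return _sample_features(config, rng, 1).iloc[0]


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a full multi-system dataset with known Error ground truth.

    ``seed`` overrides ``config.seed``; the same seed yields a bit-identical
    dataset.  The stored response satisfies Error = |ΔΔG_FoldX − ΔΔG_exp|
    exactly by construction.
    """
    if config is None:
        config = SyntheticConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    if isinstance(config.n_per_system, int):
        sizes = np.full(config.n_systems, config.n_per_system)
    else:
        lo, hi = config.n_per_system
        sizes = rng.integers(lo, hi + 1, size=config.n_systems)
    system_ids = [f"SYS{i + 1:02d}" for i in range(config.n_systems)]
    n = int(sizes.sum())

    feats = _sample_features(config, rng, n)
    feats.insert(0, "system_id", np.repeat(system_ids, sizes))
    feats.insert(1, "chain", "A")
    feats.insert(2, "position", np.concatenate([np.arange(1, s + 1) for s in sizes]))

    u = rng.normal(0.0, config.system_effect_sd, size=config.n_systems)
    system_effects = dict(zip(system_ids, u))
    u_row = np.repeat(u, sizes)

    missing = [k for k in config.beta if k not in feats.columns]
    if missing:
        raise ValueError(f"beta refers to unknown column(s): {missing}")
    mu = config.intercept + u_row.copy()
    for name, coef in config.beta.items():
        mu = mu + coef * feats[name].to_numpy(dtype=float)

    eps = rng.normal(0.0, config.noise_sd, size=n)
    error = mu + eps
    if config.clamp_negative_error:
        error = np.maximum(error, 0.0)
    else:
        # resample the noise of negative draws: Error is a magnitude
        for _ in range(1000):
            neg = error < 0
            if not neg.any():
                break
            error[neg] = mu[neg] + rng.normal(0.0, config.noise_sd, size=int(neg.sum()))
        else:
            error = np.maximum(error, 0.0)

    ddg_foldx = feats["total_mean"].to_numpy(dtype=float)
    target = rng.choice(3, size=n, p=list(config.class_skew))  # 0 stab, 1 neutral, 2 destab
    sign = np.where(target == 2, -1.0, 1.0)
    toward_zero = np.where(ddg_foldx >= 0, 1.0, -1.0)
    sign = np.where(target == 1, toward_zero, sign)
    feats["ddg_exp"] = ddg_foldx - sign * error

    cols = ["system_id", "chain", "position", "wt_aa", "mut_aa", "ddg_exp"]
    cols += [f"{t}_mean" for t in CANONICAL_TERMS]
    cols += [f"{t}_sd" for t in CANONICAL_TERMS]
    if config.single_structure:
        cols += [f"{t}_single" for t in CANONICAL_TERMS]
    cols += ["is_proline", "volume_change", "hydrophobicity_change", "charge_change", "ss_class", "rsa"]
    df = feats[cols].copy()
    return SyntheticDataset(
        df=df,
        beta=dict(config.beta),
        intercept=config.intercept,
        noise_sd=config.noise_sd,
        system_effects=system_effects,
        error=error,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# text fixtures


_FOLDX4_HEADERS = {v: k for k, v in FOLDX4_COLUMN_MAP.items()}
_FOLDX4_RAW = [
    "Pdb",
    "total energy",
    "Backbone Hbond",
    "Sidechain Hbond",
    "Van der Waals",
    "Electrostatics",
    "Solvation Polar",
    "Solvation Hydrophobic",
    "Van der Waals clashes",
    "entropy sidechain",
    "entropy mainchain",
    "sloop_entropy",
    "mloop_entropy",
    "cis_bond",
    "torsional clash",
    "backbone clash",
    "helix dipole",
    "water bridge",
    "disulfide",
    "electrostatic kon",
    "partial covalent bonds",
    "energy Ionisation",
    "Entropy Complex",
]


def write_fxout(path: str | Path, rows: list[tuple[str, dict[str, float]]]) -> None:
    """Write a FoldX 4 "Dif" fxout table (synthetic fixture dialect).

    ``rows`` map canonical term names to values; non-canonical FoldX columns
    are emitted as zeros.
    """
    lines = [
        "FoldX 4 (synthetic fixture)",
        "Output type: Dif",
        "",
    ]
    lines.append("\t".join(_FOLDX4_RAW))
    for tag, terms in rows:
        vals = []
        for h in _FOLDX4_RAW[1:]:
            canon = FOLDX4_COLUMN_MAP.get(h.lower())
            vals.append(f"{terms.get(canon, 0.0):.5f}" if canon else "0")
        lines.append("\t".join([tag] + vals))
    Path(path).write_text("\n".join(lines) + "\n")


def format_dssp(residues: list[tuple[str, int, str, str, int]]) -> str:
    """Render classic DSSP text from (chain, resnum, aa, ss, acc) tuples.

    ``ss`` may be '' for unassigned structure.  Synthetic fixture writer: the
    output carries only the fields the reader consumes (fixed columns for
    residue identity, structure code, accessibility, H-bond placeholders and
    phi/psi), padded to the classic line width.
    """
    header = [
        "==== Secondary Structure Definition (synthetic fixture) ====",
        "REFERENCE / SYNTHETIC",
        f"  {len(residues)}  1  0  0  0 TOTAL NUMBER OF RESIDUES, ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N"
        "    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    lines = []
    for i, (chain, resnum, aa, ss, acc) in enumerate(residues, start=1):
        line = [" "] * 120
        line[0:5] = f"{i:5d}"
        line[5:10] = f"{resnum:5d}"
        line[11] = chain
        line[13] = aa
        line[16] = ss if ss else " "
        line[34:38] = f"{acc:4d}"
        line[38:45] = f"{0:7d}"
        line[46:50] = " 0.0"
        line[50:56] = f"{0:6d}"
        line[57:61] = " 0.0"
        line[61:67] = f"{0:6d}"
        line[68:72] = " 0.0"
        line[72:78] = f"{0:6d}"
        line[79:83] = " 0.0"
        line[103:109] = f"{0.0:6.1f}"
        line[109:115] = f"{0.0:6.1f}"
        lines.append("".join(line).rstrip("\n"))
    return "\n".join(header + lines) + "\n"


def make_fixture_suite(out_dir: str | Path, seed: int = 20230) -> dict[str, str]:
    """Write small text fixtures plus three canonical synthetic datasets.

    Emits an fxout table, a DSSP file, a 5-row tidy table, and three CSVs:
    ``calibration`` (correctly specified defaults), ``misspecified`` (the
    true predictor ``total_sd`` is hidden from the observable columns) and
    ``degenerate`` (zero noise and coefficients, Error ≡ intercept).
    Returns the manifest {relative path: sha256}, also written as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cal = generate_dataset(
        SyntheticConfig(n_per_system=60, seed=int(rng.integers(2**31)))
    )
    cal.df.to_csv(out / "calibration.csv", index=False)

    mis = generate_dataset(
        SyntheticConfig(n_per_system=60, seed=int(rng.integers(2**31)))
    )
    mis.df.drop(columns=["total_sd"]).to_csv(out / "misspecified.csv", index=False)

    deg = generate_dataset(
        SyntheticConfig(
            n_systems=4, n_per_system=20, beta={}, noise_sd=0.0,
            seed=int(rng.integers(2**31)),
        )
    )
    deg.df.to_csv(out / "degenerate.csv", index=False)

    small = generate_dataset(SyntheticConfig(n_systems=5, n_per_system=1, seed=seed))
    small.df.to_csv(out / "tidy_fixture.csv", index=False)

    fx_rows = []
    for i in range(3):
        terms = {t: float(np.round(rng.normal(0, 0.5), 5)) for t in CANONICAL_TERMS}
        fx_rows.append((f"Dif_snapshot_{i}.pdb", terms))
    write_fxout(out / "dif_fixture.fxout", fx_rows)

    residues = [("A", i + 1, aa, ss, int(rng.integers(0, 180)))
                for i, (aa, ss) in enumerate(zip("MKVLAYTREG", ["H", "H", "E", "E", "", "T", "S", "G", "B", ""]))]
    (out / "dssp_fixture.dssp").write_text(format_dssp(residues))

    manifest = {}
    for f in sorted(out.glob("*")):
        if f.name == "manifest.json":
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
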