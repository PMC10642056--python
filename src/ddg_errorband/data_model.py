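"""Domain types and file readers for the ΔΔG error-modelling pipeline.

The unit of analysis is a single missense mutation in one protein system,
carrying a FoldX-predicted stability change (ΔΔG_FoldX, kcal/mol) — either
from a single experimental structure or averaged over molecular-dynamics
snapshots — and, when available, an experimentally measured ΔΔG_exp.

Three on-disk formats are supported:

* FoldX 4 "Dif" fxout tables (tab-separated, banner lines before a header
  row whose first field is ``Pdb``),
* classic DSSP text output (parsed through Biopython),
* a tidy per-mutation CSV/TSV with per-term means and SDs over snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import make_dssp_dict

__all__ = [
    "AA_CODES",
    "CANONICAL_TERMS",
    "CONSTITUENT_TERMS",
    "FOLDX4_COLUMN_MAP",
    "MutationRecord",
    "EnergyTerms",
    "SnapshotSeries",
    "AggregatedEnergies",
    "DsspResidue",
    "read_foldx_dif",
    "aggregate_snapshots",
    "read_dssp",
    "read_tidy_table",
    "write_tidy_table",
    "tidy_columns",
]

AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The 16 constituent FoldX energy terms plus the total, under canonical
#: snake_case names.  These are the only terms admitted into predictor pools.
CANONICAL_TERMS: tuple[str, ...] = (
    "backbone_vdw_clash",
    "cis_bond",
    "disulfide",
    "electrostatic",
    "electrostatic_kon",
    "entropy_mainchain",
    "entropy_sidechain",
    "helix_dipole",
    "hbond_backbone",
    "hbond_sidechain",
    "ionization",
    "solvation_hydrophobic",
    "solvation_polar",
    "torsional_clash",
    "vdw",
    "vdw_clash",
    "total",
)

CONSTITUENT_TERMS: tuple[str, ...] = tuple(t for t in CANONICAL_TERMS if t != "total")

#: Frozen mapping from FoldX 4 "Dif" fxout column headers (normalised to
#: lower case) to canonical term names.  Extra FoldX 4 columns (water bridge,
#: partial covalent bonds, loop entropies, complex entropy) are parsed but
#: kept under their raw headers and excluded from the canonical 17.
FOLDX4_COLUMN_MAP: dict[str, str] = {
    "total energy": "total",
    "backbone hbond": "hbond_backbone",
    "sidechain hbond": "hbond_sidechain",
    "van der waals": "vdw",
    "electrostatics": "electrostatic",
    "solvation polar": "solvation_polar",
    "solvation hydrophobic": "solvation_hydrophobic",
    "van der waals clashes": "vdw_clash",
    "entropy sidechain": "entropy_sidechain",
    "entropy mainchain": "entropy_mainchain",
    "cis_bond": "cis_bond",
    "torsional clash": "torsional_clash",
    "backbone clash": "backbone_vdw_clash",
    "helix dipole": "helix_dipole",
    "disulfide": "disulfide",
    "electrostatic kon": "electrostatic_kon",
    "energy ionisation": "ionization",
}

SS_LEVELS: tuple[str, ...] = ("B", "E", "G", "H", "I", "S", "T", "none")

BIOCHEM_COLUMNS: tuple[str, ...] = (
    "is_proline",
    "volume_change",
    "hydrophobicity_change",
    "charge_change",
    "ss_class",
    "rsa",
)

KEY_COLUMNS: tuple[str, ...] = ("system_id", "chain", "position", "wt_aa", "mut_aa")


@dataclass(frozen=True)
class MutationRecord:
    """One point mutation in one protein system.

    ``ddg_exp`` is the experimentally measured ΔΔG (kcal/mol); it may be
    ``None`` for prediction-only use.  Positions follow the author (PDB/DSSP)
    numbering; an insertion code, if any, is concatenated onto ``position``
    upstream and the integer part kept here.
    """

    system_id: str
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    ddg_exp: float | None = None

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_CODES:
            raise ValueError(f"unknown wild-type residue code {self.wt_aa!r}")
        if self.mut_aa not in AA_CODES:
            raise ValueError(f"unknown mutant residue code {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"wt and mutant residues are identical ({self.wt_aa}) at "
                f"{self.system_id}/{self.chain}{self.position}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ddg_exp is not None and not math.isfinite(self.ddg_exp):
            raise ValueError("ddg_exp must be finite when present")

    @property
    def key(self) -> tuple:
        return (self.system_id, self.chain, self.position, self.wt_aa, self.mut_aa)


class EnergyTerms(dict):
    """FoldX energy decomposition for one structure (kcal/mol per term).

    A dict keyed by canonical term name.  All 17 canonical keys must be
    present and finite; extra (non-canonical) keys are allowed and ignored
    by downstream pools.
    """

    def __init__(self, values: dict[str, float]):
        super().__init__(values)
        missing = [t for t in CANONICAL_TERMS if t not in self]
        if missing:
            raise ValueError(f"missing canonical term(s): {', '.join(missing)}")
        for term in CANONICAL_TERMS:
            v = self[term]
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"non-finite value for term {term!r}: {v!r}")


@dataclass
class SnapshotSeries:
    """Per-snapshot FoldX energies for one mutation over an MD trajectory."""

    mutation: MutationRecord
    snapshots: list[EnergyTerms]


@dataclass
class AggregatedEnergies:
    """Snapshot means and SDs per term; ``ddg_foldx`` is the total's mean."""

    mean: EnergyTerms
    sd: EnergyTerms | None
    n_snapshots: int

    @property
    def ddg_foldx(self) -> float:
        return self.mean["total"]


@dataclass(frozen=True)
class DsspResidue:
    """One residue row of a DSSP file (absolute accessibility in Å²)."""

    chain: str
    position: int
    icode: str
    aa: str
    ss_class: str
    acc: float


def read_foldx_dif(path: str | Path, dialect: str = "foldx4") -> list[tuple[str, EnergyTerms]]:
    """Parse a FoldX "Dif" fxout table into (structure tag, EnergyTerms) pairs.

    Banner/comment lines are skipped until the header row, recognised by its
    first tab-separated field being ``Pdb``.  Headers are mapped to canonical
    term names through :data:`FOLDX4_COLUMN_MAP`; unmapped columns are kept
    under their raw (lower-cased) names.
    """
    if dialect != "foldx4":
        raise ValueError(f"unknown fxout dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.split("\t")[0].strip() == "Pdb":
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no header row (first field 'Pdb') found")
    raw_headers = [h.strip() for h in lines[header_idx].split("\t")]
    mapped = [FOLDX4_COLUMN_MAP.get(h.lower(), h.lower()) for h in raw_headers[1:]]
    missing = [t for t in CANONICAL_TERMS if t not in mapped]
    if missing:
        raise ValueError(
            f"{path}: missing canonical term column(s): {', '.join(missing)}"
        )
    records: list[tuple[str, EnergyTerms]] = []
    for line in lines[header_idx + 1 :]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(raw_headers):
            raise ValueError(f"{path}: row has {len(fields)} fields, expected {len(raw_headers)}")
        values = {name: float(v) for name, v in zip(mapped, fields[1:])}
        records.append((fields[0].strip(), EnergyTerms(values)))
    return records


def aggregate_snapshots(
    series: SnapshotSeries, sd_kind: str = "sample", require_sd: bool = True
) -> AggregatedEnergies:
    """Average per-term energies over MD snapshots.

    The per-term mean is the final ΔΔG of that term; the per-term SD (sample
    SD by default, divisor n−1) quantifies conformational variability across
    the trajectory and feeds the SD predictor pool.
    """
    n = len(series.snapshots)
    if n == 0:
        raise ValueError("cannot aggregate an empty snapshot series")
    if sd_kind not in ("sample", "population"):
        raise ValueError(f"unknown sd_kind {sd_kind!r}")
    if n == 1 and require_sd:
        raise ValueError("SD requested but series has a single snapshot")
    keys = list(series.snapshots[0])
    arr = np.array([[snap[k] for k in keys] for snap in series.snapshots], dtype=float)
    mean = EnergyTerms(dict(zip(keys, arr.mean(axis=0))))
    sd = None
    if n >= 2:
        ddof = 1 if sd_kind == "sample" else 0
        sds = arr.std(axis=0, ddof=ddof)
        sds[np.ptp(arr, axis=0) == 0.0] = 0.0  # sd is exactly 0 iff all equal
        sd = EnergyTerms(dict(zip(keys, sds)))
    return AggregatedEnergies(mean=mean, sd=sd, n_snapshots=n)


def read_dssp(path: str | Path) -> list[DsspResidue]:
    """Read classic DSSP text output into per-residue records.

    Parsing is delegated to Biopython's DSSP-file reader.  Blank structure
    codes become ``"none"``; chain-break rows (``!``) are skipped by the
    underlying parser.
    """
    dssp_dict, keys = make_dssp_dict(str(path))
    out = []
    for chainid, res_id in keys:
        aa, ss, acc = dssp_dict[(chainid, res_id)][:3]
        ss_class = "none" if ss in (" ", "-", "") else ss
        _, resseq, icode = res_id
        out.append(
            DsspResidue(
                chain=chainid,
                position=resseq,
                icode=icode.strip(),
                aa=aa,
                ss_class=ss_class,
                acc=float(acc),
            )
        )
    return out


def tidy_columns(
    with_biochem: bool = True, with_single: bool = False, with_sd: bool = True
) -> list[str]:
    """Column manifest of the tidy per-mutation table, in canonical order."""
    cols = list(KEY_COLUMNS) + ["ddg_exp"]
    cols += [f"{t}_mean" for t in CANONICAL_TERMS]
    if with_sd:
        cols += [f"{t}_sd" for t in CANONICAL_TERMS]
    if with_single:
        cols += [f"{t}_single" for t in CANONICAL_TERMS]
    if with_biochem:
        cols += list(BIOCHEM_COLUMNS)
    return cols


def _validate_tidy(df: pd.DataFrame, strict: bool, require_ddg_exp: bool) -> pd.DataFrame:
    required = list(KEY_COLUMNS) + ["ddg_exp"] + [f"{t}_mean" for t in CANONICAL_TERMS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"tidy table missing required column(s): {', '.join(missing)}")
    known = set(
        tidy_columns(with_biochem=True, with_single=True, with_sd=True)
    )
    unknown = [c for c in df.columns if c not in known]
    if unknown and strict:
        raise ValueError(f"unknown column(s) in strict mode: {', '.join(unknown)}")

    numeric = [c for c in df.columns if c.endswith(("_mean", "_sd", "_single"))]
    for c in numeric + ["ddg_exp"]:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.isna() & df[c].notna()
            if bad.any():
                raise ValueError(f"non-numeric values in column {c!r}")
            df[c] = vals
    if require_ddg_exp and df["ddg_exp"].isna().any():
        raise ValueError("missing ddg_exp values (use require_ddg_exp=False for prediction mode)")

    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].to_records(index=False)
        raise ValueError(f"duplicate mutation key(s): {list(keys)[:5]}")

    # row-level invariants mirror MutationRecord's
    for _, row in df.iterrows():
        MutationRecord(
            system_id=str(row["system_id"]),
            chain=str(row["chain"]),
            position=int(row["position"]),
            wt_aa=str(row["wt_aa"]),
            mut_aa=str(row["mut_aa"]),
            ddg_exp=None if pd.isna(row["ddg_exp"]) else float(row["ddg_exp"]),
        )
    return df


def read_tidy_table(
    path: str | Path,
    strict: bool = True,
    require_ddg_exp: bool = True,
) -> pd.DataFrame:
    """Read and validate a tidy per-mutation table (CSV, or TSV by extension).

    Rows with missing ``ddg_exp`` are admitted only with
    ``require_ddg_exp=False`` (prediction mode).  Duplicate mutation keys are
    an error — one record per mutation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return _validate_tidy(df, strict=strict, require_ddg_exp=require_ddg_exp)


def write_tidy_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy table; round-trips through :func:`read_tidy_table`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def records_from_tidy(
    df: pd.DataFrame, n_snapshots: int = 100
) -> list[tuple[MutationRecord, AggregatedEnergies, dict]]:
    """Explode a tidy table into typed (mutation, energies, extras) tuples.

    The tidy schema does not store the snapshot count, so ``n_snapshots``
    (default 100, the usual trajectory sampling) is attached to every record.
    """
    out = []
    has_sd = all(f"{t}_sd" in df.columns for t in CANONICAL_TERMS)
    for _, row in df.iterrows():
        rec = MutationRecord(
            system_id=str(row["system_id"]),
            chain=str(row["chain"]),
            position=int(row["position"]),
            wt_aa=str(row["wt_aa"]),
            mut_aa=str(row["mut_aa"]),
            ddg_exp=None if pd.isna(row["ddg_exp"]) else float(row["ddg_exp"]),
        )
        mean = EnergyTerms({t: float(row[f"{t}_mean"]) for t in CANONICAL_TERMS})
        sd = (
            EnergyTerms({t: float(row[f"{t}_sd"]) for t in CANONICAL_TERMS})
            if has_sd
            else None
        )
        extras = {
            c: row[c]
            for c in BIOCHEM_COLUMNS
            if c in df.columns
        }
        out.append((rec, AggregatedEnergies(mean=mean, sd=sd, n_snapshots=n_snapshots), extras))
    return out
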