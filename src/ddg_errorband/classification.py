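"""Stability classification with and without error bounds.

A mutation is *stabilizing* if ΔΔG < −0.5 kcal/mol, *destabilizing* if
ΔΔG > 0.5 kcal/mol, and *neutral* in between (boundaries inclusive).  With a
per-mutation error bound B, the interval [ΔΔG_FoldX − B, ΔΔG_FoldX + B] may
overlap several classes; a prediction is only *unambiguous* when exactly one
class is overlapped.  Binned relative-frequency summaries along ΔΔG_FoldX
and a with-replacement resampling scheme that flattens the ΔΔG_exp
distribution support the accompanying classification-accuracy analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "StabilityClass",
    "BoundedClass",
    "BinSpec",
    "classify_exp",
    "classify_with_bounds",
    "bin_frequencies",
    "resample_uniform_bins",
    "default_bin_edges",
]

CLASS_LABELS = ("stabilizing", "neutral", "destabilizing")

#: Neutral band half-width (kcal/mol); neutral owns the ±0.5 boundaries.
THRESHOLD = 0.5


@dataclass(frozen=True)
class StabilityClass:
    label: str

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class BoundedClass:
    """Classification of the interval ΔΔG_FoldX ± B against the class bands."""

    interval: tuple[float, float]
    labels_overlapped: tuple[str, ...]

    @property
    def unambiguous(self) -> bool:
        return len(self.labels_overlapped) == 1

    @property
    def outcome(self) -> str:
        return self.labels_overlapped[0] if self.unambiguous else "ambiguous"


@dataclass(frozen=True)
class BinSpec:
    """Left-open right-closed bins along a ΔΔG axis, with open outer bins."""

    axis: str
    edges: tuple[float, ...]
    open_outer: bool = True

    def __post_init__(self):
        if self.axis not in ("ddg_exp", "ddg_foldx"):
            raise ValueError(f"unknown bin axis {self.axis!r}")
        e = np.asarray(self.edges, dtype=float)
        if e.size < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")

    def assign(self, values) -> np.ndarray:
        """Bin index per value; −1 marks out-of-range when outer bins closed."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, v, side="left")  # (a, b] bins
        if self.open_outer:
            return idx
        out = idx - 1
        out[(v <= self.edges[0]) | (v > self.edges[-1])] = -1
        return out

    def labels(self) -> list[str]:
        e = list(self.edges)
        inner = [f"({lo:g}, {hi:g}]" for lo, hi in zip(e[:-1], e[1:])]
        if self.open_outer:
            return [f"<= {e[0]:g}"] + inner + [f"> {e[-1]:g}"]
        return inner

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1 if self.open_outer else len(self.edges) - 1


def default_bin_edges(values, width: float = 1.0) -> tuple[float, ...]:
    """Bin edges of the given width aligned to the ±0.5 class boundaries."""
    v = np.asarray(values, dtype=float)
    lo = math.floor((v.min() + THRESHOLD) / width) * width - THRESHOLD
    hi = math.ceil((v.max() + THRESHOLD) / width) * width - THRESHOLD
    edges = np.arange(lo, hi + width / 2, width)
    return tuple(float(x) for x in edges)


def classify_exp(ddg: float) -> StabilityClass:
    """Point classification of a ΔΔG value by the ±0.5 kcal/mol thresholds."""
    if not math.isfinite(ddg):
        raise ValueError("non-finite ΔΔG")
    if ddg < -THRESHOLD:
        return StabilityClass("stabilizing")
    if ddg > THRESHOLD:
        return StabilityClass("destabilizing")
    return StabilityClass("neutral")


def classify_with_bounds(ddg_foldx: float, bound: float) -> BoundedClass:
    """Classify the closed interval [ΔΔG_FoldX − B, ΔΔG_FoldX + B].

    Overlap is computed against stabilizing (−∞, −0.5), neutral [−0.5, 0.5]
    and destabilizing (0.5, ∞); with B = 0 this degenerates to the point
    classification of ΔΔG_FoldX.
    """
    if not math.isfinite(ddg_foldx):
        raise ValueError("non-finite ΔΔG")
    if not (math.isfinite(bound) and bound >= 0):
        raise ValueError(f"bound must be finite and >= 0, got {bound}")
    lo, hi = ddg_foldx - bound, ddg_foldx + bound
    labels = []
    if lo < -THRESHOLD:
        labels.append("stabilizing")
    if lo <= THRESHOLD and hi >= -THRESHOLD:
        labels.append("neutral")
    if hi > THRESHOLD:
        labels.append("destabilizing")
    return BoundedClass(interval=(lo, hi), labels_overlapped=tuple(labels))


def bin_frequencies(
    data: pd.DataFrame,
    bins: BinSpec,
    classifier: str = "exp_truth_vs_foldx",
    bound_col: str = "bound",
) -> pd.DataFrame:
    """Per-bin relative class frequencies along a ΔΔG axis.

    ``exp_truth_vs_foldx`` bins the data along ``bins.axis`` (usually
    ΔΔG_FoldX) and tabulates the true class of ΔΔG_exp per bin; ``bounded``
    tabulates the interval-classification outcome (one of the three classes
    or ``ambiguous``) using per-row bounds from ``bound_col``.  Fractions sum
    to 1 in every nonempty bin; empty bins are reported with n = 0 and zero
    fractions, never NaN.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    axis_vals = data[bins.axis].to_numpy(dtype=float)
    idx = bins.assign(axis_vals)
    if classifier == "exp_truth_vs_foldx":
        outcome = np.array([classify_exp(v).label for v in data["ddg_exp"]])
        categories = list(CLASS_LABELS)
    elif classifier == "bounded":
        outcome = np.array(
            [
                classify_with_bounds(v, b).outcome
                for v, b in zip(data["ddg_foldx"], data[bound_col])
            ]
        )
        categories = list(CLASS_LABELS) + ["ambiguous"]
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    labels = bins.labels()
    rows = []
    for b in range(bins.n_bins):
        mask = idx == b
        n = int(mask.sum())
        row = {"bin": labels[b], "n": n}
        for cat in categories:
            row[cat] = float(np.mean(outcome[mask] == cat)) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def resample_uniform_bins(
    data: pd.DataFrame,
    bins: BinSpec,
    n_per_bin: int = 1000,
    seed: int | None = None,
    skip_empty: bool = True,
) -> pd.DataFrame:
    """Resample ``n_per_bin`` rows with replacement from each nonempty bin.

    Flattens the distribution along the binning axis (usually ΔΔG_exp),
    simulating mutations drawn uniformly across stability effects.  One
    master seed spawns an independent child stream per bin, so results are
    reproducible without cross-bin coupling.  Output size is
    ``n_per_bin × (number of nonempty bins)``.
    """
    if bins.axis != "ddg_exp":
        raise ValueError("resampling is defined over ddg_exp bins")
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    if len(data) == 0:
        raise ValueError("empty dataset")
    idx = bins.assign(data[bins.axis].to_numpy(dtype=float))
    children = np.random.SeedSequence(seed).spawn(bins.n_bins)
    pieces = []
    for b in range(bins.n_bins):
        members = np.flatnonzero(idx == b)
        if members.size == 0:
            if not skip_empty:
                raise ValueError(f"bin {bins.labels()[b]} is empty")
            warnings.warn(f"skipping empty bin {bins.labels()[b]}")
            continue
        rng = np.random.default_rng(children[b])
        take = rng.choice(members, size=n_per_bin, replace=True)
        pieces.append(data.iloc[take])
    return pd.concat(pieces, ignore_index=True)
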