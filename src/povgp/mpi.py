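"""Alkire-Foster multidimensional deprivation statistics.

A household's deprivation profile over D = 10 binary indicators in three
dimensions (education, health, standard of living) is collapsed into a
weighted score c_i = sum_d w_d * depvec_{i,d}; the household is poor when
c_i exceeds the cutoff theta (strictly; the default theta = 0.3).  Per
commune j,

    H_j   = (1 / N_j) * #{i : c_i > theta}          (headcount ratio)
    A_j   = mean of c_i over the poor households     (intensity)
    MPI_j = H_j * A_j

Education and health indicators carry weight 1/6 each, the six standard of
living indicators 1/18 each, so each dimension carries exactly 1/3.
Weights are held as exact rationals and converted to floats only when the
scores are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorScheme",
    "DEFAULT_SCHEME",
    "deprivation_vectors",
    "commune_stats",
    "theta_sweep",
]

DEFAULT_THETA = 0.3

_EDUCATION = ["years_of_schooling", "school_attendance"]
_HEALTH = ["child_mortality", "nutrition"]
_LIVING = ["cooking_fuel", "sanitation", "water", "electricity", "floor", "assets"]


@dataclass(frozen=True)
class IndicatorScheme:
    """Indicator names, dimensions and exact rational weights."""

    indicators: tuple[str, ...] = tuple(_EDUCATION + _HEALTH + _LIVING)
    weights: tuple[Fraction, ...] = tuple(
        [Fraction(1, 6)] * 4 + [Fraction(1, 18)] * 6
    )
    dimensions: tuple[str, ...] = tuple(
        ["education"] * 2 + ["health"] * 2 + ["standard_of_living"] * 6
    )

    def __post_init__(self) -> None:
        if len(self.indicators) != len(self.weights) or len(self.indicators) != len(
            self.dimensions
        ):
            raise ValueError("indicators, weights and dimensions must align")
        if sum(self.weights, Fraction(0)) != 1:
            raise ValueError("indicator weights must sum to 1 exactly")

    @property
    def weight_array(self) -> np.ndarray:
        return np.array([float(w) for w in self.weights])

    @property
    def integer_weights(self) -> tuple[np.ndarray, int]:
        """Weights as integers over their least common denominator.

        Scoring with integer numerators keeps the weighted score a single
        correctly rounded rational, so strict comparisons against the
        poverty cutoff are exact (a household at c = 1/2 must not drift to
        0.5000...01 through float accumulation).
        """
        import math as _math

        denom = 1
        for w in self.weights:
            denom = denom * w.denominator // _math.gcd(denom, w.denominator)
        return np.array([int(w * denom) for w in self.weights]), denom

    def dimension_weight(self, dimension: str) -> Fraction:
        return sum(
            (w for w, d in zip(self.weights, self.dimensions) if d == dimension),
            Fraction(0),
        )


DEFAULT_SCHEME = IndicatorScheme()


def deprivation_vectors(
    households: pd.DataFrame,
    scheme: IndicatorScheme = DEFAULT_SCHEME,
    theta: float = DEFAULT_THETA,
    cutoffs: dict[str, Callable] | None = None,
    min_observed_weight: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Household deprivation vectors and weighted scores.

    ``households`` carries one row per household with the 10 indicator
    columns either binary (1 = deprived) or, when ``cutoffs`` supplies a
    callable per indicator, raw achievements converted to deprivation via
    achievement <= cutoff.

    Missing indicator values: a household's score is computed over the
    observed indicators with the weights renormalised, but only when at
    least ``min_observed_weight`` of the total weight is observed;
    households below that are dropped.
    """
    missing_cols = [c for c in scheme.indicators if c not in households.columns]
    if missing_cols:
        raise ValueError(f"missing indicator columns: {missing_cols}")
    dep = households[list(scheme.indicators)].copy()
    if cutoffs:
        for name, rule in cutoffs.items():
            dep[name] = rule(households[name]).astype(float)
    vals = dep.to_numpy(dtype=float)
    bad = ~np.isin(vals[~np.isnan(vals)], (0.0, 1.0))
    if bad.any():
        raise ValueError("deprivation indicators must be binary (0/1) or missing")

    wi, denom = scheme.integer_weights
    observed = ~np.isnan(vals)
    obs_int = (observed * wi).sum(axis=1)
    keep = obs_int >= (min_observed_weight * denom) - 1e-9
    num = np.nansum(vals * wi, axis=1)  # exact small-integer arithmetic
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / obs_int

    out = households[["household_id", "commune_id"]].copy()
    for j, name in enumerate(scheme.indicators):
        out[name] = vals[:, j]
    out["c"] = c
    out["is_poor"] = c > theta
    return out.loc[keep].reset_index(drop=True)


def commune_stats(
    scores: pd.DataFrame,
    theta: float = DEFAULT_THETA,
    scheme: IndicatorScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Commune-level H, A, MPI and per-indicator deprivation proportions.

    A commune with no poor households has H = 0, A missing and MPI = 0.
    Per-indicator proportions divide by the number of households observed
    on that indicator.
    """
    rows = []
    for cid, g in scores.groupby("commune_id", sort=True):
        c = g["c"].to_numpy()
        poor = c > theta
        n = len(g)
        H = float(poor.sum()) / n
        A = float(c[poor].mean()) if poor.any() else np.nan
        mpi = H * A if poor.any() else 0.0
        row = {"commune_id": cid, "N": n, "H": H, "A": A, "MPI": mpi}
        for name in scheme.indicators:
            col = g[name].to_numpy(dtype=float)
            obs = ~np.isnan(col)
            row[f"prop_{name}"] = float(np.nansum(col) / obs.sum()) if obs.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def theta_sweep(
    scores: pd.DataFrame,
    theta_grid: np.ndarray | list[float] | None = None,
    scheme: IndicatorScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Commune statistics across a grid of poverty cutoffs.

    The default grid runs from 0.2 to 0.75 in steps of 0.05.  H is
    non-increasing in theta for every commune.
    """
    if theta_grid is None:
        theta_grid = np.round(np.arange(0.20, 0.7501, 0.05), 10)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if np.any(theta_grid <= 0.0) or np.any(theta_grid >= 1.0):
        raise ValueError("theta grid must lie in (0, 1)")
    frames = []
    for th in theta_grid:
        stats = commune_stats(scores, theta=float(th), scheme=scheme)
        stats.insert(0, "theta", float(th))
        frames.append(stats)
    return pd.concat(frames, ignore_index=True)
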