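"""Validation harness: spatial and standard cross-validation, metrics.

The spatial CV protocol guards against optimism from spatial
autocorrelation: each repeat samples a region, then a commune inside it,
and takes as the training set all communes whose centroids lie within a
radius d of that commune -- d starts at 100 km and grows by 50 km until the
training set reaches a floor (225 communes on the 552-commune map,
otherwise 40% rounded up).  The evaluation set is the geographically
separated complement.  Metrics (Pearson r, Spearman rho, RMSE) are pooled
over each repeat's evaluation set and summarised as mean (SD) over repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from povgp import fusion
from povgp.gp import FitConfig, TrainingSet, fit, predict
from povgp.synthetic import CommuneMap

__all__ = [
    "SpatialCVConfig",
    "CVResult",
    "spatial_cv_split",
    "standard_cv_split",
    "make_spatial_splits",
    "run_cv",
    "metrics",
    "linear_baseline",
]


@dataclass(frozen=True)
class SpatialCVConfig:
    """Spatial CV settings: radius schedule, training floor, repeats."""

    d_init: float = 100.0
    d_step: float = 50.0
    min_train_size: int | None = None  # None -> 225 at n=552, else ceil(0.4 n)
    n_repeats: int = 250
    seed: int = 0
    max_seed_retries: int = 100

    def resolve_floor(self, n_communes: int) -> int:
        if self.min_train_size is not None:
            floor = self.min_train_size
        elif n_communes == 552:
            floor = 225
        else:
            floor = math.ceil(0.40 * n_communes)
        if not 0 < floor < n_communes:
            raise ValueError("training floor must lie strictly between 0 and n")
        return floor

    def __post_init__(self) -> None:
        if self.d_init <= 0 or self.d_step <= 0:
            raise ValueError("d_init and d_step must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


@dataclass
class CVResult:
    """Per-repeat metrics and coverage bookkeeping."""

    per_repeat: pd.DataFrame  # columns: repeat, pipeline, pearson, spearman, rmse, n_eval
    eval_counts: pd.Series  # commune -> times evaluated
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.per_repeat.groupby("pipeline")[["pearson", "spearman", "rmse"]]
        out = g.mean().add_suffix("_mean").join(g.std(ddof=1).add_suffix("_sd"))
        out["n_repeats"] = self.per_repeat.groupby("pipeline").size()
        return out


def spatial_cv_split(
    cmap: CommuneMap, config: SpatialCVConfig, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """One geographically blocked train/eval split.

    Samples a region uniformly, then a commune within it; the training set
    is every commune within distance d of that seed commune, with d grown
    from d_init in steps of d_step until the training floor is met.  If the
    radius growth swallows the whole map the seed is resampled, up to
    ``max_seed_retries`` times.
    """
    n = cmap.n
    floor = config.resolve_floor(n)
    regions = sorted(set(cmap.region_ids))
    region_arr = np.array(cmap.region_ids)
    ids = np.array(cmap.commune_ids)
    for _ in range(config.max_seed_retries):
        region = regions[rng.integers(len(regions))]
        members = np.flatnonzero(region_arr == region)
        seed_idx = int(members[rng.integers(len(members))])
        dist = np.sqrt(((cmap.centroids - cmap.centroids[seed_idx]) ** 2).sum(axis=1))
        d = config.d_init
        while True:
            train_mask = dist <= d
            if train_mask.sum() >= floor:
                break
            d += config.d_step
        if train_mask.all():
            continue  # no evaluation set left; resample the seed commune
        return list(ids[train_mask]), list(ids[~train_mask])
    raise RuntimeError(
        "could not produce a split with a nonempty evaluation set; "
        "the training floor may be too close to the map size"
    )


def standard_cv_split(
    commune_ids, k: int = 10, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Random k-fold partition of the communes into near-equal folds."""
    ids = np.asarray(commune_ids)
    if len(ids) < k:
        raise ValueError("need at least k communes for k folds")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(len(ids))
    return [ids[fold] for fold in np.array_split(perm, k)]


def make_spatial_splits(
    cmap: CommuneMap, config: SpatialCVConfig
) -> list[tuple[list[str], list[str]]]:
    """The full seeded sequence of spatial splits for ``n_repeats``."""
    rng = np.random.default_rng(config.seed)
    return [spatial_cv_split(cmap, config, rng) for _ in range(config.n_repeats)]


def metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(Pearson r, Spearman rho, RMSE); correlations are NaN when either
    input has zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("inputs must have equal length >= 3")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_true) == 0.0 or np.std(y_pred) == 0.0:
        return np.nan, np.nan, rmse
    pear = float(sps.pearsonr(y_true, y_pred)[0])
    spear = float(sps.spearmanr(y_true, y_pred)[0])
    return pear, spear, rmse


def _fit_predict_source(
    features: pd.DataFrame,
    targets: pd.Series,
    cmap: CommuneMap,
    train_ids: list[str],
    eval_ids: list[str],
    fit_config: FitConfig,
    source: str,
) -> pd.DataFrame:
    cidx = {cid: i for i, cid in enumerate(cmap.commune_ids)}
    S_all = cmap.centroids
    Xtr = features.loc[train_ids].to_numpy()
    Str = S_all[[cidx[c] for c in train_ids]]
    ytr = targets.loc[train_ids].to_numpy()
    train = TrainingSet.from_raw(Xtr, Str, ytr, list(features.columns))
    model = fit(train, fit_config, source=source)
    Xev = features.loc[eval_ids].to_numpy()
    Sev = S_all[[cidx[c] for c in eval_ids]]
    return predict(model, Xev, Sev, commune_ids=eval_ids)


def run_cv(
    cmap: CommuneMap,
    features_by_source: dict[str, pd.DataFrame],
    targets: pd.Series,
    cv_config: SpatialCVConfig,
    fit_config: FitConfig | None = None,
    mode: str = "spatial",
    splits: list[tuple[list[str], list[str]]] | None = None,
) -> CVResult:
    """Repeated CV of the full pipeline: per-source GP fits plus fusion.

    Per repeat, each source model is refitted on the training communes
    (hyperparameters included, so no information leaks across the split),
    predictions are made on the held-out communes, fused by inverse
    variance, and metrics computed for each single-source pipeline and the
    fused one.  ``mode`` selects the spatial protocol or shuffled k-fold
    splits; precomputed ``splits`` override both (used to share splits with
    baselines).
    """
    fit_config = fit_config or FitConfig()
    source_names = list(features_by_source)
    if splits is None:
        if mode == "spatial":
            splits = make_spatial_splits(cmap, cv_config)
        elif mode == "standard":
            rng = np.random.default_rng(cv_config.seed)
            splits = []
            for _ in range(cv_config.n_repeats):
                folds = standard_cv_split(cmap.commune_ids, k=10, rng=rng)
                for f in folds:
                    ev = list(f)
                    tr = [c for c in cmap.commune_ids if c not in set(ev)]
                    splits.append((tr, ev))
        else:
            raise ValueError("mode must be 'spatial' or 'standard'")

    rows = []
    eval_counts = pd.Series(0, index=pd.Index(cmap.commune_ids, name="commune_id"))
    skipped: list[str] = []
    for rep, (train_ids, eval_ids) in enumerate(splits):
        y_ev = targets.loc[eval_ids].to_numpy()
        if np.std(y_ev) == 0.0:
            skipped.append(f"repeat {rep}: zero-variance evaluation target")
            continue
        eval_counts.loc[eval_ids] += 1
        preds = {}
        for si, name in enumerate(source_names):
            fc = replace(fit_config, seed=fit_config.seed + 1000 * rep + si)
            preds[name] = _fit_predict_source(
                features_by_source[name],
                targets,
                cmap,
                train_ids,
                eval_ids,
                fc,
                name,
            )
            p, s, r = metrics(y_ev, preds[name]["mean"].to_numpy())
            rows.append(
                {
                    "repeat": rep,
                    "pipeline": name,
                    "pearson": p,
                    "spearman": s,
                    "rmse": r,
                    "n_eval": len(eval_ids),
                }
            )
        if len(source_names) == 2:
            fused = fusion.fuse_tables(preds[source_names[0]], preds[source_names[1]])
            fused = fused.set_index("commune_id").loc[eval_ids]
            p, s, r = metrics(y_ev, fused["mean"].to_numpy())
            rows.append(
                {
                    "repeat": rep,
                    "pipeline": "fused",
                    "pearson": p,
                    "spearman": s,
                    "rmse": r,
                    "n_eval": len(eval_ids),
                }
            )
    if (eval_counts == 0).any():
        warnings.warn(
            f"{int((eval_counts == 0).sum())} communes never appeared in an "
            "evaluation set across the repeats",
            RuntimeWarning,
        )
    return CVResult(pd.DataFrame(rows), eval_counts, skipped)


def linear_baseline(
    features: pd.DataFrame,
    targets: pd.Series,
    cmap: CommuneMap,
    cv_config: SpatialCVConfig,
    splits: list[tuple[list[str], list[str]]] | None = None,
) -> CVResult:
    """Four-covariate ordinary-least-squares baseline under the same splits.

    Fits y ~ intercept + X (typically call volume, phone ownership per
    capita, nightlights-analogue and population density) by least squares
    on each training split; rank-deficient designs fall back to the
    pseudoinverse with a warning.
    """
    if splits is None:
        splits = make_spatial_splits(cmap, cv_config)
    rows = []
    eval_counts = pd.Series(0, index=pd.Index(cmap.commune_ids, name="commune_id"))
    for rep, (train_ids, eval_ids) in enumerate(splits):
        Xtr = np.column_stack(
            [np.ones(len(train_ids)), features.loc[train_ids].to_numpy()]
        )
        ytr = targets.loc[train_ids].to_numpy()
        if np.linalg.matrix_rank(Xtr) < Xtr.shape[1]:
            warnings.warn("rank-deficient baseline design; using pseudoinverse", RuntimeWarning)
        coef, *_ = np.linalg.lstsq(Xtr, ytr, rcond=None)
        Xev = np.column_stack(
            [np.ones(len(eval_ids)), features.loc[eval_ids].to_numpy()]
        )
        y_ev = targets.loc[eval_ids].to_numpy()
        if np.std(y_ev) == 0.0:
            continue
        eval_counts.loc[eval_ids] += 1
        p, s, r = metrics(y_ev, Xev @ coef)
        rows.append(
            {
                "repeat": rep,
                "pipeline": "linear_baseline",
                "pearson": p,
                "spearman": s,
                "rmse": r,
                "n_eval": len(eval_ids),
            }
        )
    return CVResult(pd.DataFrame(rows), eval_counts)
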