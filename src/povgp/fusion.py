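"""Inverse-variance fusion of two source-specific GP predictions.

Each commune has two posterior Gaussians, y_c ~ N(m_c, s2_c) from the CDR
model and y_e ~ N(m_e, s2_e) from the environmental model.  The combined
estimate is the two-component mixture with weights proportional to the
inverse predictive variances,

    w_c = (1/s2_c) / (1/s2_c + 1/s2_e),    w_e = 1 - w_c,

whose exact first two moments are

    mean = w_c m_c + w_e m_e
    var  = w_c s2_c + w_e s2_e + w_c w_e (m_c - m_e)^2.

The cross term is the between-source disagreement; it makes the mixture
variance honest when the two sources conflict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FusedPrediction",
    "mixture_weights",
    "combine",
    "fuse_tables",
    "best_source_map",
]

VARIANCE_FLOOR = 1e-12


@dataclass
class FusedPrediction:
    commune_id: object
    w_c: float
    w_e: float
    mean: float
    variance: float
    best_source: str  # "cdr", "env" or "tie"


def mixture_weights(sigma_c2: float, sigma_e2: float) -> tuple[float, float]:
    """Inverse-variance mixture weights (w_c, w_e); they sum to 1 exactly.

    Variances are floored at 1e-12 before inversion; if both fall below the
    floor the weights are equal (with a warning).  Negative variances are
    an error.
    """
    if sigma_c2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be nonnegative")
    if sigma_c2 < VARIANCE_FLOOR and sigma_e2 < VARIANCE_FLOOR:
        warnings.warn("both variances below floor; using equal weights", RuntimeWarning)
        return 0.5, 0.5
    pc = 1.0 / max(sigma_c2, VARIANCE_FLOOR)
    pe = 1.0 / max(sigma_e2, VARIANCE_FLOOR)
    w_c = pc / (pc + pe)
    return w_c, 1.0 - w_c


def combine(pred_c: pd.Series | dict, pred_e: pd.Series | dict) -> FusedPrediction:
    """Fuse one commune's two source predictions into mixture moments."""
    if pred_c["commune_id"] != pred_e["commune_id"]:
        raise ValueError(
            f"commune id mismatch: {pred_c['commune_id']} vs {pred_e['commune_id']}"
        )
    w_c, w_e = mixture_weights(float(pred_c["variance"]), float(pred_e["variance"]))
    mc, me = float(pred_c["mean"]), float(pred_e["mean"])
    s2c, s2e = float(pred_c["variance"]), float(pred_e["variance"])
    mean = w_c * mc + w_e * me
    var = w_c * s2c + w_e * s2e + w_c * w_e * (mc - me) ** 2
    if s2c < s2e:
        best = "cdr"
    elif s2e < s2c:
        best = "env"
    else:
        best = "tie"
    return FusedPrediction(pred_c["commune_id"], w_c, w_e, mean, var, best)


def fuse_tables(preds_c: pd.DataFrame, preds_e: pd.DataFrame) -> pd.DataFrame:
    """Fuse aligned prediction tables (columns commune_id, mean, variance).

    Communes present in only one table pass through unfused with weight 1
    and a provenance flag in ``best_source``.
    """
    c = preds_c.set_index("commune_id")
    e = preds_e.set_index("commune_id")
    rows = []
    for cid in c.index.union(e.index):
        if cid in c.index and cid in e.index:
            f = combine(
                {"commune_id": cid, **c.loc[cid][["mean", "variance"]].to_dict()},
                {"commune_id": cid, **e.loc[cid][["mean", "variance"]].to_dict()},
            )
            rows.append(
                {
                    "commune_id": cid,
                    "w_c": f.w_c,
                    "w_e": f.w_e,
                    "mean": f.mean,
                    "variance": f.variance,
                    "best_source": f.best_source,
                }
            )
        else:
            src, tbl = ("cdr_only", c) if cid in c.index else ("env_only", e)
            rows.append(
                {
                    "commune_id": cid,
                    "w_c": 1.0 if src == "cdr_only" else 0.0,
                    "w_e": 0.0 if src == "cdr_only" else 1.0,
                    "mean": float(tbl.loc[cid, "mean"]),
                    "variance": float(tbl.loc[cid, "variance"]),
                    "best_source": src,
                }
            )
    return pd.DataFrame(rows)


def best_source_map(fused: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-commune label of the lower-variance source, plus label counts."""
    table = fused[["commune_id", "best_source"]].copy()
    counts = table["best_source"].value_counts().to_dict()
    return table, counts
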