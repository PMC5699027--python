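"""Commune-level features from subscriber event logs.

Pipeline: (1) locate every subscriber at a home antenna -- the antenna at
which they place the most nocturnal events (19:00-07:00) each month, with
the yearly home taken as the modal monthly home; (2) drop subscribers who
are not reliably locatable (fewer than six months with at least five
interactions and a defined monthly home); (3) compute monthly behavioural
features per subscriber; (4) average features over the retained subscribers
homed at each antenna; (5) interpolate antenna means to communes with
Voronoi overlap weights w_{c,a} = Area(c ∩ a) / Area(a), renormalised over
the antennas that carry data.

Conventions (documented so tests are unambiguous): the nocturnal window is
the half-open [19:00, 07:00), ties in modal antenna counts break to the
lexicographically smallest antenna id, entropies are in nats, and features
undefined for a subscriber-month (e.g. interevent statistics of a
single-event month) are excluded from the antenna mean rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from povgp.geometry import bounded_voronoi, overlap_weight_table
from povgp.synthetic import AntennaSet, CommuneMap

__all__ = [
    "HomeAssignment",
    "FEATURE_NAMES",
    "assign_home_antennas",
    "filter_subscribers",
    "compute_subscriber_features",
    "antenna_feature_means",
    "voronoi_overlap_weights",
    "commune_feature_vector",
    "aggregate_log_to_communes",
    "estimate_commune_subscribers",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "active_days",
    "n_interactions_call",
    "n_interactions_text",
    "ratio_call_text",
    "interevent_time_mean",
    "interevent_time_sd",
    "n_contacts",
    "entropy_of_contacts",
    "percent_nocturnal",
    "percent_initiated",
    "n_antennas",
    "entropy_of_antennas",
    "radius_of_gyration",
]

MIN_MONTHLY_INTERACTIONS = 5
MIN_QUALIFYING_MONTHS = 6


@dataclass
class HomeAssignment:
    """Per-subscriber home antennas (monthly and yearly modal)."""

    subscriber_id: str
    monthly_home: dict[int, str] = field(default_factory=dict)
    year_home: str | None = None
    retained: bool = False


def _is_nocturnal(ts: pd.Series) -> pd.Series:
    hour = ts.dt.hour
    return (hour >= 19) | (hour < 7)


def assign_home_antennas(log: pd.DataFrame) -> dict[str, HomeAssignment]:
    """Home antenna per subscriber-month from nocturnal event counts.

    The monthly home is the antenna with the most events in [19:00, 07:00)
    that month (daytime events are ignored); the yearly home is the modal
    monthly home.  All ties break to the smallest antenna id.  Subscribers
    with no nocturnal events in any month get no home and are marked
    not-retained.
    """
    assignments = {
        sid: HomeAssignment(sid) for sid in log["subscriber_id"].unique()
    }
    if log.empty:
        return assignments
    ts = pd.to_datetime(log["timestamp"])
    noct = log.loc[_is_nocturnal(ts).to_numpy()].copy()
    noct["month"] = pd.to_datetime(noct["timestamp"]).dt.month
    counts = (
        noct.groupby(["subscriber_id", "month", "antenna_id"])
        .size()
        .rename("n")
        .reset_index()
    )
    # max count per subscriber-month, ties -> smallest antenna_id
    counts = counts.sort_values(
        ["subscriber_id", "month", "n", "antenna_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = counts.drop_duplicates(["subscriber_id", "month"], keep="first")
    for row in top.itertuples(index=False):
        assignments[row.subscriber_id].monthly_home[int(row.month)] = row.antenna_id
    for a in assignments.values():
        if a.monthly_home:
            homes = pd.Series(list(a.monthly_home.values()))
            vc = homes.value_counts()
            best = vc[vc == vc.max()].index.min()
            a.year_home = best
    return assignments


def filter_subscribers(
    log: pd.DataFrame,
    assignments: dict[str, HomeAssignment],
    min_monthly: int = MIN_MONTHLY_INTERACTIONS,
    min_months: int = MIN_QUALIFYING_MONTHS,
) -> set[str]:
    """Retain subscribers locatable for at least half of the year.

    A month qualifies when the subscriber has >= ``min_monthly``
    interactions and a defined monthly home; retention requires
    >= ``min_months`` qualifying months.  Updates the ``retained`` flag on
    the assignments and returns the retained subscriber ids.
    """
    retained: set[str] = set()
    if not log.empty:
        month = pd.to_datetime(log["timestamp"]).dt.month
        monthly_n = (
            log.assign(month=month)
            .groupby(["subscriber_id", "month"])
            .size()
            .rename("n")
        )
        for sid, a in assignments.items():
            if sid not in monthly_n.index.get_level_values(0):
                continue
            n_by_month = monthly_n.loc[sid]
            qualifying = sum(
                1
                for m, n in n_by_month.items()
                if n >= min_monthly and int(m) in a.monthly_home
            )
            if qualifying >= min_months:
                retained.add(sid)
    for a in assignments.values():
        a.retained = a.subscriber_id in retained and a.year_home is not None
    return {sid for sid in retained if assignments[sid].retained}


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in nats of a count vector."""
    counts = counts[counts > 0]
    if len(counts) == 0:
        return np.nan
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def compute_subscriber_features(
    log: pd.DataFrame,
    assignments: dict[str, HomeAssignment],
    month: int,
    antennas: AntennaSet | None = None,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Monthly behavioural features per subscriber.

    Radius of gyration requires antenna coordinates; when ``antennas`` is
    omitted the spatial features are emitted as missing.  Undefined
    statistics (interevent times of a single-event month, call/text ratio
    with no texts) are missing values, never zeros.
    """
    if not 1 <= month <= 12:
        raise ValueError("month must lie in 1..12")
    ts = pd.to_datetime(log["timestamp"])
    sub = log.loc[(ts.dt.month == month).to_numpy()].copy()
    sub["timestamp"] = pd.to_datetime(sub["timestamp"])
    if retained_only:
        keep = {s for s, a in assignments.items() if a.retained}
        sub = sub[sub["subscriber_id"].isin(keep)]

    pos = None
    if antennas is not None:
        pos = {aid: antennas.positions[j] for j, aid in enumerate(antennas.antenna_ids)}

    rows = []
    for sid, g in sub.groupby("subscriber_id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        n_call = int((g["kind"] == "call").sum())
        n_text = int((g["kind"] == "text").sum())
        n_ev = len(g)
        gaps = g["timestamp"].diff().dt.total_seconds().dropna().to_numpy()
        peer_counts = g["peer_id"].value_counts().to_numpy()
        ant_counts = g["antenna_id"].value_counts()
        rog = np.nan
        if pos is not None and len(ant_counts) > 0:
            pts = np.array([pos[a] for a in ant_counts.index])
            w = ant_counts.to_numpy().astype(float)
            centre = (pts * w[:, None]).sum(axis=0) / w.sum()
            rog = float(
                np.sqrt((w * ((pts - centre) ** 2).sum(axis=1)).sum() / w.sum())
            )
        rows.append(
            {
                "subscriber_id": sid,
                "month": month,
                "active_days": int(g["timestamp"].dt.normalize().nunique()),
                "n_interactions_call": n_call,
                "n_interactions_text": n_text,
                "ratio_call_text": (n_call / n_text) if n_text > 0 else np.nan,
                "interevent_time_mean": float(gaps.mean()) if len(gaps) >= 1 else np.nan,
                "interevent_time_sd": float(gaps.std(ddof=1)) if len(gaps) >= 2 else np.nan,
                "n_contacts": int(g["peer_id"].nunique()),
                "entropy_of_contacts": _entropy(peer_counts),
                "percent_nocturnal": float(_is_nocturnal(g["timestamp"]).mean()),
                "percent_initiated": float((g["direction"] == "out").mean()),
                "n_antennas": int(len(ant_counts)),
                "entropy_of_antennas": _entropy(ant_counts.to_numpy()),
                "radius_of_gyration": rog,
            }
        )
    return pd.DataFrame(rows, columns=["subscriber_id", "month"] + FEATURE_NAMES)


def antenna_feature_means(
    features: pd.DataFrame, assignments: dict[str, HomeAssignment]
) -> pd.DataFrame:
    """Average feature values over retained subscribers homed at each antenna.

    Missing subscriber values are excluded from the mean of that feature.
    Returns a DataFrame indexed by antenna_id with columns
    ``<feature>__m<month>``; antennas with no retained subscribers are
    absent.
    """
    feats = features.copy()
    home = {
        sid: a.year_home for sid, a in assignments.items() if a.retained and a.year_home
    }
    feats["antenna_id"] = feats["subscriber_id"].map(home)
    feats = feats.dropna(subset=["antenna_id"])
    value_cols = [c for c in feats.columns if c in FEATURE_NAMES]
    means = feats.groupby(["antenna_id", "month"])[value_cols].mean()
    wide = means.unstack("month")
    wide.columns = [f"{feat}__m{int(m)}" for feat, m in wide.columns]
    return wide.sort_index()


def voronoi_overlap_weights(cmap: CommuneMap, antennas: AntennaSet) -> pd.DataFrame:
    """Overlap weights w_{c,a} = Area(c ∩ a) / Area(a).

    Antenna cells come from the Voronoi tessellation of the antenna sites
    clipped to the map extent.  Zero-area intersections are omitted;
    degenerate antenna cells are skipped with a warning.
    """
    cells = bounded_voronoi(antennas.positions, cmap.extent_km)
    source_polys = {}
    for aid, cell in zip(antennas.antenna_ids, cells):
        if cell.area <= 0.0:
            logger.warning("degenerate Voronoi cell for antenna %s; skipped", aid)
            continue
        source_polys[aid] = cell
    target_polys = dict(zip(cmap.commune_ids, cmap.polygons))
    rows = overlap_weight_table(target_polys, source_polys)
    return pd.DataFrame(rows, columns=["commune_id", "antenna_id", "weight"])


def commune_feature_vector(
    weights: pd.DataFrame, antenna_means: pd.DataFrame
) -> pd.DataFrame:
    """Overlap-weighted average of antenna means per commune.

    For each feature the weights are renormalised over the antennas that
    both intersect the commune and carry a value for that feature; communes
    with no such antenna get a missing value (reported via the coverage
    log).
    """
    out = {}
    uncovered: list[str] = []
    for cid, g in weights.groupby("commune_id", sort=True):
        avail = g[g["antenna_id"].isin(antenna_means.index)]
        if avail.empty:
            uncovered.append(str(cid))
            out[cid] = pd.Series(np.nan, index=antenna_means.columns)
            continue
        vals = antenna_means.loc[avail["antenna_id"]]
        w = avail["weight"].to_numpy()[:, None] * vals.notna().to_numpy()
        num = np.nansum(vals.to_numpy() * w, axis=0)
        den = w.sum(axis=0)
        res = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[cid] = pd.Series(res, index=antenna_means.columns)
    if uncovered:
        logger.warning(
            "%d communes have no intersecting antenna with data: %s",
            len(uncovered),
            ", ".join(uncovered[:10]),
        )
    table = pd.DataFrame(out).T
    table.index.name = "commune_id"
    return table


def estimate_commune_subscribers(
    weights: pd.DataFrame, assignments: dict[str, HomeAssignment]
) -> pd.Series:
    """Estimated retained-subscriber count per commune via overlap weights.

    Mirrors the population sanity check: each antenna's retained-subscriber
    count is spread over communes proportionally to w_{c,a}.
    """
    per_antenna = pd.Series(
        [a.year_home for a in assignments.values() if a.retained and a.year_home]
    ).value_counts()
    w = weights.copy()
    w["n"] = w["antenna_id"].map(per_antenna).fillna(0.0)
    w["share"] = w["weight"] * w["n"]
    return w.groupby("commune_id")["share"].sum()


def aggregate_log_to_communes(
    log: pd.DataFrame,
    cmap: CommuneMap,
    antennas: AntennaSet,
    months: range | list[int] = range(1, 13),
) -> pd.DataFrame:
    """Full event-log-to-commune-features pipeline.

    Convenience wrapper chaining home assignment, filtering, monthly
    feature computation, antenna means and overlap-weighted commune means.
    """
    assignments = assign_home_antennas(log)
    filter_subscribers(log, assignments)
    monthly = [
        compute_subscriber_features(log, assignments, m, antennas=antennas)
        for m in months
    ]
    features = pd.concat(monthly, ignore_index=True)
    means = antenna_feature_means(features, assignments)
    weights = voronoi_overlap_weights(cmap, antennas)
    return commune_feature_vector(weights, means)
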