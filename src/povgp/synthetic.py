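"""Seeded synthetic study data: communes, antennas, event logs, censuses.

The generators emulate the statistical structure the estimation pipeline
assumes, at the scale of the study setting (a country of 552 communes in
14 regions, 121 of them urban, roughly 700 km across):

* a Voronoi tessellation of random seed points as the commune map, with
  regions formed by spatially clustering the seeds;
* per-source commune feature tables and a latent deprivation field drawn
  from the GP regression model itself (linear term + product-kernel GP +
  noise), with the noise-free components returned for oracle tests;
* subscriber-level event logs with a nocturnal home-antenna structure and
  Poisson monthly activity, with the ground-truth home assignment returned
  for recovery tests;
* commune household tables whose per-indicator deprivation probabilities
  are supplied by the caller (typically derived from the latent field), so
  Alkire-Foster statistics computed downstream track the latent field.

Everything is driven by a single integer seed; identical configuration and
seed give bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans

from povgp.geometry import bounded_voronoi
from povgp.gp import GPHyperParams, kernel_matrix

__all__ = [
    "SourceConfig",
    "SyntheticConfig",
    "CommuneMap",
    "AntennaSet",
    "LatentField",
    "generate_commune_map",
    "place_antennas",
    "generate_latent_field",
    "generate_cdr_log",
    "generate_household_table",
    "generate_two_source_dataset",
    "deprivation_probs_from_latent",
]

INDICATOR_NAMES = [
    "years_of_schooling",
    "school_attendance",
    "child_mortality",
    "nutrition",
    "cooking_fuel",
    "sanitation",
    "water",
    "electricity",
    "floor",
    "assets",
]


@dataclass(frozen=True)
class SourceConfig:
    """Generative settings for one feature source (cdr or env)."""

    name: str
    n_features: int = 8
    beta_true: tuple[float, ...] = (1.0, -1.0, 0.5, -0.5, 0.0, 0.0, 0.0, 0.0)
    sigma_f2: float = 0.5
    ell: float = 2.5
    ell_s: float = 50.0
    sigma_n2: float = 0.1

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if len(self.beta_true) != self.n_features:
            raise ValueError("beta_true length must equal n_features")
        if self.sigma_f2 < 0 or self.sigma_n2 < 0:
            raise ValueError("variances must be nonnegative")
        if self.ell <= 0 or self.ell_s <= 0:
            raise ValueError("length-scales must be positive")

    @property
    def params(self) -> GPHyperParams:
        return GPHyperParams(
            beta=np.array(self.beta_true),
            ell=self.ell,
            ell_s=self.ell_s,
            sigma_f2=max(self.sigma_f2, 1e-12),
            sigma_n2=max(self.sigma_n2, 1e-12),
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full configuration of the synthetic study setting.

    Defaults mirror the study geography: 552 communes (121 urban, 431
    rural) in 14 regions on a ~700 km square; household counts per commune
    approximate a 10% census sample; the nocturnal share of phone events
    and monthly activity rates are set to plausible human values.
    """

    n_communes: int = 552
    n_urban: int = 121
    n_regions: int = 14
    map_extent_km: float = 700.0
    sources: tuple[SourceConfig, ...] = (
        SourceConfig(name="cdr"),
        SourceConfig(name="env", beta_true=(-0.8, 1.2, 0.0, 0.6, 0.0, 0.0, 0.0, 0.0)),
    )
    households_per_commune: tuple[int, int] = (100, 400)
    subscribers_per_commune: tuple[int, int] = (20, 60)
    events_per_month_mean: float = 30.0
    nocturnal_fraction: float = 0.35
    home_attachment: float = 0.95
    mobility: float = 1.0
    household_frailty: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_communes < 1:
            raise ValueError("n_communes must be at least 1")
        if self.n_urban > self.n_communes:
            raise ValueError("n_urban cannot exceed n_communes")
        if self.n_regions > self.n_communes:
            raise ValueError("n_regions cannot exceed n_communes")
        if self.n_urban < 0 or self.n_regions < 1:
            raise ValueError("counts must be nonnegative (n_regions >= 1)")
        if self.map_extent_km <= 0:
            raise ValueError("map_extent_km must be positive")
        for p in (self.nocturnal_fraction, self.home_attachment, self.mobility):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.households_per_commune
        if lo < 0 or hi < lo:
            raise ValueError("invalid households_per_commune range")
        lo, hi = self.subscribers_per_commune
        if lo < 0 or hi < lo:
            raise ValueError("invalid subscribers_per_commune range")
        for src in self.sources:
            src.validate()

    def source(self, name: str) -> SourceConfig:
        for src in self.sources:
            if src.name == name:
                return src
        raise KeyError(name)


@dataclass
class CommuneMap:
    """Areal units: polygons, centroids, region membership, urban flags."""

    commune_ids: list[str]
    polygons: list[Polygon]
    centroids: np.ndarray  # (n, 2) km
    region_ids: list[str]
    is_urban: np.ndarray  # (n,) bool
    extent_km: float

    @property
    def n(self) -> int:
        return len(self.commune_ids)

    def index_of(self, commune_id: str) -> int:
        return self.commune_ids.index(commune_id)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "commune_id": self.commune_ids,
                "region_id": self.region_ids,
                "is_urban": self.is_urban,
                "cx": self.centroids[:, 0],
                "cy": self.centroids[:, 1],
                "area_km2": [p.area for p in self.polygons],
            }
        )


@dataclass
class AntennaSet:
    """Antenna sites in km coordinates, tagged with their commune."""

    antenna_ids: list[str]
    positions: np.ndarray  # (m, 2)
    commune_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.antenna_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antenna_id": self.antenna_ids,
                "commune_id": self.commune_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )


@dataclass
class LatentField:
    """A draw from the single-source generative model, with components.

    y = X beta_true + f + eps holds exactly by construction.
    """

    source: str
    X: np.ndarray
    beta_true: np.ndarray
    f: np.ndarray
    eps: np.ndarray
    y: np.ndarray
    feature_names: list[str]


# ---------------------------------------------------------------------------


def generate_commune_map(config: SyntheticConfig) -> CommuneMap:
    """Tile the square extent into communes by a seeded Voronoi tessellation.

    The n_urban smallest-area cells are flagged urban (a proxy for dense
    urban centres); regions are formed by k-means clustering of the seed
    points, which yields spatially contiguous groups.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.map_extent_km
    seeds = rng.uniform(0.0, L, size=(config.n_communes, 2))
    polys = bounded_voronoi(seeds, L)
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    areas = np.array([p.area for p in polys])
    urban = np.zeros(config.n_communes, dtype=bool)
    urban[np.argsort(areas, kind="stable")[: config.n_urban]] = True

    if config.n_regions == 1:
        labels = np.zeros(config.n_communes, dtype=int)
    else:
        km = KMeans(
            n_clusters=config.n_regions,
            n_init=4,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(seeds)

    width = len(str(config.n_communes))
    ids = [f"C{i:0{width}d}" for i in range(config.n_communes)]
    region_ids = [f"R{int(l):02d}" for l in labels]
    return CommuneMap(ids, polys, centroids, region_ids, urban, L)


def place_antennas(cmap: CommuneMap, config: SyntheticConfig, n_extra_urban: int = 2) -> AntennaSet:
    """One antenna at every commune centroid, extra antennas in urban cells.

    Mirrors sparse rural antenna density: urban communes receive
    ``n_extra_urban`` additional sites at random interior points.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids: list[str] = []
    pos: list[np.ndarray] = []
    owner: list[str] = []
    for i, cid in enumerate(cmap.commune_ids):
        ids.append(f"A{cid[1:]}_0")
        pos.append(cmap.centroids[i])
        owner.append(cid)
        if cmap.is_urban[i]:
            poly = cmap.polygons[i]
            minx, miny, maxx, maxy = poly.bounds
            placed = 0
            for _ in range(200):
                if placed >= n_extra_urban:
                    break
                p = rng.uniform([minx, miny], [maxx, maxy])
                if poly.contains(Point(p)):
                    ids.append(f"A{cid[1:]}_{placed + 1}")
                    pos.append(p)
                    owner.append(cid)
                    placed += 1
    return AntennaSet(ids, np.array(pos), owner)


def generate_latent_field(
    cmap: CommuneMap, config: SyntheticConfig, source: str = "cdr"
) -> LatentField:
    """Draw one source's features and targets from the GP regression model.

    Features are iid standard normal; f is a draw from the product
    feature x spatial kernel evaluated at (X, centroids); y adds the linear
    term and iid Gaussian noise.  All components are returned so tests can
    verify the exact decomposition y = X beta + f + eps.
    """
    if cmap.n == 0:
        raise ValueError("commune map is empty")
    src = config.source(source)
    src.validate()
    # stable across processes (unlike builtin str hash)
    src_tag = int.from_bytes(source.encode()[:4].ljust(4, b"\0"), "big") % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, src_tag]))
    n, d = cmap.n, src.n_features
    X = rng.standard_normal((n, d))
    beta = np.array(src.beta_true)

    if src.sigma_f2 == 0.0:
        f = np.zeros(n)
    else:
        K = kernel_matrix(X, cmap.centroids, X, cmap.centroids, src.params)
        try:
            C = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError:
            try:
                C = np.linalg.cholesky(K + 1e-6 * np.eye(n))
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "simulated covariance not positive definite after jitter"
                ) from exc
        f = C @ rng.standard_normal(n)
    eps = (
        np.sqrt(src.sigma_n2) * rng.standard_normal(n)
        if src.sigma_n2 > 0
        else np.zeros(n)
    )
    y = X @ beta + f + eps
    names = [f"{source}_f{j}" for j in range(d)]
    return LatentField(source, X, beta, f, eps, y, names)


def generate_two_source_dataset(cmap: CommuneMap, config: SyntheticConfig):
    """Shared-target draw: two informative sources predicting one field.

    The common deprivation target combines each source's linear signal at
    half weight with a single spatially smooth GP component and noise:

        y = 0.5 * X_c beta_c + 0.5 * X_e beta_e + f_s(s) + eps

    Each single-source model then sees only part of the signal, while the
    fused model can recover more of it -- the regime in which combining
    sources is expected to help.  Returns (features_by_source, y, truth)
    where features_by_source maps source name -> DataFrame indexed by
    commune_id and truth holds the components.
    """
    if len(config.sources) < 2:
        raise ValueError("two sources are required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = cmap.n
    features: dict[str, pd.DataFrame] = {}
    linear = np.zeros(n)
    for src in config.sources[:2]:
        X = rng.standard_normal((n, src.n_features))
        linear += 0.5 * X @ np.array(src.beta_true)
        features[src.name] = pd.DataFrame(
            X,
            index=pd.Index(cmap.commune_ids, name="commune_id"),
            columns=[f"{src.name}_f{j}" for j in range(src.n_features)],
        )
    s0 = config.sources[0]
    sf2 = float(np.mean([s.sigma_f2 for s in config.sources[:2]]))
    sn2 = float(np.mean([s.sigma_n2 for s in config.sources[:2]]))
    if sf2 > 0:
        spatial_params = GPHyperParams(
            beta=np.zeros(1), ell=1.0, ell_s=s0.ell_s, sigma_f2=sf2, sigma_n2=1e-12
        )
        zeros = np.zeros((n, 1))
        K = kernel_matrix(zeros, cmap.centroids, zeros, cmap.centroids, spatial_params)
        C = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        f_s = C @ rng.standard_normal(n)
    else:
        f_s = np.zeros(n)
    eps = np.sqrt(sn2) * rng.standard_normal(n) if sn2 > 0 else np.zeros(n)
    y = pd.Series(
        linear + f_s + eps, index=pd.Index(cmap.commune_ids, name="commune_id"), name="y"
    )
    truth = {"linear": linear, "f_spatial": f_s, "eps": eps}
    return features, y, truth


# ---------------------------------------------------------------------------
# CDR event log


def generate_cdr_log(
    cmap: CommuneMap, antennas: AntennaSet, config: SyntheticConfig
):
    """Simulate a year of call/text events with nocturnal home structure.

    Subscriber counts per commune follow a spatially smooth intensity
    field (a population-density proxy: real settlement density varies
    smoothly in space), mapped into the configured
    ``subscribers_per_commune`` range.  Every subscriber gets a
    ground-truth home antenna in their commune and a Poisson number of
    events per month.  Nocturnal events (19:00-07:00) occur at the home
    antenna with probability ``home_attachment`` (scaled by ``mobility``);
    daytime events wander to nearby antennas with probability
    0.5 * ``mobility``.  Returns (log, truth): the event DataFrame and a
    per-subscriber DataFrame with the true home antenna and commune.
    """
    config.validate()
    if antennas.n == 0:
        raise ValueError("at least one antenna is required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))

    ant_by_commune: dict[str, list[int]] = {}
    for j, cid in enumerate(antennas.commune_ids):
        ant_by_commune.setdefault(cid, []).append(j)
    # nearest antennas for daytime wandering
    from scipy.spatial import cKDTree

    tree = cKDTree(antennas.positions)
    k_near = min(5, antennas.n)

    lo, hi = config.subscribers_per_commune
    # smooth population-density proxy: GP over centroids, rank-mapped to
    # the configured subscriber range
    if cmap.n > 1 and hi > lo:
        dens_params = GPHyperParams(
            beta=np.zeros(1),
            ell=1.0,
            ell_s=max(cmap.extent_km / 4.0, 1e-6),
            sigma_f2=1.0,
            sigma_n2=1e-12,
        )
        zeros = np.zeros((cmap.n, 1))
        Kd = kernel_matrix(zeros, cmap.centroids, zeros, cmap.centroids, dens_params)
        u = np.linalg.cholesky(Kd + 1e-8 * np.eye(cmap.n)) @ rng.standard_normal(cmap.n)
        ranks = np.argsort(np.argsort(u)) / max(cmap.n - 1, 1)
        n_subs_all = np.rint(lo + (hi - lo) * ranks).astype(int)
    else:
        n_subs_all = np.full(cmap.n, lo)

    rows = []
    truth_rows = []
    sub_idx = 0
    p_away_night = config.mobility * (1.0 - config.home_attachment)
    p_away_day = config.mobility * 0.5
    for i, cid in enumerate(cmap.commune_ids):
        n_subs = int(n_subs_all[i])
        local = ant_by_commune.get(cid) or [
            int(tree.query(cmap.centroids[i])[1])
        ]
        for _ in range(n_subs):
            sid = f"S{sub_idx:06d}"
            sub_idx += 1
            home = int(local[rng.integers(len(local))])
            truth_rows.append(
                {"subscriber_id": sid, "home_antenna": antennas.antenna_ids[home], "commune_id": cid}
            )
            _, near = tree.query(antennas.positions[home], k=k_near)
            near = np.atleast_1d(near)
            n_peers = int(rng.integers(3, 12))
            peers = [f"P{sub_idx:06d}_{p}" for p in range(n_peers)]
            peer_w = 1.0 / np.arange(1, n_peers + 1)
            peer_w /= peer_w.sum()
            for month in range(1, 13):
                n_ev = rng.poisson(config.events_per_month_mean)
                if n_ev == 0:
                    continue
                nocturnal = rng.random(n_ev) < config.nocturnal_fraction
                away_p = np.where(nocturnal, p_away_night, p_away_day)
                away = rng.random(n_ev) < away_p
                ant = np.full(n_ev, home)
                if away.any():
                    ant[away] = near[rng.integers(0, len(near), size=int(away.sum()))]
                day = rng.integers(1, 29, size=n_ev)
                noct_hours = np.array([19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5, 6])
                hour = np.where(
                    nocturnal,
                    noct_hours[rng.integers(0, 12, size=n_ev)],
                    rng.integers(7, 19, size=n_ev),
                )
                minute = rng.integers(0, 60, size=n_ev)
                second = rng.integers(0, 60, size=n_ev)
                is_call = rng.random(n_ev) < 0.6
                dur = np.where(is_call, rng.exponential(120.0, size=n_ev), np.nan)
                peer = rng.choice(peers, size=n_ev, p=peer_w)
                outgoing = rng.random(n_ev) < 0.5
                epoch = pd.Timestamp(2013, month, 1).value // 10**9
                ts = epoch + (day - 1) * 86400 + hour * 3600 + minute * 60 + second
                rows.append(
                    (
                        np.repeat(sid, n_ev),
                        np.asarray(antennas.antenna_ids, dtype=object)[ant],
                        ts.astype("int64"),
                        np.where(is_call, "call", "text"),
                        dur,
                        np.where(outgoing, "out", "in"),
                        peer,
                    )
                )
    columns = [
        "subscriber_id",
        "antenna_id",
        "timestamp",
        "kind",
        "duration_s",
        "direction",
        "peer_id",
    ]
    if rows:
        cols = [np.concatenate([r[j] for r in rows]) for j in range(7)]
        log = pd.DataFrame(dict(zip(columns, cols)))
        log["timestamp"] = pd.to_datetime(log["timestamp"], unit="s")
    else:
        log = pd.DataFrame(columns=columns)
    log = log.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return log, truth


# ---------------------------------------------------------------------------
# household census


def generate_household_table(
    cmap: CommuneMap,
    target_indicator_probs: np.ndarray | pd.DataFrame,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Draw household deprivation indicators per commune.

    ``target_indicator_probs`` is an (n_communes, 10) matrix of per-commune
    deprivation probabilities.  With frailty off (default) indicators are
    independent Bernoulli draws, so empirical proportions converge to the
    targets.  With frailty on, a single latent uniform per household is
    thresholded against every indicator probability, inducing strong
    positive within-household correlation while preserving the marginals.
    """
    probs = (
        target_indicator_probs.to_numpy()
        if isinstance(target_indicator_probs, pd.DataFrame)
        else np.asarray(target_indicator_probs, dtype=float)
    )
    if probs.shape != (cmap.n, len(INDICATOR_NAMES)):
        raise ValueError(
            f"target_indicator_probs must have shape ({cmap.n}, {len(INDICATOR_NAMES)})"
        )
    if np.any(probs < 0.0) or np.any(probs > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    lo, hi = config.households_per_commune
    frames = []
    hh_idx = 0
    for i, cid in enumerate(cmap.commune_ids):
        n_hh = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if n_hh == 0:
            continue
        if config.household_frailty:
            u = rng.random((n_hh, 1))
            dep = (u < probs[i][None, :]).astype(int)
        else:
            dep = (rng.random((n_hh, len(INDICATOR_NAMES))) < probs[i][None, :]).astype(int)
        frame = pd.DataFrame(dep, columns=INDICATOR_NAMES)
        frame.insert(0, "commune_id", cid)
        frame.insert(
            0, "household_id", [f"H{hh_idx + j:07d}" for j in range(n_hh)]
        )
        hh_idx += n_hh
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def deprivation_probs_from_latent(
    y: np.ndarray | pd.Series,
    base_logits: np.ndarray | None = None,
    slope: float = 1.2,
) -> np.ndarray:
    """Map a latent deprivation field to per-indicator probabilities.

    The standardized field enters a logistic link with per-indicator
    intercepts, so communes high on the latent field are deprived more
    often on every indicator (the monotone coupling the downstream model
    assumes).
    """
    y = np.asarray(y, dtype=float)
    z = (y - y.mean()) / (y.std() or 1.0)
    if base_logits is None:
        base_logits = np.linspace(-1.0, 0.5, len(INDICATOR_NAMES))
    logits = base_logits[None, :] + slope * z[:, None]
    return 1.0 / (1.0 + np.exp(-logits))
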