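"""Establishment potential via a presence-background suitability model.

The workflow mirrors standard correlative niche modelling practice:
occurrence records are deduplicated and spatially thinned to one point per
grid cell, collinear covariates are screened out, a penalized
presence-vs-background classifier is fit on standardized linear and
quadratic features, suitability is predicted per pixel and averaged over an
ensemble of models, and the per-region establishment potential is a zonal
statistic (max by default) of the ensemble surface. Model skill is
summarized by k-fold cross-validated AUC and omission rate.

The classifier is a ridge-penalized logistic regression — a documented
surrogate for MaxEnt-style presence-background models; any externally
produced suitability raster can be substituted via :class:`SuitabilityGrid`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .grids import CovariateStack, Grid, RegionGrid, SuitabilityGrid

__all__ = [
    "OccurrenceSet",
    "SuitabilityModel",
    "SDMEvaluation",
    "thin_occurrences",
    "screen_covariates",
    "sample_background",
    "fit_suitability",
    "predict_suitability",
    "fit_host_chained",
    "ensemble_mean",
    "zonal_potential",
    "evaluate_kfold",
]


@dataclass
class OccurrenceSet:
    """Species presence points in WGS84 lon/lat degrees."""

    species: str
    points: np.ndarray  # shape (n, 2): lon, lat

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.size:
            lon, lat = self.points[:, 0], self.points[:, 1]
            if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
                raise ValueError("coordinates outside WGS84 bounds")

    def __len__(self) -> int:
        return len(self.points)


def thin_occurrences(
    occ: OccurrenceSet,
    cellsize: float,
    seed: int | None = None,
    origin: tuple[float, float] = (-180.0, 90.0),
) -> OccurrenceSet:
    """Spatially rarefy occurrences to at most one point per grid cell.

    Exact duplicate coordinates are removed first. Within a cell the point
    with the lowest (lon, lat) sort key is kept; pass a ``seed`` to pick the
    survivor at random instead. Thinning is idempotent.
    """
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    if len(occ) == 0:
        return OccurrenceSet(occ.species, np.empty((0, 2)))
    pts = np.unique(occ.points, axis=0)
    west, north = origin
    col = np.floor((pts[:, 0] - west) / cellsize).astype(int)
    row = np.floor((north - pts[:, 1]) / cellsize).astype(int)
    cells = pd.DataFrame({"row": row, "col": col, "lon": pts[:, 0], "lat": pts[:, 1]})
    if seed is None:
        keep = cells.sort_values(["lon", "lat"]).groupby(["row", "col"]).head(1)
    else:
        rng = np.random.default_rng(seed)
        cells = cells.sample(frac=1.0, random_state=rng.integers(2**31))
        keep = cells.groupby(["row", "col"]).head(1)
    return OccurrenceSet(occ.species, keep[["lon", "lat"]].to_numpy())


def screen_covariates(stack: CovariateStack, r_threshold: float = 0.7) -> list[str]:
    """Greedy collinearity screening of a covariate stack.

    While any covariate pair exceeds ``|Pearson r| > r_threshold`` over their
    shared valid pixels, the member of the worst pair with the higher mean
    absolute correlation to the remaining covariates is dropped. Constant
    covariates are dropped with a warning.
    """
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    arr = stack.as_array()
    flat = arr.reshape(arr.shape[0], -1)
    valid = ~np.isnan(flat).any(axis=0)
    flat = flat[:, valid]
    names = list(stack.names)
    sds = flat.std(axis=1)
    for name in [n for n, sd in zip(names, sds) if sd == 0]:
        warnings.warn(f"dropping constant covariate {name!r}", stacklevel=2)
    keep = [i for i, sd in enumerate(sds) if sd > 0]
    flat = flat[keep]
    names = [names[i] for i in keep]
    while len(names) > 1:
        r = np.corrcoef(flat)
        np.fill_diagonal(r, 0.0)
        absr = np.abs(r)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_threshold:
            break
        drop = i if absr[i].mean() >= absr[j].mean() else j
        flat = np.delete(flat, drop, axis=0)
        del names[drop]
    return names


def sample_background(
    stack: CovariateStack, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` pixel-centre points uniformly without replacement from valid pixels."""
    if n <= 0:
        raise ValueError("n must be positive")
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    if n > rows.size:
        raise ValueError(f"requested {n} background points but only {rows.size} valid pixels")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    west, north = stack.origin
    lon = west + (cols[idx] + 0.5) * stack.cellsize
    lat = north - (rows[idx] + 0.5) * stack.cellsize
    return np.column_stack([lon, lat])


def _extract_covariates(points: np.ndarray, stack: CovariateStack) -> np.ndarray:
    """Covariate vectors at point locations; NaN rows where any covariate is nodata."""
    g0 = stack.grids[0]
    row, col = g0.cell_index(points[:, 0], points[:, 1])
    nrows, ncols = g0.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    out = np.full((len(points), len(stack.names)), np.nan)
    arr = stack.as_array()
    out[inside] = arr[:, row[inside], col[inside]].T
    return out


def _design(x: np.ndarray, quadratic: bool) -> np.ndarray:
    return np.hstack([x, x**2]) if quadratic else x


@dataclass
class SuitabilityModel:
    """Penalized presence-background classifier with standardized features.

    ``score(x)`` maps covariate vectors to the logistic output in [0, 1].
    """

    feature_names: list[str]
    quadratic: bool
    mean_: np.ndarray
    scale_: np.ndarray
    clf: LogisticRegression
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        return self.clf.coef_.ravel()

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = (_design(x, self.quadratic) - self.mean_) / self.scale_
        return self.clf.predict_proba(z)[:, 1]


def fit_suitability(
    presences: OccurrenceSet,
    background: np.ndarray,
    stack: CovariateStack,
    features: tuple[str, ...] = ("linear", "quadratic"),
    regularization: float = 1.0,
) -> SuitabilityModel:
    """Fit the presence-vs-background suitability classifier.

    Presences falling on nodata pixels are dropped with a warning; a model
    with every presence dropped, or with too few presences for the feature
    count, is an error. ``regularization`` is the ridge penalty weight
    (larger = stronger shrinkage).
    """
    unknown = set(features) - {"linear", "quadratic"}
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    quadratic = "quadratic" in features
    xp = _extract_covariates(presences.points, stack)
    good = ~np.isnan(xp).any(axis=1)
    if not good.all():
        warnings.warn(
            f"dropped {int((~good).sum())} presences on nodata pixels", stacklevel=2
        )
    xp = xp[good]
    if len(xp) == 0:
        raise ValueError("all presence points fell on nodata pixels")
    n_feat = len(stack.names) * (2 if quadratic else 1)
    if len(xp) < max(10, n_feat + 1):
        raise ValueError(
            f"too few usable presences ({len(xp)}) for {n_feat} features"
        )
    xb = _extract_covariates(np.asarray(background, dtype=float), stack)
    xb = xb[~np.isnan(xb).any(axis=1)]
    X = _design(np.vstack([xp, xb]), quadratic)
    y = np.concatenate([np.ones(len(xp)), np.zeros(len(xb))])
    mean_, scale_ = X.mean(axis=0), X.std(axis=0)
    degenerate = bool((scale_ == 0).any())
    notes = []
    if degenerate:
        notes.append("constant feature(s); coefficients not identifiable")
    scale_ = np.where(scale_ == 0, 1.0, scale_)
    clf = LogisticRegression(C=1.0 / max(regularization, 1e-12), max_iter=2000)
    clf.fit((X - mean_) / scale_, y)
    names = list(stack.names) + ([f"{n}^2" for n in stack.names] if quadratic else [])
    return SuitabilityModel(names, quadratic, mean_, scale_, clf, degenerate, notes)


def predict_suitability(model: SuitabilityModel, stack: CovariateStack) -> SuitabilityGrid:
    """Apply a fitted model per pixel; nodata in any covariate propagates."""
    base = [n for n in model.feature_names if not n.endswith("^2")]
    missing = [n for n in base if n not in stack.names]
    if missing:
        raise ValueError(f"stack missing model covariates: {missing}")
    sub = stack.subset(base)
    arr = sub.as_array()
    flat = arr.reshape(arr.shape[0], -1).T
    valid = ~np.isnan(flat).any(axis=1)
    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        out[valid] = model.score(flat[valid])
    return SuitabilityGrid(out.reshape(sub.shape), sub.origin, sub.cellsize)


def fit_host_chained(
    presences: OccurrenceSet,
    host_suitability: SuitabilityGrid,
    background: np.ndarray,
    regularization: float = 1.0,
) -> SuitabilityModel:
    """Univariate model of pest presence on a host-plant suitability surface.

    Chains a second species distribution model on the predictions of a first
    (e.g. a pest on its preferred host tree): the host suitability raster is
    the single covariate. A constant host surface yields a degenerate fit,
    flagged on the returned model.
    """
    stack = CovariateStack(
        ["host_suitability"],
        [Grid(host_suitability.values, host_suitability.origin, host_suitability.cellsize)],
    )
    return fit_suitability(
        presences, background, stack, features=("linear", "quadratic"),
        regularization=regularization,
    )


def ensemble_mean(grids: list[SuitabilityGrid]) -> SuitabilityGrid:
    """Per-pixel mean across suitability grids; nodata if any member is nodata."""
    if not grids:
        raise ValueError("need at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if not Grid.same_geometry(first, g):
            raise ValueError("ensemble members must share geometry")
    arr = np.stack([g.values for g in grids])
    mean = arr.mean(axis=0)  # NaN propagates: nodata if any member is nodata
    return SuitabilityGrid(mean, first.origin, first.cellsize)


def zonal_potential(
    suit: SuitabilityGrid, zones: RegionGrid, stat: str = "max"
) -> pd.DataFrame:
    """Zonal summary (max/mean/median) of suitability per region.

    Regions whose pixels are all nodata in the suitability grid get a
    missing value. Returns columns ``region`` and ``establishment``.
    """
    if stat not in {"max", "mean", "median"}:
        raise ValueError(f"unknown zonal statistic {stat!r}")
    if suit.geometry() != zones.geometry():
        raise ValueError("suitability and region grids must share geometry")
    labels = zones.labels.ravel()
    values = suit.values.ravel()
    labelled = labels != None  # noqa: E711 — object array comparison
    df = pd.DataFrame({"region": labels[labelled], "value": values[labelled]})
    agg = df.groupby("region")["value"].agg(stat)  # NaN-skipping by default
    counts = df.dropna(subset=["value"]).groupby("region").size()
    agg[~agg.index.isin(counts.index)] = np.nan
    return agg.rename("establishment").rename_axis("region").reset_index()


@dataclass
class SDMEvaluation:
    """Cross-validated discrimination and omission of a suitability model."""

    auc: float
    omission_rate: float
    folds: int
    threshold_rule: str
    fold_auc: list[float] = field(default_factory=list)
    fold_omission: list[float] = field(default_factory=list)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the rank statistic: P(pos > neg) with ties counting 1/2."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def evaluate_kfold(
    presences: OccurrenceSet,
    background: np.ndarray,
    stack: CovariateStack,
    k: int = 5,
    seed: int = 0,
    threshold_rule: str = "min_training_presence",
    features: tuple[str, ...] = ("linear", "quadratic"),
    regularization: float = 1.0,
) -> SDMEvaluation:
    """k-fold cross-validation of the suitability model.

    Presences are split into k seeded folds. Per fold, the model is trained
    on the remaining presences (all background), AUC is computed rank-based
    on held-out presences vs background scores, and the omission rate is the
    fraction of held-out presences scoring below the threshold — by default
    the minimum score over training presences.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(presences)
    if k > n:
        raise ValueError(f"k={k} exceeds number of presences ({n})")
    if threshold_rule != "min_training_presence":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    xb = _extract_covariates(np.asarray(background, dtype=float), stack)
    xb = xb[~np.isnan(xb).any(axis=1)]
    aucs, omissions = [], []
    for held in folds:
        train_idx = np.setdiff1d(order, held)
        train = OccurrenceSet(presences.species, presences.points[train_idx])
        model = fit_suitability(
            train, background, stack, features=features, regularization=regularization
        )
        x_held = _extract_covariates(presences.points[held], stack)
        x_held = x_held[~np.isnan(x_held).any(axis=1)]
        if len(x_held) == 0:
            continue
        s_held = model.score(x_held)
        s_bg = model.score(xb)
        x_train = _extract_covariates(train.points, stack)
        x_train = x_train[~np.isnan(x_train).any(axis=1)]
        threshold = model.score(x_train).min()
        aucs.append(_rank_auc(s_held, s_bg))
        omissions.append(float((s_held < threshold).mean()))
    if not aucs:
        raise ValueError("no evaluable folds (all held-out presences on nodata)")
    return SDMEvaluation(
        auc=float(np.mean(aucs)),
        omission_rate=float(np.mean(omissions)),
        folds=k,
        threshold_rule=threshold_rule,
        fold_auc=aucs,
        fold_omission=omissions,
    )
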