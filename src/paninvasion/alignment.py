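"""Alignment correlations and the 1-10 paninvasion severity score.

A paninvasion threatens a global market when a pest's transport,
establishment and impact potentials are *aligned* across regions: the
regions most likely to receive and sustain the pest are also the regions
whose vulnerable industry is largest. Alignment is measured per impact
measure as the Spearman rank correlation between impact potential and the
fitted values of an ordinary least-squares regression of impact on
transport and establishment potentials.

Severity then asks whether predicted per-region invasion risk lines up
with market size: the fitted impact values are rescaled to a 1-10 risk
scale, correlated with market size, and the correlation rho is mapped
linearly from [-1, 1] onto [1, 10] — 1 means the global market is buffered
(complete negative correlation), 10 means a paninvasion is likely
(complete positive correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignmentResult",
    "RiskAssessment",
    "fit_alignment_regression",
    "alignment_correlation",
    "quadrant_classify",
    "rescale_to_risk",
    "severity_score",
    "assess_paninvasion",
]


@dataclass
class AlignmentResult:
    """OLS fit of one impact measure on transport + establishment, with Spearman alignment."""

    impact_measure: str
    coefficients: dict[str, float]  # intercept, transport, establishment
    regions: list[str]
    fitted: np.ndarray
    impact: np.ndarray
    rho: float
    p_value: float
    n: int
    dropped_regions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "impact_measure": self.impact_measure,
            "coefficients": self.coefficients,
            "rho": self.rho,
            "p": self.p_value,
            "n": self.n,
            "regions": self.regions,
            "fitted": [float(v) for v in self.fitted],
            "dropped_regions": self.dropped_regions,
        }


def fit_alignment_regression(
    potentials: pd.DataFrame, impact_measure: str
) -> AlignmentResult:
    """OLS of impact potential on transport and establishment potentials.

    ``impact_measure`` is ``"grape"`` or ``"wine"`` (column
    ``impact_<measure>``). Regions with any of the three values missing are
    listwise-dropped and reported. Requires at least 3 complete regions and
    a full-rank design; perfect collinearity between transport and
    establishment is an error naming the pair.
    """
    col = f"impact_{impact_measure}"
    if col not in potentials.columns:
        raise ValueError(f"unknown impact measure {impact_measure!r}")
    needed = ["transport", "establishment", col]
    complete = potentials.dropna(subset=needed)
    dropped = sorted(set(potentials["region"]) - set(complete["region"]))
    n = len(complete)
    if n < 3:
        raise ValueError(f"need >=3 complete regions, got {n}")
    T = complete["transport"].to_numpy(float)
    E = complete["establishment"].to_numpy(float)
    y = complete[col].to_numpy(float)
    X = np.column_stack([np.ones(n), T, E])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient design: transport and establishment are collinear"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rho, p = alignment_correlation(y, fitted)
    return AlignmentResult(
        impact_measure=impact_measure,
        coefficients={
            "intercept": float(beta[0]),
            "transport": float(beta[1]),
            "establishment": float(beta[2]),
        },
        regions=list(complete["region"]),
        fitted=fitted,
        impact=y,
        rho=rho,
        p_value=p,
        n=n,
        dropped_regions=dropped,
    )


def alignment_correlation(impact, fitted) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with two-sided t-approximation p.

    Constant input vectors leave the rank correlation undefined and raise.
    """
    impact = np.asarray(impact, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if impact.shape != fitted.shape:
        raise ValueError("impact and fitted must have equal length")
    if impact.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(impact) == 0 or np.ptp(fitted) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(impact, fitted)
    return float(res.statistic), float(res.pvalue)


def quadrant_classify(
    potentials: pd.DataFrame,
    thresholds: tuple[float, float] = (0.5, 0.5),
) -> pd.DataFrame:
    """Pandemic-severity-framework-style quadrant labels per region.

    Transport and establishment are min-max scaled to [0, 1] over the
    regions where both are present; each region is labelled high/low on
    each axis against the scaled thresholds (default midpoints). Returns
    columns region, transport_scaled, establishment_scaled, quadrant.
    """
    sub = potentials.dropna(subset=["transport", "establishment"])
    if sub.empty:
        raise ValueError("no region has both transport and establishment")
    t = sub["transport"].to_numpy(float)
    e = sub["establishment"].to_numpy(float)
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        raise ValueError("cannot scale a constant axis")
    ts = (t - t.min()) / np.ptp(t)
    es = (e - e.min()) / np.ptp(e)
    tt, te = thresholds
    labels = np.where(
        ts >= tt,
        np.where(es >= te, "high-high", "high-low"),
        np.where(es >= te, "low-high", "low-low"),
    )
    return pd.DataFrame(
        {
            "region": sub["region"].to_numpy(),
            "transport_scaled": ts,
            "establishment_scaled": es,
            "quadrant": labels,
        }
    )


def rescale_to_risk(fitted) -> np.ndarray:
    """Min-max map of fitted impact values onto the 1-10 risk scale.

    The minimum maps to 1 and the maximum to 10; the map is affine so
    ranks (and hence any Spearman correlation) are preserved.
    """
    fitted = np.asarray(fitted, dtype=float)
    if fitted.size < 2 or np.ptp(fitted) == 0:
        raise ValueError("need >=2 distinct values to rescale")
    scaled = (fitted - fitted.min()) / np.ptp(fitted)
    return 1.0 + 9.0 * scaled


def severity_score(rho: float) -> tuple[float, int]:
    """Map a risk-market correlation onto the 1-10 paninvasion severity scale.

    ``continuous = 1 + 9 * (rho + 1) / 2`` so that rho = -1 gives 1 (market
    buffered) and rho = +1 gives 10 (paninvasion likely); the headline
    integer rounds half away from zero.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    continuous = 1.0 + 9.0 * (rho + 1.0) / 2.0
    integer = int(math.floor(continuous + 0.5))  # half away from zero (values are >= 1)
    return continuous, integer


@dataclass
class RiskAssessment:
    """Per-region risk plus the global 1-10 severity score."""

    impact_measure: str
    correlation_kind: str
    alignment: AlignmentResult
    per_region_risk: pd.DataFrame  # region, risk
    market_rho: float
    market_p: float
    severity_continuous: float
    severity_score: int
    n: int
    dropped_regions: list[str]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "impact_measure": self.impact_measure,
            "correlation_kind": self.correlation_kind,
            "coefficients": self.alignment.coefficients,
            "rho": self.alignment.rho,
            "p": self.alignment.p_value,
            "n": self.n,
            "dropped_regions": self.dropped_regions,
            "per_region_risk": {
                r: float(v)
                for r, v in zip(
                    self.per_region_risk["region"], self.per_region_risk["risk"]
                )
            },
            "market_rho": self.market_rho,
            "market_p": self.market_p,
            "severity_continuous": self.severity_continuous,
            "severity_score": self.severity_score,
        }


def assess_paninvasion(
    potentials: pd.DataFrame,
    impact_measure: str = "grape",
    correlation_kind: str = "spearman",
) -> RiskAssessment:
    """Full severity pipeline: regression, risk rescaling, market correlation, score.

    Regions missing any of transport, establishment, the impact measure or
    market size are listwise-dropped (and reported). The risk-market
    correlation defaults to Spearman; ``correlation_kind="pearson"`` is the
    alternative reading of the severity step.
    """
    if correlation_kind not in {"spearman", "pearson"}:
        raise ValueError(f"unknown correlation kind {correlation_kind!r}")
    col = f"impact_{impact_measure}"
    needed = ["transport", "establishment", col, "market"]
    complete = potentials.dropna(subset=[c for c in needed if c in potentials.columns])
    if len(complete) < 3:
        raise ValueError(f"need >=3 regions with all components, got {len(complete)}")
    align = fit_alignment_regression(complete, impact_measure)
    risk = rescale_to_risk(align.fitted)
    market = complete.set_index("region").loc[align.regions, "market"].to_numpy(float)
    if correlation_kind == "spearman":
        res = stats.spearmanr(risk, market)
    else:
        res = stats.pearsonr(risk, market)
    market_rho, market_p = float(res.statistic), float(res.pvalue)
    continuous, integer = severity_score(market_rho)
    dropped = sorted(set(potentials["region"]) - set(align.regions))
    return RiskAssessment(
        impact_measure=impact_measure,
        correlation_kind=correlation_kind,
        alignment=align,
        per_region_risk=pd.DataFrame({"region": align.regions, "risk": risk}),
        market_rho=market_rho,
        market_p=market_p,
        severity_continuous=continuous,
        severity_score=integer,
        n=align.n,
        dropped_regions=dropped,
    )
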