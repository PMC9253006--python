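"""Transport, impact and market-size potentials from tabular trade/production data.

The transport potential of a destination region is the log10 of its mean
annual tonnage imported from the invaded region set over a fixed year
window. Impact potential is the log10 mean annual grape or wine production
tonnage; market size is the log10 mean annual wine-export value in USD.
Years absent from the data count as zero in the mean (fixed-window
averaging), and a zero mean has no defined log, so it propagates as
missing and the region is dropped from downstream correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GALLONS_TO_TONNES = 3.776e-3
"""Wine density conversion: metric tons per U.S. gallon."""

VALID_COMMODITIES = frozenset({"grape", "wine"})


def _check_window(years: tuple[int, int]) -> range:
    lo, hi = int(years[0]), int(years[1])
    if hi < lo:
        raise ValueError(f"empty year window {years}")
    return range(lo, hi + 1)


def _log10_or_missing(mean_values: pd.Series, plus_one: bool = False) -> pd.Series:
    """log10 of positive means; zeros become NaN unless ``plus_one``."""
    if plus_one:
        return np.log10(mean_values + 1.0)
    out = pd.Series(np.nan, index=mean_values.index, dtype=float)
    pos = mean_values > 0
    out[pos] = np.log10(mean_values[pos])
    return out


def mean_annual_tonnage(
    flows: pd.DataFrame,
    invaded_origins: set[str] | list[str],
    years: tuple[int, int],
) -> pd.DataFrame:
    """Mean annual tonnage imported by each destination from the invaded set.

    Parameters
    ----------
    flows : DataFrame with columns origin_region, dest_region, year, tonnes.
    invaded_origins : origin regions making up the invaded set.
    years : inclusive ``(first, last)`` window; years with no recorded flow
        contribute zero, and the divisor is the fixed window length.

    Returns
    -------
    DataFrame with columns ``region`` and ``mean_tonnes`` (tonnes/year).
    """
    window = _check_window(years)
    invaded = set(invaded_origins)
    if not invaded:
        raise ValueError("invaded origin set is empty")
    if (flows["tonnes"] < 0).any():
        raise ValueError("negative tonnage in trade flows")
    sub = flows[
        flows["origin_region"].isin(invaded) & flows["year"].isin(window)
    ]
    self_trade = set(sub["dest_region"]) & invaded
    if self_trade:
        warnings.warn(
            f"self-trade destinations within the invaded set: {sorted(self_trade)}",
            stacklevel=2,
        )
    totals = sub.groupby("dest_region")["tonnes"].sum()
    out = (totals / len(window)).rename("mean_tonnes").rename_axis("region")
    return out.reset_index()


def transport_potential(mean_tonnes, plus_one: bool = False):
    """log10 of mean annual tonnage; zero tonnage maps to missing (NaN).

    Accepts a scalar or a Series; negative input is an error.
    """
    scalar = np.isscalar(mean_tonnes)
    s = pd.Series([mean_tonnes]) if scalar else pd.Series(mean_tonnes, dtype=float)
    if (s < 0).any():
        raise ValueError("tonnage must be non-negative")
    out = _log10_or_missing(s, plus_one)
    return float(out.iloc[0]) if scalar else out


def convert_gallons_to_tonnes(gallons):
    """Convert wine volume in U.S. gallons to metric tons (3.776e-3 t/gallon)."""
    arr = np.asarray(gallons, dtype=float)
    if (arr < 0).any():
        raise ValueError("gallons must be non-negative")
    out = arr * GALLONS_TO_TONNES
    return float(out) if np.isscalar(gallons) else out


def impact_potential(
    records: pd.DataFrame,
    commodity: str,
    years: tuple[int, int],
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-region log10 mean annual production tonnage for one commodity.

    Gallon-unit wine records are converted to tonnes first. Unknown
    commodities and grape records in gallons are errors.
    """
    if commodity not in VALID_COMMODITIES:
        raise ValueError(f"unknown commodity {commodity!r}; expected one of {sorted(VALID_COMMODITIES)}")
    window = _check_window(years)
    sub = records[records["commodity"] == commodity].copy()
    if (sub["quantity"] < 0).any():
        raise ValueError("negative production quantity")
    bad_unit = ~sub["unit"].isin({"tonnes", "gallons"})
    if bad_unit.any():
        raise ValueError(f"unknown units: {sorted(sub.loc[bad_unit, 'unit'].unique())}")
    gal = sub["unit"] == "gallons"
    if commodity == "grape" and gal.any():
        raise ValueError("grape production cannot be recorded in gallons")
    sub.loc[gal, "quantity"] = convert_gallons_to_tonnes(sub.loc[gal, "quantity"].to_numpy())
    sub = sub[sub["year"].isin(window)]
    mean = sub.groupby("region")["quantity"].sum() / len(window)
    out = _log10_or_missing(mean, plus_one).rename("impact").rename_axis("region")
    return out.reset_index()


def market_size(
    records: pd.DataFrame,
    years: tuple[int, int],
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-region log10 mean annual wine-export value (USD/year)."""
    window = _check_window(years)
    if (records["usd_value"] < 0).any():
        raise ValueError("negative export value")
    sub = records[records["year"].isin(window)]
    mean = sub.groupby("region")["usd_value"].sum() / len(window)
    out = _log10_or_missing(mean, plus_one).rename("market").rename_axis("region")
    return out.reset_index()


def assemble_potentials(
    regions: pd.DataFrame,
    level: str,
    transport: pd.DataFrame | None = None,
    establishment: pd.DataFrame | None = None,
    impact_grape: pd.DataFrame | None = None,
    impact_wine: pd.DataFrame | None = None,
    market: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outer-join all potential components onto the region set of one level.

    Each component is a two-column frame ``(region, value)``. The result has
    one row per region in the level, with NaN where a component is missing.
    A component region not present in the region set is an error.
    """
    base = regions[regions["level"] == level]
    if base.empty:
        raise ValueError(f"no regions at level {level!r}")
    if base["region"].duplicated().any():
        dups = sorted(base.loc[base["region"].duplicated(), "region"])
        raise ValueError(f"duplicate region identifiers: {dups}")
    out = base[["region", "invaded"]].copy()
    components = {
        "transport": transport,
        "establishment": establishment,
        "impact_grape": impact_grape,
        "impact_wine": impact_wine,
        "market": market,
    }
    known = set(out["region"])
    for name, comp in components.items():
        if comp is None:
            out[name] = np.nan
            continue
        comp = comp.rename(columns={comp.columns[1]: name})[["region", name]]
        if comp["region"].duplicated().any():
            raise ValueError(f"duplicate region keys in component {name!r}")
        unknown = set(comp["region"]) - known
        if unknown:
            raise ValueError(f"component {name!r} has regions outside the region set: {sorted(unknown)}")
        out = out.merge(comp, on="region", how="left")
    est = out["establishment"].dropna()
    if est.size and ((est < 0) | (est > 1)).any():
        raise ValueError("establishment potential must lie in [0, 1]")
    return out.reset_index(drop=True)


@dataclass
class TransportValidation:
    """Exploratory check that invaded regions sit higher on transport potential.

    Reports a Wilcoxon rank-sum comparison of invaded vs uninvaded transport
    potentials (with the rank AUC, i.e. the probability that a random invaded
    region outranks a random uninvaded one) and a univariate logistic
    regression of invaded status on transport potential.
    """

    direction: str
    auc: float
    rank_statistic: float
    rank_p: float
    logit_coef: float
    logit_p: float
    n_invaded: int
    n_uninvaded: int


def validate_transport_metric(potentials: pd.DataFrame) -> TransportValidation:
    """Two-sample rank test + logistic fit of invaded status on transport.

    Requires at least two invaded and two uninvaded regions with non-missing
    transport potential.
    """
    sub = potentials.dropna(subset=["transport"])
    inv = sub.loc[sub["invaded"].astype(bool), "transport"].to_numpy()
    uninv = sub.loc[~sub["invaded"].astype(bool), "transport"].to_numpy()
    if len(inv) < 2 or len(uninv) < 2:
        raise ValueError(
            f"need >=2 regions per group with transport potential "
            f"(invaded={len(inv)}, uninvaded={len(uninv)})"
        )
    mwu = stats.mannwhitneyu(inv, uninv, alternative="two-sided")
    auc = mwu.statistic / (len(inv) * len(uninv))
    direction = "positive" if np.median(inv) > np.median(uninv) else "negative"

    import statsmodels.api as sm

    x = sm.add_constant(np.concatenate([inv, uninv]))
    y = np.concatenate([np.ones(len(inv)), np.zeros(len(uninv))])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=False, maxiter=200)
        logit_coef, logit_p = float(fit.params[1]), float(fit.pvalues[1])
    except np.linalg.LinAlgError:
        # perfect separation: the MLE slope diverges; report its sign and
        # leave the Wald p undefined (the rank test still carries inference)
        sign = 1.0 if direction == "positive" else -1.0
        logit_coef, logit_p = sign * np.inf, np.nan
    return TransportValidation(
        direction=direction,
        auc=float(auc),
        rank_statistic=float(mwu.statistic),
        rank_p=float(mwu.pvalue),
        logit_coef=logit_coef,
        logit_p=logit_p,
        n_invaded=len(inv),
        n_uninvaded=len(uninv),
    )
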