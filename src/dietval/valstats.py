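"""Group- and individual-level accuracy statistics for recall validation.

The weighed food record (WFR) is the benchmark; each 24-hour recall (R24)
modality is compared to it with:

* **Equivalence (TOST)** — two one-sided paired t tests on the log scale.
  With paired log differences d_i = ln(R24_i) - ln(WFR_i) and a 10 % bound,
  the margin is theta = ln(1.1) symmetric about zero; the TOST p-value is
  the max of the two one-sided p-values and p < 0.05 declares the recall
  equivalent to the benchmark within the bound.
* **Bland-Altman agreement** — mean bias (R24 - WFR) and 95 % limits of
  agreement, bias +/- 1.96 x SD of the differences.
* **Difference-in-differences (DiD)** — contrast of the (WFR - R24) mean
  difference between the two interview-modality arms, fitted as a random
  intercept mixed model on the stacked two-rows-per-respondent data with a
  source x arm interaction. For balanced complete pairs this coincides with
  a pooled two-sample t test on per-respondent differences; the p-value
  uses a t reference with n - 2 degrees of freedom.
* **Percentage-error bands** — share of respondents whose R24 falls within
  +/-10/20/30/50 % of their WFR (boundary inclusive), plus over/under
  beyond +/-50 %.
* **Food-group comparison** — median per-group energy shares under each
  method with a paired Wilcoxon signed-rank test, reported only for groups
  consumed by at least 10 % of respondents under both methods.

The design-stage sample size for detecting an improvement in correlation
with the benchmark (from rho0 to rho1) uses the Fisher z transformation:
n = ceil(((z_{1-alpha/2} + z_power) / (atanh(rho1) - atanh(rho0)))^2 + 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import atanh, ceil, log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .intake import IntakeTable, food_group_energy_shares
from .nutrients import NUTRIENTS

__all__ = [
    "EquivalenceResult",
    "BlandAltmanResult",
    "DiDResult",
    "ErrorBandRow",
    "DesignParams",
    "SampleSizeResult",
    "ValidationReport",
    "tost_equivalence",
    "bland_altman",
    "diff_in_differences",
    "error_band_table",
    "foodgroup_comparison",
    "sample_size_correlation",
    "power_simulation_correlation",
    "build_validation_report",
    "MEASURES",
]

#: Comparison measures reported at group level: item count, total gram
#: amount, then the ten nutrients.
MEASURES: tuple[str, ...] = ("item_count", "gram_total", *NUTRIENTS)

DEFAULT_BANDS: tuple[float, ...] = (10.0, 20.0, 30.0, 50.0)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class EquivalenceResult:
    measure: str
    n_pairs: int
    n_zero_excluded: int
    geo_mean_wfr: float
    geo_mean_r24: float
    mean_log_diff: float
    sd_log_diff: float
    bound: float  # theta on the log scale
    p_value: float
    equivalent: bool


@dataclass(frozen=True)
class BlandAltmanResult:
    measure: str
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    points: pd.DataFrame = field(repr=False)  # columns: mean, difference


@dataclass(frozen=True)
class DiDResult:
    measure: str
    mean_diff_capi: float  # mean (WFR - R24) in the CAPI arm
    mean_diff_papi: float
    estimate: float  # mean_diff_capi - mean_diff_papi
    se: float
    p_value: float
    n_capi: int
    n_papi: int


@dataclass(frozen=True)
class ErrorBandRow:
    measure: str
    n: int
    within: dict[float, float]  # band half-width (%) -> cumulative % of respondents
    over_pct: float  # error > widest band
    under_pct: float  # error < -widest band


@dataclass(frozen=True)
class DesignParams:
    """Design assumptions for the correlation-improvement sample size."""

    rho0: float = 0.60  # correlation considered unsatisfactory
    rho1: float = 0.75  # practically important improvement
    alpha: float = 0.05  # two-sided
    power: float = 0.80
    nonresponse_inflation: float = 0.125

    def __post_init__(self) -> None:
        if not 0.0 < self.rho0 < 1.0 or not 0.0 < self.rho1 < 1.0:
            raise ValueError("correlations must be in (0, 1)")
        if self.rho1 <= self.rho0:
            raise ValueError("rho1 must exceed rho0 (effect size would be <= 0)")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.nonresponse_inflation < 0.0:
            raise ValueError("nonresponse_inflation must be >= 0")


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_arm: int
    n_inflated: int
    params: DesignParams


@dataclass
class ValidationReport:
    """Per-measure group- and individual-level comparison results, per arm."""

    equivalence: pd.DataFrame  # arm x measure TOST results
    bland_altman: pd.DataFrame  # arm x measure bias and limits of agreement
    ba_points: pd.DataFrame  # long (arm, measure, respondent, mean, difference)
    did: pd.DataFrame  # per-measure difference-in-differences
    error_bands: pd.DataFrame  # arm x measure band percentages
    foodgroups: pd.DataFrame  # arm x group share comparison


# ---------------------------------------------------------------------------
# group-level statistics


def tost_equivalence(
    wfr: np.ndarray | pd.Series,
    r24: np.ndarray | pd.Series,
    bound_fraction: float = 0.10,
    alpha: float = 0.05,
    measure: str = "",
) -> EquivalenceResult:
    """Paired two one-sided t test of log-scale equivalence at a ratio bound.

    Pairs with a zero on either side are excluded from the log-scale test
    and tallied in ``n_zero_excluded``. With zero variance the decision is
    exact: p = 0 if |mean log diff| < theta else 1.
    """
    wfr = np.asarray(wfr, dtype=float)
    r24 = np.asarray(r24, dtype=float)
    if wfr.shape != r24.shape:
        raise ValueError("wfr and r24 must be the same length")
    if np.any(wfr < 0) or np.any(r24 < 0):
        raise ValueError("intakes cannot be negative")
    ok = (wfr > 0) & (r24 > 0)
    n_zero = int(np.sum(~ok))
    wfr, r24 = wfr[ok], r24[ok]
    n = len(wfr)
    if n < 2:
        raise ValueError(f"need >= 2 positive pairs, got {n}")
    if bound_fraction <= 0:
        raise ValueError("bound_fraction must be > 0")

    d = np.log(r24) - np.log(wfr)
    theta = log(1.0 + bound_fraction)
    dbar = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p = 0.0 if abs(dbar) < theta else 1.0
    else:
        se = sd / sqrt(n)
        p_lower = stats.t.sf((dbar + theta) / se, n - 1)  # H1: mean d > -theta
        p_upper = stats.t.cdf((dbar - theta) / se, n - 1)  # H1: mean d < theta
        p = float(max(p_lower, p_upper))
    return EquivalenceResult(
        measure=measure,
        n_pairs=n,
        n_zero_excluded=n_zero,
        geo_mean_wfr=float(np.exp(np.mean(np.log(wfr)))),
        geo_mean_r24=float(np.exp(np.mean(np.log(r24)))),
        mean_log_diff=dbar,
        sd_log_diff=sd,
        bound=theta,
        p_value=p,
        equivalent=bool(p < alpha),
    )


def bland_altman(
    wfr: np.ndarray | pd.Series, r24: np.ndarray | pd.Series, measure: str = ""
) -> BlandAltmanResult:
    """Mean bias (R24 - WFR) and 95 % limits of agreement, with plot points."""
    wfr = np.asarray(wfr, dtype=float)
    r24 = np.asarray(r24, dtype=float)
    if wfr.shape != r24.shape or len(wfr) < 2:
        raise ValueError("need >= 2 paired values of equal length")
    diff = r24 - wfr
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    points = pd.DataFrame({"mean": (wfr + r24) / 2.0, "difference": diff})
    return BlandAltmanResult(
        measure=measure,
        n=len(wfr),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        points=points,
    )


def diff_in_differences(long: pd.DataFrame, measure: str = "") -> DiDResult:
    """Difference-in-differences of (WFR - R24) between arms via a mixed model.

    ``long`` has one row per respondent x source with columns
    respondent_id, arm (CAPI | PAPI), source (WFR | R24), value. The model
    is value ~ is_wfr * is_capi with a respondent random intercept (REML);
    the interaction coefficient is the DiD estimate and its p-value uses a
    t reference with (number of respondents - 2) degrees of freedom.

    For complete pairs with the between-respondent variance component away
    from its zero boundary — the usual situation in intake data, where
    consumption levels differ across respondents far more than the
    within-pair recall error — this coincides with a pooled two-sample t
    test on the per-respondent differences.
    """
    import statsmodels.formula.api as smf

    required = {"respondent_id", "arm", "source", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"long frame must have columns {sorted(required)}")
    arms = long.groupby("respondent_id")["arm"].nunique()
    if (arms > 1).any():
        bad = arms.index[arms > 1][0]
        raise ValueError(f"respondent {bad} appears in both arms")

    df = long.copy()
    df["is_wfr"] = (df["source"] == "WFR").astype(float)
    df["is_capi"] = (df["arm"] == "CAPI").astype(float)

    wide = df.pivot_table(
        index=["respondent_id", "arm"], columns="source", values="value"
    ).dropna(subset=["WFR", "R24"])
    diffs = wide["WFR"] - wide["R24"]
    arm_idx = wide.index.get_level_values("arm")
    d_capi = diffs[arm_idx == "CAPI"]
    d_papi = diffs[arm_idx == "PAPI"]
    if len(d_capi) < 2 or len(d_papi) < 2:
        raise ValueError("need >= 2 complete pairs per arm")
    n_resp = len(d_capi) + len(d_papi)

    # pooled within-arm variance of the per-respondent differences; when it
    # vanishes (e.g. noise-free data) the model is singular and the decision
    # is exact
    ss = float(((d_capi - d_capi.mean()) ** 2).sum() + ((d_papi - d_papi.mean()) ** 2).sum())
    contrast = float(d_capi.mean() - d_papi.mean())
    if ss == 0.0:
        p = 1.0 if contrast == 0.0 else 0.0
        estimate, se = contrast, 0.0
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "value ~ is_wfr * is_capi", df, groups=df["respondent_id"]
                )
                fit = model.fit(reml=True, method="powell", maxiter=5000)
            estimate = float(fit.params["is_wfr:is_capi"])
            se = float(fit.bse["is_wfr:is_capi"])
        except np.linalg.LinAlgError:
            # numerically singular fit: use the closed form the balanced
            # random-intercept model reduces to
            estimate = contrast
            sp2 = ss / (n_resp - 2)
            se = sqrt(sp2 * (1.0 / len(d_capi) + 1.0 / len(d_papi)))
        if not np.isfinite(se) or se <= 0:
            raise RuntimeError(f"difference-in-differences fit failed for {measure!r}")
        p = float(2.0 * stats.t.sf(abs(estimate / se), n_resp - 2))
    return DiDResult(
        measure=measure,
        mean_diff_capi=float(d_capi.mean()),
        mean_diff_papi=float(d_papi.mean()),
        estimate=estimate,
        se=se,
        p_value=p,
        n_capi=len(d_capi),
        n_papi=len(d_papi),
    )


# ---------------------------------------------------------------------------
# individual-level statistics


def error_band_table(
    wfr: np.ndarray | pd.Series,
    r24: np.ndarray | pd.Series,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    measure: str = "",
    ids: list | None = None,
) -> ErrorBandRow:
    """Cumulative percentage of respondents within each percentage-error band.

    The error is e_i = 100 (R24_i - WFR_i) / WFR_i; band membership is
    boundary inclusive (|e| <= band). Respondents beyond the widest band are
    split into over- and underestimates. Zero WFR values make the error
    undefined and raise, naming the respondent.
    """
    wfr = np.asarray(wfr, dtype=float)
    r24 = np.asarray(r24, dtype=float)
    if wfr.shape != r24.shape or len(wfr) == 0:
        raise ValueError("need paired values of equal, nonzero length")
    if np.any(wfr == 0):
        which = np.flatnonzero(wfr == 0)
        label = [ids[i] for i in which] if ids is not None else list(which)
        raise ValueError(f"zero WFR value(s) for respondent(s) {label}: error undefined")
    bands = tuple(sorted(bands))
    e = 100.0 * (r24 - wfr) / wfr
    n = len(e)
    within = {b: float(100.0 * np.mean(np.abs(e) <= b)) for b in bands}
    widest = bands[-1]
    return ErrorBandRow(
        measure=measure,
        n=n,
        within=within,
        over_pct=float(100.0 * np.mean(e > widest)),
        under_pct=float(100.0 * np.mean(e < -widest)),
    )


def foodgroup_comparison(
    shares_wfr: pd.DataFrame,
    shares_r24: pd.DataFrame,
    min_consumer_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-group median energy shares with a paired signed-rank test.

    Inputs are respondent x group percentage-share frames for each method
    (same index and columns). Zero within-respondent differences are
    dropped; the exact null distribution is used for <= 25 nonzero pairs
    without ties, the normal approximation otherwise. The test p-value is
    suppressed (``reported`` False) for groups consumed by fewer than
    ``min_consumer_fraction`` of respondents under either method — small
    numbers make the test unreliable.
    """
    if shares_wfr.empty:
        raise ValueError("no respondents")
    shares_r24 = shares_r24.reindex(
        index=shares_wfr.index, columns=shares_wfr.columns
    ).fillna(0.0)
    rows = []
    n = len(shares_wfr)
    for group in shares_wfr.columns:
        w = shares_wfr[group].to_numpy(dtype=float)
        r = shares_r24[group].to_numpy(dtype=float)
        frac_w = float(np.mean(w > 0))
        frac_r = float(np.mean(r > 0))
        d = r - w
        nz = d[d != 0]
        note = ""
        if len(nz) == 0:
            p = np.nan
            note = "all paired differences zero; test undefined"
        else:
            absolute = np.abs(nz)
            exact_ok = len(nz) <= 25 and len(np.unique(absolute)) == len(absolute)
            res = stats.wilcoxon(
                nz, method="exact" if exact_ok else "approx", correction=not exact_ok
            )
            p = float(res.pvalue)
        reported = (
            frac_w >= min_consumer_fraction
            and frac_r >= min_consumer_fraction
            and not np.isnan(p)
        )
        rows.append(
            {
                "group": group,
                "n": n,
                "median_wfr": float(np.median(w)),
                "q25_wfr": float(np.percentile(w, 25)),
                "q75_wfr": float(np.percentile(w, 75)),
                "median_r24": float(np.median(r)),
                "q25_r24": float(np.percentile(r, 25)),
                "q75_r24": float(np.percentile(r, 75)),
                "consumer_frac_wfr": frac_w,
                "consumer_frac_r24": frac_r,
                "n_nonzero_diffs": int(len(nz)),
                "p_value": p,
                "reported": reported,
                "note": note,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# design-stage sample size


def sample_size_correlation(params: DesignParams = DesignParams()) -> SampleSizeResult:
    """Sample size per arm to detect a correlation improvement, via Fisher z."""
    q = atanh(params.rho1) - atanh(params.rho0)
    z_alpha = stats.norm.ppf(1.0 - params.alpha / 2.0)
    z_power = stats.norm.ppf(params.power)
    n = ceil(((z_alpha + z_power) / q) ** 2 + 3.0)
    n_inflated = ceil(n * (1.0 + params.nonresponse_inflation))
    return SampleSizeResult(n_per_arm=int(n), n_inflated=int(n_inflated), params=params)


def power_simulation_correlation(
    n: int,
    params: DesignParams = DesignParams(),
    n_replicates: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical power of the Fisher z test of rho = rho0 at true rho = rho1.

    Draws ``n_replicates`` samples of ``n`` bivariate-normal pairs with
    correlation rho1, tests H0: rho = rho0 two-sided at level alpha, and
    returns the rejection fraction (in the direction of improvement). This
    is the brute-force cross-check of :func:`sample_size_correlation`.
    """
    rng = np.random.default_rng(seed)
    rho = params.rho1
    x = rng.standard_normal((n_replicates, n))
    y = rho * x + sqrt(1.0 - rho**2) * rng.standard_normal((n_replicates, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = np.sum(xc * yc, axis=1) / np.sqrt(
        np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1)
    )
    z = np.arctanh(r)
    stat = (z - atanh(params.rho0)) * sqrt(n - 3)
    z_crit = stats.norm.ppf(1.0 - params.alpha / 2.0)
    return float(np.mean(stat > z_crit))


# ---------------------------------------------------------------------------
# full report


def build_validation_report(
    intakes: IntakeTable,
    bound_fraction: float = 0.10,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    min_consumer_fraction: float = 0.10,
    alpha: float = 0.05,
) -> ValidationReport:
    """Run every comparison on a (QC-filtered) intake table.

    Equivalence, Bland-Altman and error bands are computed per arm against
    that arm's WFR; the difference-in-differences contrasts the arms. Pairs
    with a zero WFR value are dropped from the error bands for that measure
    (tallied in ``n_dropped_zero_wfr``).
    """
    nut = intakes.nutrients
    eq_rows, ba_rows, band_rows, did_rows = [], [], [], []
    ba_points = []

    for measure in MEASURES:
        wide_all = nut[measure].astype(float).unstack("source")
        arm_of = nut["arm"].groupby("respondent_id").first()

        long = nut.reset_index()[["respondent_id", "arm", "source", measure]].rename(
            columns={measure: "value"}
        )
        did = diff_in_differences(long, measure=measure)
        did_rows.append(
            {
                "measure": measure,
                "mean_diff_capi": did.mean_diff_capi,
                "mean_diff_papi": did.mean_diff_papi,
                "estimate": did.estimate,
                "se": did.se,
                "p_value": did.p_value,
            }
        )

        for arm in ("CAPI", "PAPI"):
            ids = arm_of.index[arm_of == arm]
            wide = wide_all.loc[wide_all.index.intersection(ids)].dropna()
            wfr, r24 = wide["WFR"].to_numpy(), wide["R24"].to_numpy()

            eq = tost_equivalence(
                wfr, r24, bound_fraction=bound_fraction, alpha=alpha, measure=measure
            )
            eq_rows.append(
                {
                    "arm": arm,
                    "measure": measure,
                    "n_pairs": eq.n_pairs,
                    "n_zero_excluded": eq.n_zero_excluded,
                    "geo_mean_wfr": eq.geo_mean_wfr,
                    "geo_mean_r24": eq.geo_mean_r24,
                    "mean_log_diff": eq.mean_log_diff,
                    "sd_log_diff": eq.sd_log_diff,
                    "bound": eq.bound,
                    "p_value": eq.p_value,
                    "equivalent": eq.equivalent,
                }
            )

            ba = bland_altman(wfr, r24, measure=measure)
            ba_rows.append(
                {
                    "arm": arm,
                    "measure": measure,
                    "n": ba.n,
                    "bias": ba.bias,
                    "sd_diff": ba.sd_diff,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                }
            )
            pts = ba.points.copy()
            pts.insert(0, "respondent_id", list(wide.index))
            pts.insert(0, "measure", measure)
            pts.insert(0, "arm", arm)
            ba_points.append(pts)

            nonzero = wfr > 0
            band = error_band_table(
                wfr[nonzero], r24[nonzero], bands=bands, measure=measure
            )
            row = {
                "arm": arm,
                "measure": measure,
                "n": band.n,
                "n_dropped_zero_wfr": int(np.sum(~nonzero)),
                "over_pct": band.over_pct,
                "under_pct": band.under_pct,
            }
            row.update({f"within_{int(b)}_pct": v for b, v in band.within.items()})
            band_rows.append(row)

    # food-group share comparison per arm
    fg_frames = []
    shares = intakes.group_energy.div(intakes.group_energy.sum(axis=1), axis=0) * 100.0
    arm_of = nut["arm"].groupby("respondent_id").first()
    for arm in ("CAPI", "PAPI"):
        ids = arm_of.index[arm_of == arm]
        sub = shares.loc[shares.index.get_level_values("respondent_id").isin(ids)]
        w = sub.xs("WFR", level="source")
        r = sub.xs("R24", level="source")
        common = w.index.intersection(r.index)
        fg = foodgroup_comparison(
            w.loc[common], r.loc[common], min_consumer_fraction=min_consumer_fraction
        )
        fg.insert(0, "arm", arm)
        fg_frames.append(fg.reset_index())

    return ValidationReport(
        equivalence=pd.DataFrame(eq_rows),
        bland_altman=pd.DataFrame(ba_rows),
        ba_points=pd.concat(ba_points, ignore_index=True),
        did=pd.DataFrame(did_rows),
        error_bands=pd.DataFrame(band_rows),
        foodgroups=pd.concat(fg_frames, ignore_index=True),
    )
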