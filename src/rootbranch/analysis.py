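"""Per-sample analyses: distribution diagnostics, model fitting with
goodness of fit, and the fine/thick parent-root-diameter comparison.

A *sample* is one species x site collection of inter-branch distances, each
attached to the parent root it was measured on and that root's apical
diameter.  Samples used for the full analysis are expected to carry at
least 150 records (smaller samples are analysed but flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .calibration import CalibrationTable, estimate_params
from .errors import BinningError, SampleSizeError, SplitError
from .model import BranchingParams, simulate_ibd

__all__ = [
    "IBDSample",
    "FitResult",
    "DiameterSplitResult",
    "distribution_diagnostics",
    "goodness_of_fit",
    "fit_sample",
    "diameter_split_analysis",
    "panel_summary",
    "FULL_ANALYSIS_MIN_RECORDS",
]

#: inclusion rule for a full analysis: at least this many branch roots
FULL_ANALYSIS_MIN_RECORDS = 150


@dataclass
class IBDSample:
    """One species x site sample of inter-branch distances.

    ``records`` has columns ``parent_root_id``, ``parent_diameter_mm``,
    ``ibd_mm``; all distances and diameters strictly positive.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"parent_root_id", "parent_diameter_mm", "ibd_mm"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if (self.records["ibd_mm"] <= 0).any():
            raise ValueError("all IBD values must be strictly positive")
        if (self.records["parent_diameter_mm"] <= 0).any():
            raise ValueError("all parent diameters must be strictly positive")

    @property
    def ibd(self) -> np.ndarray:
        return self.records["ibd_mm"].to_numpy(dtype=float)

    @property
    def diameters(self) -> np.ndarray:
        return self.records["parent_diameter_mm"].to_numpy(dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters plus a chi-square goodness of fit for one sample."""

    sample_id: str
    params: BranchingParams
    chi2: float
    dof: int
    p_value: float
    n_obs: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "isd": self.params.isd,
            "cv_d": self.params.cv_d,
            "p_em": self.params.p_em,
            "chi2": self.chi2,
            "dof": self.dof,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "flags": ";".join(self.flags),
        }


@dataclass(frozen=True)
class DiameterSplitResult:
    """Separate fits for laterals on fine vs thick parent roots.

    The split threshold is the central diameter value,
    ``0.5 * (min diameter + max diameter)``; records exactly at the
    threshold go to the fine stratum.  Relative differences are
    ``(thick - fine) / (0.5 * (thick + fine))`` — symmetric and bounded.
    """

    sample_id: str
    threshold: float
    fine_fit: FitResult
    thick_fit: FitResult
    rel_diff_isd: float
    rel_diff_pem: float
    flags: tuple[str, ...] = ()


def _safe_test(func, *args, **kwargs):
    """Run a scipy test, returning (stat, p) or (nan, nan) on degenerate input."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = func(*args, **kwargs)
        return float(res.statistic), float(res.pvalue)
    except (ValueError, ZeroDivisionError):
        return float("nan"), float("nan")


def distribution_diagnostics(
    sample: IBDSample, correlation: str = "pearson", min_n: int = 8
) -> dict:
    """Distributional diagnostics of a sample's IBD values.

    Returns median, coefficient of variation, skewness, D'Agostino skewness
    test and Shapiro-Wilk p-values, the same on log-transformed IBD, and
    the correlation (default Pearson; ``correlation="spearman"`` for rank)
    between parent diameter and IBD.  Degenerate (constant) inputs yield
    NaN test results rather than an error.
    """
    x = sample.ibd
    if x.size < min_n:
        raise SampleSizeError(
            f"need at least {min_n} records for diagnostics, got {x.size}"
        )
    log_x = np.log(x)
    d = sample.diameters
    corr_func = stats.pearsonr if correlation == "pearson" else stats.spearmanr
    corr_r, corr_p = _safe_test(corr_func, d, x)

    def _moments(v: np.ndarray, prefix: str) -> dict:
        constant = np.ptp(v) == 0.0
        skew = float(stats.skew(v, bias=False)) if not constant else float("nan")
        _, ago_p = _safe_test(stats.skewtest, v) if not constant else (np.nan, np.nan)
        _, sw_p = _safe_test(stats.shapiro, v) if not constant else (np.nan, np.nan)
        return {
            f"{prefix}skewness": skew,
            f"{prefix}agostino_p": ago_p,
            f"{prefix}shapiro_p": sw_p,
        }

    out = {
        "sample_id": sample.sample_id,
        "n": int(x.size),
        "median": float(np.median(x)),
        "cv": float(np.std(x, ddof=1) / np.mean(x)) if x.size > 1 else float("nan"),
        **_moments(x, ""),
        **_moments(log_x, "log_"),
        "diameter_ibd_r": corr_r,
        "diameter_ibd_p": corr_p,
    }
    return out


def _decile_bins(reference: np.ndarray, n_obs: int, n_bins: int = 10,
                 min_expected: float = 5.0):
    """Bin edges from reference deciles, merged until expected counts >= 5.

    Returns (edges, expected_proportions).  Edges span (0, inf) so every
    positive observation falls in a bin.
    """
    inner = np.quantile(reference, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.concatenate([[0.0], np.unique(inner), [np.inf]])
    counts, _ = np.histogram(reference, bins=edges)
    props = counts / counts.sum()
    # merge the weakest bin into its smaller neighbour until all are viable
    while props.size > 1 and (props * n_obs).min() < min_expected:
        i = int(np.argmin(props))
        if i == 0:
            j = 1
        elif i == props.size - 1:
            j = i - 1
        else:
            j = i - 1 if props[i - 1] <= props[i + 1] else i + 1
        lo, hi = sorted((i, j))
        props = np.concatenate([props[:lo], [props[lo] + props[hi]], props[hi + 1:]])
        edges = np.delete(edges, hi)
    return edges, props


def goodness_of_fit(
    sample: IBDSample,
    params: BranchingParams,
    n_sim: int = 100_000,
    rng: np.random.Generator | None = None,
    flags: tuple[str, ...] = (),
) -> FitResult:
    """Chi-square comparison of a sample against the model at ``params``.

    A large simulation at ``params`` (``n_sim`` laterals) defines the
    reference distribution; bins are placed at its deciles and merged until
    every expected count is at least 5.  ``dof = bins - 1`` — parameters
    are estimated externally by indicator inversion, not from the binned
    likelihood, so the nominal dof is approximate (no Rao-style correction
    is applied).

    Raises
    ------
    BinningError
        If fewer than 4 usable bins remain after merging.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = sample.ibd
    reference = simulate_ibd(params, n_sim, rng)
    edges, props = _decile_bins(reference, x.size)
    if props.size < 4:
        raise BinningError(
            f"only {props.size} usable bins for sample {sample.sample_id!r}"
        )
    observed, _ = np.histogram(x, bins=edges)
    expected = props / props.sum() * x.size
    chi2, p_value = stats.chisquare(observed, f_exp=expected)
    return FitResult(
        sample_id=sample.sample_id,
        params=params,
        chi2=float(chi2),
        dof=int(props.size - 1),
        p_value=float(p_value),
        n_obs=int(x.size),
        flags=flags,
    )


def fit_sample(
    sample: IBDSample,
    table: CalibrationTable,
    rng: np.random.Generator,
    n_sim: int = 100_000,
    min_n: int = 30,
) -> FitResult:
    """Estimate parameters by indicator inversion, then test the fit.

    Samples below the 150-record inclusion floor are fitted anyway but
    flagged ``below_150_records``.
    """
    est = estimate_params(sample.ibd, table, min_n=min_n)
    flags = list(est.flags)
    if sample.n_records < FULL_ANALYSIS_MIN_RECORDS:
        flags.append("below_150_records")
    return goodness_of_fit(
        sample, est.params, n_sim=n_sim, rng=rng, flags=tuple(flags)
    )


def _symmetric_rel_diff(thick: float, fine: float) -> float:
    denom = 0.5 * (thick + fine)
    return float((thick - fine) / denom) if denom != 0 else float("nan")


def diameter_split_analysis(
    sample: IBDSample,
    table: CalibrationTable,
    rng: np.random.Generator,
    n_sim: int = 100_000,
    min_stratum: int = 30,
) -> DiameterSplitResult:
    """Fit the model separately on fine vs thick parent roots.

    The threshold is ``0.5 * (min + max diameter)``; ties go to the fine
    stratum.  Strata below ``min_stratum`` records are fitted (indicator
    floor relaxed to 8) but flagged.

    Raises
    ------
    SplitError
        If either stratum is empty or has fewer than 8 records.
    """
    d = sample.diameters
    threshold = 0.5 * (float(d.min()) + float(d.max()))
    fine_mask = d <= threshold
    flags: list[str] = []
    strata: dict[str, FitResult] = {}
    for name, mask in (("fine", fine_mask), ("thick", ~fine_mask)):
        n = int(mask.sum())
        if n < 8:
            raise SplitError(
                f"{name} stratum of sample {sample.sample_id!r} has {n} records"
            )
        if n < min_stratum:
            flags.append(f"{name}_stratum_below_floor")
        sub = IBDSample(
            sample_id=f"{sample.sample_id}/{name}",
            records=sample.records.loc[mask].reset_index(drop=True),
        )
        strata[name] = fit_sample(sub, table, rng, n_sim=n_sim, min_n=8)
    fine_fit, thick_fit = strata["fine"], strata["thick"]
    return DiameterSplitResult(
        sample_id=sample.sample_id,
        threshold=float(threshold),
        fine_fit=fine_fit,
        thick_fit=thick_fit,
        rel_diff_isd=_symmetric_rel_diff(thick_fit.params.isd, fine_fit.params.isd),
        rel_diff_pem=_symmetric_rel_diff(thick_fit.params.p_em, fine_fit.params.p_em),
        flags=tuple(flags),
    )


def _corr_or_nan(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    return _safe_test(stats.pearsonr, x, y)


def panel_summary(
    fits: list[FitResult],
    splits: list[DiameterSplitResult] | None = None,
    samples: list[IBDSample] | None = None,
) -> dict:
    """Panel-level synthesis of per-sample fits and diameter splits.

    Reports per-parameter ranges and fold factors, cross-parameter
    correlations (R^2), and — when splits are given — the correlation
    between relative ISD and P_em differences, the paired fine/thick ISD
    comparison, and the thick-vs-fine ISD regression against the identity
    line.  When raw samples are given, a one-way ANOVA of log(IBD) on the
    sample factor is included.  Undefined statistics (degenerate panels)
    are reported as NaN, never raised.
    """
    if len(fits) < 2:
        raise ValueError("panel_summary needs at least 2 fits")
    p = pd.DataFrame(
        {
            "isd": [f.params.isd for f in fits],
            "cv_d": [f.params.cv_d for f in fits],
            "p_em": [f.params.p_em for f in fits],
        }
    )
    out: dict = {"n_samples": len(fits)}
    for col in ("isd", "cv_d", "p_em"):
        v = p[col].to_numpy()
        out[f"{col}_min"] = float(v.min())
        out[f"{col}_max"] = float(v.max())
        out[f"{col}_fold"] = float(v.max() / v.min()) if v.min() > 0 else float("nan")
    for a, b in (("isd", "cv_d"), ("isd", "p_em"), ("cv_d", "p_em")):
        r, pv = _corr_or_nan(p[a].to_numpy(), p[b].to_numpy())
        out[f"r2_{a}_{b}"] = r**2 if np.isfinite(r) else float("nan")
        out[f"p_{a}_{b}"] = pv
    out["n_rejected_05"] = int(sum(f.p_value < 0.05 for f in fits))

    if splits:
        rd_isd = np.array([s.rel_diff_isd for s in splits])
        rd_pem = np.array([s.rel_diff_pem for s in splits])
        r, pv = _corr_or_nan(rd_isd, rd_pem)
        out["reldiff_isd_pem_r"] = r
        out["reldiff_isd_pem_p"] = pv
        fine = np.array([s.fine_fit.params.isd for s in splits])
        thick = np.array([s.thick_fit.params.isd for s in splits])
        _, paired_p = _safe_test(stats.ttest_rel, fine, thick)
        out["isd_fine_thick_paired_p"] = paired_p
        if np.ptp(fine) > 0 and fine.size >= 3:
            ols = sm.OLS(thick, sm.add_constant(fine)).fit()
            lo, hi = ols.conf_int()[1]
            out["isd_thick_on_fine_slope"] = float(ols.params[1])
            out["isd_slope_ci_low"] = float(lo)
            out["isd_slope_ci_high"] = float(hi)
            out["isd_slope_ci_covers_1"] = bool(lo <= 1.0 <= hi)
        else:
            out["isd_thick_on_fine_slope"] = float("nan")

    if samples:
        df = pd.concat(
            [
                pd.DataFrame(
                    {"log_ibd": np.log(s.ibd), "sample_id": s.sample_id}
                )
                for s in samples
            ],
            ignore_index=True,
        )
        if df["sample_id"].nunique() >= 2:
            model = smf.ols("log_ibd ~ C(sample_id)", data=df).fit()
            anova = sm.stats.anova_lm(model, typ=1)
            out["anova_species_F"] = float(anova["F"].iloc[0])
            out["anova_species_p"] = float(anova["PR(>F)"].iloc[0])
    return out
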