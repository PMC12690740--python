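"""Diel foraging-activity analysis of per-frame detections.

Detections from 24-h recordings are binned into clock-aligned 10-min bins;
each recorder's day is summarised by its frame-weighted mean detection
rate (positive frames / frames), a sensitivity-scaled rate correcting for
the detector's per-plant sensitivity, and the time of its peak-activity
bin expressed as a day fraction (0 = midnight, 0.5 = noon).  Two analyses
compare plant groups:

* a beta regression of the scaled rate on group — maximum-likelihood fit
  of a beta density parameterised by mean μ (logit link) and precision φ;
* an ordinary least-squares model of peak time on group.

Both are followed by all pairwise group contrasts with Tukey–Kramer
adjustment via the studentized-range distribution (normal approximation
for the beta model, residual-df version for the linear model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import studentized_range

__all__ = [
    "ActivityBin",
    "RecorderDaySummary",
    "BetaRegressionFit",
    "Contrast",
    "bin_detections",
    "summarize_recorder",
    "fit_beta_regression",
    "pairwise_contrasts",
    "fit_group_lm",
]

SECONDS_PER_DAY = 86_400
_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class ActivityBin:
    recorder_id: str
    bin_start_clock: float  # seconds since midnight
    bin_width_s: float
    n_frames: int
    n_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_frames):
            raise ValueError("require 0 <= n_positive <= n_frames")

    @property
    def detection_rate(self) -> float:
        return self.n_positive / self.n_frames if self.n_frames else float("nan")


@dataclass(frozen=True)
class RecorderDaySummary:
    recorder_id: str
    group: str
    mean_rate: float
    plant_sensitivity: float
    scaled_rate: float
    peak_time: float  # day fraction in [0, 1)


@dataclass(frozen=True)
class BetaRegressionFit:
    coefficients: dict[str, float]  # logit-scale mean model, treatment coding
    phi: float
    log_likelihood: float
    cov: np.ndarray  # coefficient covariance (mean model block)
    groups: tuple[str, ...]
    converged: bool
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    estimate: float
    std_error: float
    statistic: float
    p_adjusted: float


def bin_detections(
    starts: Sequence[float],
    detected: Sequence[bool],
    recorder_id: str,
    recording_start_clock: float,
    bin_width_s: float = 600.0,
) -> list[ActivityBin]:
    """Assign frames to clock-aligned bins by their start timestamp.

    ``recording_start_clock`` is the wall-clock second of the first sample;
    frame clock times wrap at midnight.  Totals are conserved: bin frame
    and positive counts sum to the table totals.
    """
    starts = np.asarray(starts, dtype=np.float64)
    det = np.asarray(detected, dtype=bool)
    if starts.shape != det.shape:
        raise ValueError("starts and detected must have equal length")
    clock = (recording_start_clock + starts) % SECONDS_PER_DAY
    idx = np.floor(clock / bin_width_s).astype(int)
    bins = []
    for b in np.unique(idx):
        sel = idx == b
        bins.append(
            ActivityBin(
                recorder_id=recorder_id,
                bin_start_clock=float(b * bin_width_s),
                bin_width_s=float(bin_width_s),
                n_frames=int(sel.sum()),
                n_positive=int(det[sel].sum()),
            )
        )
    return bins


def summarize_recorder(
    bins: Sequence[ActivityBin],
    group: str,
    plant_sensitivity: float,
) -> RecorderDaySummary:
    """Collapse one recorder's bins to the quantities the models consume.

    ``mean_rate`` is frame-weighted so partial bins at recording edges do
    not distort the daily mean.  ``peak_time`` is the midpoint of the
    highest-rate bin (ties -> earliest) as a day fraction.  ``scaled_rate``
    divides by the plant's sensitivity and clamps into (0, 1) for the beta
    likelihood.
    """
    if not bins:
        raise ValueError("summarize_recorder needs at least one bin")
    if not (0 < plant_sensitivity <= 1):
        raise ValueError("plant_sensitivity must be in (0, 1]")
    n_frames = sum(b.n_frames for b in bins)
    n_pos = sum(b.n_positive for b in bins)
    mean_rate = n_pos / n_frames if n_frames else float("nan")
    best = max(bins, key=lambda b: (b.detection_rate, -b.bin_start_clock))
    peak_time = (best.bin_start_clock + best.bin_width_s / 2.0) / SECONDS_PER_DAY
    scaled = mean_rate / plant_sensitivity
    scaled = min(max(scaled, _CLAMP_EPS), 1.0 - _CLAMP_EPS)
    return RecorderDaySummary(
        recorder_id=bins[0].recorder_id,
        group=group,
        mean_rate=mean_rate,
        plant_sensitivity=plant_sensitivity,
        scaled_rate=scaled,
        peak_time=peak_time % 1.0,
    )


def _beta_negloglik(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    beta, log_phi = params[:-1], params[-1]
    mu = expit(X @ beta)
    phi = np.exp(log_phi)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
    return -float(np.sum(ll))


def fit_beta_regression(
    summaries: Sequence[RecorderDaySummary],
    response: Literal["scaled_rate"] = "scaled_rate",
    max_iter: int = 500,
) -> BetaRegressionFit:
    """Maximum-likelihood beta regression of the response on group.

    Mean model: logit(μ_i) = β0 + β_g (treatment coding, first group
    alphabetically as reference); common precision φ.  Standard errors come
    from the inverse observed information at the MLE.  Moment estimates of
    (μ, φ) seed the optimiser; the MLE's likelihood is checked against the
    seed's.
    """
    y = np.asarray([getattr(s, response) for s in summaries], dtype=np.float64)
    groups = [s.group for s in summaries]
    levels = tuple(sorted(set(groups)))
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 observations per group")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly in (0, 1)")

    X = np.column_stack(
        [np.ones(y.size)] + [(np.asarray(groups) == g).astype(float) for g in levels[1:]]
    )
    names = ["(Intercept)"] + [f"group[{g}]" for g in levels[1:]]

    # moment-based start: group means on logit scale, phi from pooled variance
    gmeans = {g: y[np.asarray(groups) == g].mean() for g in levels}
    mu0 = np.clip(np.array([gmeans[g] for g in groups]), 1e-4, 1 - 1e-4)
    resid_var = max(float(np.var(y - mu0)), 1e-6)
    mu_bar = float(np.mean(mu0))
    phi0 = max(mu_bar * (1 - mu_bar) / resid_var - 1.0, 1.0)
    beta0 = [float(np.log(gmeans[levels[0]] / (1 - gmeans[levels[0]])))]
    beta0 += [
        float(np.log(gmeans[g] / (1 - gmeans[g]))) - beta0[0] for g in levels[1:]
    ]
    x0 = np.array(beta0 + [np.log(phi0)])

    res = minimize(
        _beta_negloglik,
        x0,
        args=(X, y),
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    # observed information via central differences for honest SEs
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, _beta_negloglik, args=(X, y))
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
    k = X.shape[1]
    fit = BetaRegressionFit(
        coefficients=dict(zip(names, res.x[:-1])),
        phi=float(np.exp(res.x[-1])),
        log_likelihood=-float(res.fun),
        cov=cov_all[:k, :k],
        groups=levels,
        converged=bool(res.success),
        group_means={
            g: float(expit(res.x[0] + (res.x[1 + levels[1:].index(g)] if g != levels[0] else 0.0)))
            for g in levels
        },
    )
    return fit


def _beta_linpred_cov(fit: BetaRegressionFit) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor per group and its covariance under treatment coding."""
    k = len(fit.groups)
    beta = np.array(list(fit.coefficients.values()))
    L = np.zeros((k, beta.size))
    L[:, 0] = 1.0
    for i in range(1, k):
        L[i, i] = 1.0
    eta = L @ beta
    cov = L @ fit.cov @ L.T
    return eta, cov


def tukey_p(statistic: float, k: int, df: float = np.inf) -> float:
    """Two-sided Tukey–Kramer p-value from the studentized-range law.

    For k = 2 this reduces to the unadjusted two-sided test.
    """
    q = abs(statistic) * np.sqrt(2.0)
    return float(np.clip(studentized_range.sf(q, k, df), 0.0, 1.0))


def pairwise_contrasts(
    fit: "BetaRegressionFit | GroupLMFit",
    adjust: Literal["tukey", "none"] = "tukey",
) -> list[Contrast]:
    """All pairwise group differences with multiplicity adjustment.

    Beta-regression contrasts are on the link (logit) scale with a normal
    approximation; linear-model contrasts are on the response scale with
    residual degrees of freedom.
    """
    if isinstance(fit, BetaRegressionFit):
        eta, cov = _beta_linpred_cov(fit)
        groups, df = fit.groups, np.inf
    else:
        eta, cov = fit.group_mean_vector, fit.group_mean_cov
        groups, df = fit.groups, fit.df_resid
    k = len(groups)
    if k < 2:
        raise ValueError("contrasts need at least 2 groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            est = float(eta[i] - eta[j])
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            stat = est / se if se > 0 else np.inf
            if adjust == "tukey":
                p = tukey_p(stat, k, df)
            else:
                from scipy.stats import norm, t as t_dist

                dist = norm if np.isinf(df) else t_dist(df)
                p = float(2 * dist.sf(abs(stat)))
            out.append(Contrast(groups[i], groups[j], est, se, stat, p))
    return out


@dataclass(frozen=True)
class GroupLMFit:
    """OLS of a response on group, with what contrasts need."""

    groups: tuple[str, ...]
    group_mean_vector: np.ndarray
    group_mean_cov: np.ndarray
    df_resid: float
    residuals: np.ndarray
    r_squared: float
    qq_correlation: float  # straightness of the normal Q-Q plot of residuals


def fit_group_lm(
    summaries: Sequence[RecorderDaySummary],
    response: Literal["peak_time"] = "peak_time",
) -> tuple[GroupLMFit, list[Contrast]]:
    """OLS of peak foraging time on group plus Tukey-adjusted contrasts.

    Group estimates are the arithmetic per-group means (cell-means OLS);
    the Q-Q correlation of residuals against normal quantiles is reported
    as a residual-normality diagnostic.
    """
    y = np.asarray([getattr(s, response) for s in summaries], dtype=np.float64)
    groups = np.asarray([s.group for s in summaries])
    levels = tuple(sorted(set(groups)))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    X = np.column_stack([(groups == g).astype(float) for g in levels])  # cell means
    model = sm.OLS(y, X).fit()
    means = model.params
    cov = model.cov_params()
    resid = model.resid
    from scipy.stats import norm

    order = np.argsort(resid)
    n = resid.size
    theo = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    if n > 2 and np.std(resid) > 1e-14:
        qq_r = float(np.corrcoef(theo, resid[order])[0, 1])
    else:
        qq_r = float("nan")
    fit = GroupLMFit(
        groups=levels,
        group_mean_vector=np.asarray(means),
        group_mean_cov=np.asarray(cov),
        df_resid=float(model.df_resid),
        residuals=np.asarray(resid),
        r_squared=float(model.rsquared),
        qq_correlation=qq_r,
    )
    return fit, pairwise_contrasts(fit, adjust="tukey")
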