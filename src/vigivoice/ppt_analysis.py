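"""Mixed-effects analysis of psychophysiological test scores.

Each PPT score is regressed on sleep latency (hours awake) and the
circadian phase covariate with a random intercept per subject:

    y_ij = b0 + bL * L_ij + bP * P_ij + u_i + e_ij,
    u_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2).

Models are fitted by maximum likelihood (not REML) so that fixed-effect
likelihood-ratio comparisons between nested models are valid. The
significance of each factor is assessed by refitting without it and
referring twice the log-likelihood difference to chi-squared(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import PPT_TESTS

__all__ = ["MixedModelFit", "fit_mixed", "lrt_factor", "analysis_table"]


@dataclass
class MixedModelFit:
    """Result of one mixed-model fit (ML)."""

    params: dict[str, float]          # intercept, latency, phase
    bse: dict[str, float]             # standard errors of the above
    sigma_b2: float                   # subject random-intercept variance
    sigma_e2: float                   # residual variance
    loglike: float
    converged: bool
    boundary: bool                    # random-effect variance pinned near 0

    def coef(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> float:
        return self.bse[name]


def _fit(df: pd.DataFrame, fixed: list[str]) -> MixedModelFit:
    rhs = " + ".join(fixed) if fixed else "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"score ~ {rhs}", df, groups=df["subject_id"])
        try:
            res = model.fit(reml=False, maxiter=500)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell", maxiter=1000)
    params = {"intercept": float(res.params["Intercept"])}
    bse = {"intercept": float(res.bse["Intercept"])}
    for name in fixed:
        params[name] = float(res.params[name])
        bse[name] = float(res.bse[name])
    sigma_b2 = float(res.cov_re.iloc[0, 0])
    sigma_e2 = float(res.scale)
    boundary = sigma_b2 < 1e-8 * max(sigma_e2, 1e-12)
    return MixedModelFit(
        params=params, bse=bse, sigma_b2=sigma_b2, sigma_e2=sigma_e2,
        loglike=float(res.llf), converged=bool(res.converged),
        boundary=boundary)


def fit_mixed(
    scores: np.ndarray,
    latency_h: np.ndarray,
    phase: np.ndarray,
    subject_ids: np.ndarray,
) -> MixedModelFit:
    """ML fit of score ~ latency + phase + (1 | subject).

    Latency is entered in hours awake; phase is the cosine time-of-day
    covariate in [-1, 1]. Requires at least two subjects with at least
    three observations each. A fit whose random-intercept variance is
    pinned at the zero boundary is flagged (``boundary``), in which case
    the fixed effects coincide with ordinary least squares.
    """
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=np.float64),
        "latency": np.asarray(latency_h, dtype=np.float64),
        "phase": np.asarray(phase, dtype=np.float64),
        "subject_id": np.asarray(subject_ids),
    })
    counts = df.groupby("subject_id").size()
    if len(counts) < 2:
        raise ValueError("mixed model needs >= 2 subjects")
    if (counts < 3).any():
        raise ValueError("mixed model needs >= 3 observations per subject")
    return _fit(df, ["latency", "phase"])


def lrt_factor(
    scores: np.ndarray,
    latency_h: np.ndarray,
    phase: np.ndarray,
    subject_ids: np.ndarray,
    factor: str,
) -> float:
    """Likelihood-ratio p-value for dropping one fixed factor.

    Fits the full model and the model without ``factor`` (both by ML)
    and returns the upper chi-squared(1) tail of twice the log-likelihood
    difference. A numerically negative statistic is clamped to 0.
    """
    if factor not in ("latency", "phase"):
        raise ValueError(f"factor must be 'latency' or 'phase', got {factor!r}")
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=np.float64),
        "latency": np.asarray(latency_h, dtype=np.float64),
        "phase": np.asarray(phase, dtype=np.float64),
        "subject_id": np.asarray(subject_ids),
    })
    full = _fit(df, ["latency", "phase"])
    reduced = _fit(df, ["phase" if factor == "latency" else "latency"])
    stat = 2.0 * (full.loglike - reduced.loglike)
    if stat < 0.0:
        warnings.warn(f"negative LRT statistic {stat:.3g} clamped to 0")
        stat = 0.0
    return float(chi2.sf(stat, df=1))


def analysis_table(data: pd.DataFrame) -> pd.DataFrame:
    """Coefficient + p-value table for all four PPT tests.

    ``data`` must carry subject_id, latency_h, phase, and one column per
    test. Latency coefficients are in test units per hour awake; phase
    coefficients in test units per unit of the cosine covariate.
    """
    rows = []
    for test in PPT_TESTS:
        fit = fit_mixed(data[test].to_numpy(), data["latency_h"].to_numpy(),
                        data["phase"].to_numpy(), data["subject_id"].to_numpy())
        p_lat = lrt_factor(data[test].to_numpy(), data["latency_h"].to_numpy(),
                           data["phase"].to_numpy(), data["subject_id"].to_numpy(),
                           "latency")
        p_ph = lrt_factor(data[test].to_numpy(), data["latency_h"].to_numpy(),
                          data["phase"].to_numpy(), data["subject_id"].to_numpy(),
                          "phase")
        rows.append({
            "test": test,
            "latency_coef_per_h": fit.coef("latency"),
            "latency_se": fit.se("latency"),
            "p_latency": p_lat,
            "phase_coef_per_unit": fit.coef("phase"),
            "phase_se": fit.se("phase"),
            "p_phase": p_ph,
            "sigma_b2": fit.sigma_b2,
            "sigma_e2": fit.sigma_e2,
        })
    return pd.DataFrame(rows)
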