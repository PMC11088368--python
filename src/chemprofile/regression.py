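"""Mixed-model contrasts of alpha diversity and beta regression of
substance detectability on retention time.

The alpha-diversity models are linear mixed models: Shannon index or
richness regressed on sex and days after laying (optionally their
interaction) with a random intercept per breeding pair, fitted by REML.
Fixed effects are judged by whether the Wald 95% CI contains zero.

Detectability (the proportion of samples in which each substance occurs) is
modelled as a beta regression with a logit link on the mean and a constant
precision parameter phi, with an orthogonal polynomial of retention time as
the predictor.  Proportions of exactly 0 or 1 lie outside the beta support
and are shrunk inward by y' = (y (N - 1) + 0.5) / N before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.othermod.betareg import BetaModel
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LmmFit",
    "BetaRegFit",
    "fit_alpha_lmm",
    "fit_detectability_betareg",
    "orthogonal_polynomial",
    "shrink_proportions",
]


@dataclass
class LmmFit:
    """Fixed-effect estimates of a random-intercept mixed model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    conf_low: np.ndarray
    conf_high: np.ndarray
    pair_variance: float
    residual_variance: float
    n_obs: int
    converged: bool
    boundary: bool  # pair variance estimated at (or collapsed to) zero
    method: str  # "reml" or "ols"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "conf_low": self.conf_low,
                "conf_high": self.conf_high,
            }
        )

    def significant(self) -> dict[str, bool]:
        """Does the 95% CI exclude zero, per non-intercept term?"""
        return {
            t: not (lo <= 0.0 <= hi)
            for t, lo, hi in zip(self.terms, self.conf_low, self.conf_high)
            if t != "intercept"
        }


def _lmm_design(meta: pd.DataFrame, include_interaction: bool):
    sex = (meta["sex"].to_numpy() == "male").astype(float)
    days = meta["days_after_laying"].to_numpy(dtype=float)
    cols = {"intercept": np.ones(len(meta)), "sex_male": sex, "days_after_laying": days}
    if include_interaction:
        cols["sex_male:days_after_laying"] = sex * days
    return pd.DataFrame(cols)


def fit_alpha_lmm(
    response: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    include_interaction: bool = True,
    ci_level: float = 0.95,
) -> LmmFit:
    """Mixed model: response ~ sex + days (+ sex:days) + (1 | pair).

    Samples without a pair id form singleton groups.  When every group is a
    singleton the pair variance is unidentifiable and the model reduces
    exactly to ordinary least squares, which is then fitted directly.  A
    REML fit whose pair variance collapses to zero is returned with the
    ``boundary`` flag set, not raised.
    """
    y = np.asarray(response, dtype=float)
    biol = meta[~meta["is_blank"]] if "is_blank" in meta.columns else meta
    if len(y) != len(biol):
        raise ValueError("response length does not match non-blank samples")
    X = _lmm_design(biol, include_interaction)
    groups = biol["pair_id"].fillna("solo_" + biol["sample_id"].astype(str)).to_numpy()
    # t quantile with residual df: at n ~ 20 the plain normal quantile makes
    # Wald intervals visibly too short
    z = stats.t.ppf(0.5 + ci_level / 2, df=max(len(y) - X.shape[1], 1))

    all_singleton = pd.Series(groups).value_counts().max() == 1
    if all_singleton:
        res = sm.OLS(y, X).fit()
        beta, se = res.params.to_numpy(), res.bse.to_numpy()
        return LmmFit(
            terms=list(X.columns),
            beta=beta,
            se=se,
            conf_low=beta - z * se,
            conf_high=beta + z * se,
            pair_variance=0.0,
            residual_variance=float(res.scale),
            n_obs=len(y),
            converged=True,
            boundary=True,
            method="ols",
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    beta = np.asarray(res.fe_params)
    with np.errstate(invalid="ignore"):
        se = np.asarray(res.bse_fe)
    pair_var = float(np.asarray(res.cov_re)[0, 0])
    return LmmFit(
        terms=list(X.columns),
        beta=beta,
        se=se,
        conf_low=beta - z * se,
        conf_high=beta + z * se,
        pair_variance=pair_var,
        residual_variance=float(res.scale),
        n_obs=len(y),
        converged=bool(res.converged),
        boundary=pair_var < 1e-8 * max(float(res.scale), 1.0),
        method="reml",
    )


def orthogonal_polynomial(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of ``x`` (no intercept column).

    Columns are mutually orthogonal with unit sum of squares and orthogonal
    to the constant, matching the convention of orthogonalised polynomial
    regressors; signs are fixed so each column correlates positively with
    the corresponding raw power.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no spread in x")
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Z = Q[:, 1:]
    for j in range(degree):
        if Z[:, j] @ V[:, j + 1] < 0:
            Z[:, j] = -Z[:, j]
    return Z


def shrink_proportions(y: np.ndarray, n: int) -> np.ndarray:
    """Move proportions off the {0, 1} boundary: y' = (y (n - 1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """Beta-regression fit of detectability against a retention-time polynomial."""

    terms: list[str]
    beta: np.ndarray  # logit-mean scale coefficients
    se: np.ndarray
    p_values: np.ndarray  # Wald
    phi: float  # precision
    log_likelihood: float
    boundary_transformed: bool
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "P": self.p_values,
            }
        )


def fit_detectability_betareg(
    table: pd.DataFrame,
    degree: int = 2,
    raw_basis: bool = False,
) -> BetaRegFit:
    """Polynomial beta regression of detection proportion on retention time.

    ``table`` is a detectability profile with columns ``consensus_rt`` and
    ``detection_proportion`` (one row per substance).  The mean is
    logit-linked with constant precision phi; retention time enters through
    an orthogonal polynomial basis of the given degree (``raw_basis=True``
    uses centred raw powers instead).  Wald P-values per coefficient.
    """
    rt = table["consensus_rt"].to_numpy(dtype=float)
    y = table["detection_proportion"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("detection proportions must lie in [0, 1]")
    n = len(y)
    on_boundary = bool(((y == 0) | (y == 1)).any())
    if on_boundary:
        y = shrink_proportions(y, n)
    if raw_basis:
        c = rt - rt.mean()
        Z = np.column_stack([c**k for k in range(1, degree + 1)])
    else:
        Z = orthogonal_polynomial(rt, degree)
    X = sm.add_constant(Z)
    names = ["intercept"] + [f"rt^{k}" for k in range(1, degree + 1)]

    model = BetaModel(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", True):
        grad = np.linalg.norm(model.score(res.params))
        raise RuntimeError(f"beta regression did not converge (|gradient| = {grad:.3g})")
    k = X.shape[1]
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    phi = float(np.exp(params[k]))  # precision is log-linked
    return BetaRegFit(
        terms=names,
        beta=params[:k],
        se=se[:k],
        p_values=pvals[:k],
        phi=phi,
        log_likelihood=float(res.llf),
        boundary_transformed=on_boundary,
        converged=True,
    )
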