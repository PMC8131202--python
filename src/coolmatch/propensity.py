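"""Propensity model: probability of being enterally fed given background variables.

Maximum-likelihood logistic regression (Newton, relative log-likelihood
tolerance 1e-8, at most 100 iterations) of the FED indicator on every
covariate column of the analysis table, with a ridge-stabilised fallback
(penalty 1e-6) when the likelihood is unbounded under perfect separation.
Extreme-propensity babies are then removed: outside the common support of
the two groups' score ranges, then outside fixed caps (default [0.01, 0.99]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .derive import AnalysisTable

logger = logging.getLogger(__name__)

__all__ = ["PropensityFit", "fit_propensity", "exclude_extreme"]


@dataclass
class PropensityFit:
    params: pd.Series  # intercept ('const') + one coefficient per kept column
    bse: pd.Series
    linear_predictor: pd.Series  # per infant_id
    score: pd.Series  # per infant_id, in (0, 1)
    converged: bool
    used_ridge: bool
    dropped_columns: list[str] = field(default_factory=list)
    llf: float = float("nan")

    def summary_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: (None if np.isnan(v) else float(v)) for k, v in self.bse.items()},
            "converged": bool(self.converged),
            "used_ridge": bool(self.used_ridge),
            "dropped_columns": list(self.dropped_columns),
            "log_likelihood": None if np.isnan(self.llf) else float(self.llf),
        }


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant and linearly dependent columns (QR with pivoting)."""
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        return X, dropped
    M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    r = qr(M, mode="r", pivoting=True)
    R, piv = r[0], r[1]
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(M.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    redundant = sorted(piv[rank:])
    names = ["const"] + list(X.columns)
    more = [names[j] for j in redundant if j > 0]
    dropped += more
    return X.drop(columns=more), dropped


def fit_propensity(analysis: AnalysisTable, covariate_columns: list[str] | None = None) -> PropensityFit:
    """Fit the propensity of enteral feeding on all covariate columns."""
    df = analysis.df
    cols = covariate_columns if covariate_columns is not None else analysis.covariate_columns
    y = (df["exposure"] == "FED").astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("cannot fit propensity model: only one exposure group present")

    X, dropped = _drop_collinear(df[cols])
    if dropped:
        logger.warning("dropped %d constant/collinear covariate column(s): %s", len(dropped), dropped)
    Xc = sm.add_constant(X.to_numpy(float), prepend=True)
    names = ["const"] + list(X.columns)

    model = sm.Logit(y, Xc)
    used_ridge = False
    converged = False
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:  # perfect separation or singular Hessian
        res = None
    if res is None or not converged or not np.all(np.isfinite(res.params)):
        logger.warning("logistic fit unstable; falling back to ridge-stabilised fit (penalty 1e-6)")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(alpha=1e-6, L1_wt=0.0, disp=0, maxiter=200)
        used_ridge = True
        converged = True

    params = pd.Series(np.asarray(res.params, float), index=names)
    try:
        bse = pd.Series(np.asarray(res.bse, float), index=names)
    except Exception:
        bse = pd.Series(np.nan, index=names)
    lp = Xc @ params.to_numpy()
    score = 1.0 / (1.0 + np.exp(-lp))
    idx = pd.Index(df["infant_id"])
    return PropensityFit(
        params=params,
        bse=bse,
        linear_predictor=pd.Series(lp, index=idx, name="linear_predictor"),
        score=pd.Series(score, index=idx, name="score"),
        converged=converged,
        used_ridge=used_ridge,
        dropped_columns=dropped,
        llf=float(getattr(res, "llf", np.nan)),
    )


def exclude_extreme(
    analysis: AnalysisTable,
    fit: PropensityFit,
    caps: tuple[float, float] = (0.01, 0.99),
    common_support: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop babies with extreme propensity.

    Default policy: scores outside the overlap of the two groups' score
    ranges, then outside the fixed caps.  Returns the filtered table (with a
    ``score`` column) and the exclusion log.
    """
    df = analysis.df.copy()
    df["score"] = fit.score.reindex(df["infant_id"]).to_numpy()
    keep = pd.Series(True, index=df.index)
    if common_support:
        fed = df["exposure"] == "FED"
        lo = max(df.loc[fed, "score"].min(), df.loc[~fed, "score"].min())
        hi = min(df.loc[fed, "score"].max(), df.loc[~fed, "score"].max())
        keep &= (df["score"] >= lo) & (df["score"] <= hi)
    keep &= (df["score"] >= caps[0]) & (df["score"] <= caps[1])
    exclusions = [
        {"infant_id": r.infant_id, "reason": "extreme propensity", "score": float(r.score)}
        for r in df.loc[~keep, ["infant_id", "score"]].itertuples()
    ]
    filtered = df.loc[keep].reset_index(drop=True)
    if len(filtered) == 0:
        raise ValueError("extreme-propensity exclusion removed every baby")
    return filtered, exclusions
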