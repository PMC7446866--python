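"""Development/validation splitting, class rebalancing, and logistic modelling.

The modelling workflow mirrors a rare-outcome classification study: stratify
the cohort on the observed outcome, assign 75% of each stratum to a
development sample, rebalance the development sample by downsampling the
majority class 1:1, fit a main-effects binary logistic regression by
iteratively reweighted least squares (IRLS), and score the untouched
validation sample with raw predicted probabilities.

The model API follows the Model/Results convention: build a
:class:`HomelessnessClassifier` from arrays or a DataFrame, call ``fit()``,
and work with the returned :class:`ClassifierResults` (parameters, standard
errors, ``predict``, ``summary``).

No intercept correction is applied after downsampling, so predicted
probabilities are calibrated to the balanced sample, not the population; the
downstream analysis uses them exactly as produced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "round_half_up",
    "stratified_split",
    "downsample_majority",
    "HomelessnessClassifier",
    "ClassifierResults",
    "fit_logistic",
    "predict_probability",
]

MAX_ITER = 100
COEF_TOL = 1e-8
SEPARATION_RIDGE = 1e-6
# |coefficient| beyond which the fit is treated as (quasi-)separated
_SEPARATION_BOUND = 30.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (.5 -> up)."""
    return int(np.floor(x + 0.5))


def stratified_split(
    ids,
    labels,
    dev_fraction: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly assign ids to development/validation within outcome strata.

    Within each stratum (label true/false), exactly
    ``round_half_up(dev_fraction * stratum size)`` ids go to development,
    chosen uniformly at random; the remainder form the validation partition.
    Deterministic for a fixed seed.
    """
    if not 0 < dev_fraction < 1:
        raise ValueError("dev_fraction must be in (0, 1)")
    ids = np.asarray(ids)
    labels = np.asarray(labels).astype(bool)
    if ids.shape != labels.shape:
        raise ValueError("ids and labels must be aligned")
    rng = np.random.default_rng(seed)
    partition = np.empty(ids.shape, dtype=object)
    stratum = np.where(labels, "known_homeless", "not_known_homeless")
    for value in (True, False):
        idx = np.flatnonzero(labels == value)
        n_dev = round_half_up(dev_fraction * idx.size)
        perm = rng.permutation(idx.size)
        partition[idx[perm[:n_dev]]] = "development"
        partition[idx[perm[n_dev:]]] = "validation"
    return pd.DataFrame({"person_id": ids, "stratum": stratum, "partition": partition})


def downsample_majority(ids, labels, seed: int = 0) -> np.ndarray:
    """Balance classes 1:1: keep all minority ids plus an equal-size uniform
    subsample (without replacement) of the majority class."""
    ids = np.asarray(ids)
    labels = np.asarray(labels).astype(bool)
    if ids.shape != labels.shape:
        raise ValueError("ids and labels must be aligned")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the development sample")
    minority, majority = (labels, ~labels) if n_pos <= n_neg else (~labels, labels)
    n_min = int(minority.sum())
    rng = np.random.default_rng(seed)
    keep_major = rng.choice(ids[majority], size=n_min, replace=False)
    return np.concatenate([ids[minority], keep_major])


@dataclass
class ClassifierResults:
    """Fitted logistic-regression results.

    ``params`` holds the intercept (``const``) followed by named coefficients
    on the log-odds scale; ``bse`` the asymptotic standard errors from the
    observed Fisher information at the optimum.
    """

    params: pd.Series
    bse: pd.Series
    converged: bool
    n_iterations: int
    llf: float
    llf_history: list = field(default_factory=list)
    nobs: int = 0
    ridge: float = 0.0
    dropped: list = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def coefficients(self) -> dict:
        return {k: float(v) for k, v in self.params.items() if k != "const"}

    def predict(self, features) -> np.ndarray:
        """Predicted probabilities for a feature matrix or DataFrame.

        DataFrame columns are aligned to the fitted coefficient names; an
        unknown or missing feature name is an error.
        """
        names = [k for k in self.params.index if k != "const"]
        if isinstance(features, pd.DataFrame):
            unknown = set(features.columns) - set(names)
            if unknown:
                raise KeyError(f"unknown feature name(s): {sorted(unknown)}")
            missing = set(names) - set(features.columns)
            if missing:
                raise KeyError(f"missing feature(s): {sorted(missing)}")
            x = features[names].to_numpy(dtype=float)
        else:
            x = np.asarray(features, dtype=float)
            if x.ndim == 1:
                x = x[None, :]
            if x.shape[1] != len(names):
                raise ValueError(f"expected {len(names)} features, got {x.shape[1]}")
        eta = self.intercept + x @ self.params[names].to_numpy(dtype=float)
        return expit(eta)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "converged": self.converged,
                "n_iterations": self.n_iterations,
                "llf": self.llf,
                "nobs": self.nobs,
                "ridge": self.ridge,
                "dropped": list(self.dropped),
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            "Binary logistic regression (IRLS)",
            f"  observations: {self.nobs}   log-likelihood: {self.llf:.3f}",
            f"  converged: {self.converged} in {self.n_iterations} iterations"
            + (f"   ridge: {self.ridge:g}" if self.ridge else ""),
            "",
            f"{'term':<28}{'coef':>12}{'std err':>12}",
            "-" * 52,
        ]
        for name in self.params.index:
            lines.append(f"{name:<28}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}")
        return "\n".join(lines)


class HomelessnessClassifier:
    """Main-effects binary logistic regression fitted by IRLS.

    Parameters
    ----------
    endog : array-like of bool
        Outcome labels (observed known-case status in the study workflow).
    exog : 2-D array-like
        Predictor matrix, one column per feature, without a constant; an
        intercept is always added.
    feature_names : sequence of str, optional
        Column names; defaults to ``x1..xk`` or DataFrame columns.
    """

    def __init__(self, endog, exog, feature_names: Optional[Sequence[str]] = None):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.endog = np.asarray(endog).astype(float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per observation")
        if feature_names is None:
            feature_names = [f"x{i + 1}" for i in range(self.exog.shape[1])]
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("feature names must be unique")
        self.feature_names = list(feature_names)
        if self.endog.shape[0] < self.exog.shape[1] + 1:
            raise ValueError("need at least one more observation than parameters")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, label: str, features: Sequence[str]):
        return cls(data[label].to_numpy(), data[list(features)], feature_names=list(features))

    @staticmethod
    def _loglike(y, eta, beta, ridge):
        # numerically safe Bernoulli log-likelihood: sum y*eta - log(1+exp(eta))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if ridge:
            ll -= 0.5 * ridge * float(beta @ beta)
        return ll

    def _irls(self, ridge: float):
        y = self.endog
        X = np.column_stack([np.ones(len(y)), self.exog])
        k = X.shape[1]
        beta = np.zeros(k)
        eta = X @ beta
        ll = self._loglike(y, eta, beta, ridge)
        history = [ll]
        converged = False
        it = 0
        for it in range(1, MAX_ITER + 1):
            mu = expit(eta)
            w = mu * (1.0 - mu)
            w = np.maximum(w, 1e-10)
            # Newton step on the penalised log-likelihood
            grad = X.T @ (y - mu) - ridge * beta
            hess = (X * w[:, None]).T @ X + ridge * np.eye(k)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # step-halving keeps the log-likelihood monotone non-decreasing
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                cand_ll = self._loglike(y, X @ cand, cand, ridge)
                if cand_ll >= ll - 1e-12:
                    break
                scale *= 0.5
            delta = np.max(np.abs(scale * step))
            beta = beta + scale * step
            eta = X @ beta
            ll = self._loglike(y, eta, beta, ridge)
            history.append(ll)
            if delta < COEF_TOL:
                converged = True
                break
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        fisher = (X * w[:, None]).T @ X + ridge * np.eye(k)
        try:
            cov = np.linalg.inv(fisher)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(k, np.nan)
        return beta, bse, converged, it, ll, history

    def fit(self, ridge: Optional[float] = None) -> ClassifierResults:
        """Maximum-likelihood fit; a tiny ridge is applied automatically only
        when the unpenalised fit shows (quasi-)separation and is reported on
        the results object."""
        names = ["const"] + self.feature_names
        keep = np.std(self.exog, axis=0) > 0
        dropped = [n for n, k in zip(self.feature_names, keep) if not k]
        if dropped:
            warnings.warn(f"dropping constant predictor(s): {dropped}", stacklevel=2)
            model = HomelessnessClassifier(
                self.endog,
                self.exog[:, keep],
                [n for n, k in zip(self.feature_names, keep) if k],
            )
            res = model.fit(ridge=ridge)
            res.dropped = dropped
            return res

        applied_ridge = float(ridge) if ridge else 0.0
        beta, bse, converged, it, ll, hist = self._irls(applied_ridge)
        separated = (not converged) or (not np.all(np.isfinite(beta))) or np.max(np.abs(beta)) > _SEPARATION_BOUND
        if ridge is None and separated:
            warnings.warn(
                "possible separation detected; refitting with ridge penalty "
                f"{SEPARATION_RIDGE:g}",
                stacklevel=2,
            )
            applied_ridge = SEPARATION_RIDGE
            beta, bse, converged, it, ll, hist = self._irls(applied_ridge)
        if not converged:
            warnings.warn("IRLS did not converge within the iteration limit", stacklevel=2)
        return ClassifierResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            converged=bool(converged),
            n_iterations=it,
            llf=ll,
            llf_history=hist,
            nobs=len(self.endog),
            ridge=applied_ridge,
        )


def fit_logistic(features, labels, feature_names=None, ridge: Optional[float] = None) -> ClassifierResults:
    """Functional wrapper: fit a logistic model and return its results."""
    return HomelessnessClassifier(labels, features, feature_names=feature_names).fit(ridge=ridge)


def predict_probability(model: ClassifierResults, features) -> np.ndarray:
    """Predicted probabilities from fitted results (see ``ClassifierResults.predict``)."""
    return model.predict(features)
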