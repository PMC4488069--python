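"""Logistic-regression engine: all-subsets search, AICc model averaging,
influence diagnostics and pseudo-R².

The workflow this implements is the multimodel-inference recipe standard in
occurrence modelling: fit every subset of the candidate predictors with a
binomial-error, logit-link GLM; rank by the small-sample Akaike criterion
AICc = -2l + 2k + 2k(k+1)/(n-k-1); keep the models within 2 AICc units of
the best; and average coefficients across that candidate set with Akaike
weights w_i proportional to exp(-delta_i/2).  Both the "full" average
(absent terms count as zero) and the "conditional" average (over containing
models only) are computed, along with the unconditional standard error
sum_i w_i * sqrt(var_i + (b_i - b_bar)^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "FitResult", "CandidateModel", "AveragedModel",
    "fit_logistic", "aicc", "all_subsets", "candidate_set", "model_average",
    "predict_average", "cooks_distance", "pseudo_r2",
]

_SEPARATION_COEF = 1e2  # |beta| beyond this on unit-scaled data flags separation


@dataclass
class FitResult:
    """One fitted logistic regression.

    ``coefficients`` holds the intercept first, then slopes in ``predictors``
    order; ``k`` counts all estimated parameters (slopes + intercept).
    """

    predictors: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    k: int
    n: int
    fitted: np.ndarray
    converged: bool
    separation: bool
    design: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation

    def coefficient(self, term: str) -> float:
        if term == "intercept":
            return float(self.coefficients[0])
        return float(self.coefficients[1 + self.predictors.index(term)])

    def standard_error(self, term: str) -> float:
        if term == "intercept":
            return float(self.standard_errors[0])
        return float(self.standard_errors[1 + self.predictors.index(term)])


@dataclass
class CandidateModel:
    """A fitted subset with its AICc rank within a search."""

    fit: FitResult
    aicc: float
    delta: float
    weight: float
    index: int  # enumeration index, used as the stable tie-break


@dataclass
class AveragedModel:
    """Akaike-weight average over a candidate set.

    ``full`` estimates set a term to zero in models that lack it;
    ``conditional`` estimates average over containing models only.
    ``importance`` is the summed weight of models containing each term.
    """

    terms: tuple[str, ...]
    full: dict[str, float]
    conditional: dict[str, float]
    se_full: dict[str, float]
    se_conditional: dict[str, float]
    importance: dict[str, float]
    members: list[CandidateModel]

    def estimates(self, variant: str = "full") -> dict[str, float]:
        if variant not in ("full", "conditional"):
            raise ValueError(f"unknown averaging variant {variant!r}")
        return self.full if variant == "full" else self.conditional

    def standard_errors(self, variant: str = "full") -> dict[str, float]:
        return self.se_full if variant == "full" else self.se_conditional

    def significant(self, variant: str = "full", z: float = 1.96) -> dict[str, bool]:
        """Wald check: zero outside estimate +/- z * unconditional SE."""
        est = self.estimates(variant)
        se = self.standard_errors(variant)
        return {t: abs(est[t]) > z * se[t] if se[t] > 0 else est[t] != 0.0
                for t in self.terms}

    def to_frame(self) -> pd.DataFrame:
        sig = self.significant("full")
        return pd.DataFrame({
            "term": list(self.terms),
            "estimate_full": [self.full[t] for t in self.terms],
            "se_full": [self.se_full[t] for t in self.terms],
            "estimate_conditional": [self.conditional[t] for t in self.terms],
            "se_conditional": [self.se_conditional[t] for t in self.terms],
            "importance": [self.importance[t] for t in self.terms],
            "significant": [sig[t] for t in self.terms],
        })


def _as_design(X, predictors: tuple[str, ...]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(predictors)].to_numpy(float) if predictors else np.empty((len(X), 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_logistic(X, y, predictors: tuple[str, ...] | None = None) -> FitResult:
    """Maximum-likelihood logistic regression (binomial error, logit link).

    Fitting is iteratively reweighted least squares via statsmodels GLM with
    convergence tolerance 1e-8 and at most 100 iterations; standard errors
    come from the inverse observed information.  Complete or quasi-complete
    separation is reported as a flag, not an exception — separated models are
    excluded from ranking by the subset search.
    """
    if predictors is None:
        if isinstance(X, pd.DataFrame):
            predictors = tuple(X.columns)
        else:
            arr = np.asarray(X, dtype=float)
            n_slopes = 1 if arr.ndim == 1 else (arr.shape[1] if arr.size else 0)
            predictors = tuple(f"x{i + 1}" for i in range(n_slopes))
    predictors = tuple(predictors)
    y = np.asarray(y, dtype=float)
    design = _as_design(X, predictors)
    n, k = design.shape
    if n <= k:
        raise ValueError(f"n={n} must exceed the {k} estimated parameters")
    separation = False
    converged = False
    coef = np.full(k, np.nan)
    se = np.full(k, np.nan)
    loglik = np.nan
    fitted = np.full(n, np.nan)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.GLM(y, design, family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-8)
            coef = np.asarray(res.params, float)
            se = np.asarray(res.bse, float)
            loglik = float(res.llf)
            fitted = np.asarray(res.fittedvalues, float)
            converged = bool(res.converged)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation = True
    if np.any(np.abs(coef) > _SEPARATION_COEF) or not np.all(np.isfinite(se)):
        separation = True
    fitted = np.clip(fitted, 1e-12, 1 - 1e-12)
    return FitResult(predictors=predictors, coefficients=coef,
                     standard_errors=se, loglik=loglik, k=k, n=n,
                     fitted=fitted, converged=converged, separation=separation,
                     design=design, response=y)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def all_subsets(X: pd.DataFrame, y, max_predictors: int = 20
                ) -> list[CandidateModel]:
    """Fit every predictor subset (including intercept-only) and rank by AICc.

    Enumeration is binary counting on the input column order, so results are
    deterministic for a given column order.  Subsets that fail to converge or
    show separation are kept in the returned list (flagged, with zero weight)
    but excluded from the delta/weight ranking.  Ties in AICc resolve by
    enumeration index.
    """
    cols = list(X.columns)
    p = len(cols)
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors means {2 ** p} models; pass max_predictors={p} "
            "to confirm you want an enumeration this large")
    fits: list[FitResult] = []
    for m in range(2 ** p):
        subset = tuple(cols[j] for j in range(p) if m >> j & 1)
        fits.append(fit_logistic(X[list(subset)], y, subset))
    usable = [i for i, f in enumerate(fits) if f.ok]
    if not usable:
        raise RuntimeError("no subset converged cleanly; cannot rank models")
    scores = {i: aicc(fits[i].loglik, fits[i].k, fits[i].n) for i in usable}
    best = min(scores.values())
    raw = {i: np.exp(-0.5 * (scores[i] - best)) for i in usable}
    total = sum(raw.values())
    out = []
    for i, f in enumerate(fits):
        if i in scores:
            out.append(CandidateModel(fit=f, aicc=scores[i],
                                      delta=scores[i] - best,
                                      weight=raw[i] / total, index=i))
        else:
            out.append(CandidateModel(fit=f, aicc=np.inf, delta=np.inf,
                                      weight=0.0, index=i))
    out.sort(key=lambda c: (c.aicc, c.index))
    return out


def candidate_set(models: list[CandidateModel], delta_max: float = 2.0
                  ) -> list[CandidateModel]:
    """Models with delta strictly below ``delta_max``, weights renormalized.

    The best model always qualifies (delta = 0), so the set is never empty.
    """
    if not models:
        raise ValueError("empty model list")
    kept = [c for c in models if c.fit.ok and c.delta < delta_max]
    total = sum(c.weight for c in kept)
    return [CandidateModel(fit=c.fit, aicc=c.aicc, delta=c.delta,
                           weight=c.weight / total, index=c.index)
            for c in kept]


def model_average(candidates: list[CandidateModel]) -> AveragedModel:
    """Akaike-weight average of coefficients over a candidate set.

    A term absent from a member model contributes a zero-estimate,
    zero-variance pseudo-entry to the full average and its unconditional SE;
    the conditional variant renormalizes over containing models only.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    terms: list[str] = ["intercept"]
    for c in candidates:
        for t in c.fit.predictors:
            if t not in terms:
                terms.append(t)
    full, cond, se_f, se_c, imp = {}, {}, {}, {}, {}
    for t in terms:
        entries = []  # (weight, beta, var) over containing models
        for c in candidates:
            if t == "intercept" or t in c.fit.predictors:
                entries.append((c.weight, c.fit.coefficient(t),
                                c.fit.standard_error(t) ** 2))
        w_in = sum(w for w, _, _ in entries)
        b_full = sum(w * b for w, b, _ in entries)  # absent models add 0
        b_cond = sum(w * b for w, b, _ in entries) / w_in
        # unconditional SE: containing models plus zero pseudo-entries (full)
        se_full = sum(w * np.sqrt(v + (b - b_full) ** 2) for w, b, v in entries)
        se_full += (1.0 - w_in) * abs(0.0 - b_full)
        se_cond = sum((w / w_in) * np.sqrt(v + (b - b_cond) ** 2)
                      for w, b, v in entries)
        full[t], cond[t] = float(b_full), float(b_cond)
        se_f[t], se_c[t] = float(se_full), float(se_cond)
        imp[t] = float(w_in)
    return AveragedModel(terms=tuple(terms), full=full, conditional=cond,
                         se_full=se_f, se_conditional=se_c, importance=imp,
                         members=list(candidates))


def predict_average(avg: AveragedModel, X: pd.DataFrame,
                    mode: str = "mean_probability") -> np.ndarray:
    """Predicted presence probabilities from an averaged model.

    ``mean_probability`` (default) averages each member model's predicted
    probability with its weight — well defined under the logit link.
    ``coefficients`` instead applies the logistic to the full-averaged
    coefficient vector.
    """
    missing = [t for t in avg.terms if t != "intercept" and t not in X.columns]
    if missing:
        raise KeyError(f"prediction matrix lacks columns {missing!r}")
    if mode == "mean_probability":
        out = np.zeros(len(X))
        for c in avg.members:
            design = _as_design(X, c.fit.predictors)
            out += c.weight / (1.0 + np.exp(-design @ c.fit.coefficients))
        return out
    if mode == "coefficients":
        slopes = [t for t in avg.terms if t != "intercept"]
        design = _as_design(X, tuple(slopes))
        beta = np.array([avg.full["intercept"]] + [avg.full[t] for t in slopes])
        return 1.0 / (1.0 + np.exp(-design @ beta))
    raise ValueError(f"unknown prediction mode {mode!r}")


def cooks_distance(fit: FitResult) -> np.ndarray:
    """One-step Cook's distance per observation.

    D_i = r_i^2 h_i / (k (1 - h_i)^2) with Pearson residuals r_i and hat
    values h_i from the IRLS-weighted design — the standard one-step
    approximation to the case-deletion refit.  Observations with D close to
    1 dominate the fit and are candidates for exclusion.
    """
    if not fit.ok:
        raise ValueError("Cook's distance requires a clean, converged fit")
    p = fit.fitted
    w = p * (1.0 - p)
    Xw = fit.design * np.sqrt(w)[:, None]
    # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    h = np.einsum("ij,jk,ik->i", Xw, xtx_inv, Xw)
    r_pearson = (fit.response - p) / np.sqrt(w)
    return (r_pearson ** 2 * h) / (fit.k * (1.0 - h) ** 2)


def pseudo_r2(fit: FitResult, null_fit: FitResult, variant: str = "cox_snell"
              ) -> float:
    """Likelihood-ratio pseudo-R² against the intercept-only model.

    ``cox_snell``: 1 - exp(-(2/n)(l1 - l0)); ``nagelkerke`` divides by its
    maximum 1 - exp((2/n) l0), so it can reach 1.  Negative values (fit worse
    than null) are allowed with a warning.
    """
    if null_fit.k != 1:
        raise ValueError("null_fit must be intercept-only")
    if fit.n != null_fit.n:
        raise ValueError("fit and null must use the same observations")
    n = fit.n
    cs = 1.0 - np.exp(-(2.0 / n) * (fit.loglik - null_fit.loglik))
    if cs < 0:
        warnings.warn("model fits worse than the intercept-only null")
    if variant == "cox_snell":
        return float(cs)
    if variant == "nagelkerke":
        return float(cs / (1.0 - np.exp((2.0 / n) * null_fit.loglik)))
    raise ValueError(f"unknown pseudo-R2 variant {variant!r}")
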