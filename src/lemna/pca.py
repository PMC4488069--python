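"""Correlation-matrix PCA of site environmental conditions.

Variables are centred and scaled (so the decomposition is of the correlation
matrix), components are ordered by eigenvalue, and within each component the
loading of largest magnitude is made positive — loadings are only defined up
to reflection, and a fixed convention keeps output stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SiteTable

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    variables: tuple[str, ...]
    loadings: pd.DataFrame        # variables x components
    proportions: np.ndarray       # variance share per component
    scores: pd.DataFrame = field(repr=False)  # sites x components
    eigenvalues: np.ndarray = field(default=None, repr=False)

    def loadings_table(self) -> pd.DataFrame:
        """Loadings with a proportion-of-variance footer row."""
        out = self.loadings.copy()
        out.loc["Proportion of Variance"] = self.proportions
        return out


def pca_correlation(sites: SiteTable | pd.DataFrame,
                    variables: list[str]) -> PCAResult:
    """PCA of the correlation matrix of the named site variables.

    Rows with any missing value among ``variables`` are dropped (logged).
    Score columns have exactly zero mean and variance equal to the
    eigenvalues (sample variance, ddof=1).
    """
    df = sites.data if isinstance(sites, SiteTable) else sites
    if len(variables) < 2:
        raise ValueError("PCA needs at least two variables")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise KeyError(f"unknown variables {missing!r}")
    X = df[variables].to_numpy(float)
    keep = np.all(np.isfinite(X), axis=1)
    if not keep.all():
        log.info("PCA dropped %d rows with missing values", (~keep).sum())
    X = X[keep]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variables cannot enter a correlation PCA: {const!r}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # reflection convention: largest-|loading| entry positive per component
    for j in range(p):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comp_names = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(eigvec, index=list(variables), columns=comp_names)
    scores = pd.DataFrame(Z @ eigvec, columns=comp_names)
    if "site_id" in df.columns:
        scores.insert(0, "site_id", df.loc[keep, "site_id"].to_numpy())
    return PCAResult(variables=tuple(variables), loadings=loadings,
                     proportions=eigval / eigval.sum(), scores=scores,
                     eigenvalues=eigval)
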