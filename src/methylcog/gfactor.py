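"""General cognitive ability (g) as the first unrotated principal component.

Test scores are z-standardized and the correlation matrix of the battery is
eigendecomposed; PC1 scores, standardized to mean 0 / SD 1, serve as the
measured g.  Because the PCA operates on correlations, the result is
invariant to affine rescaling of any raw test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GFactorResult:
    loadings: pd.Series          # unit-norm PC1 eigenvector entries per test
    eigenvalues: np.ndarray      # descending, sum to n_tests
    proportion_variance_pc1: float
    g_scores: pd.Series          # mean 0, SD 1

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.to_dict(),
            "eigenvalues": self.eigenvalues.tolist(),
            "proportion_variance_pc1": float(self.proportion_variance_pc1),
        }


def variance_explained(eigenvalue: float, n_tests: int) -> float:
    """Share of battery variance carried by one component of a
    correlation-matrix PCA: eigenvalue / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be a positive count")
    if eigenvalue < 0:
        raise ValueError("eigenvalue must be non-negative")
    return eigenvalue / n_tests


def derive_g(tests: pd.DataFrame) -> GFactorResult:
    """Extract g as the standardized PC1 of the z-scored battery.

    Loadings are sign-fixed so their mean is positive (higher g = better
    performance when tests are scored positively).  Raises if the battery
    has fewer than two tests, incomplete scores, or a constant test.
    """
    if tests.shape[1] < 2:
        raise ValueError("battery must contain at least 2 tests")
    if tests.isna().to_numpy().any():
        raise ValueError("battery contains missing scores; run impute_tests first")
    sd = tests.std(ddof=1)
    scale = tests.abs().mean().clip(lower=1.0)
    constant = sd[sd <= 1e-12 * scale].index.tolist()
    if constant:
        raise ValueError(f"constant test column(s): {constant}")
    Z = (tests - tests.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    v1 = eigvec[:, 0]
    if v1.mean() < 0:
        v1 = -v1
    raw = Z.to_numpy() @ v1
    g = (raw - raw.mean()) / raw.std(ddof=1)
    return GFactorResult(
        loadings=pd.Series(v1, index=tests.columns, name="pc1_loading"),
        eigenvalues=eigval,
        proportion_variance_pc1=variance_explained(eigval[0], tests.shape[1]),
        g_scores=pd.Series(g, index=tests.index, name="g"),
    )


def impute_tests(tests: pd.DataFrame, max_missing: float = 0.5) -> pd.DataFrame:
    """Regression-impute missing test scores from the battery correlations.

    Each subject's missing z-scores are predicted from their observed
    z-scores via the conditional-expectation weights R_mo R_oo^{-1} built
    from the pairwise-complete battery correlation matrix, then mapped back
    to the raw scale.  Subjects missing more than ``max_missing`` of the
    battery are dropped with a log entry.  Deterministic.
    """
    frac = tests.isna().mean(axis=1)
    dropped = tests.index[frac > max_missing]
    if len(dropped):
        logger.warning("impute_tests: excluding %d subject(s) missing > %.0f%% "
                       "of tests: %s", len(dropped), 100 * max_missing,
                       list(dropped[:5]))
    out = tests.drop(index=dropped).copy()
    if not out.isna().to_numpy().any():
        return out
    mu, sd = out.mean(), out.std(ddof=1)
    Z = (out - mu) / sd
    R = Z.corr(min_periods=2).to_numpy()
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    zv = Z.to_numpy()
    for i in range(zv.shape[0]):
        miss = np.isnan(zv[i])
        if not miss.any():
            continue
        obs = ~miss
        Roo = R[np.ix_(obs, obs)] + 1e-8 * np.eye(int(obs.sum()))
        Rmo = R[np.ix_(miss, obs)]
        zv[i, miss] = Rmo @ np.linalg.solve(Roo, zv[i, obs])
    filled = pd.DataFrame(zv, index=out.index, columns=out.columns)
    return filled * sd + mu
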