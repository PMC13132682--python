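"""Apply a trained score model to any cohort and evaluate against measured g.

Scoring aligns the cohort's beta matrix to the model's candidate-probe
pool, standardizes with the *training* means and SDs (never the target
cohort's), zero-fills anything unmeasured or non-finite, forms the weighted
sum over the selected CpGs, and z-scales by the training raw-score
distribution.  Covariate coefficients are never applied outside training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ScoreModel
from .qc import BetaMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    scores: pd.DataFrame             # columns: raw, z, n_missing
    excluded: dict[str, str] = field(default_factory=dict)
    n_absent_probes: int = 0

    @property
    def z(self) -> pd.Series:
        return self.scores["z"]

    @property
    def raw(self) -> pd.Series:
        return self.scores["raw"]


@dataclass
class ScoreMetrics:
    r2: float | None
    r2_calibrated: float | None
    rmse: float
    mae: float
    pearson_r: float | None
    spearman_rho: float | None
    n: int
    note: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("r2", "r2_calibrated", "rmse", "mae", "pearson_r",
                 "spearman_rho", "n", "note")}


def compute_score(
    beta: BetaMatrix,
    model: ScoreModel,
    max_missing: float = 0.10,
) -> ScoreSet:
    """Compute raw and z-scaled scores for every sample in ``beta``.

    Samples missing more than ``max_missing`` of the model's measured pool
    are excluded with a reason code; a probe absent from the cohort (or
    lacking finite training scaling) contributes exactly zero.
    """
    pool = model.probe_pool
    present = [p for p in pool if p in beta.probe_ids]
    if not present:
        raise ValueError("none of the model's probes are present in the beta matrix")
    absent = len(pool) - len(present)
    if absent:
        logger.info("compute_score: %d/%d pool probes absent from cohort; "
                    "zero-filled", absent, len(pool))

    vals = beta.values.loc[present].to_numpy(dtype=float).T  # n x m
    n_missing = np.isnan(vals).sum(axis=1)
    miss_frac = n_missing / len(pool)

    mu = np.array([model.scaling[p][0] for p in present])
    sigma = np.array([model.scaling[p][1] for p in present])
    ok = np.isfinite(mu) & np.isfinite(sigma) & (sigma > 0)
    std = np.zeros_like(vals)
    with np.errstate(invalid="ignore"):
        std[:, ok] = (vals[:, ok] - mu[ok]) / sigma[ok]
    std[~np.isfinite(std)] = 0.0

    w = np.array([model.weights.get(p, 0.0) for p in present])
    raw = std @ w
    if model.raw_score_sd <= 0:
        raise ValueError("model raw-score SD must be positive")
    z = (raw - model.raw_score_mean) / model.raw_score_sd

    scores = pd.DataFrame({"raw": raw, "z": z, "n_missing": n_missing},
                          index=beta.sample_ids)
    excluded = {str(s): "missing_cpg_fraction"
                for s in beta.sample_ids[miss_frac > max_missing]}
    if excluded:
        scores = scores.drop(index=list(excluded))
        logger.warning("compute_score: excluded %d sample(s) with > %.0f%% "
                       "missing pool probes", len(excluded), 100 * max_missing)
    return ScoreSet(scores, excluded, absent)


def evaluate_score(scores: ScoreSet | pd.Series, g: pd.Series) -> ScoreMetrics:
    """Criterion-validity metrics of the score against measured g.

    R^2 is reported primarily as the squared Pearson correlation (the score
    is z-scaled, not calibrated to g's units); the calibrated
    1 - SS_res/SS_tot variant is reported alongside.  RMSE and MAE are on
    the standardized scales; Spearman uses average ranks for ties.
    """
    s = scores.z if isinstance(scores, ScoreSet) else scores
    joined = pd.concat([s.rename("score"), g.rename("g")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError(f"need at least 3 paired observations, have {len(joined)}")
    x, y = joined["score"].to_numpy(), joined["g"].to_numpy()
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    mae = float(np.mean(np.abs(x - y)))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2_cal = float(1.0 - np.sum((y - x) ** 2) / ss_tot) if ss_tot > 0 else None
    if x.std() == 0 or y.std() == 0:
        return ScoreMetrics(None, r2_cal, rmse, mae, None, None, len(joined),
                            note="constant input; correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    rho = float(sps.spearmanr(x, y).statistic)
    return ScoreMetrics(r * r, r2_cal, rmse, mae, r, rho, len(joined))
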