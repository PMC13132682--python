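"""Probe- and sample-level quality control for methylation beta matrices.

The pipeline order is fixed: probe filtering -> detection-p masking and
imputation -> replicate collapsing -> (M-values, used only for PCA outlier
flagging).  Scoring always happens on the beta scale.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: beta values are clipped to [EPS, 1-EPS] before the logit-like M transform
EPS = 1e-6

ANNOTATION_COLUMNS = [
    "locus_id",
    "is_cross_reactive",
    "is_snp_proximal",
    "has_cg_prefix",
    "on_450k",
    "candidate",
]


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions with optional detection p-values.

    ``values`` is a probes-by-samples DataFrame of beta values in [0, 1]
    (NaN marks missing cells).  ``detection_p`` is an aligned per-cell
    detection p-value frame, or None.  ``annotation`` carries per-probe
    metadata (see :data:`ANNOTATION_COLUMNS`).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    platform: str = "unknown"
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"{bad} beta values outside [0, 1]")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError("detection_p shape does not match values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_probes(self, probes: pd.Index | list) -> "BetaMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probes]
        ann = None if self.annotation is None else self.annotation.loc[probes]
        return BetaMatrix(self.values.loc[probes], dp, self.platform, ann)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.values.copy(),
            None if self.detection_p is None else self.detection_p.copy(),
            self.platform,
            None if self.annotation is None else self.annotation.copy(),
        )


@dataclass
class QcReport:
    """Bookkeeping of what each QC step removed, flagged or imputed."""

    probes_removed_by_rule: dict[str, int] = field(default_factory=dict)
    removed_probe_ids: dict[str, list[str]] = field(default_factory=dict)
    samples_flagged: dict[str, str] = field(default_factory=dict)
    missing_imputed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_annotation(
    probe_ids,
    locus_id=None,
    is_cross_reactive=False,
    is_snp_proximal=False,
    on_450k=True,
    candidate=True,
) -> pd.DataFrame:
    """Build a ProbeAnnotation frame; scalar arguments are broadcast."""
    idx = pd.Index(probe_ids, name="probe_id")
    ann = pd.DataFrame(index=idx)
    ann["locus_id"] = locus_id if locus_id is not None else idx
    ann["is_cross_reactive"] = is_cross_reactive
    ann["is_snp_proximal"] = is_snp_proximal
    ann["has_cg_prefix"] = idx.str.startswith("cg")
    ann["on_450k"] = on_450k
    ann["candidate"] = candidate
    return ann


def _check_annotated(beta: BetaMatrix, ann: pd.DataFrame) -> None:
    missing = beta.probe_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} has no annotation row "
                         f"({len(missing)} unannotated probes in total)")


def filter_probes(
    beta: BetaMatrix,
    ann: pd.DataFrame,
    candidates: list[str] | pd.Index | None = None,
) -> tuple[BetaMatrix, QcReport]:
    """Drop cross-reactive, non-"cg" and SNP-proximal probes.

    If ``candidates`` is given the surviving panel is additionally
    restricted to that allowlist (EWAS candidate set).  Probe order is
    preserved; each removed probe is attributed to the first rule it
    violates so rule counts sum to the total removed.
    """
    _check_annotated(beta, ann)
    a = ann.loc[beta.probe_ids]
    report = QcReport()
    removed = pd.Series(False, index=beta.probe_ids)
    rules = [
        ("cross_reactive", a["is_cross_reactive"].astype(bool)),
        ("non_cg_prefix", ~a["has_cg_prefix"].astype(bool)),
        ("snp_proximal", a["is_snp_proximal"].astype(bool)),
    ]
    if candidates is not None:
        rules.append(("not_in_candidate_list",
                      ~beta.probe_ids.isin(pd.Index(candidates))))
    for name, mask in rules:
        new = mask & ~removed
        report.probes_removed_by_rule[name] = int(new.sum())
        report.removed_probe_ids[name] = beta.probe_ids[new].tolist()
        removed |= mask
    kept = beta.probe_ids[~removed]
    logger.info("filter_probes: %d -> %d probes", beta.n_probes, len(kept))
    return beta.select_probes(kept), report


def apply_sample_qc(
    beta: BetaMatrix,
    sample_qc: pd.DataFrame,
    min_bisulfite_conversion: float = 85.0,
) -> tuple[BetaMatrix, QcReport]:
    """Drop samples failing assay-level metadata checks.

    ``sample_qc`` is indexed by sample id with optional columns
    ``bisulfite_conversion`` (percent) and ``predicted_sex`` /
    ``reported_sex``.  These are metadata filters only; no assay-level
    quantity is computed here.
    """
    report = QcReport()
    keep = []
    for s in beta.sample_ids:
        reason = None
        if s in sample_qc.index:
            row = sample_qc.loc[s]
            if "bisulfite_conversion" in sample_qc.columns and \
                    row["bisulfite_conversion"] <= min_bisulfite_conversion:
                reason = "bisulfite_conversion"
            elif {"predicted_sex", "reported_sex"} <= set(sample_qc.columns) and \
                    row["predicted_sex"] != row["reported_sex"]:
                reason = "sex_mismatch"
        if reason is None:
            keep.append(s)
        else:
            report.samples_flagged[str(s)] = reason
    out = BetaMatrix(beta.values[keep],
                     None if beta.detection_p is None else beta.detection_p[keep],
                     beta.platform, beta.annotation)
    return out, report


def _impute_probe(
    target: np.ndarray,
    donors: np.ndarray,
    obs: np.ndarray,
    k: int,
    ridge: float,
    self_index: int | None = None,
) -> np.ndarray:
    """Predict the missing cells of one probe from its k most correlated
    donor probes by ridge-stabilized linear regression."""
    y = target[obs]
    Z = donors[:, obs]
    sd_y = y.std()
    sd_z = Z.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Z - Z.mean(axis=1, keepdims=True)) @ (y - y.mean()) / (
            len(y) * np.where(sd_z > 0, sd_z, np.inf) * (sd_y if sd_y > 0 else np.inf)
        )
    r = np.nan_to_num(r)
    if self_index is not None:
        r[self_index] = 0.0
    order = np.argsort(-np.abs(r))[:k]
    Zk = donors[order]
    mu_z = Zk[:, obs].mean(axis=1)
    Zc = (Zk[:, obs] - mu_z[:, None]).T
    G = Zc.T @ Zc + ridge * len(y) * np.eye(k)
    b = np.linalg.solve(G, Zc.T @ (y - y.mean()))
    pred = y.mean() + (Zk[:, ~obs] - mu_z[:, None]).T @ b
    return np.clip(pred, 0.0, 1.0)


def mask_and_impute(
    beta: BetaMatrix,
    p_threshold: float = 0.01,
    k_neighbors: int = 10,
    ridge: float = 1e-3,
) -> tuple[BetaMatrix, QcReport]:
    """Mask detection failures and impute every missing cell.

    Cells with detection p > ``p_threshold`` are set missing; missing cells
    are then imputed per probe by ridge-stabilized regression on the
    ``k_neighbors`` most correlated other probes.  Donor probes are
    mean-initialized first (at realistic missingness almost no probe is
    observed in every sample), so the regression exploits inter-probe
    linear structure rather than degenerating to a mean fill; probes with
    fewer than ``k_neighbors`` donors or fewer than 3 observed cells fall
    back to the probe mean.  Probes missing in every sample are dropped and
    reported.
    """
    vals = beta.values.to_numpy(dtype=float).copy()
    report = QcReport()
    if beta.detection_p is not None:
        fail = beta.detection_p.to_numpy(dtype=float) > p_threshold
        vals[fail] = np.nan
    miss = np.isnan(vals)

    all_missing = miss.all(axis=1)
    if all_missing.any():
        ids = beta.probe_ids[all_missing].tolist()
        report.probes_removed_by_rule["missing_in_all_samples"] = len(ids)
        report.removed_probe_ids["missing_in_all_samples"] = [str(i) for i in ids]
        vals = vals[~all_missing]
        miss = miss[~all_missing]
    probe_index = beta.probe_ids[~all_missing]

    report.missing_imputed = int(miss.sum())
    if miss.any():
        # mean-initialize the donor pool so correlations are computable even
        # when no probe is observed in every sample
        row_mean = np.nanmean(vals, axis=1)
        filled = np.where(miss, row_mean[:, None], vals)
        for i in np.where(miss.any(axis=1))[0]:
            obs = ~miss[i]
            if filled.shape[0] > k_neighbors and obs.sum() >= 3:
                vals[i, ~obs] = _impute_probe(vals[i], filled, obs,
                                              k_neighbors, ridge,
                                              self_index=i)
            else:
                vals[i, ~obs] = vals[i, obs].mean()
    out = pd.DataFrame(vals, index=probe_index, columns=beta.sample_ids)
    ann = None if beta.annotation is None else beta.annotation.loc[probe_index]
    return BetaMatrix(out, None, beta.platform, ann), report


def collapse_replicates(beta: BetaMatrix, ann: pd.DataFrame) -> BetaMatrix:
    """Average replicate probes targeting the same CpG locus.

    Requires a complete matrix (run after :func:`mask_and_impute`).  Rows
    sharing ``locus_id`` are replaced by their per-sample arithmetic mean,
    re-indexed by locus.  Idempotent: collapsing a collapsed matrix is the
    identity.
    """
    if beta.values.isna().to_numpy().any():
        raise ValueError("collapse_replicates requires a complete matrix; "
                         "run mask_and_impute first")
    _check_annotated(beta, ann)
    locus = ann.loc[beta.probe_ids, "locus_id"]
    collapsed = beta.values.groupby(locus, sort=False).mean()
    collapsed.index.name = "probe_id"
    new_ann = None
    if beta.annotation is not None:
        new_ann = beta.annotation.groupby(locus, sort=False).first()
        new_ann.index.name = "probe_id"
        new_ann["locus_id"] = new_ann.index
    return BetaMatrix(collapsed, None, beta.platform, new_ann)


def beta_to_m(values: pd.DataFrame | np.ndarray, eps: float = EPS):
    """Map beta fractions to M-values, M = log2(beta / (1 - beta)).

    Values are clipped to [eps, 1-eps] first so boundary betas stay finite.
    """
    clipped = np.clip(np.asarray(values, dtype=float), eps, 1.0 - eps)
    m = np.log2(clipped / (1.0 - clipped))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(m, index=values.index, columns=values.columns)
    return m


def m_to_beta(values: pd.DataFrame | np.ndarray):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(values, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-m))
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(b, index=values.index, columns=values.columns)
    return b


def flag_pc_outliers(m: pd.DataFrame, z_cut: float = 3.0) -> list:
    """Flag samples extreme on PC1 or PC2 of the sample-by-CpG M matrix.

    The matrix is column-centered (per probe) without scaling; PC scores
    are z-scored and samples with |z| > ``z_cut`` on either of the first
    two components are flagged.  Sign-invariant by construction.
    """
    if m.shape[1] < 3:
        raise ValueError("flag_pc_outliers needs at least 3 samples")
    X = m.to_numpy(dtype=float).T  # samples x probes
    X = X - X.mean(axis=0)
    n_comp = min(2, *X.shape)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (scores - scores.mean(axis=0)) / sd
    flagged = np.abs(z).max(axis=1) > z_cut
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} PCA outlier sample(s) flagged",
                      stacklevel=2)
    return list(m.columns[flagged])
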