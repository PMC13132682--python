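"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

A cohort consists of a phenotype table (demographics, cell fractions, batch,
MCI diagnosis, comparator clock and biomarker columns), a probe-by-sample
beta matrix whose causal probes carry a latent general-ability signal, and a
ground-truth record for parameter-recovery tests.

Methylation is generated on the M-value scale (where effects are additive)
and mapped to beta through the inverse of M = log2(beta/(1-beta)), which
keeps beta in (0, 1) automatically.  A minority-group indicator shifts both
education and a subset of causal-probe baselines, so the downstream
group -> methylation -> cognition mediation structure is genuinely present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .qc import BetaMatrix, m_to_beta, make_annotation

logger = logging.getLogger(__name__)

CELL_TYPES = ["gran", "cd4t", "cd8t", "bcell", "nk", "mono"]
#: mean blood immune-cell composition used for the Dirichlet draw
CELL_MEANS = np.array([0.55, 0.15, 0.10, 0.07, 0.07, 0.06])
CELL_CONCENTRATION = 60.0


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults describe a population-based discovery cohort: ~2,069 older
    adults (age truncated-normal 75.22 +/- 7.01 on [65, 98]), MCI
    prevalence 23.8%, a 19-test battery whose PC1 loadings sit in
    (0.4, 0.8), and a 600-probe panel with 30 causal CpGs of +/-0.06
    M-value effect per SD of latent g.
    """

    n_subjects: int = 2069
    n_probes: int = 600
    n_causal: int = 30
    causal_effect_sd: float = 0.06
    age_range: tuple[float, float] = (65.0, 98.0)
    age_mean: float = 75.22
    age_sd: float = 7.01
    mci_prevalence: float = 0.238
    battery_size: int = 19
    loading_range: tuple[float, float] = (0.4, 0.8)
    battery_noise_sd: float = 0.8
    platform_overlap: float = 558 / 600
    missing_rate: float = 0.005
    n_replicate_loci: int = 6
    seed: int = 20251014
    # nuisance structure on the M-value scale
    m_noise_sd: float = 0.40
    age_effect_sd: float = 0.01
    cell_effect_sd: float = 0.30
    # latent co-methylation factors (arrays show strong inter-probe
    # correlation from shared regulatory and compositional variation)
    n_methyl_factors: int = 5
    methyl_factor_sd: float = 0.15
    n_batches: int = 3
    batch_effect_sd: float = 0.08
    # demographic / mediation structure
    prop_female: float = 0.57
    race_probs: tuple[float, float, float] = (0.80, 0.14, 0.06)
    prop_hispanic: float = 0.10
    education_mean: float = 12.8
    education_sd: float = 3.0
    group_edu_effect: float = 1.5
    edu_g_effect: float = 0.35
    group_g_effect: float = 0.35
    group_probe_shift: float = 0.06
    mci_g_slope: float = -1.1
    mci_age_slope: float = 0.04
    # QC-exercise probes
    n_cross_reactive: int = 5
    n_snp_proximal: int = 5
    n_non_cg: int = 5

    def validate(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValueError("n_causal cannot exceed n_probes")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("degenerate age_range: low must be < high")
        for name in ("mci_prevalence", "missing_rate", "prop_female",
                     "prop_hispanic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.platform_overlap <= 1.0:
            raise ValueError("platform_overlap must be in (0, 1]")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loading_range must be within (0, 1]")
        if self.battery_size < 2:
            raise ValueError("battery_size must be at least 2")


@dataclass
class ProbeArchitecture:
    """Per-probe generative parameters, shared across cohorts so that a
    model trained on one platform transports to the other."""

    probe_ids: list[str]
    baseline: np.ndarray
    causal_idx: np.ndarray
    causal_weights: np.ndarray  # full-length, nonzero exactly on causal_idx
    age_effects: np.ndarray
    cell_effects: np.ndarray  # n_probes x 6
    group_shift: np.ndarray  # nonzero on half the causal probes
    factor_loadings: np.ndarray = None  # n_probes x n_methyl_factors


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    g_true: pd.Series
    causal_probe_ids: list[str]
    causal_weights: pd.Series
    mediator_paths: dict[str, float]
    architecture: ProbeArchitecture = field(repr=False, default=None)


def _draw_architecture(config: CohortConfig, rng: np.random.Generator) -> ProbeArchitecture:
    p = config.n_probes
    probe_ids = [f"cg{i:07d}" for i in range(1, p + 1)]
    baseline = rng.normal(0.0, 1.5, size=p)
    causal_idx = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    weights = np.zeros(p)
    weights[causal_idx] = rng.choice([-1.0, 1.0], size=config.n_causal) * config.causal_effect_sd
    age_effects = rng.normal(0.0, config.age_effect_sd, size=p)
    cell_effects = rng.normal(0.0, config.cell_effect_sd, size=(p, len(CELL_TYPES)))
    # the group shift is aligned against each probe's causal weight sign so
    # the implied score deficit is coherent across probes
    group_shift = np.zeros(p)
    half = causal_idx[: config.n_causal // 2]
    group_shift[half] = -config.group_probe_shift * np.sign(weights[half])
    factor_loadings = rng.normal(0.0, config.methyl_factor_sd,
                                 size=(p, config.n_methyl_factors))
    return ProbeArchitecture(probe_ids, baseline, causal_idx, weights,
                             age_effects, cell_effects, group_shift,
                             factor_loadings)


def _calibrate_intercept(linpred: np.ndarray, prevalence: float) -> float:
    """Intercept for a logistic diagnosis model hitting a target mean risk."""
    if prevalence <= 0.0:
        return -np.inf
    if prevalence >= 1.0:
        return np.inf
    f = lambda b0: special.expit(b0 + linpred).mean() - prevalence
    return optimize.brentq(f, -30.0, 30.0)


def generate_cohort(
    config: CohortConfig,
    architecture: ProbeArchitecture | None = None,
) -> tuple[pd.DataFrame, BetaMatrix, SyntheticTruth]:
    """Generate one synthetic cohort: phenotypes, beta matrix, ground truth.

    Passing the ``architecture`` of a previous cohort reuses its per-probe
    parameters (baselines, causal weights, age and cell effects), emulating
    two cohorts measured on the same underlying epigenome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_subjects

    if architecture is None:
        architecture = _draw_architecture(config, np.random.default_rng([config.seed, 99]))
    arch = architecture

    # --- demographics ----------------------------------------------------
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    female = rng.random(n) < config.prop_female
    race = rng.choice(["White", "Black", "Other"], size=n, p=config.race_probs)
    hispanic = (rng.random(n) < config.prop_hispanic).astype(int)
    minority = ((race != "White") | (hispanic == 1)).astype(int)
    education = np.clip(
        config.education_mean + config.education_sd * rng.normal(size=n)
        - config.group_edu_effect * minority, 0.0, 20.0)
    z_edu = (education - education.mean()) / education.std()

    # --- latent general ability ------------------------------------------
    resid_sd = np.sqrt(max(1.0 - config.edu_g_effect ** 2, 0.05))
    g_true = (config.edu_g_effect * z_edu
              - config.group_g_effect * (minority - minority.mean())
              + resid_sd * rng.normal(size=n))

    # --- cell fractions, batch, diagnosis --------------------------------
    cells = rng.dirichlet(CELL_MEANS * CELL_CONCENTRATION, size=n)
    batch = rng.integers(0, config.n_batches, size=n)
    lin = config.mci_g_slope * g_true + config.mci_age_slope * (age - config.age_mean)
    b0 = _calibrate_intercept(lin, config.mci_prevalence)
    mci = (rng.random(n) < special.expit(b0 + lin)).astype(int)

    # --- methylation on the M scale --------------------------------------
    batch_shift = rng.normal(0.0, config.batch_effect_sd,
                             size=(config.n_probes, config.n_batches))
    cell_dev = cells - CELL_MEANS
    M = (arch.baseline[:, None]
         + np.outer(arch.causal_weights, g_true)
         + np.outer(arch.age_effects, age - config.age_mean)
         + arch.cell_effects @ cell_dev.T
         + batch_shift[:, batch]
         + np.outer(arch.group_shift, minority)
         + arch.factor_loadings @ rng.normal(size=(arch.factor_loadings.shape[1], n))
         + rng.normal(0.0, config.m_noise_sd, size=(config.n_probes, n)))
    beta_vals = m_to_beta(M)

    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    probe_ids = list(arch.probe_ids)

    # QC-exercise probes: flag a few non-causal probes, append non-cg probes
    noncausal = np.setdiff1d(np.arange(config.n_probes), arch.causal_idx)
    flag_rng = np.random.default_rng([config.seed, 3])
    n_flag = config.n_cross_reactive + config.n_snp_proximal
    flagged = flag_rng.choice(noncausal, size=min(n_flag, len(noncausal)), replace=False)
    xr_idx = flagged[: config.n_cross_reactive]
    snp_idx = flagged[config.n_cross_reactive:]

    values = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)
    if config.n_non_cg:
        ch_ids = [f"ch.1.{i:06d}" for i in range(1, config.n_non_cg + 1)]
        ch_vals = m_to_beta(rng.normal(0.0, 1.0, size=(config.n_non_cg, n)))
        values = pd.concat([values,
                            pd.DataFrame(ch_vals, index=ch_ids, columns=sample_ids)])
    ann = make_annotation(values.index)
    ann.iloc[xr_idx, ann.columns.get_loc("is_cross_reactive")] = True
    ann.iloc[snp_idx, ann.columns.get_loc("is_snp_proximal")] = True
    ann["candidate"] = (ann["has_cg_prefix"] & ~ann["is_cross_reactive"]
                        & ~ann["is_snp_proximal"])

    beta = BetaMatrix(values, None, platform="array_v1", annotation=ann)

    # --- comparator clock, biomarkers, screener --------------------------
    grimage = 0.97 * age - 1.2 * g_true + rng.normal(0.0, 3.5, size=n)
    nfl = np.exp(2.5 + 0.03 * (age - config.age_mean) + 0.5 * rng.normal(size=n))
    gfap = np.exp(4.5 + 0.02 * (age - config.age_mean) + 0.5 * rng.normal(size=n))
    screener = np.clip(np.round(27.0 + 1.2 * g_true - 0.05 * (age - config.age_mean)
                                + rng.normal(0.0, 1.2, size=n)), 0, 30)

    pheno = pd.DataFrame({
        "age": age,
        "sex": np.where(female, "F", "M"),
        "education": education,
        "race": race,
        "hispanic": hispanic,
        "minority": minority,
        "batch": [f"plate{b + 1}" for b in batch],
        "mci": mci,
        **{c: cells[:, i] for i, c in enumerate(CELL_TYPES)},
        "grimage": grimage,
        "nfl": nfl,
        "gfap": gfap,
        "screener": screener,
    }, index=pd.Index(sample_ids, name="sample_id"))

    ab = (config.group_probe_shift, config.causal_effect_sd)
    truth = SyntheticTruth(
        g_true=pd.Series(g_true, index=pheno.index, name="g_true"),
        causal_probe_ids=[arch.probe_ids[i] for i in arch.causal_idx],
        causal_weights=pd.Series(arch.causal_weights, index=arch.probe_ids),
        mediator_paths={"a_probe_shift": ab[0], "b_probe_weight": ab[1],
                        "group_edu_effect": config.group_edu_effect,
                        "group_g_effect": config.group_g_effect},
        architecture=arch,
    )
    return pheno, beta, truth


def generate_test_battery(
    g_true: pd.Series,
    config: CohortConfig,
) -> pd.DataFrame:
    """Cognitive test battery: test_k = lambda_k * g + unique noise.

    Loadings are drawn uniformly from ``config.loading_range``; the unique
    noise SD is ``config.battery_noise_sd``.  Scores are reported on an
    arbitrary raw scale (mean 50, SD 10 per test) since the g-factor
    derivation is affine-invariant.
    """
    if config.battery_size < 2:
        raise ValueError("battery_size must be at least 2")
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.loading_range
    lam = rng.uniform(lo, hi, size=config.battery_size)
    g = np.asarray(g_true, dtype=float)
    noise = rng.normal(0.0, 1.0, size=(len(g), config.battery_size))
    latent = g[:, None] * lam[None, :] + config.battery_noise_sd * noise
    raw = 50.0 + 10.0 * latent
    cols = [f"test_{k + 1:02d}" for k in range(config.battery_size)]
    idx = g_true.index if isinstance(g_true, pd.Series) else pd.RangeIndex(len(g))
    return pd.DataFrame(raw, index=idx, columns=cols)


def split_platforms(
    beta: BetaMatrix,
    config: CohortConfig,
) -> tuple[BetaMatrix, BetaMatrix]:
    """Re-express a beta matrix on a second array platform.

    The second platform keeps a seeded random fraction ``platform_overlap``
    of probes, acquires per-cell detection failures at ``missing_rate``
    (cells set missing, detection p raised above 0.01), and duplicates
    ``n_replicate_loci`` loci as replicate probes to exercise collapsing.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    probes = beta.probe_ids
    n_keep = int(round(config.platform_overlap * len(probes)))
    keep_pos = np.sort(rng.choice(len(probes), size=n_keep, replace=False))
    kept = probes[keep_pos]

    values = beta.values.loc[kept].copy()
    ann = make_annotation(kept) if beta.annotation is None else beta.annotation.loc[kept].copy()

    # replicate probes: duplicate the first few kept loci with small noise
    n_rep = min(config.n_replicate_loci, len(kept))
    rep_src = list(kept[:n_rep])
    rep_rows, rep_ids = [], []
    for pid in rep_src:
        dup = np.clip(values.loc[pid].to_numpy()
                      + rng.normal(0.0, 0.01, size=beta.n_samples), 0.0, 1.0)
        rep_ids.append(f"{pid}_rep2")
        rep_rows.append(dup)
    if rep_ids:
        values = pd.concat([values, pd.DataFrame(rep_rows, index=rep_ids,
                                                 columns=values.columns)])
        rep_ann = make_annotation(rep_ids, locus_id=rep_src)
        # replicate ids lack the bare "cg" prefix check only if renamed oddly;
        # they inherit candidacy from their source locus
        rep_ann["has_cg_prefix"] = True
        rep_ann[["is_cross_reactive", "is_snp_proximal", "on_450k", "candidate"]] = \
            ann.loc[rep_src, ["is_cross_reactive", "is_snp_proximal", "on_450k", "candidate"]].to_numpy()
        ann = pd.concat([ann, rep_ann])

    detp = pd.DataFrame(rng.uniform(0.0, 0.009, size=values.shape),
                        index=values.index, columns=values.columns)
    if config.missing_rate > 0:
        fail = rng.random(values.shape) < config.missing_rate
        v = values.to_numpy()
        v[fail] = np.nan
        values = pd.DataFrame(v, index=values.index, columns=values.columns)
        d = detp.to_numpy()
        d[fail] = rng.uniform(0.011, 0.5, size=int(fail.sum()))
        detp = pd.DataFrame(d, index=values.index, columns=values.columns)

    second = BetaMatrix(values, detp, platform="array_v2", annotation=ann)
    return beta, second


def stratified_split(
    pheno: pd.DataFrame,
    train_fraction: float,
    strata: list[str],
    seed: int,
) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive train/test partition stratified on categorical columns.

    Within each stratum cell the training share is within one subject of
    ``train_fraction``.  Singleton cells go to the training set with a
    warning.
    """
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must be in [0, 1]")
    for col in strata:
        if col not in pheno.columns:
            raise ValueError(f"stratum column {col!r} not in phenotype table")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    groups = pheno.groupby(list(strata), sort=True, observed=True) if strata else [((), pheno)]
    for key, cell in groups:
        idx = cell.index.to_numpy()
        if len(idx) == 1 and train_fraction < 1.0:
            warnings.warn(f"stratum cell {key} has a single subject; "
                          "assigned to training", stacklevel=2)
            train_parts.append(idx)
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    train = pd.Index(np.concatenate(train_parts) if train_parts else [])
    test = pd.Index(np.concatenate(test_parts) if test_parts else [])
    # preserve the phenotype row order
    train = pheno.index[pheno.index.isin(train)]
    test = pheno.index[pheno.index.isin(test)]
    return train, test


def simulate_mediation_triple(
    n: int,
    a: float = 0.7,
    b: float = 0.5,
    direct: float = 0.65,
    edu_to_mediator: float = 0.0,
    treat_to_edu: float = 0.7,
    treat_prob: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear mediation benchmark with known paths.

    ``mediator = a*T + edu_to_mediator*E + e`` and
    ``outcome = b*mediator + direct*T + e``; with the defaults the
    population proportion mediated is a*b / (a*b + direct) = 0.35.
    Setting ``edu_to_mediator`` > 0 routes part of the treatment effect
    through an education column, so adjusting for education attenuates the
    mediated share.
    """
    rng = np.random.default_rng(seed)
    T = (rng.random(n) < treat_prob).astype(float)
    E = treat_to_edu * T + rng.normal(size=n)
    M = a * T + edu_to_mediator * E + rng.normal(size=n)
    Y = b * M + direct * T + rng.normal(size=n)
    return pd.DataFrame({"treatment": T, "education": E,
                         "mediator": M, "outcome": Y})


def external_cohort_config(seed: int = 7, **overrides) -> CohortConfig:
    """A clinic-based external validation cohort: smaller (n=112), younger
    (68.4 +/- 10.4 on [46, 89]), more educated, higher MCI prevalence
    (33%), a 14-test battery, and a reduced second-platform probe panel."""
    base = dict(
        n_subjects=112, age_range=(46.0, 89.0), age_mean=68.37, age_sd=10.44,
        mci_prevalence=0.33, battery_size=14, education_mean=16.2,
        education_sd=2.1, prop_female=0.70, race_probs=(0.857, 0.0, 0.143),
        prop_hispanic=0.089, n_batches=2, seed=seed,
    )
    base.update(overrides)
    return replace(CohortConfig(), **base)
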