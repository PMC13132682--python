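"""Four-stage workflow orchestration: derive g -> train -> internal test ->
external validation, behind one configuration object.

Every artifact is written under the output directory and listed in a
manifest with its content hash, the configuration snapshot, and the seeds
used, so a re-run with the same configuration reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as syn
from . import enet, gfactor, io, qc, scoring, stats
from .model import ScoreModel, read_model, write_model

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "methylcog_run"
    seed: int = 20251014
    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    external: syn.CohortConfig | None = None
    run_external: bool = True
    train_fraction: float = 0.7
    strata: tuple[str, ...] = ("mci", "race", "sex", "edu_tertile")
    alpha_grid: tuple[float, ...] = enet.DEFAULT_ALPHA_GRID
    n_folds: int = 10
    fold_seed: int = enet.DEFAULT_FOLD_SEED
    detection_p_threshold: float = 0.01
    max_missing: float = 0.10
    pc_z_cut: float = 3.0
    mediation_b: int = 1000

    def __post_init__(self):
        if not 0.0 < self.train_fraction <= 1.0:
            raise ConfigError("train_fraction must be in (0, 1]")
        if self.run_external and self.external is None:
            self.external = syn.external_cohort_config(seed=self.seed + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            for key in ("cohort", "external"):
                if key in raw and raw[key] is not None:
                    base = asdict(syn.CohortConfig()) if key == "cohort" else \
                        asdict(syn.external_cohort_config())
                    base.update(raw[key])
                    for tup in ("age_range", "loading_range", "race_probs"):
                        if tup in base:
                            base[tup] = tuple(base[tup])
                    raw[key] = syn.CohortConfig(**base)
            for tup in ("strata", "alpha_grid"):
                if tup in raw:
                    raw[tup] = tuple(raw[tup])
            return cls(**raw)
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.snapshot()
        d.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def qc_cohort(beta: qc.BetaMatrix, p_threshold: float = 0.01,
              pc_z_cut: float = 3.0) -> tuple[qc.BetaMatrix, dict]:
    """Standard QC chain: probe filters -> mask/impute -> collapse ->
    M-value PCA sample-outlier flagging (flagged samples dropped)."""
    ann = beta.annotation
    if ann is None:
        ann = qc.make_annotation(beta.probe_ids)
    b1, rep1 = qc.filter_probes(beta, ann)
    b2, rep2 = qc.mask_and_impute(b1, p_threshold=p_threshold)
    b3 = qc.collapse_replicates(b2, b2.annotation if b2.annotation is not None else ann)
    m = qc.beta_to_m(b3.values)
    flagged = qc.flag_pc_outliers(m, z_cut=pc_z_cut)
    if flagged:
        keep = [s for s in b3.sample_ids if s not in set(flagged)]
        b3 = qc.BetaMatrix(b3.values[keep], None, b3.platform, b3.annotation)
    report = {
        "probe_filter": rep1.to_dict(),
        "mask_impute": rep2.to_dict(),
        "pc_outlier_samples": list(flagged),
        "n_probes_out": b3.n_probes,
        "n_samples_out": b3.n_samples,
    }
    return b3, report


def _prep_pheno(pheno: pd.DataFrame) -> pd.DataFrame:
    out = pheno.copy()
    out["sex_male"] = (out["sex"] == "M").astype(float)
    out["edu_tertile"] = pd.qcut(out["education"], 3,
                                 labels=["low", "mid", "high"], duplicates="drop")
    return out


def _validate_cohort(pheno: pd.DataFrame, score_z: pd.Series,
                     mediation_b: int, seed: int,
                     screener_col: str = "screener") -> dict:
    """Full validation battery for one scored cohort."""
    ph = pheno.loc[score_z.index.intersection(pheno.index)]
    z = score_z.loc[ph.index]
    base = ph[["age", "sex_male", "education"]]
    report: dict = {}

    report["group_tests"] = {
        "mci": stats.group_tests(z, ph["mci"]),
        "race": stats.group_tests(z, ph["race"]),
        "age": stats.group_tests(z, ph["age"]),
    }
    report["incremental_validity"] = stats.incremental_r2(
        ph["g"], base, z.rename("methylcog")).to_dict()
    disc = stats.discrimination_suite(
        ph.assign(score=z), z, diagnosis_col="mci",
        base_cols=("age", "sex_male", "education"),
        screener_col=screener_col if screener_col in ph.columns else None)
    report["discrimination"] = disc.to_dict()

    # independence from the epigenetic-aging comparator
    if "grimage" in ph.columns:
        mc_resid = stats.residualize(z.rename("methylcog"), ph["age"])
        grim_resid = stats.residualize(ph["grimage"], ph["age"])
        report["clock_comparison"] = {
            "resid_correlation": stats.partial_correlation(mc_resid, grim_resid),
            "incremental_over_grim": stats.incremental_r2(
                ph["g"], grim_resid.to_frame("grim_resid"),
                mc_resid.rename("methylcog_resid")).to_dict(),
        }

    # biomarker partial correlations (age- and sex-adjusted)
    biomarkers = [c for c in ("nfl", "gfap") if c in ph.columns]
    if biomarkers:
        covs = ph[["age", "sex_male"]]
        report["biomarker_partial_r"] = {
            b: stats.partial_correlation(z, np.log(ph[b]), covs)
            for b in biomarkers
        }

    # moderation and mediation of the minority-group difference
    report["moderation_minority"] = stats.moderation_fit(
        ph["g"], z, ph["minority"], base[["age", "sex_male"]])
    med = stats.mediation_bootstrap(
        ph["minority"], z, ph["g"], ph[["age", "sex_male"]],
        B=mediation_b, seed=seed)
    med_edu = stats.mediation_bootstrap(
        ph["minority"], z, ph["g"], ph[["age", "sex_male", "education"]],
        B=mediation_b, seed=seed)
    report["mediation_minority"] = {"unadjusted": med.to_dict(),
                                    "education_adjusted": med_edu.to_dict()}

    # dual-criterion outlier sensitivity
    mask = stats.outlier_mask(z.to_numpy())
    pearson_all = stats.partial_correlation(z, ph["g"])
    keep = ~mask
    pearson_trim = stats.partial_correlation(z[keep], ph["g"][keep]) \
        if keep.sum() >= 3 else None
    report["outlier_sensitivity"] = {
        "n_flagged": int(mask.sum()),
        "r_all": pearson_all["r"],
        "r_without_outliers": None if pearson_trim is None else pearson_trim["r"],
    }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> QC -> g -> split -> train -> score -> validate.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def save(name, writer):
        path = outdir / name
        writer(path)
        artifacts[name] = _sha256(path)

    stage = "simulate"
    try:
        pheno_a, beta_a, truth_a = syn.generate_cohort(config.cohort)
        battery_a = syn.generate_test_battery(truth_a.g_true, config.cohort)
        if config.run_external:
            pheno_b, beta_b_full, truth_b = syn.generate_cohort(
                config.external, architecture=truth_a.architecture)
            _, beta_b = syn.split_platforms(beta_b_full, config.external)
            battery_b = syn.generate_test_battery(truth_b.g_true, config.external)
        else:
            logger.info("external cohort disabled; external stages skipped")

        stage = "qc"
        beta_a, qc_a = qc_cohort(beta_a, config.detection_p_threshold,
                                 config.pc_z_cut)
        reports = {"qc_discovery": qc_a}
        if config.run_external:
            beta_b, qc_b = qc_cohort(beta_b, config.detection_p_threshold,
                                     config.pc_z_cut)
            reports["qc_external"] = qc_b
        # candidate pool: allowlisted probes that survived QC in every cohort
        ann_a = beta_a.annotation
        pool = [p for p in beta_a.probe_ids
                if ann_a is None or bool(ann_a.loc[p, "candidate"])]
        if config.run_external:
            pool = [p for p in pool if p in set(beta_b.probe_ids)]
        reports["candidate_pool_size"] = len(pool)

        stage = "derive_g"
        battery_a = gfactor.impute_tests(battery_a)
        g_a = gfactor.derive_g(battery_a)
        pheno_a = _prep_pheno(pheno_a)
        pheno_a["g"] = g_a.g_scores
        reports["gfactor_discovery"] = g_a.to_dict()
        if config.run_external:
            g_b = gfactor.derive_g(gfactor.impute_tests(battery_b))
            pheno_b = _prep_pheno(pheno_b)
            pheno_b["g"] = g_b.g_scores
            reports["gfactor_external"] = g_b.to_dict()

        stage = "split"
        # restrict to samples that survived QC in their cohort
        pheno_a = pheno_a.loc[pheno_a.index.intersection(beta_a.sample_ids)]
        if config.run_external:
            pheno_b = pheno_b.loc[pheno_b.index.intersection(beta_b.sample_ids)]
        pheno_a = pheno_a.dropna(subset=["g"])
        train_idx, test_idx = syn.stratified_split(
            pheno_a, config.train_fraction, list(config.strata), config.seed)
        reports["split"] = {"n_train": len(train_idx), "n_test": len(test_idx)}

        stage = "train"
        beta_train = qc.BetaMatrix(beta_a.values[list(train_idx)], None,
                                   beta_a.platform, beta_a.annotation)
        design = enet.build_design(beta_train, pheno_a.loc[train_idx], pool,
                                   max_missing=config.max_missing)
        cv = enet.cross_validate(design, config.alpha_grid, config.n_folds,
                                 config.fold_seed)
        model = enet.select_and_fit(design, cv, meta={
            "config_hash": config.config_hash(), "seed": config.seed})
        save("model.json", lambda p: write_model(model, p))

        stage = "score"
        score_sets = {}
        for name, b, idx in [("train", beta_a, train_idx),
                             ("test", beta_a, test_idx)]:
            sub = qc.BetaMatrix(b.values[list(idx)], None, b.platform, b.annotation)
            ss = scoring.compute_score(sub, model, config.max_missing)
            score_sets[name] = ss
            save(f"scores_{name}.tsv", lambda p, ss=ss: io.write_table_tsv(ss.scores, p))
        if config.run_external:
            ss = scoring.compute_score(beta_b, model, config.max_missing)
            score_sets["external"] = ss
            save("scores_external.tsv", lambda p: io.write_table_tsv(ss.scores, p))

        stage = "validate"
        metrics = {}
        for name, ss in score_sets.items():
            ph = pheno_a if name in ("train", "test") else pheno_b
            g = ph["g"].loc[ph.index.intersection(ss.scores.index)]
            metrics[name] = scoring.evaluate_score(ss, g).to_dict()
        reports["score_metrics"] = metrics
        reports["validation_test"] = _validate_cohort(
            pheno_a.loc[test_idx], score_sets["test"].z,
            config.mediation_b, config.seed)
        if config.run_external:
            reports["validation_external"] = _validate_cohort(
                pheno_b, score_sets["external"].z,
                config.mediation_b, config.seed)
        save("report.json", lambda p: io.write_json(reports, p))
    except (ConfigError,):
        raise
    except Exception as e:
        partial = outdir / "manifest.partial.json"
        io.write_json({"failed_stage": stage, "error": str(e),
                       "artifacts": artifacts}, partial)
        raise StageError(stage, e) from e

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.snapshot(),
        "artifacts": artifacts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    io.write_json(manifest, outdir / "manifest.json")
    logger.info("pipeline complete in %.1fs; %d artifacts",
                manifest["elapsed_s"], len(artifacts))
    return manifest
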