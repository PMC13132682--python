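"""Serializable score-model artifact: CpG weights plus training scaling.

The JSON schema is versioned; readers refuse unknown versions and name the
offending field on malformed input, so a model trained once can be applied
to any later cohort bit-for-bit reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

SCHEMA_VERSION = 1


class ModelSchemaError(ValueError):
    """Raised when a model file has an unsupported version or a malformed field."""


@dataclass
class ScoreModel:
    """Final elastic-net artifact used for scoring.

    ``weights`` holds the nonzero CpG coefficients; ``scaling`` maps every
    candidate-pool probe to its training (mu, sigma) — sigma is NaN for
    probes that were unmeasured or constant in training, and such probes
    contribute zero at scoring time.  ``covariates`` are stored for
    provenance but never applied outside the training design.
    """

    alpha: float
    lam: float
    intercept: float
    weights: dict[str, float]
    scaling: dict[str, tuple[float, float]]
    raw_score_mean: float
    raw_score_sd: float
    covariates: dict[str, float] = field(default_factory=dict)
    fold_seed: int | None = None
    fold_assignment: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ModelSchemaError("model must contain at least one CpG weight")
        missing = set(self.weights) - set(self.scaling)
        if missing:
            raise ModelSchemaError(
                f"weighted probe(s) without scaling parameters: {sorted(missing)[:5]}")

    @property
    def probe_pool(self) -> list[str]:
        return list(self.scaling)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.intercept,
            "weights": [{"probe": p, "b": b} for p, b in self.weights.items()],
            "scaling": [{"probe": p, "mu": mu, "sigma": sigma}
                        for p, (mu, sigma) in self.scaling.items()],
            "raw_score": {"mean": self.raw_score_mean, "sd": self.raw_score_sd},
            "folds": {"seed": self.fold_seed, "assignment": self.fold_assignment},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unsupported model schema version {version!r} "
                f"(this reader supports version {SCHEMA_VERSION})")
        def _num(value, path):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ModelSchemaError(f"field {path!r} must be a number, "
                                       f"got {type(value).__name__}")
            return float(value)
        try:
            weights = {w["probe"]: _num(w["b"], f"weights[{i}].b")
                       for i, w in enumerate(d["weights"])}
            scaling = {s["probe"]: (_num(s["mu"], f"scaling[{i}].mu"),
                                    _num(s["sigma"], f"scaling[{i}].sigma"))
                       for i, s in enumerate(d["scaling"])}
            return cls(
                alpha=_num(d["alpha"], "alpha"),
                lam=_num(d["lambda"], "lambda"),
                intercept=_num(d["intercept"], "intercept"),
                weights=weights,
                scaling=scaling,
                raw_score_mean=_num(d["raw_score"]["mean"], "raw_score.mean"),
                raw_score_sd=_num(d["raw_score"]["sd"], "raw_score.sd"),
                covariates={k: _num(v, f"covariates.{k}")
                            for k, v in d.get("covariates", {}).items()},
                fold_seed=d.get("folds", {}).get("seed"),
                fold_assignment=d.get("folds", {}).get("assignment", {}),
                meta=d.get("meta", {}),
                schema_version=version,
            )
        except KeyError as e:
            raise ModelSchemaError(f"missing required field {e.args[0]!r}") from e


def write_model(model: ScoreModel, path: str | Path) -> None:
    d = model.to_dict()
    d["covariates"] = model.covariates
    Path(path).write_text(json.dumps(d, indent=1, allow_nan=True))


def read_model(path: str | Path) -> ScoreModel:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelSchemaError(f"malformed model JSON: {e}") from e
    return ScoreModel.from_dict(d)
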