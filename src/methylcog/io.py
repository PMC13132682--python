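"""Plain-text persistence: TSV for matrices and tables, JSON for reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import ANNOTATION_COLUMNS, BetaMatrix


def write_beta_tsv(beta: BetaMatrix, path: str | Path) -> None:
    """Probes as rows, samples as columns, first column the probe id."""
    df = beta.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def read_beta_tsv(path: str | Path, platform: str = "unknown",
                  annotation: pd.DataFrame | None = None) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BetaMatrix(df, None, platform, annotation)


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_pheno_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    return ann


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder,
                                     allow_nan=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
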