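"""Plain-text readers and writers for cohorts.

One delimited-text matrix file per subject per modality (square, tab
separated, header row of region labels), a JSON cohort manifest mapping
subject ids to file paths, a CSV table of cognitive scores and a JSON
ground-truth record when the cohort is synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_manifest",
    "read_manifest",
    "write_scores",
    "read_scores",
]


def write_matrix(path: str | Path, M: np.ndarray, region_labels: list[str]) -> None:
    pd.DataFrame(np.asarray(M), columns=list(region_labels)).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return M, list(df.columns)


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_scores(path: str | Path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, index_label="subject", float_format="%.12g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")
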