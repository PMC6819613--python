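"""Delimited-text I/O for omics matrices and label tables.

Matrix dialect: TSV, first column the sample ID (header cell ``sample_id``),
remaining header cells the feature IDs. Missing entries are written as
``NA``; empty strings are also accepted on read. Labels are a two-column
TSV (sample ID, integer subtype label).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .preprocess import OmicsMatrix

NA_TOKEN = "NA"


def write_omics_tsv(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    values = matrix.values.astype(object)
    values[matrix.missing_mask] = np.nan
    frame = pd.DataFrame(values, index=matrix.sample_ids, columns=matrix.feature_ids)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_omics_tsv(path: str | os.PathLike) -> OmicsMatrix:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN, ""], keep_default_na=False
    )
    values = frame.to_numpy(dtype=float)
    mask = np.isnan(values)
    values = np.where(mask, 0.0, values)
    return OmicsMatrix(
        values=values,
        sample_ids=[str(s) for s in frame.index],
        feature_ids=[str(c) for c in frame.columns],
        missing_mask=mask,
    )


def write_labels_tsv(
    sample_ids: list[str], labels: np.ndarray, path: str | os.PathLike
) -> None:
    frame = pd.DataFrame({"sample_id": sample_ids, "label": np.asarray(labels, int)})
    frame.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    return [str(s) for s in frame["sample_id"]], frame["label"].to_numpy(dtype=int)
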