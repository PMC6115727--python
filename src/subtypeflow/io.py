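"""TSV readers and writers for expression matrices, labels and results.

All on-disk formats are plain text: genes-in-rows TSV matrices with a header
row of sample IDs and a first column of gene IDs, and simple two-column label
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x samples TSV: header of sample IDs, first column gene IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_matrix_tsv(path: str | Path, values: np.ndarray, gene_ids, sample_ids) -> None:
    df = pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(matrix_path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an :class:`ExpressionMatrix` from a matrix TSV and an optional
    two-column (sample_id, group) annotation TSV."""
    values, gene_ids, sample_ids = read_matrix_tsv(matrix_path)
    group = None
    if labels_path is not None:
        ann = read_label_tsv(labels_path)
        missing = [s for s in sample_ids if s not in ann]
        if missing:
            raise ValueError(f"samples missing from annotation: {missing[:5]}")
        group = np.array([ann[s] for s in sample_ids], dtype=object)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids, group=group)


def read_label_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, label) into a dict. A header line is
    tolerated and detected by the first field being 'sample_id' or 'id'."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1} has fewer than 2 columns")
            if i == 0 and parts[0].lower() in {"sample_id", "id", "sample"}:
                continue
            out[parts[0]] = parts[1]
    return out


def write_label_tsv(path: str | Path, ids, labels, header=("sample_id", "label")) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, lab in zip(ids, labels):
            fh.write(f"{i}\t{lab}\n")


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
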