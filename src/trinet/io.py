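"""Plain-text I/O for all pipeline artifacts.

Matrices travel as TSV (feature ids in the first column, sample ids in
the header), sample tables as CSV, gene sets as GMT, target maps as
two-column TSV and reports as JSON.  Count layers are validated as
nonnegative integers on load; missing values (empty fields or NA) are
allowed only in the protein layer.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, OmicsMatrix, validate_sample_table


def load_matrix(path, layer: str) -> OmicsMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups[:5]}")
    if layer.endswith("_counts"):
        values = df.to_numpy()
        if np.isnan(values.astype(float)).any():
            rows, cols = np.where(np.isnan(values.astype(float)))
            raise ValueError(f"{path}: missing value at row {df.index[rows[0]]!r}, column {df.columns[cols[0]]!r}")
        frac, _ = np.modf(values.astype(float))
        if (frac != 0).any():
            rows, cols = np.where(frac != 0)
            raise ValueError(
                f"{path}: non-integer count {values[rows[0], cols[0]]!r} at "
                f"row {df.index[rows[0]]!r}, column {df.columns[cols[0]]!r}"
            )
        df = df.astype(np.int64)
    else:
        df = df.astype(float)
    return OmicsMatrix(df, layer)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def load_sample_table(path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path))


def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = tuple(parts[2:])
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            desc = sets.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_target_map(path) -> dict:
    """Two-column TSV (mirna_id, mrna_id) -> {mirna: sorted targets}."""
    out: dict = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header and header[0] != "mirna_id":  # headerless file: first row is data
            out.setdefault(header[0], set()).add(header[1])
        for row in reader:
            if len(row) >= 2:
                out.setdefault(row[0], set()).add(row[1])
    return {k: sorted(v) for k, v in out.items()}


def write_target_map(target_map: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for mi in sorted(target_map):
            for g in sorted(target_map[mi]):
                fh.write(f"{mi}\t{g}\n")
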