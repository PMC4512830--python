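"""Readers and writers for the pipeline's on-disk formats.

Expression matrices and DS matrices are plain TSV (feature or sample ids
in the first column, ids in the header); pathway collections are GMT
(set name, description, then gene ids, tab-separated); labels are a
two-column TSV mapping sample ids to {tumor, normal}; regulons, ground
truth and manifests are JSON.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .dea import TUMOR, NORMAL
from .pea import PathwayCollection

logger = logging.getLogger(__name__)


def read_expression(path) -> pd.DataFrame:
    """Read a features x samples TSV matrix.

    Duplicate feature ids are rejected; non-numeric cells raise an error
    naming the offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no features (empty file)") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    try:
        out = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    # integer matrices stay integer through a round-trip
    if (out.dtypes == float).all():
        flo = out.to_numpy()
        if ((flo == flo.round()) | pd.isna(flo)).all():
            as_int = out.astype("int64", errors="ignore")
            if (as_int.to_numpy() == flo).all():
                out = as_int
    return out


def write_expression(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    idx = matrix.index.name or "feature_id"
    matrix.to_csv(path, sep="\t", index_label=idx)


def read_labels(path) -> pd.Series:
    """Read a sample_id TAB {tumor,normal} file into a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly 2 columns")
    labels = df.iloc[:, 0].str.strip()
    bad = sorted(set(labels.unique()) - {TUMOR, NORMAL})
    if bad:
        raise ValueError(f"{path}: unexpected phenotype values {bad}")
    if labels.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    labels.name = "phenotype"
    return labels


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("phenotype").to_csv(Path(path), sep="\t",
                                      index_label="sample_id")


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file (name TAB description TAB gene...).

    Duplicate genes within a set are deduplicated with a warning; duplicate
    set names and lines with fewer than 3 fields are rejected with the line
    number.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning("%s:%d: set %r has repeated genes, deduplicated",
                               path, lineno, name)
            sets[name] = unique
    return PathwayCollection(sets=sets)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(Path(path), "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_ds_matrix(path) -> pd.DataFrame:
    """Read a samples x pathway-pairs DS matrix TSV."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index.name = "sample_id"
    return df


def write_ds_matrix(ds: pd.DataFrame, path) -> None:
    ds.to_csv(Path(path), sep="\t", index_label="sample_id")
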