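"""Plain-text readers and writers: matrices, sample sheets, gene sets, results.

All outputs are TSV or JSON.  Writers prepend ``#``-prefixed header comments
carrying the tool version, a short config hash and the seed, so every file
is self-describing; readers skip comment lines.  Round-trips preserve values
to full float precision (floats are written with repr-level precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataFormatError, ValidationError
from .expression import SAMPLE_SHEET_COLUMNS, ExpressionMatrix
from .orthology import GROUP_COLUMN, OrthologTable

FLOAT_FMT = "%.17g"


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _header_lines(meta: Mapping | None) -> list[str]:
    lines = [f"# epiconserve version={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def _write_tsv(path, df: pd.DataFrame, meta: Mapping | None,
               index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FMT)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"malformed TSV {path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise DataFormatError(f"missing file: {path}") from exc


# -- expression matrices + sample sheets -----------------------------------

def write_matrix(path, matrix: ExpressionMatrix,
                 meta: Mapping | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("unit", matrix.unit)
    _write_tsv(path, matrix.data, meta)


def write_sample_sheet(path, matrix_or_samples,
                       meta: Mapping | None = None) -> None:
    samples = (matrix_or_samples.samples
               if isinstance(matrix_or_samples, ExpressionMatrix)
               else matrix_or_samples)
    _write_tsv(path, samples, meta)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"replicate": "Int64"})
    if "sample_id" not in df.columns:
        raise DataFormatError(f"{path}: sample sheet needs a sample_id column")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: sample sheet missing columns {missing}")
    return df.set_index("sample_id")


def read_matrix(path, sample_sheet_path, unit: str = "raw") -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus its sample sheet.

    The matrix' first column is the gene/group id; remaining columns must be
    a subset-equal of the sample sheet's sample ids.
    """
    df = _read_tsv(path, index_col=0)
    samples = read_sample_sheet(sample_sheet_path)
    extra = [c for c in df.columns if c not in samples.index]
    if extra:
        raise DataFormatError(
            f"{path}: samples absent from sample sheet: {extra}")
    return ExpressionMatrix(df.astype(float), samples.loc[list(df.columns)],
                            unit)


# -- orthologue tables ------------------------------------------------------

def write_ortholog_table(path, table: OrthologTable,
                         meta: Mapping | None = None) -> None:
    _write_tsv(path, table.table, meta, index=False)


# (reading lives in orthology.load_ortholog_table, kept close to validation)


# -- gene sets ---------------------------------------------------------------

def write_gene_set(path, genes: Iterable[str],
                   meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_set(path) -> set[str]:
    """Newline-delimited ids; ``#`` comment lines ignored; empty file ok."""
    out = set()
    try:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" in line or " " in line:
                    raise DataFormatError(
                        f"{path}: line {lineno}: expected one id per line")
                out.add(line)
    except FileNotFoundError as exc:
        raise DataFormatError(f"missing file: {path}") from exc
    return out


# -- results -----------------------------------------------------------------

def write_results_tsv(path, df: pd.DataFrame,
                      meta: Mapping | None = None) -> None:
    _write_tsv(path, df, meta, index=False)


def write_de_table(path, called: pd.DataFrame, transition: str,
                   meta: Mapping | None = None) -> None:
    out = called.reset_index()
    out.insert(1, "transition", transition)
    out = out.rename(columns={out.columns[0]: GROUP_COLUMN})
    _write_tsv(path, out, meta, index=False)


def read_de_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    needed = {GROUP_COLUMN, "log2fc", "p", "q", "direction"}
    missing = needed - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: DE table missing columns {missing}")
    return df.set_index(GROUP_COLUMN)


def write_json(path, obj, meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": {"version": __version__, **(meta or {})}, **obj} \
        if isinstance(obj, dict) else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
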