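"""Delimited-text I/O, run manifests and seeding helpers.

All matrices are plain tab- or comma-separated text: one header row of feature
ids, one leading column of sample ids, rows = samples (cells or lines),
columns = features (genes or drugs). Missing values are empty fields and are
rejected at load unless explicitly allowed (drug-sensitivity matrices).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .glm import DesignMatrix

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path, allow_missing: bool) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for c in raw_header:
        if c in seen:
            raise ParseError(f"{path}: duplicate feature id {c!r}")
        seen.add(c)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    for j, c in enumerate(df.columns):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(
                f"{path}: non-numeric value at row {row!r}, column {c!r}"
            )
        df[c] = col
    if not allow_missing and df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def load_expression_matrix(path) -> DesignMatrix:
    """Load a samples x features matrix; delimiter auto-detected.

    Duplicate feature ids, ragged rows, non-numeric cells and missing values
    are parse errors carrying the offending row/column.
    """
    df = _read_table(path, allow_missing=False)
    return DesignMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], [str(i) for i in df.index])


def load_sensitivity_matrix(path):
    """Load a lines x drugs -log(GI50) matrix; empty fields become NaN."""
    df = _read_table(path, allow_missing=True)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], [str(i) for i in df.index]


def load_labels(path, sample_ids) -> np.ndarray:
    """Load a two-column (sample id, 0/1) file aligned to ``sample_ids``."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    mapping = {}
    for _, (sid, val) in df.iterrows():
        if val not in ("0", "1"):
            raise ParseError(f"{path}: non-binary label {val!r} for sample {sid!r}")
        if sid in mapping:
            raise ParseError(f"{path}: duplicate sample id {sid!r}")
        mapping[sid] = int(val)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ParseError(f"{path}: labels missing for samples {missing[:5]}")
    extra = [s for s in mapping if s not in set(sample_ids)]
    if extra:
        raise ParseError(f"{path}: labels for unknown samples {extra[:5]}")
    return np.asarray([mapping[s] for s in sample_ids], dtype=int)


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------


def save_matrix(matrix, path, sep: str = "\t") -> None:
    """Write a DesignMatrix or DataFrame as delimited text (stable float format)."""
    if isinstance(matrix, DesignMatrix):
        matrix = matrix.to_dataframe()
    matrix.to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def save_labels(labels, sample_ids, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}{sep}{int(lab)}\n")


# ---------------------------------------------------------------------------
# manifests and seeding
# ---------------------------------------------------------------------------


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run: command, parameters, seed, input digests."""

    command: str
    parameters: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def make_manifest(command: str, parameters: dict, seed: int, inputs: dict | None = None) -> RunManifest:
    from . import __version__

    digests = {name: file_digest(p) for name, p in (inputs or {}).items()}
    return RunManifest(
        command=command,
        parameters=parameters,
        seed=int(seed),
        input_digests=digests,
        software_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def log(msg: str, verbose: bool = True) -> None:
    if verbose:
        print(msg, file=sys.stderr)
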