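"""File formats: FC matrices and time series as delimited text, decomposition
bundles as plain-text directories, phenotype tables as CSV.

FC matrices are exchanged the way connectivity matrices usually are: a square
numeric table, comma- or tab-separated, with an optional single header row of
region labels.  A decomposition bundle is a directory holding the parameter
and matrix arrays as TSV (written with 17 significant digits, so round trips
are lossless at double precision) plus a JSON metadata record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AngleBasis, Decomposition, FCMatrix
from .signals import TimeSeriesMatrix

__all__ = [
    "read_fc",
    "write_fc",
    "write_decomposition",
    "read_decomposition",
    "read_phenotypes",
    "write_timeseries",
    "read_timeseries",
]

BUNDLE_SCHEMA_VERSION = 1
_ARRAY_FMT = "%.17e"
RACE_VOCABULARY = ("AA", "EA", "CA")


def _sniff_delimiter(line: str):
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def _is_numeric_row(tokens):
    try:
        for tok in tokens:
            float(tok)
    except ValueError:
        return False
    return True


def read_fc(path) -> FCMatrix:
    """Read and validate a square delimited FC matrix (optional label header)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(first)
    tokens = first.strip().split(delim)
    labels = None
    skip = 0
    if not _is_numeric_row(tokens):
        labels = [t.strip() for t in tokens if t.strip()]
        skip = 1
    try:
        arr = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"{path}: FC matrix must be square, got {arr.shape[0]} rows x "
            f"{arr.shape[1]} columns"
        )
    try:
        return FCMatrix(arr, region_labels=labels)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_fc(fc: FCMatrix, path, delimiter: str = "\t") -> None:
    path = Path(path)
    header = ""
    if fc.region_labels is not None:
        header = delimiter.join(fc.region_labels)
    np.savetxt(path, fc.values, fmt=_ARRAY_FMT, delimiter=delimiter,
               header=header, comments="")


_BUNDLE_ARRAYS = ("phases", "jitters", "reconstruction", "residual")


def write_decomposition(dec: Decomposition, path) -> None:
    """Write a decomposition bundle directory (arrays as TSV + meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {
        "phases": dec.basis.phases,
        "jitters": dec.basis.jitters,
        "reconstruction": dec.reconstruction,
        "residual": dec.residual,
    }
    if dec.fc is not None:
        arrays["fc"] = dec.fc.values
    for name, arr in arrays.items():
        np.savetxt(path / f"{name}.tsv", np.atleast_2d(arr), fmt=_ARRAY_FMT,
                   delimiter="\t")
    meta = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "n_regions": dec.n_regions,
        "n_bases": dec.n_bases,
        "seed": dec.seed,
        "final_loss": dec.final_loss,
        "n_iterations": dec.n_iterations,
        "angle_unit": "radians",
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_decomposition(path) -> Decomposition:
    """Lossless inverse of :func:`write_decomposition`; validates the schema."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{path}: not a decomposition bundle (missing meta.json)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    version = meta.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: bundle schema version {version!r}, expected {BUNDLE_SCHEMA_VERSION}"
        )
    for key in ("n_regions", "n_bases", "seed", "final_loss", "n_iterations"):
        if key not in meta:
            raise ValueError(f"{path}: bundle metadata missing field {key!r}")
    arrays = {}
    for name in _BUNDLE_ARRAYS:
        fpath = path / f"{name}.tsv"
        if not fpath.exists():
            raise ValueError(f"{path}: bundle missing array {name}.tsv "
                             f"(schema version {BUNDLE_SCHEMA_VERSION})")
        arrays[name] = np.loadtxt(fpath, delimiter="\t", ndmin=2)
    n, r = int(meta["n_bases"]), int(meta["n_regions"])
    if arrays["phases"].shape != (n, r) or arrays["reconstruction"].shape != (r, r):
        raise ValueError(f"{path}: bundle arrays inconsistent with metadata shapes")
    fc_path = path / "fc.tsv"
    fc = None
    if fc_path.exists():
        fc = FCMatrix(np.loadtxt(fc_path, delimiter="\t", ndmin=2))
    return Decomposition(
        basis=AngleBasis(phases=arrays["phases"], jitters=arrays["jitters"]),
        reconstruction=arrays["reconstruction"],
        residual=arrays["residual"],
        final_loss=float(meta["final_loss"]),
        n_iterations=int(meta["n_iterations"]),
        seed=int(meta["seed"]),
        fc=fc,
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-scan phenotype CSV.

    Requires a ``subject_id`` column; accepts any subset of scan_id, age, sex,
    race, diagnosis.  Duplicate (subject_id, scan_id) rows are an error.
    Unknown race labels are preserved but flagged in ``race_in_vocab`` (the
    two-ancestry filter is applied downstream, not here).
    """
    path = Path(path)
    table = pd.read_csv(path)
    if "subject_id" not in table.columns:
        raise ValueError(f"{path}: phenotype table missing required column 'subject_id'")
    if "scan_id" in table.columns:
        dup = table.duplicated(subset=["subject_id", "scan_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(f"{path}: duplicate (subject_id, scan_id) at row {row}")
    if "age" in table.columns and (table["age"] < 0).any():
        row = int(np.flatnonzero((table["age"] < 0).to_numpy())[0])
        raise ValueError(f"{path}: negative age at row {row}")
    if "race" in table.columns:
        table = table.copy()
        table["race_in_vocab"] = table["race"].isin(RACE_VOCABULARY)
    return table


def write_timeseries(ts: TimeSeriesMatrix, path) -> None:
    """Regions x samples TSV with a one-line ``# dt=...`` header."""
    np.savetxt(Path(path), ts.values, fmt=_ARRAY_FMT, delimiter="\t",
               header=f"dt={ts.dt!r}", comments="# ")


def read_timeseries(path) -> TimeSeriesMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# dt="):
        raise ValueError(f"{path}: missing '# dt=' header line")
    dt = float(first.split("=", 1)[1])
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return TimeSeriesMatrix(values=values, dt=dt)
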