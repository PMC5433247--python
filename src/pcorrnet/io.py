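"""Delimited-text readers and writers.

Timeseries are tab-delimited with a header row of ROI labels and one row
per sample; an optional JSON sidecar (same stem, ``.json``) carries
``tr_seconds`` and provenance.  Connectivity and ground-truth matrices are
square labeled TSV files with a leading ``#`` comment documenting the
(target-row, source-column) orientation.  Floats are serialized with 17
significant digits so write -> read round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError
from .netops import GroundTruthNetwork
from .pcorrelation import ConnectivityMatrix
from .simulate import TimeseriesSet

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "read_ground_truth",
    "file_checksum",
]

_FLOAT_FMT = "%.17g"
_ORIENTATION_COMMENT = (
    "# rows = target ROI j, columns = source ROI i; entry (j, i) "
    "quantifies the influence of i on j"
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_table(path: Path, what: str) -> pd.DataFrame:
    # header parsed by hand: pandas silently renames duplicate labels
    header = None
    n_comment_or_header = 0
    with path.open() as fh:
        for line in fh:
            n_comment_or_header += 1
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    if header is None or not header.strip():
        raise ParseError(f"{path}: empty {what} file")
    labels = header.split("\t")
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate ROI labels in header")
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=labels,
            skiprows=n_comment_or_header, dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: {what} file has a header but no rows") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if frame.empty:
        raise ParseError(f"{path}: {what} file has a header but no rows")
    values = np.empty(frame.shape, dtype=float)
    for r, row in enumerate(frame.itertuples(index=False), start=n_comment_or_header + 1):
        for c, cell in enumerate(row):
            try:
                if pd.isna(cell):
                    raise ValueError
                values[r - n_comment_or_header - 1, c] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric or missing cell at line {r}, "
                    f"column {labels[c]!r}"
                ) from None
    return pd.DataFrame(values, columns=labels)


def read_timeseries(path: str | Path) -> TimeseriesSet:
    """Load a samples x ROIs TSV file (header = ROI labels).

    Reads ``tr_seconds`` and ``subject_id`` from the JSON sidecar when one
    exists; otherwise TR defaults to 1.0 second.
    """
    path = Path(path)
    frame = _read_table(path, "timeseries")
    tr_seconds, subject_id = 1.0, path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr_seconds = float(meta.get("tr_seconds", 1.0))
        subject_id = str(meta.get("subject_id", subject_id))
    return TimeseriesSet(
        values=frame.to_numpy(),
        tr_seconds=tr_seconds,
        roi_labels=list(frame.columns),
        subject_id=subject_id,
    )


def write_timeseries(
    ts: TimeseriesSet, path: str | Path, sidecar: dict | None = None
) -> Path:
    """Write a TimeseriesSet as TSV plus a JSON sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join(ts.roi_labels) + "\n")
        np.savetxt(fh, ts.values, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {"tr_seconds": ts.tr_seconds, "subject_id": ts.subject_id}
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Load a square labeled TSV connectivity matrix."""
    path = Path(path)
    frame = _read_table(path, "matrix")
    if frame.shape[0] != frame.shape[1]:
        raise ParseError(
            f"{path}: matrix is {frame.shape[0]}x{frame.shape[1]}, expected square"
        )
    method_tag = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        method_tag = str(json.loads(sidecar.read_text()).get("method_tag", ""))
    return ConnectivityMatrix(
        values=frame.to_numpy(), roi_labels=list(frame.columns), method_tag=method_tag
    )


def write_matrix(
    M: ConnectivityMatrix, path: str | Path, sidecar: dict | None = None
) -> Path:
    """Write a ConnectivityMatrix as labeled TSV plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(_ORIENTATION_COMMENT + "\n")
        fh.write("\t".join(M.roi_labels) + "\n")
        np.savetxt(fh, M.values, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {"method_tag": M.method_tag}
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> GroundTruthNetwork:
    """Load a binary directed adjacency matrix (same orientation as above)."""
    M = read_matrix(path)
    values = M.values
    if not np.isin(values, (0.0, 1.0)).all():
        raise ParseError(f"{path}: ground-truth adjacency must contain only 0/1")
    try:
        return GroundTruthNetwork(adjacency=values.astype(int), roi_labels=M.roi_labels)
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for experiment manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
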