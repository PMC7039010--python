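"""Byte-offset indexing of delimited expression matrices.

A data file has one row per feature: a unique feature ID column, optional
feature-metadata columns, and numeric expression columns (one per sample).
Rather than loading the whole matrix, :func:`build_index` makes a single
streaming pass that records the byte offset and length of every data line,
validates numeric tokens, and collects the (small) feature-metadata columns.
Any single feature row can then be re-read with one ``seek`` + one read.

The index is serialized to a JSON sidecar next to the data file together
with a checksum of the data file (size + SHA-256 of the first and last
64 KiB); on load, a checksum mismatch forces re-indexing.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IndexingError

INDEX_FORMAT_VERSION = 1
SIDECAR_SUFFIX = ".xidx.json"
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "null")
_CHECKSUM_CHUNK = 64 * 1024


@dataclass
class Dialect:
    """Delimited-text conventions for a data file.

    Encoding is UTF-8; both LF and CRLF line endings are accepted (the
    carriage return is stripped at parse time but counted in row lengths).
    """

    delimiter: str = "\t"
    encoding: str = "utf-8"

    def to_dict(self) -> dict:
        return {"delimiter": self.delimiter, "encoding": self.encoding}

    @classmethod
    def from_dict(cls, d: dict) -> "Dialect":
        return cls(delimiter=d["delimiter"], encoding=d.get("encoding", "utf-8"))


def sniff_dialect(path: str | os.PathLike, encoding: str = "utf-8") -> Dialect:
    """Detect the delimiter from the header line (tab beats comma beats semicolon)."""
    with open(path, "rb") as fh:
        header = fh.readline().decode(encoding)
    for cand in ("\t", ",", ";"):
        if cand in header:
            return Dialect(delimiter=cand, encoding=encoding)
    return Dialect(delimiter="\t", encoding=encoding)


def file_checksum(path: str | os.PathLike) -> dict:
    """Size plus SHA-256 of the first and last 64 KiB of ``path``."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(_CHECKSUM_CHUNK)
        if size > _CHECKSUM_CHUNK:
            fh.seek(max(size - _CHECKSUM_CHUNK, 0))
            tail = fh.read(_CHECKSUM_CHUNK)
        else:
            tail = head
    return {
        "size": size,
        "head_sha256": hashlib.sha256(head).hexdigest(),
        "tail_sha256": hashlib.sha256(tail).hexdigest(),
    }


@dataclass
class MatrixIndex:
    """Random-access index over a delimited feature-by-sample data file.

    Invariants: ``len(row_offsets) == len(row_lengths) == len(feature_ids)``;
    feature IDs and sample-column names are unique; reading the byte slice
    ``[offset, offset + length)`` and parsing it reproduces the stored row.
    """

    data_path: str
    dialect: Dialect
    header: list[str]
    id_column: str
    feature_ids: list[str]
    row_offsets: np.ndarray
    row_lengths: np.ndarray
    numeric_columns: list[int]
    metadata_columns: list[int]
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    checksum: dict = field(default_factory=dict)
    feature_meta: pd.DataFrame | None = None

    # --- instrumentation: number of data rows parsed from disk -----------
    rows_read: int = 0

    def __post_init__(self) -> None:
        self._id_to_row = {fid: i for i, fid in enumerate(self.feature_ids)}
        self._missing = set(self.missing_tokens)

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def sample_columns(self) -> list[str]:
        """Names of the numeric (expression) columns, in file order."""
        return [self.header[i] for i in self.numeric_columns]

    # ------------------------------------------------------------------
    def _parse_line(self, raw: bytes) -> list[str]:
        text = raw.decode(self.dialect.encoding)
        return text.rstrip("\r\n").split(self.dialect.delimiter)

    def _numeric_values(self, fields: list[str]) -> np.ndarray:
        out = np.empty(len(self.numeric_columns), dtype=float)
        for k, pos in enumerate(self.numeric_columns):
            tok = fields[pos]
            if tok in self._missing:
                out[k] = np.nan
            else:
                out[k] = float(tok)
        return out

    def read_values(self, feature_id: str, _fh: io.BufferedReader | None = None) -> np.ndarray:
        """Expression values for one feature, read via its byte offset.

        Missing tokens become NaN. At most one row's bytes are read.
        """
        try:
            row = self._id_to_row[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature ID: {feature_id!r}") from None
        if _fh is None:
            with open(self.data_path, "rb") as fh:
                fh.seek(int(self.row_offsets[row]))
                raw = fh.read(int(self.row_lengths[row]))
        else:
            _fh.seek(int(self.row_offsets[row]))
            raw = _fh.read(int(self.row_lengths[row]))
        self.rows_read += 1
        return self._numeric_values(self._parse_line(raw))

    def iter_values(self, feature_ids: list[str] | None = None):
        """Yield ``(feature_id, values)`` one row at a time, single open handle.

        Rows are visited in index (on-disk) order unless ``feature_ids`` is
        given, in which case that order is honoured.
        """
        ids = self.feature_ids if feature_ids is None else feature_ids
        with open(self.data_path, "rb") as fh:
            for fid in ids:
                yield fid, self.read_values(fid, _fh=fh)

    # ------------------------------------------------------------------
    def sidecar_path(self) -> str:
        return str(self.data_path) + SIDECAR_SUFFIX

    def save(self, path: str | None = None) -> str:
        path = path or self.sidecar_path()
        doc = {
            "format_version": INDEX_FORMAT_VERSION,
            "dialect": self.dialect.to_dict(),
            "header": self.header,
            "id_column": self.id_column,
            "feature_ids": self.feature_ids,
            "row_offsets": [int(v) for v in self.row_offsets],
            "row_lengths": [int(v) for v in self.row_lengths],
            "numeric_columns": self.numeric_columns,
            "metadata_columns": self.metadata_columns,
            "missing_tokens": list(self.missing_tokens),
            "checksum": self.checksum,
            "feature_meta": None
            if self.feature_meta is None
            else self.feature_meta.reset_index().to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        return path

    @classmethod
    def from_sidecar(cls, data_path: str | os.PathLike, sidecar: str | None = None) -> "MatrixIndex":
        sidecar = sidecar or str(data_path) + SIDECAR_SUFFIX
        with open(sidecar, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format_version") != INDEX_FORMAT_VERSION:
            raise IndexingError(
                f"index format version mismatch in {sidecar}: "
                f"found {doc.get('format_version')}, expected {INDEX_FORMAT_VERSION}"
            )
        current = file_checksum(data_path)
        if current != doc["checksum"]:
            raise IndexingError(f"data file {data_path} changed since indexing; re-index required")
        fm = doc["feature_meta"]
        if fm is not None:
            fm = pd.DataFrame(fm).set_index(doc["id_column"])
        return cls(
            data_path=str(data_path),
            dialect=Dialect.from_dict(doc["dialect"]),
            header=doc["header"],
            id_column=doc["id_column"],
            feature_ids=doc["feature_ids"],
            row_offsets=np.asarray(doc["row_offsets"], dtype=np.int64),
            row_lengths=np.asarray(doc["row_lengths"], dtype=np.int64),
            numeric_columns=doc["numeric_columns"],
            metadata_columns=doc["metadata_columns"],
            missing_tokens=tuple(doc["missing_tokens"]),
            checksum=doc["checksum"],
            feature_meta=fm,
        )


def build_index(
    data_path: str | os.PathLike,
    dialect: Dialect | None = None,
    id_column: str | None = None,
    metadata_columns: list[str] | None = None,
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    write_sidecar: bool = True,
) -> MatrixIndex:
    """Index a delimited data file in one streaming pass.

    Parameters
    ----------
    data_path
        Delimited text file with a header row; one data row per feature.
    dialect
        Delimiter/encoding; auto-detected from the header when None.
    id_column
        Name of the unique feature-ID column (default: first column).
    metadata_columns
        Names of non-numeric feature-metadata columns. All remaining
        columns are treated as numeric expression columns and validated.
    missing_tokens
        Strings parsed as missing in numeric columns.

    Raises
    ------
    IndexingError
        On duplicate feature IDs (naming the ID), ragged rows (with line
        number) or non-numeric tokens in numeric columns (with coordinates).
    """
    data_path = str(data_path)
    if dialect is None:
        dialect = sniff_dialect(data_path)
    missing = set(missing_tokens)

    feature_ids: list[str] = []
    offsets: list[int] = []
    lengths: list[int] = []
    meta_rows: list[list[str]] = []
    seen: set[str] = set()

    with open(data_path, "rb") as fh:
        header_raw = fh.readline()
        header = header_raw.decode(dialect.encoding).rstrip("\r\n").split(dialect.delimiter)
        if id_column is None:
            id_column = header[0]
        if id_column not in header:
            raise IndexingError(f"id column {id_column!r} not in header")
        id_pos = header.index(id_column)
        meta_names = list(metadata_columns or [])
        for name in meta_names:
            if name not in header:
                raise IndexingError(f"metadata column {name!r} not in header")
        meta_pos = [header.index(m) for m in meta_names]
        numeric_pos = [
            i for i in range(len(header)) if i != id_pos and i not in meta_pos
        ]
        sample_names = [header[i] for i in numeric_pos]
        if len(set(sample_names)) != len(sample_names):
            dupes = sorted({s for s in sample_names if sample_names.count(s) > 1})
            raise IndexingError(f"duplicate sample column names: {dupes}")

        ncol = len(header)
        lineno = 1
        while True:
            offset = fh.tell()
            raw = fh.readline()
            if not raw:
                break
            lineno += 1
            text = raw.decode(dialect.encoding).rstrip("\r\n")
            if not text:
                continue  # trailing blank line
            fields = text.split(dialect.delimiter)
            if len(fields) != ncol:
                raise IndexingError(
                    f"ragged row at line {lineno}: expected {ncol} columns, found {len(fields)}"
                )
            fid = fields[id_pos]
            if fid in seen:
                raise IndexingError(f"duplicate feature ID {fid!r} at line {lineno}")
            seen.add(fid)
            for pos in numeric_pos:
                tok = fields[pos]
                if tok in missing:
                    continue
                try:
                    float(tok)
                except ValueError:
                    raise IndexingError(
                        f"non-numeric token {tok!r} at line {lineno}, "
                        f"column {header[pos]!r} (feature {fid!r})"
                    ) from None
            feature_ids.append(fid)
            offsets.append(offset)
            lengths.append(len(raw))
            meta_rows.append([fields[p] for p in meta_pos])

    feature_meta = pd.DataFrame(meta_rows, columns=meta_names)
    feature_meta.insert(0, id_column, feature_ids)
    feature_meta = feature_meta.set_index(id_column)

    idx = MatrixIndex(
        data_path=data_path,
        dialect=dialect,
        header=header,
        id_column=id_column,
        feature_ids=feature_ids,
        row_offsets=np.asarray(offsets, dtype=np.int64),
        row_lengths=np.asarray(lengths, dtype=np.int64),
        numeric_columns=numeric_pos,
        metadata_columns=meta_pos,
        missing_tokens=tuple(missing_tokens),
        checksum=file_checksum(data_path),
        feature_meta=feature_meta,
    )
    if write_sidecar:
        idx.save()
    return idx


def load_or_build_index(
    data_path: str | os.PathLike,
    dialect: Dialect | None = None,
    id_column: str | None = None,
    metadata_columns: list[str] | None = None,
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> MatrixIndex:
    """Load a valid sidecar index if present, otherwise (re-)build it."""
    sidecar = str(data_path) + SIDECAR_SUFFIX
    if os.path.exists(sidecar):
        try:
            return MatrixIndex.from_sidecar(data_path, sidecar)
        except (IndexingError, json.JSONDecodeError, KeyError):
            pass  # stale or corrupt sidecar: rebuild below
    return build_index(
        data_path,
        dialect=dialect,
        id_column=id_column,
        metadata_columns=metadata_columns,
        missing_tokens=missing_tokens,
    )
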