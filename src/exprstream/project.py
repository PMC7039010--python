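"""Projects: the virtual join of an indexed data file with its metadata.

A project combines (i) a byte-offset index over the feature-by-sample data
file, (ii) the feature-metadata columns of that file, and (iii) a separate
sample-metadata table keyed by sample ID. The two files are joined virtually
by their unique identifiers: every expression column must have exactly one
sample-metadata row (an orphan column is an error; an extra metadata row is
only a warning and is retained).

A recorded transform (currently ``log2(x + c)``) is a pure view applied on
read; the data file on disk is never modified. Sample groups are named,
order-preserving selections produced by metadata predicates (pandas
``query`` expressions), kept with their predicate for provenance.
"""

from __future__ import annotations

import json
import logging
import os
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PredicateError, ProjectError
from .index import (
    DEFAULT_MISSING_TOKENS,
    Dialect,
    MatrixIndex,
    build_index,
    load_or_build_index,
    sniff_dialect,
)

logger = logging.getLogger("exprstream")

PROJECT_FORMAT_VERSION = 1


@dataclass
class GroupSelection:
    """A named, ordered set of sample IDs with the predicate that made it."""

    name: str
    sample_ids: list[str]
    predicate: str = ""

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ProjectError(f"group {self.name!r} contains duplicate sample IDs")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExpressionVector:
    """One feature's expression across samples, transform already applied."""

    feature_id: str
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.sample_ids):
            raise ProjectError("values and sample_ids length mismatch")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def subset(self, sample_ids: list[str] | GroupSelection) -> np.ndarray:
        """Values for the given samples, in the given order."""
        if isinstance(sample_ids, GroupSelection):
            sample_ids = sample_ids.sample_ids
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.values[[pos[s] for s in sample_ids]]


@dataclass
class Transform:
    """Recorded expression transform: identity or log2(x + pseudocount)."""

    kind: str = "none"  # none | log2
    pseudocount: float = 1.0

    def apply(self, values: np.ndarray) -> tuple[np.ndarray, int]:
        """Return transformed values and the number of new missing cells."""
        if self.kind == "none":
            return values, 0
        arg = values + self.pseudocount
        bad = np.isfinite(arg) & (arg <= 0)
        out = np.where(bad, np.nan, arg)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log2(out)
        return out, int(bad.sum())


class Project:
    """Indexed data file + feature metadata + sample metadata + state."""

    def __init__(
        self,
        index: MatrixIndex,
        sample_meta: pd.DataFrame,
        sample_id_column: str,
        sample_meta_path: str | None = None,
    ):
        self.index = index
        self.sample_meta = sample_meta
        self.sample_id_column = sample_id_column
        self.sample_meta_path = sample_meta_path
        self.transform = Transform("none")
        self.transform_warnings = 0  # count of cells turned missing by the transform
        self.groups: dict[str, GroupSelection] = {}
        self.saved_results: dict[str, dict] = {}  # name -> {"table": df, "params": dict}
        self._validate_join()

    # ------------------------------------------------------------------
    def _validate_join(self) -> None:
        meta_ids = list(self.sample_meta.index.astype(str))
        if len(set(meta_ids)) != len(meta_ids):
            raise ProjectError("duplicate sample IDs in sample metadata")
        cols = self.index.sample_columns
        orphan = [c for c in cols if c not in set(meta_ids)]
        if orphan:
            raise ProjectError(
                "expression columns with no sample-metadata row: " + ", ".join(orphan)
            )
        extra = [s for s in meta_ids if s not in set(cols)]
        if extra:
            logger.warning(
                "%d sample-metadata rows have no expression column (retained): %s",
                len(extra),
                ", ".join(extra[:10]),
            )

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.index.feature_ids

    @property
    def sample_ids(self) -> list[str]:
        """Sample IDs in data-file column order."""
        return self.index.sample_columns

    @property
    def n_features(self) -> int:
        return self.index.n_features

    @property
    def n_samples(self) -> int:
        return len(self.index.numeric_columns)

    @property
    def feature_meta(self) -> pd.DataFrame:
        return self.index.feature_meta

    # ------------------------------------------------------------------
    def set_transform(self, kind: str, pseudocount: float = 1.0) -> "Project":
        """Record a transform view; re-setting replaces the previous one."""
        if kind not in ("none", "log2"):
            raise ProjectError(f"unknown transform kind {kind!r}")
        if pseudocount < 0:
            raise ProjectError("pseudocount must be >= 0")
        self.transform = Transform(kind, float(pseudocount))
        self.transform_warnings = 0
        return self

    def _apply_transform(self, values: np.ndarray) -> np.ndarray:
        out, n_bad = self.transform.apply(values)
        if n_bad:
            self.transform_warnings += n_bad
            logger.warning(
                "%d value(s) became missing under %s(x + %g)",
                n_bad,
                self.transform.kind,
                self.transform.pseudocount,
            )
        return out

    def get_feature(self, feature_id: str) -> ExpressionVector:
        """Read one feature row via its byte offset, transform applied."""
        values = self.index.read_values(feature_id)
        return ExpressionVector(feature_id, self._apply_transform(values), self.sample_ids)

    def iter_features(self, feature_ids: list[str] | None = None):
        """Stream ``ExpressionVector``s one row at a time (single pass)."""
        for fid, values in self.index.iter_values(feature_ids):
            yield ExpressionVector(fid, self._apply_transform(values), self.sample_ids)

    # ------------------------------------------------------------------
    def select_samples(self, predicate: str, name: str | None = None) -> GroupSelection:
        """Select samples by a metadata predicate (pandas query expression).

        Supported operators: ``==``, ``!=``, ``in [..]``, ``.str.contains``,
        numeric comparisons, ``and`` / ``or``. Order-preserving and
        deterministic; an empty selection is not an error.
        """
        sel = _query(self.sample_meta, predicate)
        ids = [str(s) for s in sel.index]
        # keep only samples that exist as expression columns, in metadata order
        present = set(self.sample_ids)
        ids = [s for s in ids if s in present]
        group = GroupSelection(name or predicate, ids, predicate)
        if name is not None:
            self.groups[name] = group
        return group

    def filter_features(
        self,
        predicate: str | None = None,
        min_value: float | None = None,
        min_samples: int = 1,
    ) -> list[str]:
        """Feature IDs passing a metadata predicate and/or an expression filter.

        The expression filter keeps features with ``value > min_value`` in at
        least ``min_samples`` samples, evaluated by streaming rows.
        """
        ids = self.feature_ids
        if predicate is not None:
            sel = _query(self.feature_meta, predicate)
            keep = set(sel.index.astype(str))
            ids = [f for f in ids if f in keep]
        if min_value is not None:
            passing = []
            for vec in self.iter_features(ids):
                if int(np.sum(vec.values > min_value)) >= min_samples:
                    passing.append(vec.feature_id)
            ids = passing
        return ids

    # ------------------------------------------------------------------
    def save_result(self, name: str, table: pd.DataFrame, params: dict | None = None) -> None:
        self.saved_results[name] = {"table": table, "params": params or {}}

    def save(self, path: str | os.PathLike) -> str:
        return save_project(self, path)


def _query(df: pd.DataFrame, predicate: str) -> pd.DataFrame:
    try:
        return df.query(predicate, engine="python")
    except pd.errors.UndefinedVariableError as exc:
        raise PredicateError(f"unknown field in predicate: {exc}") from exc
    except Exception as exc:  # syntax errors etc.
        raise PredicateError(f"bad predicate {predicate!r}: {exc}") from exc


# ----------------------------------------------------------------------
def create_project(
    data_path: str | os.PathLike,
    sample_meta_path: str | os.PathLike,
    dialect: Dialect | None = None,
    feature_id_column: str | None = None,
    sample_id_column: str | None = None,
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    reuse_index: bool = True,
) -> Project:
    """Create a project from a data file and a sample-metadata file.

    Feature-metadata columns are inferred: any data-file column whose name
    is neither the feature-ID column nor a sample ID present in the
    sample-metadata table is treated as feature metadata.
    """
    sm_dialect = sniff_dialect(sample_meta_path)
    sample_meta = pd.read_csv(sample_meta_path, sep=sm_dialect.delimiter, dtype={0: str})
    if sample_id_column is None:
        sample_id_column = sample_meta.columns[0]
    if sample_id_column not in sample_meta.columns:
        raise ProjectError(f"sample id column {sample_id_column!r} not in sample metadata")
    sample_meta[sample_id_column] = sample_meta[sample_id_column].astype(str)
    sample_meta = sample_meta.set_index(sample_id_column)

    if dialect is None:
        dialect = sniff_dialect(data_path)
    with open(data_path, "rb") as fh:
        header = fh.readline().decode(dialect.encoding).rstrip("\r\n").split(dialect.delimiter)
        first_row = fh.readline().decode(dialect.encoding).rstrip("\r\n").split(dialect.delimiter)
    fid_col = feature_id_column or header[0]
    known_samples = set(sample_meta.index.astype(str))
    # A column is feature metadata only if it is not a known sample AND its
    # first-row token is non-numeric; a numeric column missing from the
    # sample metadata stays an expression column so the orphan check fires.
    meta_cols = []
    for pos, name in enumerate(header):
        if name == fid_col or name in known_samples:
            continue
        tok = first_row[pos] if pos < len(first_row) else ""
        if tok in missing_tokens:
            continue
        try:
            float(tok)
        except ValueError:
            meta_cols.append(name)

    if reuse_index:
        index = load_or_build_index(
            data_path,
            dialect=dialect,
            id_column=fid_col,
            metadata_columns=meta_cols,
            missing_tokens=missing_tokens,
        )
    else:
        index = build_index(
            data_path,
            dialect=dialect,
            id_column=fid_col,
            metadata_columns=meta_cols,
            missing_tokens=missing_tokens,
        )
    return Project(index, sample_meta, sample_id_column, str(sample_meta_path))


# ----------------------------------------------------------------------
# Project archive (save/open). Single zip with JSON state + embedded
# sample metadata + a copy of the index sidecar + saved result tables.
# The raw data file is referenced by path, never embedded.
# ----------------------------------------------------------------------
def save_project(project: Project, path: str | os.PathLike) -> str:
    path = str(path)
    state = {
        "format_version": PROJECT_FORMAT_VERSION,
        "data_path": os.path.abspath(project.index.data_path),
        "sample_id_column": project.sample_id_column,
        "transform": {"kind": project.transform.kind, "pseudocount": project.transform.pseudocount},
        "groups": {
            name: {"sample_ids": g.sample_ids, "predicate": g.predicate}
            for name, g in project.groups.items()
        },
        "results": {
            name: {"params": rec["params"]} for name, rec in project.saved_results.items()
        },
    }
    tmp_sidecar = project.index.sidecar_path()
    if not os.path.exists(tmp_sidecar):
        project.index.save()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("project.json", json.dumps(state, indent=1))
        zf.writestr(
            "sample_meta.tsv",
            project.sample_meta.reset_index().to_csv(sep="\t", index=False),
        )
        with open(tmp_sidecar, "r", encoding="utf-8") as fh:
            zf.writestr("index.json", fh.read())
        for name, rec in project.saved_results.items():
            zf.writestr(f"results/{name}.tsv", rec["table"].to_csv(sep="\t", index=False))
    return path


def open_project(path: str | os.PathLike) -> Project:
    """Open a saved project archive; validates format version and data path."""
    path = str(path)
    if not os.path.exists(path):
        raise ProjectError(f"project file not found: {path}")
    with zipfile.ZipFile(path, "r") as zf:
        state = json.loads(zf.read("project.json"))
        if state.get("format_version") != PROJECT_FORMAT_VERSION:
            raise ProjectError(
                f"project format version mismatch: found {state.get('format_version')}, "
                f"expected {PROJECT_FORMAT_VERSION}"
            )
        data_path = state["data_path"]
        if not os.path.exists(data_path):
            raise ProjectError(f"referenced data file does not exist: {data_path}")
        sidecar_text = zf.read("index.json").decode("utf-8")
        sidecar_tmp = data_path + ".xidx.json"
        if not os.path.exists(sidecar_tmp):
            with open(sidecar_tmp, "w", encoding="utf-8") as fh:
                fh.write(sidecar_text)
        try:
            index = MatrixIndex.from_sidecar(data_path, sidecar_tmp)
        except Exception:
            doc = json.loads(sidecar_text)
            index = build_index(
                data_path,
                dialect=Dialect.from_dict(doc["dialect"]),
                id_column=doc["id_column"],
                metadata_columns=[doc["header"][i] for i in doc["metadata_columns"]],
                missing_tokens=tuple(doc["missing_tokens"]),
            )
        import io as _io

        sample_meta = pd.read_csv(
            _io.StringIO(zf.read("sample_meta.tsv").decode("utf-8")), sep="\t", dtype={0: str}
        )
        sid = state["sample_id_column"]
        sample_meta[sid] = sample_meta[sid].astype(str)
        sample_meta = sample_meta.set_index(sid)
        proj = Project(index, sample_meta, sid)
        t = state["transform"]
        proj.transform = Transform(t["kind"], t["pseudocount"])
        for name, g in state["groups"].items():
            proj.groups[name] = GroupSelection(name, g["sample_ids"], g["predicate"])
        for name, rec in state["results"].items():
            table = pd.read_csv(
                _io.StringIO(zf.read(f"results/{name}.tsv").decode("utf-8")), sep="\t"
            )
            proj.saved_results[name] = {"table": table, "params": rec["params"]}
    return proj
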