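"""Reading, writing and validation of the pipeline's tabular inputs.

Three file formats are supported, all plain TSV:

* expression matrices — first row ``feature_id<TAB>sample1<TAB>...``, one
  feature per row, real-valued cells;
* target interaction tables — two columns ``mirna_id<TAB>mrna_id`` (header
  optional);
* sample metadata — columns ``sample_id``, ``class_label`` and optionally
  ``time_to_event`` + ``event_flag``.

Validation is strict: duplicate identifiers and non-finite or missing cells
are rejected at parse time.  The mutual-information estimator downstream has
no missingness contract, so imputation (if any) must happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TargetNetwork",
    "SampleMetadata",
    "ParseError",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_targets",
    "write_targets",
    "union_targets",
    "read_metadata",
    "write_metadata",
    "align_samples",
]

CLASS_LABELS = ("normal", "primary", "metastatic")


class ValidationError(ValueError):
    """A structurally well-formed input violated a data-model invariant."""


class ParseError(ValueError):
    """An input file could not be parsed into the expected structure."""


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """A features × samples real-valued expression matrix.

    Values are arbitrary normalized expression levels, assumed continuous.
    Feature and sample identifiers must be unique and every cell finite.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_f = _find_duplicates(self.feature_ids)
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {dup_f}")
        dup_s = _find_duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {dup_s}")
        expected = (len(self.feature_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != (features, samples) {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def row(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples."""
        try:
            return self.values[self._index[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        rows = [self._index[f] for f in ids]
        return ExpressionMatrix(ids, list(self.sample_ids), self.values[rows])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [lookup[s] for s in ids]
        return ExpressionMatrix(list(self.feature_ids), ids, self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class TargetNetwork:
    """Directed miRNA→mRNA interaction records (predicted or validated)."""

    edges: frozenset
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.edges = frozenset((str(a), str(b)) for a, b in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set[str]:
        return {a for a, _ in self.edges}

    @property
    def mrnas(self) -> set[str]:
        return {b for _, b in self.edges}

    def targets(self, mirna_id: str) -> set[str]:
        return {b for a, b in self.edges if a == mirna_id}


@dataclass
class SampleMetadata:
    """Per-sample class labels and optional recurrence time/event columns."""

    sample_ids: list[str]
    class_label: list[str]
    time_to_event: Optional[np.ndarray] = None
    event_flag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        dup = _find_duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids in metadata: {dup}")
        if len(self.class_label) != len(self.sample_ids):
            raise ValidationError("class_label length mismatch")
        bad = sorted(set(self.class_label) - set(CLASS_LABELS))
        if bad:
            raise ValidationError(
                f"unknown class labels {bad}; expected one of {CLASS_LABELS}"
            )
        if (self.time_to_event is None) != (self.event_flag is None):
            raise ValidationError(
                "time_to_event and event_flag must be present together"
            )
        if self.time_to_event is not None:
            self.time_to_event = np.asarray(self.time_to_event, dtype=float)
            self.event_flag = np.asarray(self.event_flag, dtype=bool)
            if len(self.time_to_event) != len(self.sample_ids):
                raise ValidationError("time_to_event length mismatch")
            if len(self.event_flag) != len(self.sample_ids):
                raise ValidationError("event_flag length mismatch")
            if np.any(~np.isfinite(self.time_to_event)) or np.any(self.time_to_event < 0):
                raise ValidationError("time_to_event must be finite and nonnegative")

    @property
    def has_survival(self) -> bool:
        return self.time_to_event is not None

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = list(sample_ids)
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [lookup[s] for s in ids]
        labels = [self.class_label[i] for i in idx]
        if self.has_survival:
            return SampleMetadata(
                ids, labels, self.time_to_event[idx], self.event_flag[idx]
            )
        return SampleMetadata(ids, labels)

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "class_label": self.class_label}
        if self.has_survival:
            data["time_to_event"] = self.time_to_event
            data["event_flag"] = self.event_flag.astype(int)
        return pd.DataFrame(data)


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a TSV expression matrix (row 1 = sample ids, column 1 = feature ids)."""
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ParseError(
                f"{path}: non-numeric or missing cell at feature "
                f"{df.index[i]!r}, sample {col!r} (row {i + 2}, column {j + 2})"
            )
        # numpy's strtod is correctly rounded; pandas' fast parser can be
        # off by one ulp, which would break exact write/read round-trips
        values[:, j] = df[col].to_numpy(dtype=float)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            fh.write(fid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_targets(path, source_tag: str = "") -> TargetNetwork:
    """Read a two-column miRNA→mRNA interaction TSV; duplicate rows collapse."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            if lineno == 1 and parts == ["mirna_id", "mrna_id"]:
                continue  # optional header
            edges.add((parts[0].strip(), parts[1].strip()))
            n_rows += 1
    if not edges:
        logger.warning("%s: empty target table (0 edges)", path)
    else:
        logger.info(
            "%s: %d rows -> %d unique miRNA-mRNA edges", path, n_rows, len(edges)
        )
    return TargetNetwork(frozenset(edges), source_tag or path.stem)


def write_targets(net: TargetNetwork, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def union_targets(*nets: TargetNetwork, source_tag: str = "union") -> TargetNetwork:
    """Set-union of interaction tables (e.g. pooling validated-interaction databases)."""
    edges: set[tuple[str, str]] = set()
    for net in nets:
        edges |= set(net.edges)
    return TargetNetwork(frozenset(edges), source_tag)


def read_metadata(path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "class_label"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    time = event = None
    if "time_to_event" in df.columns or "event_flag" in df.columns:
        if not {"time_to_event", "event_flag"} <= set(df.columns):
            raise ParseError(
                f"{path}: time_to_event and event_flag must appear together"
            )
        time = pd.to_numeric(df["time_to_event"], errors="raise").to_numpy()
        event = pd.to_numeric(df["event_flag"], errors="raise").to_numpy().astype(bool)
    return SampleMetadata(
        list(df["sample_id"]), list(df["class_label"]), time, event
    )


def write_metadata(meta: SampleMetadata, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def align_samples(
    mir: ExpressionMatrix,
    mrna: ExpressionMatrix,
    meta: Optional[SampleMetadata] = None,
):
    """Restrict all inputs to their shared samples, in lexicographic order.

    The canonical (sorted) sample order makes permutation seeds reproduce
    across runs regardless of input file column order.
    """
    shared = set(mir.sample_ids) & set(mrna.sample_ids)
    if meta is not None:
        shared &= set(meta.sample_ids)
    if len(shared) < 2:
        raise ValidationError(
            f"insufficient overlapping samples: {len(shared)} shared "
            "(at least 2 required)"
        )
    order = sorted(shared)
    logger.info(
        "aligned on %d shared samples (dropped %d miRNA, %d mRNA)",
        len(order),
        mir.n_samples - len(order),
        mrna.n_samples - len(order),
    )
    mir_a = mir.subset_samples(order)
    mrna_a = mrna.subset_samples(order)
    meta_a = meta.subset(order) if meta is not None else None
    return mir_a, mrna_a, meta_a
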