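"""Count-table and sample-metadata I/O.

Feature tables are plain TSV: a header row of sample IDs (the first header
cell is the feature-ID column, conventionally ``#FeatureID``), one row per
feature, non-negative integer counts.  Lines starting with ``#`` before the
header are treated as comments.  Orientation is fixed as features x samples;
a transposed file is never auto-detected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diversity import AbundanceVector

GROUPS = ("disturbed", "control")
ASSAYS = ("taxonomic", "functional")


class TableValidationError(ValueError):
    """Raised when a count table or metadata table violates its contract."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's design annotation: which group and which assay."""

    sample_id: str
    group: str
    assay: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.assay not in ASSAYS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: assay must be one of {ASSAYS}, got {self.assay!r}"
            )


class CountTable:
    """Features x samples matrix of read counts with string IDs.

    Invariants enforced at construction: counts are non-negative integers,
    feature and sample IDs are unique, and every sample column has at least
    one read (empty samples are rejected).
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts)
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            as_int = np.asarray(counts, dtype=np.float64)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.floor(as_int)):
                bad = np.argwhere(
                    ~np.isfinite(as_int) | (as_int != np.floor(as_int))
                )[0]
                raise TableValidationError(
                    f"non-integer count at feature {feature_ids[bad[0]]!r}, "
                    f"sample {sample_ids[bad[1]]!r}"
                )
            counts = as_int.astype(np.int64)
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise TableValidationError(
                f"negative count at feature {feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        for name, ids in (("feature", feature_ids), ("sample", sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise TableValidationError(f"duplicate {name} ID {x!r}")
                seen.add(x)
        col_sums = counts.sum(axis=0)
        empty = np.nonzero(col_sums == 0)[0]
        if empty.size:
            raise TableValidationError(
                f"sample {sample_ids[empty[0]]!r} has zero total count"
            )
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.counts = counts
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        nf, ns = self.shape
        return f"<CountTable {nf} features x {ns} samples, {self.grand_total()} reads>"


def read_count_table(path: str | Path) -> CountTable:
    """Read and validate a features x samples TSV count table."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip()]
    # leading comment lines before the header
    start = 0
    while start < len(lines) and lines[start].startswith("#") and (
        start + 1 < len(lines)
        and lines[start].rstrip("\n").split("\t")[0] not in ("#FeatureID",)
    ):
        # "#FeatureID" marks the header itself; any other leading "#" line is a comment
        start += 1
    try:
        frame = pd.read_csv(
            io.StringIO("".join(lines[start:])),
            sep="\t",
            index_col=0,
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    sample_ids = [str(c) for c in frame.columns]
    if len(set(sample_ids)) != len(sample_ids) or any(
        c.endswith(f".{k}") and c[: -len(f".{k}")] in sample_ids
        for c in sample_ids
        for k in range(1, 10)
    ):
        # pandas mangles duplicate headers to "X.1"; detect both raw and mangled
        raise TableValidationError(f"{path}: duplicate sample ID in header")
    feature_ids = [str(i) for i in frame.index]
    values = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                values[i, j] = int(str(raw))
            except (TypeError, ValueError):
                raise TableValidationError(
                    f"{path}: non-integer count {raw!r} at feature "
                    f"{feature_ids[i]!r}, sample {col!r}"
                ) from None
    return CountTable(feature_ids, sample_ids, values)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table in the TSV dialect ``read_count_table`` accepts."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#FeatureID\t" + "\t".join(table.sample_ids) + "\n")
        for fid, row in zip(table.feature_ids, table.counts):
            fh.write(fid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a metadata TSV with columns sample_id, group, assay, label."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    required = {"sample_id", "group", "assay"}
    missing = required - set(frame.columns)
    if missing:
        raise TableValidationError(f"{path}: metadata missing columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                assay=str(row["assay"]),
                label="" if "label" not in frame.columns or pd.isna(row.get("label")) else str(row["label"]),
            )
        )
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        {"sample_id": m.sample_id, "group": m.group, "assay": m.assay, "label": m.label}
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def column_vector(table: CountTable, sample_id: str) -> AbundanceVector:
    """Extract one sample's abundance vector (zero-count features dropped)."""
    if sample_id not in table._sample_index:
        raise KeyError(f"unknown sample ID {sample_id!r}")
    col = table.counts[:, table._sample_index[sample_id]]
    return AbundanceVector.from_counts(col, sample_id=sample_id)


def split_groups(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    assay: str,
) -> tuple[list[AbundanceVector], list[AbundanceVector]]:
    """Partition a table's samples into (disturbed, control) abundance vectors.

    Only metadata rows matching *assay* are considered; every sample in the
    table must be covered by a metadata row for that assay.
    """
    if assay not in ASSAYS:
        raise TableValidationError(f"assay must be one of {ASSAYS}, got {assay!r}")
    by_sample = {m.sample_id: m for m in metadata if m.assay == assay}
    disturbed, control = [], []
    for sid in table.sample_ids:
        meta = by_sample.get(sid)
        if meta is None:
            raise TableValidationError(
                f"sample {sid!r} has no metadata row for assay {assay!r}"
            )
        vec = column_vector(table, sid)
        (disturbed if meta.group == "disturbed" else control).append(vec)
    return disturbed, control
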