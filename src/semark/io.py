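"""Readers, writers and validated in-memory containers for all tabular formats.

Everything here is plumbing: tab/comma-separated tables in, validated
containers out, with strict rejection of malformed input (no silent
coercion). Science lives in the sibling modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FPKM_TISSUES, QPCR_TISSUES, check_tissues

logger = logging.getLogger("semark")

#: token used in Ct tables for reactions below the detection limit
UNDETECTED_TOKEN = "ND"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# FPKM expression matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FpkmMatrix:
    """A transcript-by-tissue FPKM expression table.

    ``values`` has one row per transcript and one column per tissue; all
    entries are finite and non-negative, and both id axes are unique.
    """

    transcript_ids: tuple[str, ...]
    tissues: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.transcript_ids), len(self.tissues)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.tissues)} tissues"
            )
        if vals.size and not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite FPKM value for transcript "
                f"{self.transcript_ids[bad[0]]!r}, tissue {self.tissues[bad[1]]!r}"
            )
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative FPKM value for transcript "
                f"{self.transcript_ids[bad[0]]!r}, tissue {self.tissues[bad[1]]!r}"
            )
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            seen: set[str] = set()
            dup = next(t for t in self.transcript_ids if t in seen or seen.add(t))
            raise ValueError(f"duplicate transcript id {dup!r}")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError(f"duplicate tissue label in {self.tissues}")
        object.__setattr__(self, "transcript_ids", tuple(self.transcript_ids))
        object.__setattr__(self, "tissues", tuple(self.tissues))
        object.__setattr__(self, "values", vals)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def column(self, tissue: str) -> np.ndarray:
        try:
            return self.values[:, self.tissues.index(tissue)]
        except ValueError:
            raise KeyError(f"tissue {tissue!r} not in matrix (has {self.tissues})") from None

    def row(self, transcript_id: str) -> dict[str, float]:
        i = self.transcript_ids.index(transcript_id)
        return dict(zip(self.tissues, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.tissues))
        df.insert(0, "transcript_id", list(self.transcript_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FpkmMatrix":
        if df.columns[0] != "transcript_id":
            raise ValueError(
                f"first column must be 'transcript_id', got {df.columns[0]!r}"
            )
        tissues = tuple(str(c) for c in df.columns[1:])
        ids = tuple(str(t) for t in df["transcript_id"])
        return cls(ids, tissues, df.iloc[:, 1:].to_numpy(dtype=float))


def read_fpkm_table(path: str | Path, tissues: Sequence[str] = FPKM_TISSUES) -> FpkmMatrix:
    """Read a transcript x tissue FPKM table (TSV, or CSV by extension).

    The header row must name ``transcript_id`` followed by tissue columns;
    duplicate ids, missing cells, non-numeric or negative values are all
    rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.columns[0] != "transcript_id":
        raise ValueError(
            f"{path}: malformed header — first column must be 'transcript_id', "
            f"got {df.columns[0]!r}"
        )
    check_tissues(df.columns[1:], tissues, f"{path}: header")
    missing = [t for t in tissues if t not in df.columns[1:]]
    if missing:
        raise ValueError(f"{path}: malformed header — missing tissue column(s) {missing}")
    for col in df.columns[1:]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.loc[numeric.isna(), "transcript_id"].iloc[0]
            raise ValueError(
                f"{path}: missing or non-numeric FPKM in column {col!r}, transcript {row!r}"
            )
        df[col] = numeric
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate transcript id {dup.iloc[0]!r}")
    matrix = FpkmMatrix.from_frame(df[["transcript_id", *tissues]])
    logger.info("read %d transcripts x %d tissues from %s", matrix.n_transcripts, len(tissues), path)
    return matrix


def write_fpkm_table(matrix: FpkmMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# RT-qPCR Ct measurements (long format)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    tissue: str
    gene: str
    replicate: int
    ct: float | None  #: None means the reaction stayed below detection

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass(frozen=True)
class CtDataset:
    """Long-format qPCR cycle-threshold measurements."""

    records: tuple[CtRecord, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for r in self.records:
            key = (r.tissue, r.gene, r.replicate)
            if key in seen:
                raise ValueError(f"duplicate replicate index for {key}")
            seen.add(key)
            if r.ct is not None and not (np.isfinite(r.ct) and r.ct > 0):
                raise ValueError(f"Ct must be a positive finite number, got {r.ct} for {key}")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({r.gene for r in self.records}))

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({r.tissue for r in self.records}))

    def subset(self, gene: str | None = None, tissue: str | None = None) -> tuple[CtRecord, ...]:
        return tuple(
            r
            for r in self.records
            if (gene is None or r.gene == gene) and (tissue is None or r.tissue == tissue)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": [r.tissue for r in self.records],
                "gene": [r.gene for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "ct": [UNDETECTED_TOKEN if r.ct is None else r.ct for r in self.records],
            }
        )


def read_ct_long(path: str | Path, tissues: Sequence[str] = QPCR_TISSUES) -> CtDataset:
    """Read long-format Ct measurements; ``ND`` marks undetected reactions."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ["tissue", "gene", "replicate", "ct"]
    if list(df.columns[: len(required)]) != required:
        raise ValueError(f"{path}: malformed header — expected columns {required}, got {list(df.columns)}")
    check_tissues(df["tissue"], tissues, f"{path}: tissue column")
    records = []
    for _, row in df.iterrows():
        raw = str(row["ct"]).strip()
        if raw == UNDETECTED_TOKEN:
            ct: float | None = None
        else:
            try:
                ct = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric Ct {raw!r} (only {UNDETECTED_TOKEN!r} is allowed) "
                    f"for gene {row['gene']!r}, tissue {row['tissue']!r}"
                ) from None
        records.append(CtRecord(row["tissue"], row["gene"], int(row["replicate"]), ct))
    dataset = CtDataset(tuple(records))
    logger.info("read %d Ct records from %s", len(records), path)
    return dataset


def write_ct_long(dataset: CtDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Annotation and GO tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "transcript_id",
    "database",
    "hit_accession",
    "description",
    "species",
    "e_value",
    "length_bp",
]
GO_COLUMNS = ["transcript_id", "go_id", "go_name", "category"]


def read_annotation_table(path: str | Path):
    """Read a minimal tabular export of database search hits.

    Columns: transcript_id, database (swissprot|ncbi_nt), hit_accession,
    description, species, e_value, length_bp.
    """
    from .annotate import AnnotationRecord  # local import avoids a cycle

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(f"{path}: expected columns {ANNOTATION_COLUMNS}, got {list(df.columns)}")
    records = [
        AnnotationRecord(
            transcript_id=row["transcript_id"],
            database=row["database"],
            hit_accession=row["hit_accession"],
            description=row["description"],
            species=row["species"],
            e_value=float(row["e_value"]),
            length_bp=int(row["length_bp"]),
        )
        for _, row in df.iterrows()
    ]
    logger.info("read %d annotation records from %s", len(records), path)
    return records


def read_go_table(path: str | Path):
    """Read per-transcript GO assignments (transcript_id, go_id, go_name, category)."""
    from .annotate import GoAnnotation

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if list(df.columns) != GO_COLUMNS:
        raise ValueError(f"{path}: expected columns {GO_COLUMNS}, got {list(df.columns)}")
    records = [
        GoAnnotation(
            transcript_id=row["transcript_id"],
            go_id=row["go_id"],
            go_name=row["go_name"],
            category=row["category"],
        )
        for _, row in df.iterrows()
    ]
    logger.info("read %d GO annotations from %s", len(records), path)
    return records


def read_dilution_series(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read standard-curve dilution points: columns gene, copies, ct."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = ["gene", "copies", "ct"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    series: dict[str, list[tuple[float, float]]] = {}
    for _, row in df.iterrows():
        series.setdefault(str(row["gene"]), []).append((float(row["copies"]), float(row["ct"])))
    return series
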