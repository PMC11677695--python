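"""Annotation joins: coverage, species tallies, GO rankings, candidate picks.

Consumes tabular exports of homology searches (Swiss-Prot protein hits and
NCBI-nt nucleotide hits, with E-values) and Blast2GO-style per-transcript
GO assignments; no searches are executed here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import SE_SUBSETS, round_half_up
from .deg import DegClassification
from .io import FpkmMatrix

DATABASES = ("swissprot", "ncbi_nt")
GO_CATEGORIES = ("biological_process", "cellular_component", "molecular_function")

#: ontology roots excluded from term rankings as uninformative
DEFAULT_GO_BLOCKLIST = frozenset({"GO:0008150", "GO:0003674", "GO:0005575"})

#: Swiss-Prot evidence beats nucleotide evidence when both pass the E cutoff
DEFAULT_E_THRESHOLD = 1e-15

_GO_PATTERN = re.compile(r"^GO:\d{7}$")

#: when one transcript sits in several SE subsets its candidate record keeps
#: the most specific label (smallest typical subset first)
_SUBSET_PRIORITY = ("all_se", "ec_induction", "late_se", "early_se")


@dataclass(frozen=True)
class AnnotationRecord:
    """One database hit for one transcript."""

    transcript_id: str
    database: str
    hit_accession: str
    description: str
    species: str
    e_value: float
    length_bp: int

    def __post_init__(self) -> None:
        if self.database not in DATABASES:
            raise ValueError(f"database must be one of {DATABASES}, got {self.database!r}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.length_bp < 1:
            raise ValueError(f"length_bp must be >= 1, got {self.length_bp}")


@dataclass(frozen=True)
class GoAnnotation:
    """One GO term assignment for one transcript."""

    transcript_id: str
    go_id: str
    go_name: str
    category: str

    def __post_init__(self) -> None:
        if not _GO_PATTERN.match(self.go_id):
            raise ValueError(f"go_id must match 'GO:' + 7 digits, got {self.go_id!r}")
        if self.category not in GO_CATEGORIES:
            raise ValueError(f"category must be one of {GO_CATEGORIES}, got {self.category!r}")


@dataclass(frozen=True)
class CandidateGene:
    """A marker candidate: transcript, chosen annotation (or none), subset, profile."""

    transcript_id: str
    gene_symbol: str
    chosen_annotation: AnnotationRecord | None
    subset: str
    fpkm_profile: tuple[float, ...]


@dataclass(frozen=True)
class CoverageStats:
    annotated_count: int
    na_count: int
    annotated_pct: float
    na_pct: float


def coverage_stats(
    subset_members: Iterable[str],
    records: Sequence[AnnotationRecord],
    database: str,
) -> CoverageStats:
    """Fraction of subset members with at least one hit in ``database``.

    Percentages are of the subset size, half-up rounded to 2 decimals; the
    NA percentage is computed as the complement count's share (so the two
    always sum to 100 within rounding).
    """
    members = set(subset_members)
    if not members:
        raise ValueError("coverage of an empty subset is undefined")
    if database not in DATABASES:
        raise ValueError(f"database must be one of {DATABASES}, got {database!r}")
    hit_ids = {r.transcript_id for r in records if r.database == database}
    annotated = len(members & hit_ids)
    na = len(members) - annotated
    return CoverageStats(
        annotated_count=annotated,
        na_count=na,
        annotated_pct=round_half_up(100.0 * annotated / len(members)),
        na_pct=round_half_up(100.0 * na / len(members)),
    )


def best_hits(records: Sequence[AnnotationRecord], database: str) -> dict[str, AnnotationRecord]:
    """One best record per transcript within a database.

    Lowest E-value wins; exact ties break by lexicographic accession.
    """
    best: dict[str, AnnotationRecord] = {}
    for rec in records:
        if rec.database != database:
            continue
        cur = best.get(rec.transcript_id)
        if cur is None or (rec.e_value, rec.hit_accession) < (cur.e_value, cur.hit_accession):
            best[rec.transcript_id] = rec
    return best


def species_tally(
    records: Sequence[AnnotationRecord], database: str, top_n: int = 30
) -> list[tuple[str, int]]:
    """Count transcripts per best-hit species, descending, truncated to top_n."""
    counts = Counter(rec.species for rec in best_hits(records, database).values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def go_top_terms(
    subset_unique_members: Iterable[str],
    annotations: Sequence[GoAnnotation],
    category: str,
    n: int = 10,
    blocklist: frozenset[str] = DEFAULT_GO_BLOCKLIST,
) -> list[tuple[str, str, int]]:
    """Rank GO terms of one category by distinct member-transcript count.

    Root terms in ``blocklist`` never appear. Ties break by GO id ascending;
    output truncated to ``n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    members = set(subset_unique_members)
    per_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for ann in annotations:
        if ann.category != category or ann.go_id in blocklist:
            continue
        if ann.transcript_id in members:
            per_term.setdefault(ann.go_id, set()).add(ann.transcript_id)
            names.setdefault(ann.go_id, ann.go_name)
    ranked = sorted(per_term.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(go_id, names[go_id], len(t)) for go_id, t in ranked[:n]]


def select_candidates(
    classification: DegClassification,
    matrix: FpkmMatrix,
    records: Sequence[AnnotationRecord],
    e_threshold: float = DEFAULT_E_THRESHOLD,
    include_unannotated: bool = False,
    symbol_prefix: str = "Ce",
) -> list[CandidateGene]:
    """Pick annotated marker candidates from the SE subsets.

    For each SE-subset member the Swiss-Prot best hit is chosen when its
    E-value is strictly below ``e_threshold``; otherwise the NCBI-nt best
    hit under the same cutoff; otherwise the transcript is emitted without
    an annotation only when ``include_unannotated`` is set (the route that
    surfaced the study's unannotated *NA* transcripts). Candidates carry
    their most specific subset label and full FPKM profile.
    """
    if e_threshold <= 0:
        raise ValueError(f"e_threshold must be > 0, got {e_threshold}")
    sp_best = best_hits(records, "swissprot")
    nt_best = best_hits(records, "ncbi_nt")
    se_members = classification.se_memberships()
    subset_of: dict[str, str] = {}
    for label in _SUBSET_PRIORITY:
        for tid in se_members.get(label, ()):
            subset_of.setdefault(tid, label)
    candidates: list[CandidateGene] = []
    na_counter = 0
    for tid in sorted(subset_of):
        chosen: AnnotationRecord | None = None
        sp = sp_best.get(tid)
        if sp is not None and sp.e_value < e_threshold:
            chosen = sp
        else:
            nt = nt_best.get(tid)
            if nt is not None and nt.e_value < e_threshold:
                chosen = nt
        if chosen is None and not include_unannotated:
            continue
        if chosen is None:
            na_counter += 1
            symbol = f"{symbol_prefix}NA{na_counter}"
        else:
            symbol = f"{symbol_prefix}{chosen.hit_accession}"
        candidates.append(
            CandidateGene(
                transcript_id=tid,
                gene_symbol=symbol,
                chosen_annotation=chosen,
                subset=subset_of[tid],
                fpkm_profile=tuple(float(v) for v in matrix.row(tid).values()),
            )
        )
    return candidates
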