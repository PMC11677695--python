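"""FPKM rule-based classification of transcripts into marker subsets.

The study design compares six pooled tissue transcriptomes (no replicates,
one FPKM value per tissue), so differential expression is defined by
explicit FPKM rules rather than by a count-based statistical test:

* three tissue-specific subsets (rosette leaf, rosette root, adventitious
  bud): expressed in the target tissue (FPKM >= 1) and at least 8-fold
  higher there than in every other tissue;
* four somatic-embryogenesis (SE) subsets: embryogenic-callus induction,
  early SE, late SE, and the strictest all-SE-stages subset.

"At least N times higher" is implemented multiplicatively,
``target >= fold * comparator``, so zero-FPKM comparators need no special
case and boundary equality passes. "Higher than" is strict.

Rules are declarative (disjunctions of conjunctions of three atom kinds),
evaluated vectorised over the whole matrix; :func:`classify_bruteforce`
re-evaluates them transcript-by-transcript as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .config import ALL_SUBSETS, RunConfig, SE_SUBSETS
from .io import FpkmMatrix


# ---------------------------------------------------------------------------
# Rule atoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinFpkm:
    """Transcript counts as expressed in ``tissue``: FPKM >= threshold."""

    tissue: str
    threshold: float


@dataclass(frozen=True)
class FoldAtLeast:
    """Non-strict fold test: FPKM[target] >= fold * FPKM[comparator]."""

    target: str
    comparator: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"fold must be > 0, got {self.fold}")


@dataclass(frozen=True)
class StrictlyGreater:
    """Strict comparison: FPKM[target] > FPKM[comparator]."""

    target: str
    comparator: str


Atom = Union[MinFpkm, FoldAtLeast, StrictlyGreater]


@dataclass(frozen=True)
class SubsetRule:
    """A subset definition in disjunctive normal form.

    ``clauses`` is a tuple of conjunctive clauses (tuples of atoms); a
    transcript is a member when at least one clause holds in full. All
    built-in rules are single-clause conjunctions except the early-SE rule,
    which disjoins over the two early embryogenic tissues.
    """

    name: str
    clauses: tuple[tuple[Atom, ...], ...]

    def tissues(self) -> set[str]:
        out: set[str] = set()
        for clause in self.clauses:
            for atom in clause:
                if isinstance(atom, MinFpkm):
                    out.add(atom.tissue)
                else:
                    out.add(atom.target)
                    out.add(atom.comparator)
        return out


@dataclass(frozen=True)
class DegClassification:
    """Per-subset transcript memberships over an evaluated matrix."""

    memberships: dict[str, frozenset[str]]
    universe_size: int

    def sorted_members(self, subset: str) -> list[str]:
        return sorted(self.memberships[subset])

    def se_memberships(self) -> dict[str, frozenset[str]]:
        return {s: self.memberships[s] for s in SE_SUBSETS if s in self.memberships}


# ---------------------------------------------------------------------------
# Built-in rules
# ---------------------------------------------------------------------------

def builtin_rules(config: RunConfig | None = None) -> list[SubsetRule]:
    """The seven subset definitions of the study, parameterised by config.

    With defaults (fold 8, min FPKM 1):

    1-3. ``rl_specific``/``rr_specific``/``abl_specific`` — FPKM >= 1 in the
         target tissue, and target >= 8x each of the other five tissues.
    4.   ``ec_induction`` — FPKM >= 1 in ec, ec strictly > gse, and
         ec >= 8x each of rl, rr, abl, cse.
    5.   ``early_se`` — conjunctive mode (default): some early embryogenic
         tissue t in {ec, gse} has FPKM >= 1 and t >= 8x abl.
         ``literal_or`` mode: the literal disjunction
         (ec >= 1) or (gse >= 1) or (ec >= 8x abl) or (gse >= 8x abl).
    6.   ``late_se`` — FPKM >= 1 in cse, cse strictly > gse, and
         cse >= 8x each of rl, rr, abl, ec.
    7.   ``all_se`` — FPKM >= 1 in each embryogenic tissue (ec, gse, cse)
         and each embryogenic tissue >= 8x each organogenic tissue
         (rl, rr, abl).
    """
    cfg = config or RunConfig()
    fold = cfg.fold_threshold
    floor = cfg.min_fpkm
    organo = ("rl", "rr", "abl")
    embryo = ("ec", "gse", "cse")

    rules: list[SubsetRule] = []
    for target in organo:
        others = [t for t in cfg.fpkm_tissues if t != target]
        clause = (MinFpkm(target, floor),) + tuple(
            FoldAtLeast(target, o, fold) for o in others
        )
        rules.append(SubsetRule(f"{target}_specific", (clause,)))

    rules.append(
        SubsetRule(
            "ec_induction",
            (
                (
                    MinFpkm("ec", floor),
                    StrictlyGreater("ec", "gse"),
                    FoldAtLeast("ec", "rl", fold),
                    FoldAtLeast("ec", "rr", fold),
                    FoldAtLeast("ec", "abl", fold),
                    FoldAtLeast("ec", "cse", fold),
                ),
            ),
        )
    )

    if cfg.early_rule_mode == "conjunctive":
        early_clauses: tuple[tuple[Atom, ...], ...] = (
            (MinFpkm("ec", floor), FoldAtLeast("ec", "abl", fold)),
            (MinFpkm("gse", floor), FoldAtLeast("gse", "abl", fold)),
        )
    else:  # literal_or
        early_clauses = (
            (MinFpkm("ec", floor),),
            (MinFpkm("gse", floor),),
            (FoldAtLeast("ec", "abl", fold),),
            (FoldAtLeast("gse", "abl", fold),),
        )
    rules.append(SubsetRule("early_se", early_clauses))

    rules.append(
        SubsetRule(
            "late_se",
            (
                (
                    MinFpkm("cse", floor),
                    StrictlyGreater("cse", "gse"),
                    FoldAtLeast("cse", "rl", fold),
                    FoldAtLeast("cse", "rr", fold),
                    FoldAtLeast("cse", "abl", fold),
                    FoldAtLeast("cse", "ec", fold),
                ),
            ),
        )
    )

    all_se_clause = tuple(MinFpkm(e, floor) for e in embryo) + tuple(
        FoldAtLeast(e, o, fold) for e in embryo for o in organo
    )
    rules.append(SubsetRule("all_se", (all_se_clause,)))

    assert [r.name for r in rules] == list(ALL_SUBSETS)
    return rules


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _check_rule_tissues(matrix: FpkmMatrix, rules: list[SubsetRule]) -> None:
    available = set(matrix.tissues)
    for rule in rules:
        missing = sorted(rule.tissues() - available)
        if missing:
            raise ValueError(
                f"rule {rule.name!r} references tissue(s) {missing} "
                f"absent from the matrix (has {sorted(available)})"
            )


def classify(matrix: FpkmMatrix, rules: list[SubsetRule]) -> DegClassification:
    """Evaluate every rule on every transcript (vectorised)."""
    _check_rule_tissues(matrix, rules)
    n = matrix.n_transcripts
    ids = np.asarray(matrix.transcript_ids)
    memberships: dict[str, frozenset[str]] = {}
    for rule in rules:
        hit = np.zeros(n, dtype=bool)
        for clause in rule.clauses:
            ok = np.ones(n, dtype=bool)
            for atom in clause:
                if isinstance(atom, MinFpkm):
                    ok &= matrix.column(atom.tissue) >= atom.threshold
                elif isinstance(atom, FoldAtLeast):
                    ok &= matrix.column(atom.target) >= atom.fold * matrix.column(atom.comparator)
                else:
                    ok &= matrix.column(atom.target) > matrix.column(atom.comparator)
            hit |= ok
        memberships[rule.name] = frozenset(ids[hit].tolist())
    return DegClassification(memberships, universe_size=n)


def classify_bruteforce(matrix: FpkmMatrix, rules: list[SubsetRule]) -> DegClassification:
    """Naive per-transcript, per-atom re-evaluation; oracle for classify."""
    _check_rule_tissues(matrix, rules)
    memberships: dict[str, set[str]] = {rule.name: set() for rule in rules}
    for i, tid in enumerate(matrix.transcript_ids):
        row = {t: float(matrix.values[i, j]) for j, t in enumerate(matrix.tissues)}
        for rule in rules:
            member = False
            for clause in rule.clauses:
                clause_ok = True
                for atom in clause:
                    if isinstance(atom, MinFpkm):
                        atom_ok = row[atom.tissue] >= atom.threshold
                    elif isinstance(atom, FoldAtLeast):
                        atom_ok = row[atom.target] >= atom.fold * row[atom.comparator]
                    else:
                        atom_ok = row[atom.target] > row[atom.comparator]
                    if not atom_ok:
                        clause_ok = False
                        break
                if clause_ok:
                    member = True
                    break
            if member:
                memberships[rule.name].add(tid)
    return DegClassification(
        {k: frozenset(v) for k, v in memberships.items()},
        universe_size=matrix.n_transcripts,
    )
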