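"""RT-qPCR relative quantification: standard curves, imputation, 2^-ddCt, stats.

The quantification follows the Livak 2^-ddCt scheme on cycle-threshold (Ct)
measurements taken in biological replicates across nine tissues:

* per replicate, the reference Ct is the arithmetic mean of the two
  reference-gene Cts (RPL2, TBP1) — the geometric mean of their quantities;
* dCt = Ct(target) - Ct(reference); ddCt subtracts the calibrator tissue's
  mean dCt (rosette leaf, rl); relative expression is reported on the log2
  scale, log2 fold change = -ddCt;
* amplification efficiency is assumed 100% for the fold-change arithmetic;
  dilution-series standard curves serve two separate purposes: QC of the
  reaction efficiency (90-110% band) and substitution of the curve's
  y-intercept for Cts outside the detection range;
* per gene, replicate-level log2 fold changes are compared across tissues
  by one-way ANOVA followed by all-pairs Tukey HSD, summarised as a
  compact letter display (tissues sharing a letter do not differ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import DEFAULT_CALIBRATOR, DEFAULT_REFERENCES
from .io import CtDataset, CtRecord

#: reaction-efficiency band accepted by QC, in percent
EFFICIENCY_QC_RANGE = (90.0, 110.0)


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct against log10 template copies for one gene.

    ``efficiency_pct`` is 100 * (10**(-1/slope) - 1): a slope of
    -1/log10(2) = -3.3219 cycles per decade means perfect doubling (100%).
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * (10.0 ** (-1.0 / self.slope) - 1.0)

    @property
    def qc_pass(self) -> bool:
        if self.slope >= 0:
            return False
        lo, hi = EFFICIENCY_QC_RANGE
        return lo <= self.efficiency_pct <= hi


def fit_standard_curve(
    dilution_points: Sequence[tuple[float, float]], gene: str
) -> StandardCurve:
    """Fit a dilution series (copies, ct) by least squares on log10 copies.

    Requires at least three distinct copy-number levels. A non-negative
    slope yields a curve that reports its (meaningless) efficiency but
    fails QC.
    """
    if len({c for c, _ in dilution_points}) < 3:
        raise ValueError(
            f"standard curve for {gene!r} needs >= 3 distinct copy-number levels, "
            f"got {len({c for c, _ in dilution_points})}"
        )
    copies = np.asarray([c for c, _ in dilution_points], dtype=float)
    cts = np.asarray([ct for _, ct in dilution_points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError(f"copy numbers must be positive for {gene!r}")
    fit = stats.linregress(np.log10(copies), cts)
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class ImputationAudit:
    tissue: str
    gene: str
    replicate: int
    imputed_ct: float


def impute_undetected(
    dataset: CtDataset, curves: Mapping[str, StandardCurve]
) -> tuple[CtDataset, list[ImputationAudit]]:
    """Replace undetected Cts by the gene's standard-curve y-intercept.

    Detected records pass through untouched; every substitution is listed
    in the returned audit. An undetected record whose gene has no fitted
    curve is an error.
    """
    new_records: list[CtRecord] = []
    audit: list[ImputationAudit] = []
    for rec in dataset.records:
        if rec.detected:
            new_records.append(rec)
            continue
        curve = curves.get(rec.gene)
        if curve is None:
            raise ValueError(f"no standard curve for {rec.gene!r}")
        new_records.append(CtRecord(rec.tissue, rec.gene, rec.replicate, curve.intercept))
        audit.append(ImputationAudit(rec.tissue, rec.gene, rec.replicate, curve.intercept))
    return CtDataset(tuple(new_records)), audit


# ---------------------------------------------------------------------------
# Relative expression (Livak)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelExpressionEntry:
    log2_fc: float
    se: float
    n: int
    letters: str = ""
    sig_vs_calibrator: bool = False


@dataclass(frozen=True)
class RelExpressionTable:
    """Gene x tissue log2 fold changes vs the calibrator, with statistics."""

    entries: dict[tuple[str, str], RelExpressionEntry]
    calibrator: str = DEFAULT_CALIBRATOR
    replicate_log2fc: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.entries}))

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({t for _, t in self.entries}))

    def profile_matrix(
        self, genes: Sequence[str] | None = None, tissues: Sequence[str] | None = None
    ) -> pd.DataFrame:
        """Mean log2 fold changes as a gene x tissue DataFrame."""
        genes = list(genes) if genes is not None else list(self.genes)
        tissues = list(tissues) if tissues is not None else list(self.tissues)
        data = np.full((len(genes), len(tissues)), np.nan)
        for i, g in enumerate(genes):
            for j, t in enumerate(tissues):
                entry = self.entries.get((g, t))
                if entry is None:
                    raise ValueError(f"missing entry for gene {g!r}, tissue {t!r}")
                data[i, j] = entry.log2_fc
        return pd.DataFrame(data, index=genes, columns=tissues)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "tissue": t,
                "log2_fc": e.log2_fc,
                "se": e.se,
                "n": e.n,
                "letters": e.letters,
                "sig_vs_calibrator": e.sig_vs_calibrator,
            }
            for (g, t), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def _ct_by_replicate(dataset: CtDataset, gene: str, tissue: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for rec in dataset.subset(gene=gene, tissue=tissue):
        if not rec.detected:
            raise ValueError(
                f"undetected Ct for gene {gene!r}, tissue {tissue!r} — run "
                "impute_undetected with a standard curve first"
            )
        out[rec.replicate] = rec.ct  # type: ignore[assignment]
    return out


def relative_expression(
    dataset: CtDataset,
    target: str,
    references: tuple[str, str] = DEFAULT_REFERENCES,
    calibrator: str = DEFAULT_CALIBRATOR,
    tissues: Sequence[str] | None = None,
) -> dict[str, RelExpressionEntry]:
    """Livak 2^-ddCt per-tissue log2 fold changes for one target gene.

    Replicates are paired by index across target and references within a
    tissue. The returned entries carry the replicate mean and its standard
    error; the calibrator's mean is 0 by construction.
    """
    tissue_list = list(tissues) if tissues is not None else sorted(
        {r.tissue for r in dataset.records if r.gene == target}
    )
    if calibrator not in tissue_list:
        raise ValueError(f"calibrator tissue {calibrator!r} absent from dataset for {target!r}")

    per_replicate = replicate_log2fc(dataset, target, references, calibrator, tissue_list)
    out: dict[str, RelExpressionEntry] = {}
    for tissue in tissue_list:
        vals = np.asarray(per_replicate[tissue])
        se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[tissue] = RelExpressionEntry(
            log2_fc=float(np.mean(vals)), se=se, n=len(vals)
        )
    return out


def replicate_log2fc(
    dataset: CtDataset,
    target: str,
    references: tuple[str, str] = DEFAULT_REFERENCES,
    calibrator: str = DEFAULT_CALIBRATOR,
    tissues: Sequence[str] | None = None,
) -> dict[str, list[float]]:
    """Per-replicate log2 fold changes (the inputs to ANOVA/Tukey)."""
    tissue_list = list(tissues) if tissues is not None else sorted(
        {r.tissue for r in dataset.records if r.gene == target}
    )

    def delta_cts(tissue: str) -> list[float]:
        tgt = _ct_by_replicate(dataset, target, tissue)
        if not tgt:
            raise ValueError(f"no measurements for target {target!r} in tissue {tissue!r}")
        refs = [_ct_by_replicate(dataset, ref, tissue) for ref in references]
        deltas = []
        for rep in sorted(tgt):
            for ref_cts, ref in zip(refs, references):
                if rep not in ref_cts:
                    raise ValueError(
                        f"missing reference {ref!r} measurement for tissue {tissue!r}, "
                        f"replicate {rep}"
                    )
            ref_ct = float(np.mean([ref_cts[rep] for ref_cts in refs]))
            deltas.append(tgt[rep] - ref_ct)
        return deltas

    if calibrator not in tissue_list:
        raise ValueError(f"calibrator tissue {calibrator!r} not in tissues {tissue_list}")
    cal_mean = float(np.mean(delta_cts(calibrator)))
    out: dict[str, list[float]] = {}
    for tissue in tissue_list:
        out[tissue] = [-(d - cal_mean) for d in delta_cts(tissue)]
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

def _compact_letter_display(
    groups: list[str], means: dict[str, float], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment over groups by descending mean."""
    order = sorted(groups, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(order)]
    for pair in significant:
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for dropped in (a, b):
                reduced = col - {dropped}
                if reduced and not any(reduced <= other for other in columns):
                    columns.append(reduced)
    # absorb: drop columns contained in another
    columns = [
        c for c in columns if not any(c < other for other in columns)
    ]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


@dataclass(frozen=True)
class TukeyResult:
    anova_f: float
    anova_p: float
    letters: dict[str, str]
    significant_pairs: frozenset[frozenset[str]]


def anova_tukey(values: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA over tissues followed by all-pairs Tukey HSD at alpha.

    Returns the compact letter display: two tissues share a letter exactly
    when their Tukey comparison is non-significant. Requires >= 2 groups
    with >= 2 replicates each and non-zero pooled within-group variance.
    """
    groups = sorted(values)
    if len(groups) < 2:
        raise ValueError("need at least two tissues to compare")
    for g in groups:
        if len(values[g]) < 2:
            raise ValueError(f"tissue {g!r} has fewer than 2 replicates")
    if all(np.ptp(np.asarray(values[g], dtype=float)) == 0 for g in groups):
        raise ValueError(
            "zero within-group variance in every tissue: Tukey HSD is undefined; "
            "add measurement replicates with non-identical values"
        )
    samples = [np.asarray(values[g], dtype=float) for g in groups]
    f_stat, p_val = stats.f_oneway(*samples)

    flat = np.concatenate(samples)
    labels = np.concatenate([[g] * len(values[g]) for g in groups])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    significant: set[frozenset[str]] = set()
    for (g1, g2), reject in zip(
        ((tukey.groupsunique[i], tukey.groupsunique[j]) for i, j in zip(*np.triu_indices(len(groups), 1))),
        tukey.reject,
    ):
        if reject:
            significant.add(frozenset((str(g1), str(g2))))
    means = {g: float(np.mean(values[g])) for g in groups}
    letters = _compact_letter_display(groups, means, significant)
    return TukeyResult(
        anova_f=float(f_stat),
        anova_p=float(p_val),
        letters=letters,
        significant_pairs=frozenset(significant),
    )


# ---------------------------------------------------------------------------
# Full per-gene pipeline
# ---------------------------------------------------------------------------

def relative_expression_table(
    dataset: CtDataset,
    targets: Sequence[str],
    references: tuple[str, str] = DEFAULT_REFERENCES,
    calibrator: str = DEFAULT_CALIBRATOR,
    alpha: float = 0.05,
    tissues: Sequence[str] | None = None,
    with_letters: bool = True,
) -> RelExpressionTable:
    """Quantify every target and attach Tukey letters per gene.

    Each tissue's entry is additionally flagged when its Tukey comparison
    against the calibrator is significant.
    """
    entries: dict[tuple[str, str], RelExpressionEntry] = {}
    replicate_store: dict[tuple[str, str], tuple[float, ...]] = {}
    for target in targets:
        per_rep = replicate_log2fc(dataset, target, references, calibrator, tissues)
        stats_res = anova_tukey(per_rep, alpha=alpha) if with_letters else None
        for tissue, vals in per_rep.items():
            arr = np.asarray(vals)
            se = float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
            letters = stats_res.letters[tissue] if stats_res else ""
            sig = (
                frozenset((tissue, calibrator)) in stats_res.significant_pairs
                if stats_res and tissue != calibrator
                else False
            )
            entries[(target, tissue)] = RelExpressionEntry(
                log2_fc=float(np.mean(arr)), se=se, n=len(arr), letters=letters,
                sig_vs_calibrator=sig,
            )
            replicate_store[(target, tissue)] = tuple(float(v) for v in vals)
    return RelExpressionTable(entries=entries, calibrator=calibrator, replicate_log2fc=replicate_store)
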