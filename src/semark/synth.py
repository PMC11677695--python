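"""Synthetic data with planted ground truth for offline pipeline validation.

Two generators stand in for the study's two data sources:

* :func:`gen_fpkm` emulates a pooled six-tissue bulk-RNA-seq FPKM table —
  log-normal background expression (right-skewed, median ~2) plus
  transcripts *planted* to satisfy exactly one subset rule with
  multiplicative slack on every inequality. Background rows are rejection
  sampled until they satisfy no rule, so negatives are guaranteed, not
  probabilistic.
* :func:`gen_ct` emulates the nine-tissue RT-qPCR panel: each target
  gene's Ct is a gene base Ct minus its planted log2 fold change plus
  Gaussian cycle noise; reference genes are flat by construction; any Ct
  beyond the detection ceiling (default 40 cycles) is emitted as
  undetected.

Ground truth (planted memberships / planted fold changes) is returned
alongside the data and can be serialised to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import ALL_SUBSETS, QPCR_TISSUES, RunConfig, DEFAULT_REFERENCES
from .deg import builtin_rules, classify
from .io import CtDataset, CtRecord, FpkmMatrix

#: subsets implied by each plant's construction (membership theorems:
#: an ec-induction plant necessarily passes the early-SE rule, and the
#: all-SE plant is built with equal embryogenic values so it passes
#: early-SE but fails the strict comparisons of ec-induction/late-SE)
_IMPLIED_MEMBERSHIPS: dict[str, tuple[str, ...]] = {
    "rl_specific": ("rl_specific",),
    "rr_specific": ("rr_specific",),
    "abl_specific": ("abl_specific",),
    "ec_induction": ("ec_induction", "early_se"),
    "early_se": ("early_se",),
    "late_se": ("late_se",),
    "all_se": ("all_se", "early_se"),
}

_BASE_CT_TARGET = 25.0
_REF_BASE_CT = {"RPL2": 20.0, "TBP1": 22.0}
_DEFAULT_DETECTION_LIMIT = 40.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    planted_memberships: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    noise_params: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_memberships": {
                k: sorted(v) for k, v in self.planted_memberships.items()
            },
            "planted_log2fc": [
                {"gene": g, "tissue": t, "log2fc": v}
                for (g, t), v in sorted(self.planted_log2fc.items())
            ],
            "seed": self.seed,
            "noise_params": self.noise_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# FPKM generator
# ---------------------------------------------------------------------------

def _plant_row(
    subset: str, rng: np.random.Generator, margin: float, cfg: RunConfig
) -> dict[str, float]:
    """One FPKM row passing exactly ``subset``'s rule with slack >= margin.

    Low (non-target) tissues are drawn U(0.2, 0.75): below the expression
    floor, and far enough apart that no accidental 8-fold ratio or
    floor crossing can arise among them.
    """
    fold, floor = cfg.fold_threshold, cfg.min_fpkm
    low = lambda: float(rng.uniform(0.2, 0.75))
    row = {t: low() for t in cfg.fpkm_tissues}
    if subset.endswith("_specific"):
        target = subset.removesuffix("_specific")
        others = [row[t] for t in cfg.fpkm_tissues if t != target]
        row[target] = margin * max(floor, fold * max(others))
    elif subset == "ec_induction":
        others = [row[t] for t in ("rl", "rr", "abl", "cse")]
        row["ec"] = margin * max(floor, fold * max(others))
        row["gse"] = row["ec"] / margin  # strictly below ec with slack
    elif subset == "early_se":
        row["ec"] = margin * max(floor, fold * row["abl"])
        row["rl"] = row["ec"] / 2.0  # blocks the ec-induction fold test on rl
    elif subset == "late_se":
        others = [row[t] for t in ("rl", "rr", "abl", "ec")]
        row["cse"] = margin * max(floor, fold * max(others))
    elif subset == "all_se":
        organo = [row[t] for t in ("rl", "rr", "abl")]
        v = margin * max(floor, fold * max(organo))
        row["ec"] = row["gse"] = row["cse"] = v
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return row


def gen_fpkm(
    n_background: int,
    n_per_subset: Mapping[str, int] | None = None,
    margin: float = 2.0,
    config: RunConfig | None = None,
    lognormal_median: float = 2.0,
    lognormal_sigma: float = 1.0,
) -> tuple[FpkmMatrix, SyntheticTruth]:
    """Generate an FPKM matrix with planted subset members.

    Background transcripts are i.i.d. log-normal per tissue and rejection
    sampled to satisfy no rule; planted transcripts satisfy their target
    rule's every inequality with multiplicative slack >= ``margin``
    (margin > 1 required). Classification of the result recovers the
    planted truth exactly.
    """
    if margin <= 1:
        raise ValueError(f"margin must be > 1, got {margin}")
    cfg = config or RunConfig()
    plants = dict(n_per_subset or {})
    unknown = set(plants) - set(ALL_SUBSETS)
    if unknown:
        raise ValueError(f"unknown subset(s) in n_per_subset: {sorted(unknown)}")
    if any(v < 0 for v in plants.values()):
        raise ValueError("plant counts must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    rules = builtin_rules(cfg)
    tissues = cfg.fpkm_tissues

    ids: list[str] = []
    rows: list[list[float]] = []
    truth_members: dict[str, set[str]] = {s: set() for s in ALL_SUBSETS}
    for subset in ALL_SUBSETS:  # fixed order keeps generation seed-stable
        for i in range(plants.get(subset, 0)):
            tid = f"PLT_{subset}_{i:04d}"
            row = _plant_row(subset, rng, margin, cfg)
            ids.append(tid)
            rows.append([row[t] for t in tissues])
            for implied in _IMPLIED_MEMBERSHIPS[subset]:
                truth_members[implied].add(tid)

    # background: draw, classify, redraw any row that satisfies a rule
    if n_background:
        mu = np.log(lognormal_median)
        bg = rng.lognormal(mu, lognormal_sigma, size=(n_background, len(tissues)))
        for _ in range(200):
            cls = classify(FpkmMatrix(
                tuple(f"B{i}" for i in range(len(bg))), tissues, bg
            ), rules)
            hit_ids = set().union(*cls.memberships.values())
            if not hit_ids:
                break
            bad = np.array([f"B{i}" in hit_ids for i in range(len(bg))])
            bg[bad] = rng.lognormal(mu, lognormal_sigma, size=(int(bad.sum()), len(tissues)))
        else:  # pragma: no cover - would need pathological parameters
            raise RuntimeError("background rejection sampling did not converge")
        for i in range(n_background):
            ids.append(f"BG_{i:06d}")
            rows.append(list(bg[i]))

    order = np.argsort(ids)
    matrix = FpkmMatrix(
        tuple(ids[i] for i in order),
        tissues,
        np.asarray(rows, dtype=float)[order] if rows else np.empty((0, len(tissues))),
    )
    truth = SyntheticTruth(
        planted_memberships={s: frozenset(m) for s, m in truth_members.items()},
        seed=cfg.seed,
        noise_params={
            "fpkm_lognormal_median": lognormal_median,
            "fpkm_lognormal_sigma": lognormal_sigma,
            "margin": margin,
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Ct generator
# ---------------------------------------------------------------------------

def gen_ct(
    genes: Sequence[str],
    tissues: Sequence[str] = QPCR_TISSUES,
    n_reps: int = 3,
    truth_log2fc: Mapping[tuple[str, str], float] | None = None,
    ct_sd: float = 0.2,
    detection_limit_ct: float = _DEFAULT_DETECTION_LIMIT,
    seed: int = 0,
    base_ct: float = _BASE_CT_TARGET,
    references: tuple[str, str] = DEFAULT_REFERENCES,
) -> tuple[CtDataset, SyntheticTruth]:
    """Generate a long-format Ct dataset with planted log2 fold changes.

    Per replicate, target Ct = base_ct - planted_log2fc + N(0, ct_sd);
    reference Cts fluctuate around their own bases with the same noise.
    Cts exceeding ``detection_limit_ct`` are emitted as undetected. A
    planted fold change for a reference gene is an error (references are
    stable by definition).
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    truth = dict(truth_log2fc or {})
    for (gene, tissue), value in truth.items():
        if gene in references and value != 0:
            raise ValueError(
                f"reference gene {gene!r} must have planted log2fc 0, got {value}"
            )
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    full_truth: dict[tuple[str, str], float] = {}
    for gene in list(genes) + [r for r in references if r not in genes]:
        is_ref = gene in references
        base = _REF_BASE_CT.get(gene, base_ct - 5.0) if is_ref else base_ct
        for tissue in tissues:
            planted = 0.0 if is_ref else float(truth.get((gene, tissue), 0.0))
            full_truth[(gene, tissue)] = planted
            for rep in range(1, n_reps + 1):
                noise = float(rng.normal(0.0, ct_sd)) if ct_sd > 0 else 0.0
                ct = base - planted + noise
                if ct > detection_limit_ct:
                    records.append(CtRecord(tissue, gene, rep, None))
                else:
                    records.append(CtRecord(tissue, gene, rep, ct))
    dataset = CtDataset(tuple(records))
    truth_obj = SyntheticTruth(
        planted_log2fc=full_truth,
        seed=seed,
        noise_params={"ct_sd": ct_sd, "detection_limit_ct": detection_limit_ct},
    )
    return dataset, truth_obj
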