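"""Run configuration and controlled vocabularies.

The pipeline operates on two fixed tissue panels of *Centaurium erythraea*
in-vitro cultures: the six RNA-seq tissues used for FPKM rule filtering
(organogenic rl/rr/abl and embryogenic ec/gse/cse) and the extended
nine-tissue panel profiled by RT-qPCR (adding nature-collected nl/nr and
organogenic callus oc).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import yaml

#: The six tissues of the FPKM expression matrix (fixed order).
FPKM_TISSUES: tuple[str, ...] = ("rl", "rr", "abl", "ec", "gse", "cse")

#: The nine tissues of the RT-qPCR panel (fixed order).
QPCR_TISSUES: tuple[str, ...] = ("rl", "rr", "nl", "nr", "oc", "abl", "ec", "gse", "cse")

#: The four somatic-embryogenesis stage subsets.
SE_SUBSETS: tuple[str, ...] = ("ec_induction", "early_se", "late_se", "all_se")

#: The three tissue-specific (organogenesis) subsets.
ORGANOGENESIS_SUBSETS: tuple[str, ...] = ("rl_specific", "rr_specific", "abl_specific")

#: All seven subset labels in canonical report order.
ALL_SUBSETS: tuple[str, ...] = ORGANOGENESIS_SUBSETS + SE_SUBSETS

#: Default reference genes and calibrator tissue for relative quantification.
DEFAULT_REFERENCES: tuple[str, str] = ("RPL2", "TBP1")
DEFAULT_CALIBRATOR: str = "rl"

EARLY_RULE_MODES = ("conjunctive", "literal_or")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (half-up), as in report tables.

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 0.125 into 0.12 rather than the 0.13 a report table prints.
    """
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and modes shared across the pipeline.

    Parameters
    ----------
    fold_threshold : float
        Fold-difference required by the "at least N times higher" atoms of
        the subset rules. Default 8.
    min_fpkm : float
        Minimum FPKM for a transcript to count as expressed in a tissue.
        Default 1.
    alpha : float
        Significance level for the Tukey post hoc comparisons. Default 0.05.
    seed : int
        Seed for every stochastic component (synthetic data generation).
    early_rule_mode : str
        ``"conjunctive"`` (default) requires one of {ec, gse} to pass both
        the expression floor and the fold test against abl; ``"literal_or"``
        is the literal four-way disjunction of the prose rule.
    rounding_decimals : int
        Decimals for report-time half-up rounding of percentages.
    fpkm_tissues, qpcr_tissues : tuple of str
        Tissue vocabularies; overridable for reuse on other designs.
    """

    fold_threshold: float = 8.0
    min_fpkm: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    early_rule_mode: str = "conjunctive"
    rounding_decimals: int = 2
    fpkm_tissues: tuple[str, ...] = FPKM_TISSUES
    qpcr_tissues: tuple[str, ...] = QPCR_TISSUES

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValueError(f"fold_threshold must be > 0, got {self.fold_threshold}")
        if self.min_fpkm < 0:
            raise ValueError(f"min_fpkm must be >= 0, got {self.min_fpkm}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.early_rule_mode not in EARLY_RULE_MODES:
            raise ValueError(
                f"early_rule_mode must be one of {EARLY_RULE_MODES}, got {self.early_rule_mode!r}"
            )
        object.__setattr__(self, "fpkm_tissues", tuple(self.fpkm_tissues))
        object.__setattr__(self, "qpcr_tissues", tuple(self.qpcr_tissues))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a YAML mapping; unknown keys are errors."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def round(self, x: float) -> float:
        return round_half_up(x, self.rounding_decimals)


def check_tissues(seen: Iterable[str], vocabulary: Iterable[str], context: str) -> None:
    """Raise if ``seen`` contains labels outside ``vocabulary``."""
    bad = sorted(set(seen) - set(vocabulary))
    if bad:
        raise ValueError(
            f"{context}: unknown tissue label(s) {bad}; expected a subset of {sorted(vocabulary)}"
        )
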