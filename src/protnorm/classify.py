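"""Regulation and normalisation calling — the core calculus of the pipeline.

A protein of the disease line is *regulated* versus the normal reference
when its abundance ratio r_disease exceeds ``fc_high`` (up) or falls below
``fc_low`` (down), using strict inequalities: a ratio of exactly 2.0 is
unregulated. Evidence filtering precedes the ratio test: below the active
unique-peptide minimum the verdict is ``insufficient_evidence``. Proteins
detected on only one side of the ratio are *exclusive* cases and never get
a numeric ratio.

A regulated protein is *normalised* when the treated line's ratio
r_treated has returned inside the band [fc_low, fc_high] (inclusive — the
band bounds belong to the unregulated/normalised region on both reads of
the thresholds). It shows a *trend* towards normalisation when r_treated
is still outside the band but strictly closer to 1 in log space with the
same direction of change as the disease line. Everything else — worsening,
or overshoot past the opposite cutoff — is ``not_normalised``.

All logs are base 2; reported fold changes are raw ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence

import pandas as pd

from .errors import SummaryError
from .preprocess import RatioRecord

__all__ = [
    "Thresholds",
    "RegulationCall",
    "NormalisationCall",
    "FractionSummary",
    "TierCounts",
    "call_regulation",
    "call_normalisation",
    "classify_records",
    "summarise",
    "count_filter_tiers",
]

Level = Literal["standard", "strict"]


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and evidence cut-offs.

    ``fc_low`` defaults to 1/``fc_high`` (symmetry in log space). The
    unique-peptide minimums are inclusive (>=); the biomarker fold bound is
    inclusive too, unlike the strict 2-fold regulation bound.
    """

    fc_high: float = 2.0
    fc_low: float | None = None
    up_min_standard: int = 2
    up_min_strict: int = 5
    biomarker_fold: float = 5.0

    def __post_init__(self) -> None:
        if self.fc_high <= 1:
            raise ValueError(f"fc_high must be > 1, got {self.fc_high}")
        if self.fc_low is None:
            object.__setattr__(self, "fc_low", 1.0 / self.fc_high)
        if not 0 < self.fc_low < 1:  # type: ignore[operator]
            raise ValueError(f"fc_low must be in (0, 1), got {self.fc_low}")
        if self.up_min_strict < self.up_min_standard:
            raise ValueError("up_min_strict must be >= up_min_standard")
        if self.biomarker_fold <= 1:
            raise ValueError(
                f"biomarker_fold must be > 1, got {self.biomarker_fold}"
            )

    def up_min(self, level: Level) -> int:
        if level == "standard":
            return self.up_min_standard
        if level == "strict":
            return self.up_min_strict
        raise ValueError(f"unknown filter level {level!r}")


class RegulationCall(str, Enum):
    REGULATED_UP = "regulated_up"
    REGULATED_DOWN = "regulated_down"
    UNREGULATED = "unregulated"
    INSUFFICIENT_EVIDENCE = "insufficient_evidence"
    EXCLUSIVE_DISEASE = "exclusive_disease"
    EXCLUSIVE_REFERENCE = "exclusive_reference"
    UNDETECTED = "undetected"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class NormalisationCall(str, Enum):
    NORMALISED = "normalised"
    TREND = "trend"
    NOT_NORMALISED = "not_normalised"
    NOT_APPLICABLE = "not_applicable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REGULATED = frozenset(
    {RegulationCall.REGULATED_UP, RegulationCall.REGULATED_DOWN}
)


def call_regulation(
    r_disease: float | None,
    *,
    detected_disease: bool,
    detected_reference: bool,
    unique_peptides: int,
    thresholds: Thresholds,
    level: Level = "strict",
) -> RegulationCall:
    """Classify one protein's disease/reference ratio.

    Precedence: evidence filter, then detection pattern, then the strict
    fold-change inequalities.
    """
    if r_disease is not None and r_disease <= 0:
        raise ValueError(f"r_disease must be > 0, got {r_disease}")
    if unique_peptides < thresholds.up_min(level):
        return RegulationCall.INSUFFICIENT_EVIDENCE
    if r_disease is None:
        if detected_disease and not detected_reference:
            return RegulationCall.EXCLUSIVE_DISEASE
        if detected_reference and not detected_disease:
            return RegulationCall.EXCLUSIVE_REFERENCE
        if not detected_disease and not detected_reference:
            return RegulationCall.UNDETECTED
        raise ValueError(
            "ratio absent although disease and reference are both detected"
        )
    if r_disease > thresholds.fc_high:
        return RegulationCall.REGULATED_UP
    if r_disease < thresholds.fc_low:  # type: ignore[operator]
        return RegulationCall.REGULATED_DOWN
    return RegulationCall.UNREGULATED


def call_normalisation(
    r_disease: float | None,
    r_treated: float | None,
    regulation: RegulationCall,
    thresholds: Thresholds,
) -> NormalisationCall:
    """Classify the treated/reference ratio of a regulated protein."""
    for name, r in (("r_disease", r_disease), ("r_treated", r_treated)):
        if r is not None and r <= 0:
            raise ValueError(f"{name} must be > 0, got {r}")
    if regulation not in REGULATED or r_treated is None:
        return NormalisationCall.NOT_APPLICABLE
    assert r_disease is not None
    if thresholds.fc_low <= r_treated <= thresholds.fc_high:  # type: ignore[operator]
        return NormalisationCall.NORMALISED
    log_d = math.log2(r_disease)
    log_t = math.log2(r_treated)
    same_direction = (log_d > 0) == (log_t > 0)
    if same_direction and abs(log_t) < abs(log_d):
        return NormalisationCall.TREND
    return NormalisationCall.NOT_NORMALISED


def classify_records(
    records: Sequence[RatioRecord],
    thresholds: Thresholds,
    level: Level = "strict",
) -> pd.DataFrame:
    """Per-protein classification table at one evidence level.

    Columns: accession, gene_symbol, unique_peptides, r_disease,
    r_treated, regulation_call, normalisation_call.
    """
    rows = []
    for rec in records:
        reg = call_regulation(
            rec.r_disease,
            detected_disease=rec.detected.get("disease", False),
            detected_reference=rec.detected.get("reference", False),
            unique_peptides=rec.unique_peptides,
            thresholds=thresholds,
            level=level,
        )
        norm = call_normalisation(
            rec.r_disease, rec.r_treated, reg, thresholds
        )
        rows.append(
            {
                "accession": rec.accession,
                "gene_symbol": rec.gene_symbol,
                "unique_peptides": rec.unique_peptides,
                "r_disease": rec.r_disease,
                "r_treated": rec.r_treated,
                "regulation_call": reg.value,
                "normalisation_call": norm.value,
            }
        )
    columns = [
        "accession",
        "gene_symbol",
        "unique_peptides",
        "r_disease",
        "r_treated",
        "regulation_call",
        "normalisation_call",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class FractionSummary:
    """Counts and fractions of the regulated set's normalisation outcome.

    Percentages are over the regulated proteins that carry a
    non-``not_applicable`` normalisation call (i.e. those with a treated
    ratio); they sum to 100 up to floating rounding. Rounding happens only
    at presentation.
    """

    n_regulated_up: int
    n_regulated_down: int
    n_normalised: int
    n_trend: int
    n_not_normalised: int

    @property
    def n_regulated(self) -> int:
        return self.n_regulated_up + self.n_regulated_down

    @property
    def n_with_outcome(self) -> int:
        return self.n_normalised + self.n_trend + self.n_not_normalised

    @property
    def pct_normalised(self) -> float:
        return 100.0 * self.n_normalised / self.n_with_outcome

    @property
    def pct_trend(self) -> float:
        return 100.0 * self.n_trend / self.n_with_outcome

    @property
    def pct_not_normalised(self) -> float:
        return 100.0 * self.n_not_normalised / self.n_with_outcome

    @classmethod
    def from_counts(
        cls,
        n_regulated_up: int,
        n_regulated_down: int,
        n_normalised: int,
        n_trend: int = 0,
        n_not_normalised: int | None = None,
    ) -> "FractionSummary":
        """Build a summary from published-style counts.

        When ``n_not_normalised`` is omitted it is the remainder of the
        regulated set, i.e. every regulated protein is assumed to have a
        treated ratio.
        """
        n_reg = n_regulated_up + n_regulated_down
        if n_not_normalised is None:
            n_not_normalised = n_reg - n_normalised - n_trend
        summary = cls(
            n_regulated_up=n_regulated_up,
            n_regulated_down=n_regulated_down,
            n_normalised=n_normalised,
            n_trend=n_trend,
            n_not_normalised=n_not_normalised,
        )
        if summary.n_with_outcome <= 0:
            raise SummaryError("no regulated protein has a treated ratio")
        return summary

    def as_dict(self) -> dict[str, float]:
        return {
            "n_regulated_up": self.n_regulated_up,
            "n_regulated_down": self.n_regulated_down,
            "n_normalised": self.n_normalised,
            "n_trend": self.n_trend,
            "n_not_normalised": self.n_not_normalised,
            "pct_normalised": self.pct_normalised,
            "pct_trend": self.pct_trend,
            "pct_not_normalised": self.pct_not_normalised,
        }


def summarise(classified: pd.DataFrame) -> FractionSummary:
    """Tally the regulated set's normalisation partition.

    Raises :class:`SummaryError` when the regulated set is empty or no
    regulated protein has a treated ratio (percentages undefined).
    """
    reg = classified["regulation_call"]
    norm = classified["normalisation_call"]
    is_up = reg == RegulationCall.REGULATED_UP.value
    is_down = reg == RegulationCall.REGULATED_DOWN.value
    regulated = is_up | is_down
    if not regulated.any():
        raise SummaryError("regulated set is empty; percentages undefined")
    applicable = regulated & (
        norm != NormalisationCall.NOT_APPLICABLE.value
    )
    if not applicable.any():
        raise SummaryError("no regulated protein has a treated ratio")
    return FractionSummary(
        n_regulated_up=int(is_up.sum()),
        n_regulated_down=int(is_down.sum()),
        n_normalised=int(
            (norm[applicable] == NormalisationCall.NORMALISED.value).sum()
        ),
        n_trend=int((norm[applicable] == NormalisationCall.TREND.value).sum()),
        n_not_normalised=int(
            (norm[applicable] == NormalisationCall.NOT_NORMALISED.value).sum()
        ),
    )


@dataclass(frozen=True)
class TierCounts:
    """Protein counts at the two unique-peptide evidence tiers."""

    n_identified: int
    n_regulated_standard: int
    n_unregulated_standard: int
    n_regulated_strict: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_identified": self.n_identified,
            "n_regulated_standard": self.n_regulated_standard,
            "n_unregulated_standard": self.n_unregulated_standard,
            "n_regulated_strict": self.n_regulated_strict,
        }


def count_filter_tiers(
    records: Sequence[RatioRecord],
    thresholds: Thresholds,
) -> TierCounts:
    """Regulated/unregulated counts at the standard and strict tiers."""

    def _counts(level: Level) -> tuple[int, int]:
        n_reg = n_unreg = 0
        for rec in records:
            call = call_regulation(
                rec.r_disease,
                detected_disease=rec.detected.get("disease", False),
                detected_reference=rec.detected.get("reference", False),
                unique_peptides=rec.unique_peptides,
                thresholds=thresholds,
                level=level,
            )
            if call in REGULATED:
                n_reg += 1
            elif call is RegulationCall.UNREGULATED:
                n_unreg += 1
        return n_reg, n_unreg

    reg_std, unreg_std = _counts("standard")
    reg_strict, _ = _counts("strict")
    return TierCounts(
        n_identified=len(records),
        n_regulated_standard=reg_std,
        n_unregulated_standard=unreg_std,
        n_regulated_strict=reg_strict,
    )
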