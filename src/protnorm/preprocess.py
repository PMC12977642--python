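"""Per-sample intensity scaling, replicate aggregation and ratio computation.

The upstream wet-lab workflow equalises protein amounts at several stages
(gel lanes, peptide assays, spectral intensities). Those steps cannot be
replayed from the exported table, so a single total-intensity scaling per
sample stands in for them: every sample is multiplied by one scalar so its
summed intensity equals a common target. Relative abundances within a
sample are untouched and the operation is idempotent.

No imputation and no pseudo-counts anywhere: a protein missing in one
condition yields no ratio and is handled categorically downstream as an
"exclusive" case.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import DegenerateSampleError, DesignError, IntegrityError
from .io import ProteinQuantRecord, SampleDesign

__all__ = [
    "RatioRecord",
    "sample_totals",
    "scale_total_intensity",
    "aggregate_replicates",
    "compute_ratios",
]


@dataclass
class RatioRecord:
    """Abundance ratios of one protein versus the reference condition.

    A ratio is present iff both its numerator and denominator conditions
    were detected; present ratios are finite and > 0. ``detected`` flags
    all three roles regardless.
    """

    accession: str
    r_disease: float | None
    r_treated: float | None
    detected: dict[str, bool]
    unique_peptides: int
    gene_symbol: str = ""


def sample_totals(records: Sequence[ProteinQuantRecord]) -> dict[str, float]:
    totals: dict[str, float] = {}
    for rec in records:
        for sample, value in rec.abundances.items():
            totals[sample] = totals.get(sample, 0.0) + value
    return totals


def scale_total_intensity(
    records: Sequence[ProteinQuantRecord],
    target: float | None = None,
) -> list[ProteinQuantRecord]:
    """Scale each sample by one scalar so its total intensity equals ``target``.

    Default target is the mean of the per-sample totals, which makes the
    operation idempotent. A sample whose detected abundances are all zero
    (or that detects nothing) cannot be scaled and raises
    :class:`DegenerateSampleError`.
    """
    totals = sample_totals(records)
    for sample, total in totals.items():
        if total <= 0:
            raise DegenerateSampleError(
                f"sample {sample!r} has no positive abundances"
            )
    if not totals:
        raise DegenerateSampleError("no sample has any detected protein")
    if target is None:
        target = sum(totals.values()) / len(totals)
    elif target <= 0:
        raise ValueError(f"scaling target must be > 0, got {target}")
    factors = {sample: target / total for sample, total in totals.items()}
    return [
        ProteinQuantRecord(
            accession=rec.accession,
            gene_symbol=rec.gene_symbol,
            unique_peptides=rec.unique_peptides,
            abundances={
                s: v * factors[s] for s, v in rec.abundances.items()
            },
        )
        for rec in records
    ]


def aggregate_replicates(
    records: Sequence[ProteinQuantRecord],
    design: SampleDesign,
    method: Literal["mean", "median"] = "mean",
    min_detected: int = 1,
) -> list[ProteinQuantRecord]:
    """Collapse technical replicates to one abundance per replicate group.

    A protein counts as detected in a group iff it is detected in at least
    ``min_detected`` member samples; the aggregate is taken over the
    detected values only.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if min_detected < 1:
        raise ValueError("min_detected must be >= 1")
    known = set(design.samples)
    group_members: dict[str, list[str]] = {}
    for sample, group in design.replicate_groups.items():
        group_members.setdefault(group, []).append(sample)
    agg = statistics.mean if method == "mean" else statistics.median

    out: list[ProteinQuantRecord] = []
    for rec in records:
        unknown = set(rec.abundances) - known
        if unknown:
            raise DesignError(
                f"{rec.accession}: samples not in design: {sorted(unknown)}"
            )
        grouped: dict[str, float] = {}
        for group, members in group_members.items():
            values = [
                rec.abundances[s] for s in members if s in rec.abundances
            ]
            if len(values) >= min_detected:
                grouped[group] = float(agg(values))
        out.append(
            ProteinQuantRecord(
                accession=rec.accession,
                gene_symbol=rec.gene_symbol,
                unique_peptides=rec.unique_peptides,
                abundances=grouped,
            )
        )
    return out


def compute_ratios(
    records: Sequence[ProteinQuantRecord],
    design: SampleDesign,
) -> list[RatioRecord]:
    """Disease/reference and treated/reference ratios from aggregated records.

    Requires exactly one replicate group per role (i.e. post-aggregation).
    Detection of a role means: abundance present and > 0. No pseudo-count
    is ever added; a missing side leaves the ratio absent.
    """
    group_roles = design.group_roles()
    role_groups: dict[str, list[str]] = {}
    for group, role in group_roles.items():
        role_groups.setdefault(role, []).append(group)
    for role, groups in role_groups.items():
        if len(groups) != 1:
            raise DesignError(
                f"role {role!r} maps to {len(groups)} replicate groups "
                f"{sorted(groups)}; aggregate replicates first"
            )
    group_of = {role: groups[0] for role, groups in role_groups.items()}

    seen: set[str] = set()
    out: list[RatioRecord] = []
    for rec in records:
        if rec.accession in seen:
            raise IntegrityError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
        value = {
            role: rec.abundances.get(group_of[role])
            for role in group_of
        }
        detected = {
            role: (v is not None and v > 0) for role, v in value.items()
        }

        def _ratio(num_role: str) -> float | None:
            if detected[num_role] and detected["reference"]:
                return value[num_role] / value["reference"]  # type: ignore[operator]
            return None

        out.append(
            RatioRecord(
                accession=rec.accession,
                gene_symbol=rec.gene_symbol,
                unique_peptides=rec.unique_peptides,
                r_disease=_ratio("disease"),
                r_treated=_ratio("treated"),
                detected=detected,
            )
        )
    return out
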