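"""Biomarker candidate triage.

Candidates are regulated proteins that (i) belong to at least one of the
configured cellular-component categories (by default extracellular matrix
GO:0031012, plasma membrane GO:0005886 and cell junction GO:0030054),
(ii) are dysregulated at least ``biomarker_fold``-fold in either direction
— an *inclusive* bound, deliberately unlike the strict 2-fold regulation
bound — and (iii), when ``require_normalised`` is set, were normalised by
the treatment.

External concordance (expression atlases, literature) is a manual step:
the report leaves those columns blank instead of querying versioned web
services.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .classify import NormalisationCall, RegulationCall, Thresholds
from .errors import IntegrityError
from .io import GeneSetCollection

__all__ = ["CandidateRecord", "select_candidates", "candidate_report"]

REGULATED_VALUES = {
    RegulationCall.REGULATED_UP.value,
    RegulationCall.REGULATED_DOWN.value,
}


@dataclass(frozen=True)
class CandidateRecord:
    accession: str
    gene_symbol: str
    category_ids: tuple[str, ...]
    r_disease: float
    direction: Literal["up", "down"]
    normalisation_call: str

    def __post_init__(self) -> None:
        if not self.category_ids:
            raise IntegrityError(
                f"{self.accession}: candidate must belong to >= 1 category"
            )


def _membership_ids(
    row: pd.Series,
    sets: GeneSetCollection,
    match_on: Literal["accession", "gene_symbol", "auto"],
) -> tuple[str, ...]:
    ids = []
    for set_id in sorted(sets.sets):
        members = sets[set_id].members
        if match_on == "accession":
            hit = row["accession"] in members
        elif match_on == "gene_symbol":
            hit = bool(row["gene_symbol"]) and row["gene_symbol"] in members
        else:  # auto: accession first, gene symbol as fallback
            hit = row["accession"] in members or (
                bool(row["gene_symbol"]) and row["gene_symbol"] in members
            )
        if hit:
            ids.append(set_id)
    return tuple(ids)


def select_candidates(
    classified: pd.DataFrame,
    sets: GeneSetCollection,
    categories: Sequence[str],
    thresholds: Thresholds,
    require_normalised: bool = True,
    match_on: Literal["accession", "gene_symbol", "auto"] = "auto",
) -> list[CandidateRecord]:
    """Select biomarker candidates from a classified table.

    Output is sorted by |log2 r_disease| descending, ties by accession.
    """
    restricted = sets.restrict(list(categories))
    fold = thresholds.biomarker_fold
    out: list[CandidateRecord] = []
    for _, row in classified.iterrows():
        if row["regulation_call"] not in REGULATED_VALUES:
            continue
        r = row["r_disease"]
        if pd.isna(r):
            continue
        r = float(r)
        if not (r >= fold or r <= 1.0 / fold):
            continue
        if (
            require_normalised
            and row["normalisation_call"] != NormalisationCall.NORMALISED.value
        ):
            continue
        ids = _membership_ids(row, restricted, match_on)
        if not ids:
            continue
        out.append(
            CandidateRecord(
                accession=str(row["accession"]),
                gene_symbol=str(row["gene_symbol"] or ""),
                category_ids=ids,
                r_disease=r,
                direction="up" if r > 1 else "down",
                normalisation_call=str(row["normalisation_call"]),
            )
        )
    out.sort(key=lambda c: (-abs(math.log2(c.r_disease)), c.accession))
    return out


def candidate_report(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Candidate table for external validation.

    Concordance columns are left blank for the user to fill from
    literature and expression atlases; ordering is the candidate order
    (fold magnitude descending, ties by accession).
    """
    seen: set[str] = set()
    for c in candidates:
        if c.accession in seen:
            raise IntegrityError(f"duplicate candidate accession {c.accession!r}")
        seen.add(c.accession)
    rows = [
        {
            "accession": c.accession,
            "gene_symbol": c.gene_symbol,
            "categories": ";".join(c.category_ids),
            "r_disease": c.r_disease,
            "direction": c.direction,
            "normalisation_call": c.normalisation_call,
            "literature_concordance": "",
            "expression_atlas_concordance": "",
        }
        for c in candidates
    ]
    columns = [
        "accession", "gene_symbol", "categories", "r_disease", "direction",
        "normalisation_call", "literature_concordance",
        "expression_atlas_concordance",
    ]
    return pd.DataFrame(rows, columns=columns)
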