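"""Reading and writing protein quantification tables, gene sets and results.

The quantification input is a *wide* table: one row per protein, one column
per sample. Because search-engine exports differ in layout, the reader takes
a :class:`ColumnMap` that names which header plays which semantic role
instead of assuming a vendor dialect. Both tab- and comma-separated files
are accepted; the separator is sniffed from the header line.

Identifiers are case-preserved and compared case-sensitively. Decimal
numbers must use a decimal point; comma-decimal input is rejected rather
than silently misread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DesignError, FormatError, IntegrityError, SchemaError

__all__ = [
    "ROLES",
    "ProteinQuantRecord",
    "SampleDesign",
    "GeneSet",
    "GeneSetCollection",
    "ColumnMap",
    "read_quant_table",
    "write_quant_table",
    "read_gmt",
    "write_results",
    "read_results",
    "records_to_frame",
    "frame_to_records",
]

#: The three condition roles of the design: a normal reference line, the
#: disease (cancer) line, and the treated (reprogrammed) line.
ROLES = ("reference", "disease", "treated")

#: Cell contents treated as "not detected" (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a", "none", "null"})


@dataclass
class ProteinQuantRecord:
    """One protein's quantification across samples.

    ``abundances`` maps sample id to a non-negative intensity; a sample id
    absent from the mapping means the protein was not detected in that
    sample.
    """

    accession: str
    gene_symbol: str = ""
    unique_peptides: int = 0
    abundances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accession:
            raise IntegrityError("accession must be non-empty")
        if self.unique_peptides < 0:
            raise ValueError(
                f"{self.accession}: unique_peptides must be >= 0, "
                f"got {self.unique_peptides}"
            )
        for sample, value in self.abundances.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{self.accession}: abundance in sample {sample!r} must be "
                    f"finite and >= 0, got {value!r}"
                )

    def detected_in(self, sample_id: str) -> bool:
        return sample_id in self.abundances


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to condition roles and technical-replicate groups.

    Technical replicates (repeat injections of one pooled sample) share a
    ``replicate_groups`` label; after aggregation one abundance per group
    remains.
    """

    roles: Mapping[str, str]
    replicate_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        for sample, role in self.roles.items():
            if role not in ROLES:
                raise DesignError(
                    f"sample {sample!r} has unknown role {role!r}; "
                    f"expected one of {ROLES}"
                )
        for role in ROLES:
            if role not in set(self.roles.values()):
                raise DesignError(f"design has no sample with role {role!r}")
        missing = set(self.roles) - set(self.replicate_groups)
        if missing:
            raise DesignError(
                f"samples missing from replicate_groups: {sorted(missing)}"
            )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.roles)

    def samples_for_role(self, role: str) -> tuple[str, ...]:
        return tuple(s for s, r in self.roles.items() if r == role)

    def group_roles(self) -> dict[str, str]:
        """Role of each replicate group; groups must not mix roles."""
        out: dict[str, str] = {}
        for sample, group in self.replicate_groups.items():
            role = self.roles[sample]
            if out.setdefault(group, role) != role:
                raise DesignError(
                    f"replicate group {group!r} mixes roles "
                    f"{out[group]!r} and {role!r}"
                )
        return out


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise IntegrityError(f"gene set {self.set_id!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO cellular-component categories)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in out:
                raise IntegrityError(f"duplicate gene set id {s.set_id!r}")
            out[s.set_id] = s
        return cls(sets=out)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, set_ids: Sequence[str]) -> "GeneSetCollection":
        from .errors import ConfigError

        missing = [i for i in set_ids if i not in self.sets]
        if missing:
            raise ConfigError(f"gene set ids not in collection: {missing}")
        return GeneSetCollection(sets={i: self.sets[i] for i in set_ids})


@dataclass(frozen=True)
class ColumnMap:
    """Semantic column roles → header names of a wide quantification table.

    ``abundances`` maps *sample id* (the name used in the
    :class:`SampleDesign`) to the table header holding that sample's
    intensities.
    """

    accession: str
    unique_peptides: str
    abundances: Mapping[str, str]
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.abundances:
            raise SchemaError("column map names no abundance columns")


def _sniff_separator(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_abundance(token: str, column: str, accession: str) -> float | None:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        hint = " (comma decimals are not accepted)" if "," in token else ""
        raise FormatError(
            f"{accession}: cannot parse abundance {token!r} in column "
            f"{column!r}{hint}"
        ) from None
    if not math.isfinite(value) or value < 0:
        raise ValueError(
            f"{accession}: abundance in column {column!r} must be finite "
            f"and >= 0, got {value}"
        )
    return value


def read_quant_table(
    path: str | Path,
    column_map: ColumnMap,
    *,
    zero_is_missing: bool = False,
) -> list[ProteinQuantRecord]:
    """Read a wide quantification table into records.

    Empty/NA abundance cells become absent keys. With ``zero_is_missing``
    set, a literal 0 is also treated as "not detected"; by default zeros are
    kept as measured values.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
    sep = _sniff_separator(header_line)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    wanted = [column_map.accession, column_map.unique_peptides]
    if column_map.gene_symbol is not None:
        wanted.append(column_map.gene_symbol)
    wanted.extend(column_map.abundances.values())
    for col in wanted:
        if col not in frame.columns:
            raise SchemaError(f"mapped column {col!r} not found in {path.name}")

    records: list[ProteinQuantRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        accession = str(row[column_map.accession]).strip()
        if accession in seen:
            raise IntegrityError(f"duplicate accession {accession!r}")
        seen.add(accession)
        symbol = (
            str(row[column_map.gene_symbol]).strip()
            if column_map.gene_symbol is not None
            else ""
        )
        up_token = str(row[column_map.unique_peptides]).strip()
        try:
            unique_peptides = int(float(up_token)) if up_token else 0
        except ValueError:
            raise FormatError(
                f"{accession}: cannot parse unique-peptide count {up_token!r}"
            ) from None
        abundances: dict[str, float] = {}
        for sample_id, col in column_map.abundances.items():
            value = _parse_abundance(str(row[col]), col, accession)
            if value is None:
                continue
            if zero_is_missing and value == 0:
                continue
            abundances[sample_id] = value
        records.append(
            ProteinQuantRecord(
                accession=accession,
                gene_symbol=symbol,
                unique_peptides=unique_peptides,
                abundances=abundances,
            )
        )
    return records


def records_to_frame(
    records: Sequence[ProteinQuantRecord],
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide DataFrame view of records (NaN = not detected)."""
    if samples is None:
        seen: dict[str, None] = {}
        for rec in records:
            for s in rec.abundances:
                seen.setdefault(s)
        samples = list(seen)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "accession": rec.accession,
            "gene_symbol": rec.gene_symbol,
            "unique_peptides": rec.unique_peptides,
        }
        for s in samples:
            row[s] = rec.abundances.get(s, float("nan"))
        rows.append(row)
    columns = ["accession", "gene_symbol", "unique_peptides", *samples]
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(
    frame: pd.DataFrame, samples: Sequence[str]
) -> list[ProteinQuantRecord]:
    records = []
    for _, row in frame.iterrows():
        abundances = {
            s: float(row[s]) for s in samples if pd.notna(row[s])
        }
        records.append(
            ProteinQuantRecord(
                accession=str(row["accession"]),
                gene_symbol=str(row.get("gene_symbol", "") or ""),
                unique_peptides=int(row["unique_peptides"]),
                abundances=abundances,
            )
        )
    return records


def write_quant_table(
    records: Sequence[ProteinQuantRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> None:
    """Write records as the tab-separated wide dialect the reader accepts."""
    frame = records_to_frame(records, samples)
    frame.to_csv(
        path, sep="\t", index=False, na_rep="", float_format="%.12g",
        lineterminator="\n",
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``id<TAB>description<TAB>member...``."""
    sets: dict[str, GeneSet] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT line needs id, description and at "
                    f"least one member ({len(fields)} fields found)"
                )
            set_id, name = fields[0], fields[1]
            if set_id in sets:
                raise IntegrityError(f"duplicate gene set id {set_id!r}")
            members = frozenset(m for m in fields[2:] if m)
            sets[set_id] = GeneSet(set_id=set_id, name=name, members=members)
    return GeneSetCollection(sets=sets)


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with stable column order.

    Missing values are written as empty cells (never the text "None");
    floats keep 12 significant digits so a read/write cycle is lossless for
    ratios and calls.
    """
    frame.to_csv(
        path, sep="\t", index=False, na_rep="", float_format="%.12g",
        lineterminator="\n",
    )


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    # Re-reading an empty gene_symbol column yields NaN; restore "".
    for col in ("gene_symbol", "regulation_call", "normalisation_call"):
        if col in frame.columns:
            frame[col] = frame[col].fillna("")
    return frame
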