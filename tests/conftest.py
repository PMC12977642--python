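from __future__ import annotations

import numpy as np
import pytest

from protnorm.classify import Thresholds
from protnorm.io import ColumnMap, SampleDesign
from protnorm.preprocess import RatioRecord


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def design() -> SampleDesign:
    roles = {}
    groups = {}
    for tag, role in (("ref", "reference"), ("dis", "disease"), ("trt", "treated")):
        for i in (1, 2, 3):
            roles[f"{tag}_{i}"] = role
            groups[f"{tag}_{i}"] = tag
    return SampleDesign(roles=roles, replicate_groups=groups)


@pytest.fixture
def quant_csv(tmp_path):
    path = tmp_path / "quant.csv"
    path.write_text(
        "Accession,Gene,UP,A1,A2\n"
        "P10001,FN1,6,100,200\n"
        "P10002,COL1A1,3,50,\n"
        "P10003,,1,0,10\n"
    )
    return path


@pytest.fixture
def column_map() -> ColumnMap:
    return ColumnMap(
        accession="Accession",
        unique_peptides="UP",
        gene_symbol="Gene",
        abundances={"A1": "A1", "A2": "A2"},
    )


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "GO:0031012\textracellular matrix\tFN1\tCOL1A1\tCOL1A1\n"
        "GO:0005886\tplasma membrane\tEPCAM\tMCAM\tNPTN\n"
        "GO:0030054\tcell junction\tYAP1\tEPCAM\n"
    )
    return path


def make_ratio(
    accession: str,
    r_disease: float | None = None,
    r_treated: float | None = None,
    unique_peptides: int = 6,
    detected: dict[str, bool] | None = None,
    gene_symbol: str = "",
) -> RatioRecord:
    """RatioRecord with detection flags inferred from the present ratios."""
    if detected is None:
        detected = {
            "reference": r_disease is not None or r_treated is not None,
            "disease": r_disease is not None,
            "treated": r_treated is not None,
        }
    return RatioRecord(
        accession=accession,
        gene_symbol=gene_symbol,
        unique_peptides=unique_peptides,
        r_disease=r_disease,
        r_treated=r_treated,
        detected=detected,
    )


def random_ratio_records(rng: np.random.Generator, n_rows: int):
    """Randomized classification tables exercising every rule branch."""
    records = []
    for i in range(n_rows):
        up = int(rng.integers(0, 9))
        kind = rng.random()
        if kind < 0.1:
            rec = make_ratio(
                f"R{i:04d}", None, None, up,
                detected={"reference": False, "disease": True, "treated": False},
            )
        elif kind < 0.2:
            rec = make_ratio(
                f"R{i:04d}", None, None, up,
                detected={"reference": True, "disease": False, "treated": True},
            )
        elif kind < 0.25:
            rec = make_ratio(
                f"R{i:04d}", None, None, up,
                detected={"reference": False, "disease": False, "treated": False},
            )
        else:
            # log2 ratios spanning the boundaries, including exact 2.0/0.5
            r_d = float(np.exp2(rng.uniform(-4, 4)))
            if rng.random() < 0.1:
                r_d = float(rng.choice([2.0, 0.5, 1.0]))
            if rng.random() < 0.15:
                r_t = None
            else:
                r_t = float(np.exp2(rng.uniform(-4, 4)))
                if rng.random() < 0.1:
                    r_t = float(rng.choice([2.0, 0.5, 1.0]))
            rec = make_ratio(f"R{i:04d}", r_d, r_t, up)
        records.append(rec)
    return records
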