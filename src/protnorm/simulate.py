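"""Synthetic three-condition quantification tables with planted truth.

The generator emulates the statistical structure of a label-free
three-line comparison (normal reference, cancer line, reprogrammed line):

* reference abundances are log-normal across a wide dynamic range;
* a planted fraction of proteins is dysregulated, with |log2 ratio|
  placed strictly beyond the fold-change cutoff (margin >= 0.1 in log2,
  so truth labels are well defined under the strict-inequality boundary
  rules);
* a planted fraction of the dysregulated proteins is normalised after
  treatment (treated ratio inside the band), a further fraction only
  trends towards the band (same direction, strictly closer to 1), and the
  rest stay at or beyond the disease ratio;
* technical replicates carry independent multiplicative log-normal noise
  with a configured coefficient of variation (mean-one noise, so replicate
  averaging is unbiased);
* a small fraction of proteins is *exclusive*: undetected in either the
  reference or the disease condition, mirroring missing-in-one-condition
  events;
* unique-peptide counts follow a categorical marginal so both evidence
  tiers are exercised.

Everything is drawn from one seeded NumPy generator: identical config and
seed reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    NormalisationCall,
    RegulationCall,
    Thresholds,
    call_normalisation,
    call_regulation,
)
from .errors import ConfigError, IntegrityError
from .io import ProteinQuantRecord, SampleDesign

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "RecoveryMetrics",
    "default_up_distribution",
    "generate",
    "evaluate_recovery",
]

#: Margin (log2) by which dysregulated effects stay beyond the cutoff,
#: keeping truth labels well defined under strict boundary rules.
MIN_EFFECT_MARGIN = 0.1
#: Minimum effect margin for trend proteins: leaves room for a treated
#: ratio strictly between the band edge and the disease ratio.
TREND_EFFECT_MARGIN = 0.35
#: Placement margins (log2) keeping planted ratios away from decision
#: boundaries so that moderate technical noise rarely flips a call.
BAND_INTERIOR = 0.8          # normalised/background ratios within +-0.8*band
TREND_LOWER_MARGIN = 0.2     # trend ratios start this far outside the band
TREND_UPPER_MARGIN = 0.1     # ... and stop this short of the disease ratio
WORSE_OFFSET = 0.2           # not-normalised ratios at least this far beyond


def default_up_distribution() -> dict[int, float]:
    """Default unique-peptide marginal: 5% below the standard tier (UP=1),
    15% between the tiers (UP 2-4), 80% at the strict tier (UP 5-30)."""
    dist: dict[int, float] = {1: 0.05}
    for up in range(2, 5):
        dist[up] = 0.15 / 3
    for up in range(5, 31):
        dist[up] = 0.80 / 26
    return dist


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults follow the scale and composition of a strict-tier
    three-line proteome comparison: ~2000 quantified proteins, 60%
    dysregulated, 55% of those upregulated, and a 47% / 5% / 48%
    normalised / trend / not-normalised split after treatment.
    """

    n_proteins: int = 2000
    frac_dysregulated: float = 0.60
    frac_up_given_dysreg: float = 0.55
    frac_normalised_given_dysreg: float = 0.47
    frac_trend_given_dysreg: float = 0.05
    effect_log2_mean: float = 1.5
    effect_log2_sd: float = 0.8
    cv_technical: float = 0.10
    n_replicates: int = 3
    frac_exclusive: float = 0.02
    up_count_distribution: Mapping[int, float] = field(
        default_factory=default_up_distribution
    )
    seed: int = 0
    #: log-normal reference abundance: median and sigma of ln(intensity)
    abundance_ln_median: float = 13.8  # ~1e6 on the raw scale
    abundance_ln_sd: float = 1.8

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        for name in (
            "frac_dysregulated",
            "frac_up_given_dysreg",
            "frac_normalised_given_dysreg",
            "frac_trend_given_dysreg",
            "frac_exclusive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if (
            self.frac_normalised_given_dysreg + self.frac_trend_given_dysreg
            > 1.0 + 1e-12
        ):
            raise ConfigError(
                "frac_normalised_given_dysreg + frac_trend_given_dysreg "
                "must not exceed 1"
            )
        if self.cv_technical < 0:
            raise ConfigError("cv_technical must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.effect_log2_sd < 0:
            raise ConfigError("effect_log2_sd must be >= 0")
        probs = np.array(list(self.up_count_distribution.values()))
        counts = np.array(list(self.up_count_distribution.keys()))
        if (counts < 1).any() or (counts > 30).any():
            raise ConfigError("unique-peptide counts must lie in 1..30")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("up_count_distribution must sum to 1")

    def design(self) -> SampleDesign:
        """Matching sample design: n_replicates injections per condition."""
        roles: dict[str, str] = {}
        groups: dict[str, str] = {}
        for role, tag in (
            ("reference", "ref"),
            ("disease", "dis"),
            ("treated", "trt"),
        ):
            for i in range(1, self.n_replicates + 1):
                sample = f"{tag}_{i}"
                roles[sample] = role
                groups[sample] = tag
        return SampleDesign(roles=roles, replicate_groups=groups)


@dataclass
class SyntheticTruth:
    """Planted per-protein labels and noise-free ratios.

    ``frame`` columns: accession, planted_class, planted_normalisation,
    true_r_disease, true_r_treated, unique_peptides, plus the truth calls
    the thresholds imply at each evidence level
    (regulation_standard/strict, normalisation_standard/strict).
    """

    frame: pd.DataFrame
    thresholds: Thresholds

    def fraction_normalised(self, level: str = "strict") -> float:
        """Planted fraction normalised among regulated-with-outcome."""
        reg = self.frame[f"regulation_{level}"]
        norm = self.frame[f"normalisation_{level}"]
        applicable = reg.isin(
            [
                RegulationCall.REGULATED_UP.value,
                RegulationCall.REGULATED_DOWN.value,
            ]
        ) & (norm != NormalisationCall.NOT_APPLICABLE.value)
        if not applicable.any():
            raise IntegrityError("no regulated protein with outcome in truth")
        return float(
            (norm[applicable] == NormalisationCall.NORMALISED.value).mean()
        )


def _draw_effects(
    rng: np.random.Generator,
    n: int,
    cfg: SimConfig,
    min_margin: float,
) -> np.ndarray:
    """|log2 effect| margins beyond the cutoff, >= min_margin (rejection)."""
    margins = np.maximum(
        MIN_EFFECT_MARGIN,
        np.abs(rng.normal(cfg.effect_log2_mean, cfg.effect_log2_sd, size=n)),
    )
    for _ in range(1000):
        bad = margins < min_margin
        if not bad.any():
            return margins
        margins[bad] = np.maximum(
            MIN_EFFECT_MARGIN,
            np.abs(
                rng.normal(
                    cfg.effect_log2_mean, cfg.effect_log2_sd, size=int(bad.sum())
                )
            ),
        )
    raise ConfigError(
        "effect distribution leaves no room for trend placement; "
        "increase effect_log2_mean or effect_log2_sd"
    )


def generate(
    cfg: SimConfig, thresholds: Thresholds | None = None
) -> tuple[list[ProteinQuantRecord], SyntheticTruth]:
    """Generate quantification records and their planted truth."""
    t = thresholds if thresholds is not None else Thresholds()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    band = float(np.log2(t.fc_high))

    accession = np.array([f"SYN{i:05d}" for i in range(1, n + 1)])
    gene_symbol = np.array([f"GS{i:05d}" for i in range(1, n + 1)])
    up_counts = rng.choice(
        np.array(list(cfg.up_count_distribution.keys())),
        size=n,
        p=np.array(list(cfg.up_count_distribution.values())),
    )

    # --- planted classes -------------------------------------------------
    planted = np.full(n, "background", dtype=object)
    exclusive = rng.random(n) < cfg.frac_exclusive
    excl_side = rng.random(n) < 0.5  # True: reference missing
    planted[exclusive & excl_side] = "exclusive_disease"
    planted[exclusive & ~excl_side] = "exclusive_reference"
    free = ~exclusive
    dys = free & (rng.random(n) < cfg.frac_dysregulated)
    up = rng.random(n) < cfg.frac_up_given_dysreg
    planted[dys & up] = "up"
    planted[dys & ~up] = "down"

    planted_norm = np.full(n, "none", dtype=object)
    u = rng.random(n)
    f_norm = cfg.frac_normalised_given_dysreg
    f_trend = cfg.frac_trend_given_dysreg
    planted_norm[dys & (u < f_norm)] = "normalised"
    planted_norm[dys & (u >= f_norm) & (u < f_norm + f_trend)] = "trend"
    planted_norm[dys & (u >= f_norm + f_trend)] = "not_normalised"

    # --- noise-free ratios (log2) ----------------------------------------
    log_rd = np.zeros(n)
    log_rt = np.zeros(n)
    sign = np.where(planted == "up", 1.0, -1.0)

    bg = planted == "background"
    log_rd[bg] = rng.uniform(-BAND_INTERIOR * band, BAND_INTERIOR * band, bg.sum())
    log_rt[bg] = rng.uniform(-BAND_INTERIOR * band, BAND_INTERIOR * band, bg.sum())

    for label, min_margin in (("normalised", MIN_EFFECT_MARGIN),
                              ("not_normalised", MIN_EFFECT_MARGIN),
                              ("trend", TREND_EFFECT_MARGIN)):
        mask = planted_norm == label
        m = int(mask.sum())
        if m == 0:
            continue
        margins = _draw_effects(rng, m, cfg, min_margin)
        log_rd[mask] = sign[mask] * (band + margins)
        if label == "normalised":
            log_rt[mask] = rng.uniform(
                -BAND_INTERIOR * band, BAND_INTERIOR * band, m
            )
        elif label == "trend":
            lower = band + TREND_LOWER_MARGIN
            upper = band + margins - TREND_UPPER_MARGIN
            log_rt[mask] = sign[mask] * rng.uniform(lower, np.maximum(lower, upper))
        else:
            log_rt[mask] = sign[mask] * (
                band + margins + WORSE_OFFSET + np.abs(rng.normal(0.0, 0.5, m))
            )

    # --- abundances -------------------------------------------------------
    ref_pool = np.exp(rng.normal(cfg.abundance_ln_median, cfg.abundance_ln_sd, n))
    dis_pool = ref_pool * np.exp2(log_rd)
    trt_pool = ref_pool * np.exp2(log_rt)
    # exclusive proteins: zero out one side; the surviving conditions keep
    # the reference-level abundance
    dis_pool[planted == "exclusive_reference"] = 0.0
    trt_pool[planted == "exclusive_reference"] = ref_pool[
        planted == "exclusive_reference"
    ]
    refmiss = planted == "exclusive_disease"
    dis_pool[refmiss] = ref_pool[refmiss]
    trt_pool[refmiss] = ref_pool[refmiss]
    ref_pool = np.where(refmiss, 0.0, ref_pool)

    sigma = float(np.sqrt(np.log1p(cfg.cv_technical**2)))

    def _replicates(pool: np.ndarray) -> np.ndarray:
        if sigma == 0.0:
            return np.tile(pool[:, None], (1, cfg.n_replicates))
        noise = rng.normal(
            -0.5 * sigma**2, sigma, size=(n, cfg.n_replicates)
        )
        return pool[:, None] * np.exp(noise)

    condition_values = {
        "ref": _replicates(ref_pool),
        "dis": _replicates(dis_pool),
        "trt": _replicates(trt_pool),
    }

    records: list[ProteinQuantRecord] = []
    for i in range(n):
        abundances: dict[str, float] = {}
        for tag, values in condition_values.items():
            if values[i, 0] == 0.0 or (
                tag == "ref" and refmiss[i]
            ) or (tag == "dis" and planted[i] == "exclusive_reference"):
                continue  # undetected condition: keys absent
            for j in range(cfg.n_replicates):
                abundances[f"{tag}_{j + 1}"] = float(values[i, j])
        records.append(
            ProteinQuantRecord(
                accession=str(accession[i]),
                gene_symbol=str(gene_symbol[i]),
                unique_peptides=int(up_counts[i]),
                abundances=abundances,
            )
        )

    # --- truth calls implied by the thresholds ----------------------------
    rows = []
    for i in range(n):
        detected_ref = planted[i] != "exclusive_disease"
        detected_dis = planted[i] != "exclusive_reference"
        r_d = float(np.exp2(log_rd[i])) if detected_ref and detected_dis else None
        r_t = float(np.exp2(log_rt[i])) if detected_ref else None
        row: dict[str, object] = {
            "accession": str(accession[i]),
            "planted_class": str(planted[i]),
            "planted_normalisation": str(planted_norm[i]),
            "true_r_disease": r_d if r_d is not None else float("nan"),
            "true_r_treated": r_t if r_t is not None else float("nan"),
            "unique_peptides": int(up_counts[i]),
        }
        for level in ("standard", "strict"):
            reg = call_regulation(
                r_d,
                detected_disease=detected_dis,
                detected_reference=detected_ref,
                unique_peptides=int(up_counts[i]),
                thresholds=t,
                level=level,  # type: ignore[arg-type]
            )
            norm = call_normalisation(r_d, r_t, reg, t)
            row[f"regulation_{level}"] = reg.value
            row[f"normalisation_{level}"] = norm.value
        rows.append(row)
    truth = SyntheticTruth(frame=pd.DataFrame(rows), thresholds=t)
    return records, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """Agreement between pipeline calls and planted truth."""

    confusion_regulation: pd.DataFrame
    confusion_normalisation: pd.DataFrame
    recovered_fraction_normalised: float
    planted_fraction_normalised: float

    @property
    def error_pp(self) -> float:
        """|recovered - planted| fraction normalised, percentage points."""
        return 100.0 * abs(
            self.recovered_fraction_normalised
            - self.planted_fraction_normalised
        )

    @property
    def regulation_accuracy(self) -> float:
        c = self.confusion_regulation
        return float(
            sum(
                c.loc[lab, lab]
                for lab in c.index
                if lab in c.columns
            )
            / c.to_numpy().sum()
        )


def evaluate_recovery(
    truth: SyntheticTruth,
    classified: pd.DataFrame,
    level: str = "strict",
) -> RecoveryMetrics:
    """Tabulate per-class confusion and the recovered normalised fraction.

    ``classified`` is the output of :func:`protnorm.classify.classify_records`
    at the same evidence level the truth is read at.
    """
    t_frame = truth.frame.set_index("accession")
    c_frame = classified.set_index("accession")
    if set(t_frame.index) != set(c_frame.index):
        raise IntegrityError(
            "truth and classified tables index different protein sets"
        )
    c_frame = c_frame.loc[t_frame.index]
    conf_reg = pd.crosstab(
        t_frame[f"regulation_{level}"], c_frame["regulation_call"]
    )
    conf_norm = pd.crosstab(
        t_frame[f"normalisation_{level}"], c_frame["normalisation_call"]
    )

    reg_vals = (
        RegulationCall.REGULATED_UP.value,
        RegulationCall.REGULATED_DOWN.value,
    )
    applicable = c_frame["regulation_call"].isin(reg_vals) & (
        c_frame["normalisation_call"] != NormalisationCall.NOT_APPLICABLE.value
    )
    if not applicable.any():
        raise IntegrityError("no regulated protein with outcome in calls")
    recovered = float(
        (
            c_frame.loc[applicable, "normalisation_call"]
            == NormalisationCall.NORMALISED.value
        ).mean()
    )
    return RecoveryMetrics(
        confusion_regulation=conf_reg,
        confusion_normalisation=conf_norm,
        recovered_fraction_normalised=recovered,
        planted_fraction_normalised=truth.fraction_normalised(level),
    )
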