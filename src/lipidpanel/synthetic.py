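"""Synthetic cohort generator for targeted lipid-mediator plasma panels.

Emulates the statistical structure of a mixed psychiatric cohort assayed
for bioactive lipid mediators: log-normal plasma concentrations, a subset
of analytes that sit largely below the assay's lower limit of
quantification (LLOQ), age-correlated analytes with group-wise age
distributions, sporadic gross outliers, and a disease-specific
concentration shift concentrated in the sphingolipid pathway of the
dementia group.

Nothing at the level of raw mass-spectrometry signals is simulated: the
generator produces the subjects x analytes concentration table that a
validated targeted LC-MS/MS assay would deliver after quantification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "GeneratorConfig",
    "CohortTable",
    "default_config",
    "generate_cohort",
]

# Analyte catalogue: (name, class). Sphingolipid-pathway analytes carry the
# planted disease signal; the remaining classes are background.
ANALYTES: tuple[tuple[str, str], ...] = (
    ("sphingosine", "sphingolipid"),
    ("sphingosine-1-phosphate", "sphingolipid"),
    ("sphinganine-1-phosphate", "sphingolipid"),
    ("C16 sphinganine", "sphingolipid"),
    ("C18 sphinganine", "sphingolipid"),
    ("C24 sphinganine", "sphingolipid"),
    ("C24:1 sphinganine", "sphingolipid"),
    ("Cer14:0", "sphingolipid"),
    ("Cer16:0", "sphingolipid"),
    ("Cer18:0", "sphingolipid"),
    ("Cer20:0", "sphingolipid"),
    ("Cer24:0", "sphingolipid"),
    ("Cer24:1", "sphingolipid"),
    ("GluCerC16:0", "sphingolipid"),
    ("GluCerC18:0", "sphingolipid"),
    ("GluCerC18:1", "sphingolipid"),
    ("GluCerC24:1", "sphingolipid"),
    ("LacCerC16:0", "sphingolipid"),
    ("LacCerC18:0", "sphingolipid"),
    ("LacCerC24:0", "sphingolipid"),
    ("LacCerC24:1", "sphingolipid"),
    ("LPA16:0", "lysophosphatidic_acid"),
    ("LPA18:0", "lysophosphatidic_acid"),
    ("LPA18:1", "lysophosphatidic_acid"),
    ("LPA18:2", "lysophosphatidic_acid"),
    ("LPA20:4", "lysophosphatidic_acid"),
    ("AEA", "endocannabinoid"),
    ("OEA", "endocannabinoid"),
    ("PEA", "endocannabinoid"),
    ("1-AG", "endocannabinoid"),
    ("2-AG", "endocannabinoid"),
    ("DHEA", "endocannabinoid"),
    ("cytidine", "nucleoside"),
    ("deoxycytidine", "nucleoside"),
    ("guanosine", "nucleoside"),
    ("thymidine", "nucleoside"),
    ("uridine", "nucleoside"),
    ("GTP", "nucleotide"),
    ("ATP", "nucleotide"),
    ("3',5'-cGMP", "cyclic_nucleotide"),
    ("3',5'-cAMP", "cyclic_nucleotide"),
)

#: Analytes with insufficient assay sensitivity: a large fraction of their
#: measurements fall below the LLOQ in every diagnosis group.
CENSORED_ANALYTES: tuple[str, ...] = (
    "sphingosine",
    "Cer14:0",
    "guanosine",
    "1-AG",
    "2-AG",
    "DHEA",
)

#: Core disease markers (all sphingolipids) receiving the strongest shift
#: in the dementia group, plus a halo of weaker secondary markers.
CORE_MARKERS: tuple[str, ...] = (
    "GluCerC16:0",
    "Cer24:0",
    "Cer20:0",
    "Cer16:0",
    "Cer24:1",
    "C16 sphinganine",
    "LacCerC16:0",
)
SECONDARY_MARKERS: tuple[str, ...] = (
    "sphingosine-1-phosphate",
    "GluCerC18:0",
    "GluCerC24:1",
    "Cer18:0",
    "LacCerC18:0",
    "C24 sphinganine",
)

GROUPS: tuple[str, ...] = ("depression", "bipolar", "adhd", "dementia", "control")

# Group-wise age models (mean, sd, low, high) of a mixed psychiatric
# outpatient cohort with a markedly older dementia group and healthy
# controls recruited from hospital staff.
_AGE_MODEL = {
    "depression": (43.1, 14.0, 18.0, 85.0),
    "bipolar": (43.7, 12.7, 18.0, 85.0),
    "adhd": (38.6, 15.6, 18.0, 85.0),
    "dementia": (69.9, 9.3, 50.0, 95.0),
    "control": (39.6, 13.1, 21.0, 67.0),
}
_BMI_MODEL = {
    "depression": (26.2, 6.9),
    "bipolar": (26.4, 5.4),
    "adhd": (29.1, 9.2),
    "dementia": (26.2, 3.7),
    "control": (23.6, 2.2),
}

# Typical log-scale concentration locations per analyte class (arbitrary
# concentration units differ by orders of magnitude between classes).
_CLASS_LOG_MEAN = {
    "sphingolipid": 4.0,
    "lysophosphatidic_acid": 3.0,
    "endocannabinoid": 1.0,
    "nucleoside": 5.0,
    "nucleotide": 6.5,
    "cyclic_nucleotide": 0.5,
}

_REFERENCE_AGE = 45.0  # age at which the age trend is anchored


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    All concentration parameters live on the natural-log scale; ``lloq``
    and ``detection_floor_ratio`` act on the natural concentration scale.
    """

    n_per_group: dict[str, int]
    analyte_names: list[str]
    analyte_classes: list[str]
    log_mean: np.ndarray
    log_sd: np.ndarray
    dementia_effect: np.ndarray
    age_model: dict[str, tuple[float, float, float, float]]
    age_slopes: np.ndarray
    lloq: np.ndarray
    detection_floor_ratio: float = 0.5
    outlier_rate: float = 0.003
    outlier_factor: float = 8.0
    seed: int = 0

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_names)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        for key in ("log_mean", "log_sd", "dementia_effect", "age_slopes", "lloq"):
            doc[key] = [float(v) for v in doc[key]]
        doc["age_model"] = {g: [float(x) for x in v] for g, v in doc["age_model"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("log_mean", "log_sd", "dementia_effect", "age_slopes", "lloq"):
            doc[key] = np.asarray(doc[key], dtype=float)
        doc["age_model"] = {g: tuple(v) for g, v in doc["age_model"].items()}
        return cls(**doc)


@dataclass
class CohortTable:
    """Subjects x analytes concentration table plus subject metadata.

    ``concentrations`` holds positive values or NaN (not quantifiable);
    ``below_lloq`` flags every cell whose true value fell below the
    analyte's LLOQ, whether or not a verified numeric value was retained.
    """

    concentrations: pd.DataFrame
    below_lloq: pd.DataFrame
    meta: pd.DataFrame
    analyte_classes: pd.Series

    def __post_init__(self) -> None:
        if self.concentrations.shape != self.below_lloq.shape:
            raise ValueError("below-LLOQ mask and concentration matrix differ in shape")
        if not self.concentrations.index.equals(self.meta.index):
            raise ValueError("metadata index does not match concentration rows")

    @property
    def diagnosis(self) -> pd.Series:
        return self.meta["diagnosis"]

    @property
    def age(self) -> pd.Series:
        return self.meta["age"]

    @property
    def n_subjects(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.concentrations.shape[1]

    def select_analytes(self, names) -> "CohortTable":
        names = list(names)
        return CohortTable(
            self.concentrations[names].copy(),
            self.below_lloq[names].copy(),
            self.meta.copy(),
            self.analyte_classes[names].copy(),
        )

    def to_csv(self, path, mask_path=None) -> None:
        out = pd.concat([self.meta, self.concentrations], axis=1)
        out.to_csv(path, index_label="subject_id")
        if mask_path is not None:
            self.below_lloq.astype(int).to_csv(mask_path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, mask_path=None, analyte_classes=None) -> "CohortTable":
        df = pd.read_csv(path, index_col="subject_id")
        meta_cols = ["diagnosis", "age", "sex", "bmi"]
        meta = df[meta_cols]
        conc = df.drop(columns=meta_cols)
        conc.columns.name = "analyte"
        if mask_path is not None:
            mask = pd.read_csv(mask_path, index_col="subject_id").astype(bool)
            mask = mask.reindex(index=conc.index, columns=conc.columns)
        else:
            mask = pd.DataFrame(False, index=conc.index, columns=conc.columns)
        if analyte_classes is None:
            known = {name: cls_ for name, cls_ in ANALYTES}
            analyte_classes = pd.Series(
                [known.get(c, "other") for c in conc.columns], index=conc.columns
            )
        return cls(conc, mask, meta, analyte_classes)


def default_config(
    seed: int = 0, effect_scale: float = 1.0, age_matched: bool = False
) -> GeneratorConfig:
    """Build the default study-like configuration.

    94 subjects in five diagnosis groups (20/20/12/16/26), 41 analytes of
    which six are heavily LLOQ-censored, and a dementia-specific shift on
    sphingolipid-pathway analytes. ``effect_scale`` multiplies the planted
    dementia shift. ``age_matched=True`` draws every group's ages from the
    control distribution; because several analytes rise with age and age
    correction is estimated from a small control group, a cohort whose
    dementia group is decades older retains a residual age signature even
    with ``effect_scale=0`` — a fully null cohort needs both the zero
    effect and age matching.
    """
    names = [a for a, _ in ANALYTES]
    classes = [c for _, c in ANALYTES]
    d = len(names)

    # Deterministic per-analyte spread around the class location so that
    # analytes are not interchangeable.
    log_mean = np.array(
        [_CLASS_LOG_MEAN[c] + 0.13 * (i % 7) - 0.39 for i, c in enumerate(classes)]
    )
    log_sd = np.full(d, 0.6)

    effect = np.zeros(d)
    for name in CORE_MARKERS:
        effect[names.index(name)] = 0.45
    for name in SECONDARY_MARKERS:
        effect[names.index(name)] = 0.22
    effect *= effect_scale

    # 17 analytes rise with age (log-linear), mimicking the age trend of
    # many plasma lipids; chosen across classes, fixed set.
    age_slopes = np.zeros(d)
    aged = [
        "sphingosine-1-phosphate", "sphinganine-1-phosphate", "C18 sphinganine",
        "Cer16:0", "Cer18:0", "Cer20:0", "Cer24:0", "Cer24:1",
        "GluCerC16:0", "GluCerC18:0", "LacCerC16:0", "LacCerC18:0",
        "LPA16:0", "LPA18:1", "cytidine", "uridine", "ATP",
    ]
    for name in aged:
        age_slopes[names.index(name)] = 0.03

    # LLOQ: heavy censoring (~65% of cells) for the six low-sensitivity
    # analytes, moderate for deoxycytidine (~18%, below the exclusion
    # threshold so its sub-LLOQ cells survive into imputation), negligible
    # (3 sd below the location) elsewhere.
    lloq = np.exp(log_mean - 3.0 * log_sd)
    for name in CENSORED_ANALYTES:
        i = names.index(name)
        lloq[i] = np.exp(log_mean[i] + 0.385 * log_sd[i])
    i = names.index("deoxycytidine")
    lloq[i] = np.exp(log_mean[i] - 0.9 * log_sd[i])

    age_model = dict(_AGE_MODEL)
    if age_matched:
        age_model = {g: _AGE_MODEL["control"] for g in age_model}

    return GeneratorConfig(
        n_per_group={"depression": 20, "bipolar": 20, "adhd": 12,
                     "dementia": 16, "control": 26},
        analyte_names=names,
        analyte_classes=classes,
        log_mean=log_mean,
        log_sd=log_sd,
        dementia_effect=effect,
        age_model=age_model,
        age_slopes=age_slopes,
        lloq=lloq,
        seed=seed,
    )


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(size - filled, keep.size)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw one cohort from the generative model.

    Concentrations are log-normal per analyte with an additive log-scale
    age trend (anchored at 45 y), an additive log-scale dementia shift,
    multiplicative gross outliers, and LLOQ censoring: cells below the
    LLOQ are flagged; cells below ``detection_floor_ratio * lloq`` are
    additionally unquantifiable and recorded as missing.
    """
    if any(n <= 0 for n in config.n_per_group.values()):
        raise ValueError("group counts must be positive")
    if np.any(config.lloq <= 0):
        raise ValueError("lloq must be positive")
    if not 0 <= config.outlier_rate < 1:
        raise ValueError("outlier_rate must lie in [0, 1)")

    rng = np.random.default_rng(config.seed)
    d = config.n_analytes

    rows, diag, ages, sexes, bmis = [], [], [], [], []
    for group, n in config.n_per_group.items():
        mean, sd, low, high = config.age_model[group]
        age = _truncated_normal(rng, mean, sd, low, high, n)
        bmean, bsd = _BMI_MODEL.get(group, (25.0, 4.0))
        bmi = np.clip(rng.normal(bmean, bsd, size=n), 16.0, None)
        sex = rng.choice(["m", "f"], size=n)
        log_c = (
            config.log_mean[None, :]
            + config.age_slopes[None, :] * (age[:, None] - _REFERENCE_AGE)
            + rng.normal(0.0, 1.0, size=(n, d)) * config.log_sd[None, :]
        )
        if group == "dementia":
            log_c = log_c + config.dementia_effect[None, :]
        out_mask = rng.random((n, d)) < config.outlier_rate
        direction = rng.choice([-1.0, 1.0], size=(n, d))
        log_c = log_c + out_mask * direction * np.log(config.outlier_factor)
        rows.append(np.exp(log_c))
        diag += [group] * n
        ages.append(age)
        sexes.append(sex)
        bmis.append(bmi)

    conc = np.vstack(rows)
    below = conc < config.lloq[None, :]
    floor = config.detection_floor_ratio * config.lloq
    conc = np.where(conc < floor[None, :], np.nan, conc)

    index = pd.Index([f"S{i + 1:03d}" for i in range(conc.shape[0])], name="subject_id")
    columns = pd.Index(config.analyte_names, name="analyte")
    meta = pd.DataFrame(
        {
            "diagnosis": diag,
            "age": np.concatenate(ages),
            "sex": np.concatenate(sexes),
            "bmi": np.concatenate(bmis),
        },
        index=index,
    )
    return CohortTable(
        pd.DataFrame(conc, index=index, columns=columns),
        pd.DataFrame(below, index=index, columns=columns),
        meta,
        pd.Series(config.analyte_classes, index=columns),
    )
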