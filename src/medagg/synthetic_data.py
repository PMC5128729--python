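"""Seeded generators for the evaluation datasets.

The primary generator emulates a neonatal therapeutic-drug-monitoring
collection: ~8922 complete records of preterm and term newborns treated
with gentamicin, annotated with the keywords "Gentamicin" and "neonates".
Decoy generators produce datasets on unrelated topics ("Malaria",
"adults", "cancer") with a disjoint schema (age, gender) so that keyword
routing and capability matching can be exercised against negatives.

The real collection's distributions are not published; the defaults here
are clinically plausible stand-ins (truncated-normal gestational age, body
weight increasing with gestational age, uniform postnatal age, log-normal
drug concentration) and every parameter is exposed on
:class:`GeneratorConfig` so studies can vary them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import CLINICAL_COLUMNS, Dataset, KeywordSet

__all__ = ["GeneratorConfig", "generate_gentamicin", "generate_decoy"]

#: usable complete records in the emulated collection
DEFAULT_N_RECORDS = 8922

GENTAMICIN_KEYWORDS = KeywordSet({"Gentamicin", "neonates"})


@dataclass(frozen=True)
class AttributeSpec:
    """Distribution parameters for one generated attribute."""

    lo: float
    hi: float
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"degenerate range [{self.lo}, {self.hi}]")


def _default_specs() -> dict[str, AttributeSpec]:
    return {
        # weeks; NICU population skews preterm
        "gestational_age": AttributeSpec(lo=24.0, hi=42.0, mean=34.0, sd=4.0),
        # grams; centred on a GA-dependent mean, see generate_gentamicin
        "body_weight": AttributeSpec(lo=400.0, hi=5000.0, sd=300.0),
        # days since birth
        "postnatal_age": AttributeSpec(lo=0.0, hi=28.0),
        # mg/L; log-normal location/scale on the log scale
        "concentration": AttributeSpec(lo=0.0, hi=50.0, mean=1.0, sd=0.6),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    n_records: int = DEFAULT_N_RECORDS
    seed: int = 0
    keywords: KeywordSet = GENTAMICIN_KEYWORDS
    attribute_specs: dict = field(default_factory=_default_specs)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not isinstance(self.keywords, KeywordSet):
            object.__setattr__(self, "keywords", KeywordSet(self.keywords))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; cheap at these mild truncations."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_gentamicin(config: GeneratorConfig | None = None) -> Dataset:
    """Generate a complete neonatal gentamicin TDM dataset.

    Gestational age (GA) is truncated-normal on [24, 42] weeks; body weight
    is normal around a linear function of GA (~900 g at 24 weeks, ~3300 g
    at term), truncated to [400, 5000] g, so the two are positively
    correlated as in any birth cohort; postnatal age is uniform over the
    first 28 days; gender is Bernoulli(1/2); trough/peak drug concentration
    is log-normal.  Deterministic for a fixed seed.  With
    ``missing_rate == 0`` (the default) every record is complete.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    specs = config.attribute_specs

    ga_spec = specs["gestational_age"]
    bw_spec = specs["body_weight"]
    pna_spec = specs["postnatal_age"]
    conc_spec = specs["concentration"]

    ga = _truncated_normal(rng, ga_spec.mean, ga_spec.sd, ga_spec.lo, ga_spec.hi, n)
    # fetal growth proxy: ~150 g per gestational week
    bw_mean = 3300.0 - 150.0 * (40.0 - ga)
    bw = rng.normal(bw_mean, bw_spec.sd, size=n)
    bw = np.clip(bw, bw_spec.lo, bw_spec.hi)
    pna = rng.integers(int(pna_spec.lo), int(pna_spec.hi) + 1, size=n)
    gender = np.where(rng.random(n) < 0.5, "M", "F")
    conc = rng.lognormal(conc_spec.mean, conc_spec.sd, size=n)
    conc = np.clip(conc, conc_spec.lo, conc_spec.hi)

    df = pd.DataFrame(
        {
            "pseudonym": [f"P{i:06d}" for i in range(n)],
            "body_weight": np.round(bw).astype(float),
            "gestational_age": np.round(ga, 1),
            "postnatal_age": pna.astype(float),
            "gender": gender,
            "concentration": np.round(conc, 2),
        },
        columns=list(CLINICAL_COLUMNS),
    )

    if config.missing_rate > 0 and n > 0:
        for col in ("body_weight", "gestational_age", "concentration"):
            hole = rng.random(n) < config.missing_rate
            df.loc[hole, col] = np.nan

    return Dataset(records=df, keywords=config.keywords, name="gentamicin")


def generate_decoy(
    keywords: Iterable[str], n_records: int, seed: int
) -> Dataset:
    """Generate an off-topic dataset with the disjoint schema (age, gender).

    Ages are uniform integers in [18, 100] years.  Deterministic per seed.
    """
    kw = KeywordSet(keywords)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "pseudonym": [f"D{i:06d}" for i in range(n_records)],
            "age": rng.integers(18, 101, size=n_records).astype(float),
            "gender": np.where(rng.random(n_records) < 0.5, "M", "F"),
        },
        columns=["pseudonym", "age", "gender"],
    )
    return Dataset(records=df, keywords=kw, name="decoy-" + "-".join(sorted(kw)))
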