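"""Synthetic methylation cohorts with planted age signal.

The generator emulates the structure of a two-frog-species methylation study
(X. laevis n=35, X. tropicalis n=30, six tissues plus whole-animal samples,
ages from 2 days to 19 years) optionally combined with a human cohort
(ages 0-101 y), so that every downstream stage — clustering, clocks, EWAS,
enrichment — can be exercised without any external download.

Beta values follow

    beta = clip01( baseline
                   + species_offset + tissue_offset
                   + direction * effect * g_species(age)
                   + noise )

where ``g_species`` is the same log-linear age transform the clocks use,
rescaled to [0, 1] over the species' planned age range; the planted age
signal is therefore realistically nonlinear in chronological age.  A subset
of the positively drifting CpGs is flagged as PRC2 targets (hypermethylation
of Polycomb-repressed regions with age being the hallmark the enrichment
stage must recover); a PRC1 set filled at the background rate serves as a
null comparison.

Ages are drawn log-uniformly over each species' plan range so embryos and
juveniles are well represented, with a floor of 0.005 y (~2 days) applied
when a plan's lower bound is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .age import DEFAULT_K_FRACTION, loglinear_forward
from .io import (
    AnnotationSets,
    BetaMatrix,
    MethylationCohort,
    SampleRecord,
    SpeciesRegistry,
    default_registry,
)

__all__ = [
    "SpeciesPlan",
    "SimulationConfig",
    "GroundTruth",
    "default_study_plan",
    "generate_cohort",
]

AGE_FLOOR_YEARS = 0.005  # ~2 days; youngest whole-embryo samples


@dataclass(frozen=True)
class SpeciesPlan:
    """Sampling plan for one species: tissue -> sample count, age range."""

    species: str
    age_lo: float
    age_hi: float
    tissues: Mapping[str, int]

    @property
    def n(self) -> int:
        return int(sum(self.tissues.values()))


@dataclass
class SimulationConfig:
    n_cpgs: int = 4000
    plans: Sequence[SpeciesPlan] = ()
    n_positive_cpgs: int = 300
    n_negative_cpgs: int = 200
    effect_scale: float = 0.35   # max methylation drift over the age range
    noise_sd: float = 0.03       # per-observation Gaussian sd before bounding
    tissue_offset_sd: float = 0.02
    species_offset_sd: float = 0.05
    frac_prc2: float = 0.8       # fraction of '+' CpGs flagged PRC2
    background_prc2_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cpgs <= 0:
            raise ValueError("n_cpgs must be positive")
        if self.n_positive_cpgs + self.n_negative_cpgs > self.n_cpgs:
            raise ValueError("planted CpG counts exceed n_cpgs")
        for sd in (self.noise_sd, self.tissue_offset_sd, self.species_offset_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.frac_prc2 <= 1 and 0 <= self.background_prc2_rate <= 1):
            raise ValueError("PRC2 fractions must lie in [0, 1]")
        for plan in self.plans:
            if plan.n <= 0:
                raise ValueError(f"plan for {plan.species!r} has no samples")
            if not (0 <= plan.age_lo < plan.age_hi):
                raise ValueError(f"plan for {plan.species!r} has a bad age range")


@dataclass
class GroundTruth:
    """What was planted: per-CpG direction/effect/PRC2 flag, per-sample age."""

    cpgs: pd.DataFrame      # cpg_id, direction (+1/-1/0), effect, prc2
    sample_ages: pd.Series  # generating age, indexed by sample_id
    clip_rate: float        # fraction of beta values clipped into [0, 1]

    @property
    def positive_ids(self) -> set:
        return set(self.cpgs.loc[self.cpgs["direction"] == 1, "cpg_id"])

    @property
    def negative_ids(self) -> set:
        return set(self.cpgs.loc[self.cpgs["direction"] == -1, "cpg_id"])

    @property
    def null_ids(self) -> set:
        return set(self.cpgs.loc[self.cpgs["direction"] == 0, "cpg_id"])


def default_study_plan(human_n: int = 200, seed: int = 0) -> SimulationConfig:
    """The default cohort: the study's 65-frog design plus a scaled-down
    human cohort (n=200, ages 0-101) for the dual-species clocks.

    Frog tissue counts mirror the study: laevis blood 3, brain 2, liver 3,
    muscle 6, skin 5, toe 7, whole 9 (35 total, ages 0.005-19 y);
    tropicalis blood 4, brain 4, liver 3, muscle 5, skin 4, toe 6, whole 4
    (30 total, ages 0.005-8 y).
    """
    laevis = SpeciesPlan(
        "laevis", 0.005, 19.0,
        {"blood": 3, "brain": 2, "liver": 3, "muscle": 6, "skin": 5,
         "toe": 7, "whole": 9},
    )
    tropicalis = SpeciesPlan(
        "tropicalis", 0.005, 8.0,
        {"blood": 4, "brain": 4, "liver": 3, "muscle": 5, "skin": 4,
         "toe": 6, "whole": 4},
    )
    per_tissue, rem = divmod(human_n, 5)
    human_tissues = {"blood": per_tissue + rem, "brain": per_tissue,
                     "liver": per_tissue, "muscle": per_tissue,
                     "skin": per_tissue}
    human = SpeciesPlan("human", 0.0, 101.0, human_tissues)
    return SimulationConfig(plans=(laevis, tropicalis, human), seed=seed)


def _baselines(rng, directions: np.ndarray) -> np.ndarray:
    """Per-CpG baseline methylation.

    Null CpGs mimic array bimodality (mixture of low / intermediate / high
    Beta draws, weights 0.4/0.2/0.4).  Planted CpGs keep headroom for their
    drift: '+' baselines come from the low/intermediate components, '-' from
    intermediate/high.
    """
    n = directions.size
    base = np.empty(n)
    comp_low = rng.beta(3.0, 12.0, size=n)
    comp_mid = rng.beta(5.0, 5.0, size=n)
    comp_high = rng.beta(12.0, 3.0, size=n)
    u = rng.uniform(size=n)
    for i, d in enumerate(directions):
        if d == 1:
            base[i] = comp_low[i] if u[i] < 0.6 else comp_mid[i]
        elif d == -1:
            base[i] = comp_high[i] if u[i] < 0.6 else comp_mid[i]
        else:
            base[i] = (comp_low[i] if u[i] < 0.4
                       else comp_high[i] if u[i] > 0.6 else comp_mid[i])
    return base


def generate_cohort(config: SimulationConfig,
                    registry: SpeciesRegistry | None = None):
    """Generate (cohort, annotation sets, ground truth) from *config*.

    A single seeded generator drives all draws in a fixed order, so identical
    configs give bit-identical output.
    """
    if not config.plans:
        raise ValueError("config has no species plans")
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.n_cpgs)))
    cpg_ids = [f"cg{i:0{width}d}" for i in range(config.n_cpgs)]

    directions = np.zeros(config.n_cpgs, dtype=int)
    directions[: config.n_positive_cpgs] = 1
    directions[config.n_positive_cpgs:
               config.n_positive_cpgs + config.n_negative_cpgs] = -1

    # effect magnitudes: planted CpGs drift by U(0.3, 1) * effect_scale
    effects = np.zeros(config.n_cpgs)
    planted = directions != 0
    effects[planted] = config.effect_scale * rng.uniform(0.3, 1.0, planted.sum())

    baselines = _baselines(rng, directions)

    # PRC2 membership: enriched among '+' CpGs, background rate elsewhere;
    # PRC1 is a pure background-rate null set.
    u_prc2 = rng.uniform(size=config.n_cpgs)
    prc2 = np.where(directions == 1, u_prc2 < config.frac_prc2,
                    u_prc2 < config.background_prc2_rate)
    prc1 = rng.uniform(size=config.n_cpgs) < config.background_prc2_rate

    columns = []
    records = []
    n_clipped = 0
    n_total = 0
    for plan in config.plans:
        info = registry[plan.species]
        m = info.maturity_years
        k = m * DEFAULT_K_FRACTION
        lo = max(plan.age_lo, AGE_FLOOR_YEARS)
        hi = plan.age_hi

        sp_offset = rng.normal(0.0, config.species_offset_sd, config.n_cpgs)
        tissue_names = list(plan.tissues)
        tis_offsets = {
            t: rng.normal(0.0, config.tissue_offset_sd, config.n_cpgs)
            for t in tissue_names
        }
        ages = np.exp(rng.uniform(np.log(lo), np.log(hi), plan.n))

        g_lo = loglinear_forward(lo, m, k)
        g_hi = loglinear_forward(hi, m, k)
        idx = 0
        for tissue in tissue_names:
            for _ in range(plan.tissues[tissue]):
                age = float(ages[idx])
                g = (loglinear_forward(age, m, k) - g_lo) / (g_hi - g_lo)
                raw = (baselines + sp_offset + tis_offsets[tissue]
                       + directions * effects * g
                       + rng.normal(0.0, config.noise_sd, config.n_cpgs))
                col = np.clip(raw, 0.0, 1.0)
                n_clipped += int(np.count_nonzero(col != raw))
                n_total += config.n_cpgs
                sid = f"{plan.species}_{tissue}_{idx:03d}"
                sex = ("unknown" if age < m
                       else ("female" if rng.uniform() < 0.5 else "male"))
                records.append(
                    SampleRecord(sample_id=sid, species=plan.species,
                                 tissue=tissue, age_years=age, sex=sex)
                )
                columns.append(col)
                idx += 1

    values = np.column_stack(columns)
    beta = BetaMatrix(cpg_ids, [r.sample_id for r in records], values)
    cohort = MethylationCohort(beta, records)

    sets = AnnotationSets(
        background=set(cpg_ids),
        named_sets={
            "PRC2": {c for c, f in zip(cpg_ids, prc2) if f},
            "PRC1": {c for c, f in zip(cpg_ids, prc1) if f},
        },
    )
    truth = GroundTruth(
        cpgs=pd.DataFrame(
            {"cpg_id": cpg_ids, "direction": directions,
             "effect": effects, "prc2": prc2}
        ),
        sample_ages=pd.Series(
            {r.sample_id: r.age_years for r in records}, name="age_years"
        ),
        clip_rate=n_clipped / n_total,
    )
    return cohort, sets, truth
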