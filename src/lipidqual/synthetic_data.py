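"""Synthetic fish datasets with the structure the analysis assumes.

The generator emulates the study design: ~22 species, each observed as the
mean of 10 individuals, with fatty-acid percent vectors that have realistic
SFA/MUFA/PUFA structure and a tunable linear association between trophic
level and the PUFA classes.

Construction, per species:

1. trophic level drawn uniformly on ``trophic_range``;
2. class totals start from ``base_class_mix`` (SFA, MUFA, PUFA targets in
   percent of total fatty acids, summing to the identified total, < 100)
   and shift linearly with centred trophic level: ``pufa_tl_slope`` moves
   mass between PUFA and SFA, ``n6_tl_slope`` moves the n-6 share within
   PUFA;
3. class mass is spread across the 26-acid study panel by frozen
   within-class proportions estimated once from the study data (C16:0
   dominates SFA at ~65%, oleic and palmitoleic acid dominate MUFA,
   DHA and EPA dominate n-3);
4. every entry is perturbed by unbiased multiplicative log-normal noise
   with coefficient of variation ``within_species_cv`` (log-normal keeps
   percentages positive without rejection sampling).

Everything is reproducible from ``seed`` alone; identical configs give
byte-identical CSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset_io import FattyAcidProfile, SpeciesRecord, StudyDataset

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "simulate_dataset",
    "simulate_individuals",
    "SFA_ALLOCATION",
    "MUFA_ALLOCATION",
    "N3_ALLOCATION",
    "N6_ALLOCATION",
]

# Within-class allocation of mass across the 26-acid panel: fixed constants
# estimated once from the study species means, so synthetic profiles look
# like real fish without touching the fixture at generation time.
SFA_ALLOCATION = {
    "C14:0": 0.1104, "C15:0": 0.0207, "C16:0": 0.6567,
    "C17:0": 0.0353, "C18:0": 0.1769,
}
MUFA_ALLOCATION = {
    "C14:1": 0.0111, "C15:1": 0.0089, "C16:1n-7": 0.3298, "C17:1": 0.0272,
    "C18:1n-7": 0.1369, "C18:1n-9": 0.4207, "C20:1": 0.0347,
    "C22:1": 0.0242, "C24:1": 0.0066,
}
N3_ALLOCATION = {
    "C18:3n-3": 0.0424, "C18:4n-3": 0.0353, "C20:3n-3": 0.1002,
    "C20:5n-3": 0.3150, "C22:5n-3": 0.0973, "C22:6n-3": 0.4097,
}
N6_ALLOCATION = {
    "C18:2n-6": 0.4985, "C18:3n-6": 0.0530, "C20:2n-6": 0.0897,
    "C20:4n-6": 0.0599, "C22:4": 0.0910, "C22:5n-6": 0.2078,
}

#: n-6 share of total PUFA in the study data (2.70 of 20.87)
N6_SHARE_OF_PUFA = 0.129

_NEGATIVE_TOL = 1e-9

#: hard compositional ceiling for one profile's identified total (percent)
_SUM_CEILING = 99.9


class ConfigError(ValueError):
    """A simulation config implies negative class mass."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the study: 22 species of 10 individuals each, trophic
    levels spanning 2.0-4.5, class mix at the study means (SFA 38.9,
    MUFA 31.1, PUFA 20.9 percent), lipid contents on the observed
    0.5-7.4 g/100 g range, and 10% within-species variation.  Slopes are
    percent of total fatty acids per trophic-level unit; zero slopes give
    the null (no trophic association) condition.
    """

    n_species: int = 22
    n_individuals: int = 10
    seed: int = 0
    trophic_range: tuple[float, float] = (2.0, 4.5)
    pufa_tl_slope: float = 0.0
    n6_tl_slope: float = 0.0
    base_class_mix: tuple[float, float, float] = (38.9, 31.1, 20.9)
    within_species_cv: float = 0.10
    lipid_content_range: tuple[float, float] = (0.5, 7.4)

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_individuals < 1:
            raise ValueError("counts must be >= 1")
        if self.within_species_cv < 0:
            raise ValueError("cv must be >= 0")
        if any(m <= 0 for m in self.base_class_mix):
            raise ValueError("class mix entries must be positive")
        if sum(self.base_class_mix) >= 100:
            raise ValueError("class mix must sum to an identified total < 100")
        if self.trophic_range[0] > self.trophic_range[1]:
            raise ValueError("empty trophic range")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def _species_label_means(config: SimulationConfig, tl: float) -> dict[str, float]:
    """Noise-free per-label means for one species at trophic level ``tl``."""
    base_sfa, base_mufa, base_pufa = config.base_class_mix
    mid = 0.5 * (config.trophic_range[0] + config.trophic_range[1])
    shift = config.pufa_tl_slope * (tl - mid)
    pufa = base_pufa + shift
    sfa = base_sfa - shift  # compensate so the identified total is stable
    mufa = base_mufa
    n6 = N6_SHARE_OF_PUFA * pufa + config.n6_tl_slope * (tl - mid)
    n3 = pufa - n6
    for name, mass in (("SFA", sfa), ("MUFA", mufa), ("PUFA", pufa),
                       ("n-6", n6), ("n-3", n3)):
        if mass < -_NEGATIVE_TOL:
            raise ConfigError(
                f"config yields negative {name} mass ({mass:.3f}) at TL {tl:.2f}"
            )
    sfa, mufa, n3, n6 = (max(m, 0.0) for m in (sfa, mufa, n3, n6))
    means: dict[str, float] = {}
    for alloc, mass in (
        (SFA_ALLOCATION, sfa),
        (MUFA_ALLOCATION, mufa),
        (N3_ALLOCATION, n3),
        (N6_ALLOCATION, n6),
    ):
        norm = sum(alloc.values())  # tables carry 4 decimals; keep masses exact
        for label, frac in alloc.items():
            means[label] = frac / norm * mass
    return means


def simulate_dataset(config: SimulationConfig) -> StudyDataset:
    """Draw one synthetic study dataset (species means as profiles)."""
    rng = np.random.default_rng(config.seed)
    tls = rng.uniform(*config.trophic_range, size=config.n_species)
    lipids = rng.uniform(*config.lipid_content_range, size=config.n_species)
    lengths = rng.uniform(8.0, 30.0, size=config.n_species)
    weights = rng.uniform(15.0, 250.0, size=config.n_species)

    records, profiles = [], []
    for i in range(config.n_species):
        name = f"Synthetica sp{i + 1:02d}"
        means = _species_label_means(config, tls[i])
        labels = list(means)
        noisy = np.clip(
            np.array([means[l] for l in labels])
            * _lognormal_factors(rng, config.within_species_cv, len(labels)),
            0.0,
            None,
        )
        # percent-of-total vectors cannot exceed 100: rescale the rare noisy
        # draw that breaches the compositional ceiling
        total = float(noisy.sum())
        if total > _SUM_CEILING:
            noisy *= _SUM_CEILING / total
        profiles.append(FattyAcidProfile(name, dict(zip(labels, noisy))))
        records.append(
            SpeciesRecord(
                scientific_name=name,
                common_name=f"synthetic fish {i + 1}",
                trophic_level_mean=round(float(tls[i]), 3),
                trophic_level_sd=0.2,
                lipid_content=round(float(lipids[i]), 3),
                body_length_mean=round(float(lengths[i]), 1),
                body_length_sd=round(float(lengths[i]) * 0.1, 1),
                body_weight_mean=round(float(weights[i]), 1),
                body_weight_sd=round(float(weights[i]) * 0.1, 1),
                n_individuals=config.n_individuals,
            )
        )
    return StudyDataset(records=records, profiles=profiles)


def simulate_individuals(
    config: SimulationConfig, species_means: list[FattyAcidProfile]
) -> pd.DataFrame:
    """Individual-level draws around each species mean.

    Returns a long table with columns ``species``, ``individual`` and one
    column per fatty-acid label.  Each individual's value is the species
    mean times unit-mean log-normal noise with CV ``within_species_cv``,
    so averaging individuals recovers the species mean (up to Monte-Carlo
    error; exactly when cv = 0).
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for profile in species_means:
        labels = list(profile.values)
        base = np.array([profile.values[l] for l in labels])
        for j in range(config.n_individuals):
            noisy = base * _lognormal_factors(rng, config.within_species_cv, len(labels))
            rows.append(
                {"species": profile.species, "individual": j + 1,
                 **dict(zip(labels, noisy))}
            )
    return pd.DataFrame(rows)
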