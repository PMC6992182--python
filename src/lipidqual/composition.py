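"""Class aggregation of a fatty-acid profile and lipid-content categories.

``summarize`` folds a per-acid percent vector into the class sums the rest
of the analysis runs on: SFA / MUFA / PUFA totals, the omega sums (n-3,
n-6), and the named long-chain n-3 acids EPA (C20:5n-3), DPA (C22:5n-3)
and DHA (C22:6n-3).  Everything is a plain sum of stored percentages, so
summaries are linear in the profile and no re-normalization happens here.

``ackman_category`` applies the Ackman lipid-content classification of fish
by total fat (g per 100 g wet weight): lean < 2, low fat 2-4, medium fat
4-8, high fat > 8.  The source rule leaves the boundary sides unstated;
here 2 belongs to low fat and boundaries up to and including 8 to medium
fat, i.e. [2, 4) and [4, 8].
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .dataset_io import FattyAcidProfile, StudyDataset
from .nomenclature import (
    FattyAcidClass,
    OmegaConvention,
    classify,
    omega_membership,
    parse_fatty_acid,
)

__all__ = [
    "ClassSummary",
    "LipidCategory",
    "summarize",
    "ackman_category",
    "categorize_dataset",
    "EPA_LABEL",
    "DPA_LABEL",
    "DHA_LABEL",
]

EPA_LABEL = "C20:5n-3"
DPA_LABEL = "C22:5n-3"
DHA_LABEL = "C22:6n-3"


@dataclass(frozen=True)
class ClassSummary:
    """Class-level aggregates of one profile, in percent of total fatty acids.

    ``epa_dha_share_of_n3`` is the fraction (EPA+DHA)/n-3, or None when the
    profile has no n-3 PUFA at all.
    """

    sfa: float
    mufa: float
    pufa: float
    n3: float
    n6: float
    epa: float
    dha: float
    dpa: float
    total_identified: float
    epa_dha_share_of_n3: Optional[float]

    def __post_init__(self) -> None:
        if abs((self.sfa + self.mufa + self.pufa) - self.total_identified) > 1e-9:
            raise ValueError("sfa + mufa + pufa must equal total_identified")
        if self.n3 + self.n6 > self.pufa + 1e-9:
            raise ValueError("n3 + n6 exceeds pufa")
        for name in ("epa", "dha", "dpa"):
            if getattr(self, name) > self.n3 + 1e-9:
                raise ValueError(f"{name} exceeds the n-3 sum")


class LipidCategory(enum.Enum):
    """Ackman lipid-content category of a fish."""

    LEAN = "lean"
    LOW_FAT = "low_fat"
    MEDIUM_FAT = "medium_fat"
    HIGH_FAT = "high_fat"


def summarize(
    profile: FattyAcidProfile,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> ClassSummary:
    """Aggregate one profile into class sums under an omega convention."""
    sfa = mufa = pufa = n3 = n6 = 0.0
    for label, value in profile.values.items():
        fa = parse_fatty_acid(label)
        cls = classify(fa)
        if cls is FattyAcidClass.SFA:
            sfa += value
        elif cls is FattyAcidClass.MUFA:
            mufa += value
        else:
            pufa += value
            member = omega_membership(fa, convention)
            if member == "n3":
                n3 += value
            elif member == "n6":
                n6 += value
    epa = profile.get(EPA_LABEL)
    dha = profile.get(DHA_LABEL)
    dpa = profile.get(DPA_LABEL)
    share = (epa + dha) / n3 if n3 > 0 else None
    return ClassSummary(
        sfa=sfa,
        mufa=mufa,
        pufa=pufa,
        n3=n3,
        n6=n6,
        epa=epa,
        dha=dha,
        dpa=dpa,
        total_identified=sfa + mufa + pufa,
        epa_dha_share_of_n3=share,
    )


def ackman_category(lipid_content: float) -> LipidCategory:
    """Ackman category for a lipid content in g per 100 g wet weight."""
    if lipid_content < 0:
        raise ValueError(f"negative lipid content: {lipid_content}")
    if lipid_content < 2.0:
        return LipidCategory.LEAN
    if lipid_content < 4.0:
        return LipidCategory.LOW_FAT
    if lipid_content <= 8.0:
        return LipidCategory.MEDIUM_FAT
    return LipidCategory.HIGH_FAT


def categorize_dataset(ds: StudyDataset) -> dict[LipidCategory, int]:
    """Species count per Ackman category; every category key is present."""
    counts = Counter(ackman_category(r.lipid_content) for r in ds.records)
    return {cat: counts.get(cat, 0) for cat in LipidCategory}
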