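"""The five lipid nutritional quality indices.

For one species' fatty-acid percent vector with class sums MUFA, n-3 and
n-6 (see :mod:`lipidqual.composition`):

* n-6/n-3 ratio — total n-6 PUFA over total n-3 PUFA; lower is better
  (UK Department of Health dietary guideline: below 4).
* P/S ratio — total PUFA over total SFA; values below 0.45 are considered
  undesirable.
* IA, index of atherogenicity (Ulbricht & Southgate)::

      IA = (C12:0 + 4*C14:0 + C16:0) / (MUFA + n-6 + n-3)

* IT, index of thrombogenicity (Ulbricht & Southgate)::

      IT = (C14:0 + C16:0 + C18:0)
           / (0.5*MUFA + 0.5*n-6 + 3*n-3 + n-3/n-6)

* HH, hypocholesterolemic/hypercholesterolemic ratio (Santos-Silva)::

      HH = (C18:1n-9 + C18:2n-6 + C20:4n-6 + C18:3n-3
            + C20:5n-3 + C22:5n-3 + C22:6n-3) / (C14:0 + C16:0)

Acids absent from a panel (e.g. C12:0 here) contribute zero.  All five
indices are ratios of linear forms in the percent vector, hence invariant
under uniform rescaling of a profile.  Degenerate denominators raise
:class:`UndefinedIndexError` rather than returning sentinel values, so
pathological synthetic inputs cannot silently contaminate summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .composition import ClassSummary, summarize
from .dataset_io import FattyAcidProfile, StudyDataset
from .nomenclature import OmegaConvention

__all__ = [
    "NutritionalIndices",
    "UndefinedIndexError",
    "n6_n3",
    "ps_ratio",
    "ia",
    "it",
    "hh",
    "compute_indices",
    "all_indices",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ["n6_n3_ratio", "ps_ratio", "ia", "it", "hh"]

_HH_NUMERATOR = [
    "C18:1n-9", "C18:2n-6", "C20:4n-6", "C18:3n-3",
    "C20:5n-3", "C22:5n-3", "C22:6n-3",
]


class UndefinedIndexError(ArithmeticError):
    """An index is undefined for this profile (zero denominator)."""


@dataclass(frozen=True)
class NutritionalIndices:
    """The five quality indices for one species."""

    species: str
    n6_n3_ratio: float
    ps_ratio: float
    ia: float
    it: float
    hh: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in INDEX_COLUMNS}


def n6_n3(summary: ClassSummary) -> float:
    """n-6/n-3 PUFA ratio."""
    if summary.n3 <= 0:
        raise UndefinedIndexError("n-6/n-3 undefined: no n-3 PUFA")
    return summary.n6 / summary.n3


def ps_ratio(summary: ClassSummary) -> float:
    """PUFA/SFA ratio."""
    if summary.sfa <= 0:
        raise UndefinedIndexError("P/S undefined: no SFA")
    return summary.pufa / summary.sfa


def ia(profile: FattyAcidProfile, summary: ClassSummary) -> float:
    """Index of atherogenicity."""
    denom = summary.mufa + summary.n6 + summary.n3
    if denom <= 0:
        raise UndefinedIndexError("IA undefined: MUFA + n-6 + n-3 is zero")
    num = profile.get("C12:0") + 4.0 * profile.get("C14:0") + profile.get("C16:0")
    return num / denom


def it(profile: FattyAcidProfile, summary: ClassSummary) -> float:
    """Index of thrombogenicity (requires n-6 > 0 for its n-3/n-6 term)."""
    if summary.n6 <= 0:
        raise UndefinedIndexError("IT undefined: no n-6 PUFA (n-3/n-6 term)")
    denom = (
        0.5 * summary.mufa
        + 0.5 * summary.n6
        + 3.0 * summary.n3
        + summary.n3 / summary.n6
    )
    if denom <= 0:
        raise UndefinedIndexError("IT undefined: zero denominator")
    num = profile.get("C14:0") + profile.get("C16:0") + profile.get("C18:0")
    return num / denom


def hh(profile: FattyAcidProfile) -> float:
    """Hypocholesterolemic/hypercholesterolemic ratio."""
    denom = profile.get("C14:0") + profile.get("C16:0")
    if denom <= 0:
        raise UndefinedIndexError("HH undefined: C14:0 + C16:0 is zero")
    num = sum(profile.get(label) for label in _HH_NUMERATOR)
    return num / denom


def compute_indices(
    profile: FattyAcidProfile,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> NutritionalIndices:
    """All five indices for one profile."""
    summary = summarize(profile, convention)
    try:
        return NutritionalIndices(
            species=profile.species,
            n6_n3_ratio=n6_n3(summary),
            ps_ratio=ps_ratio(summary),
            ia=ia(profile, summary),
            it=it(profile, summary),
            hh=hh(profile),
        )
    except UndefinedIndexError as exc:
        raise UndefinedIndexError(f"{profile.species}: {exc}") from exc


def all_indices(
    ds: StudyDataset,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> pd.DataFrame:
    """Species-by-index table (one row per species, the five index columns)."""
    rows = []
    for profile in ds.profiles:
        idx = compute_indices(profile, convention)
        rows.append({"species": idx.species, **idx.as_dict()})
    return pd.DataFrame(rows, columns=["species", *INDEX_COLUMNS]).set_index("species")
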