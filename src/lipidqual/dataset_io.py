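"""Tabular IO for fatty-acid profiles and species metadata.

Two CSV schemas are supported:

* profiles — one ``fatty_acid`` column and one numeric column per species;
  the token ``ND`` marks an acid that was not detected (stored as 0 and
  remembered in ``nd_labels``).
* species — one row per species with columns ``scientific_name``,
  ``common_name``, ``trophic_level``, ``trophic_level_sd``,
  ``lipid_content``, ``length``, ``length_sd``, ``weight``, ``weight_sd``
  (and optionally ``n_individuals``).

The study's own tables (22 Pearl River Estuary species, 26 fatty acids,
species means over n = 10 individuals) ship as package data and load via
:func:`load_study_fixture`.  Percent values are kept exactly as printed —
profiles are never re-normalized to 100% — because every downstream number
is defined on the as-printed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

from .nomenclature import parse_fatty_acid

__all__ = [
    "SpeciesRecord",
    "FattyAcidProfile",
    "StudyDataset",
    "SchemaError",
    "read_profiles",
    "read_species",
    "load_study_fixture",
    "write_table",
]

PathLike = Union[str, Path, IO[str]]

#: tolerance on the sum of one profile's percentages beyond 100
PROFILE_SUM_SLACK = 0.5

TROPHIC_LEVEL_RANGE = (1.0, 5.5)


class SchemaError(ValueError):
    """A table violates the expected schema (duplicates, bad columns...)."""


@dataclass(frozen=True)
class SpeciesRecord:
    """Metadata for one species: trophic level, lipid content, sizes."""

    scientific_name: str
    common_name: str
    trophic_level_mean: float
    trophic_level_sd: float
    lipid_content: float  # g per 100 g wet weight
    body_length_mean: float  # cm
    body_length_sd: float
    body_weight_mean: float  # g
    body_weight_sd: float
    n_individuals: int = 10

    def __post_init__(self) -> None:
        lo, hi = TROPHIC_LEVEL_RANGE
        if not lo <= self.trophic_level_mean <= hi:
            raise ValueError(
                f"{self.scientific_name}: trophic level "
                f"{self.trophic_level_mean} outside [{lo}, {hi}]"
            )
        if self.lipid_content < 0:
            raise ValueError(f"{self.scientific_name}: negative lipid content")
        if self.body_length_mean <= 0 or self.body_weight_mean <= 0:
            raise ValueError(f"{self.scientific_name}: non-positive body size")


@dataclass(frozen=True)
class FattyAcidProfile:
    """One species' fatty-acid composition in percent of total fatty acids.

    ``values`` maps canonical label -> percent; labels recorded as not
    detected carry value 0 and appear in ``nd_labels``.
    """

    species: str
    values: dict[str, float]
    nd_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for label, v in self.values.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(
                    f"{self.species}: {label} = {v} outside [0, 100]"
                )
        for label in self.nd_labels:
            if self.values.get(label, 0.0) != 0.0:
                raise ValueError(f"{self.species}: ND label {label} has nonzero value")
        if self.total() > 100.0 + PROFILE_SUM_SLACK:
            raise ValueError(
                f"{self.species}: percentages sum to {self.total():.2f} > 100"
            )

    def total(self) -> float:
        """Sum of all stored percentages (the identified total)."""
        return float(sum(self.values.values()))

    def get(self, label: str) -> float:
        """Percent for ``label``; 0 for acids absent from the panel."""
        return self.values.get(label, 0.0)


@dataclass(frozen=True)
class StudyDataset:
    """Paired species metadata and fatty-acid profiles, keyed consistently."""

    records: list[SpeciesRecord]
    profiles: list[FattyAcidProfile]

    def __post_init__(self) -> None:
        rec_keys = [r.scientific_name for r in self.records]
        prof_keys = [p.species for p in self.profiles]
        if sorted(rec_keys) != sorted(prof_keys):
            missing = set(rec_keys) ^ set(prof_keys)
            raise ValueError(f"records/profiles keys differ: {sorted(missing)}")
        if len(set(rec_keys)) != len(rec_keys):
            raise ValueError("duplicate species in records")

    @property
    def species(self) -> list[str]:
        return [r.scientific_name for r in self.records]

    def record(self, name: str) -> SpeciesRecord:
        return next(r for r in self.records if r.scientific_name == name)

    def profile(self, name: str) -> FattyAcidProfile:
        return next(p for p in self.profiles if p.species == name)

    def __len__(self) -> int:
        return len(self.records)


def read_profiles(path: PathLike) -> list[FattyAcidProfile]:
    """Read a profiles CSV into one :class:`FattyAcidProfile` per species.

    Cells must be numeric or the token ``ND``; fatty-acid labels are
    canonicalized through the nomenclature parser (row index reported on
    failure); duplicate labels raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        return []
    if df.columns[0] != "fatty_acid":
        raise SchemaError("first column must be 'fatty_acid'")
    labels = []
    for i, raw in enumerate(df["fatty_acid"]):
        try:
            labels.append(parse_fatty_acid(raw).label)
        except Exception as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SchemaError(f"duplicate fatty-acid rows: {dupes}")

    profiles = []
    for sp in df.columns[1:]:  # column order preserved
        values: dict[str, float] = {}
        nd: set[str] = set()
        for label, cell in zip(labels, df[sp]):
            cell = cell.strip()
            if cell.upper() == "ND":
                values[label] = 0.0
                nd.add(label)
            else:
                v = float(cell)
                if v < 0:
                    raise ValueError(f"{sp}: negative value {v} for {label}")
                values[label] = v
        profiles.append(FattyAcidProfile(sp, values, frozenset(nd)))
    return profiles


def read_species(path: PathLike) -> list[SpeciesRecord]:
    """Read a species-metadata CSV into :class:`SpeciesRecord` objects."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    required = {
        "scientific_name", "common_name", "trophic_level", "trophic_level_sd",
        "lipid_content", "length", "length_sd", "weight", "weight_sd",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"species CSV missing columns: {sorted(missing)}")
    if df["scientific_name"].duplicated().any():
        raise SchemaError("duplicate species rows")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpeciesRecord(
                scientific_name=str(row["scientific_name"]),
                common_name=str(row["common_name"]),
                trophic_level_mean=float(row["trophic_level"]),
                trophic_level_sd=float(row["trophic_level_sd"]),
                lipid_content=float(row["lipid_content"]),
                body_length_mean=float(row["length"]),
                body_length_sd=float(row["length_sd"]),
                body_weight_mean=float(row["weight"]),
                body_weight_sd=float(row["weight_sd"]),
                n_individuals=int(row.get("n_individuals", 10)),
            )
        )
    return records


def load_study_fixture() -> StudyDataset:
    """The packaged Pearl River Estuary study dataset (22 species, 26 acids)."""
    data = resources.files("lipidqual.data")
    with resources.as_file(data.joinpath("pre_table1.csv")) as p1:
        records = read_species(p1)
    with resources.as_file(data.joinpath("pre_table2.csv")) as p2:
        profiles = read_profiles(p2)
    return StudyDataset(records=records, profiles=profiles)


def write_table(rows: pd.DataFrame, path: PathLike, *, index: bool = False) -> None:
    """Write a result table as CSV (UTF-8, '.' decimal, full precision)."""
    rows.to_csv(path, index=index)


def profiles_frame(profiles: Iterable[FattyAcidProfile]) -> pd.DataFrame:
    """Profiles -> the profiles CSV schema (ND tokens restored)."""
    profiles = list(profiles)
    labels: list[str] = []
    for p in profiles:
        for label in p.values:
            if label not in labels:
                labels.append(label)
    data: dict[str, list] = {"fatty_acid": labels}
    for p in profiles:
        data[p.species] = [
            "ND" if label in p.nd_labels else p.values.get(label, 0.0)
            for label in labels
        ]
    return pd.DataFrame(data)


def species_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """Species records -> the species CSV schema."""
    return pd.DataFrame(
        [
            {
                "scientific_name": r.scientific_name,
                "common_name": r.common_name,
                "trophic_level": r.trophic_level_mean,
                "trophic_level_sd": r.trophic_level_sd,
                "lipid_content": r.lipid_content,
                "length": r.body_length_mean,
                "length_sd": r.body_length_sd,
                "weight": r.body_weight_mean,
                "weight_sd": r.body_weight_sd,
                "n_individuals": r.n_individuals,
            }
            for r in records
        ]
    )
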