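"""Fatty-acid label parsing and classification.

Fatty acids are named by the shorthand ``C<carbons>:<double_bonds>`` with an
optional omega-series suffix ``n-<series>`` giving the position of the last
double bond counted from the methyl end (e.g. ``C22:6n-3`` is DHA).  Labels
from chromatography reports come with cosmetic variation — stray whitespace,
lowercase ``c``, typographic dashes, and the occasional truncated label — so
parsing normalizes before matching, and a small alias table (shipped as
package data) maps known-bad labels to their canonical form.

Saturation classes follow the double-bond count: saturated (SFA, 0 double
bonds), monounsaturated (MUFA, 1), polyunsaturated (PUFA, >= 2).

Omega membership of a PUFA is its explicit ``n-3``/``n-6`` series.  One acid
in the study panel, C22:4, carries no series label.  Biochemically the C22:4
seen in marine fish is almost always adrenic acid (n-6), and study-level
ratio results only reproduce when it is counted as n-6; its printed n-6
range, however, excludes it.  Both readings are therefore exposed as an
:class:`OmegaConvention`: the default counts C22:4 as n-6, the strict
convention counts only explicitly labelled acids.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

__all__ = [
    "FattyAcid",
    "FattyAcidClass",
    "OmegaConvention",
    "FattyAcidParseError",
    "parse_fatty_acid",
    "classify",
    "omega_membership",
    "load_alias_table",
]

# every unicode dash variant seen in extracted tables, mapped to ASCII "-"
_DASH_VARIANTS = "‐‑‒–—―−"
_DASH_TABLE = str.maketrans({c: "-" for c in _DASH_VARIANTS})

_LABEL_RE = re.compile(r"^C(\d{1,2}):(\d)(?:n-(\d+))?$", re.IGNORECASE)

CARBON_RANGE = (4, 30)
DOUBLE_BOND_RANGE = (0, 6)
KNOWN_SERIES = (3, 6, 7, 9)


class FattyAcidParseError(ValueError):
    """Raised when a fatty-acid label cannot be parsed; names the label."""


class FattyAcidClass(enum.Enum):
    """Saturation class, determined solely by the double-bond count."""

    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


class OmegaConvention(enum.Enum):
    """How to assign the series-less C22:4 when summing n-6 PUFAs.

    DEFAULT counts C22:4 as n-6 (adrenic acid); STRICT counts only acids
    with an explicit series label.
    """

    DEFAULT = "default"
    STRICT = "strict"


@dataclass(frozen=True, order=True)
class FattyAcid:
    """Canonical identity of one fatty acid.

    Attributes
    ----------
    carbons : int
        Chain length, 4–30.
    double_bonds : int
        Number of double bonds, 0–6 (and always < carbons).
    omega_series : int or None
        Explicit omega series (3, 6, 7, 9) or None when the label carries
        no ``n-`` suffix.
    """

    carbons: int
    double_bonds: int
    omega_series: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = CARBON_RANGE
        if not lo <= self.carbons <= hi:
            raise ValueError(f"carbons {self.carbons} outside [{lo}, {hi}]")
        lo, hi = DOUBLE_BOND_RANGE
        if not lo <= self.double_bonds <= hi:
            raise ValueError(f"double_bonds {self.double_bonds} outside [{lo}, {hi}]")
        if self.double_bonds >= self.carbons:
            raise ValueError("double_bonds must be < carbons")
        if self.omega_series is not None and self.omega_series not in KNOWN_SERIES:
            raise ValueError(f"unknown omega series n-{self.omega_series}")

    @property
    def label(self) -> str:
        """Canonical text form, e.g. ``C22:6n-3`` or ``C18:0``."""
        base = f"C{self.carbons}:{self.double_bonds}"
        if self.omega_series is not None:
            base += f"n-{self.omega_series}"
        return base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _normalize(label: str) -> str:
    text = label.translate(_DASH_TABLE)
    # markdown-italic residue ("*n*-3") and interior spaces around the suffix
    text = text.replace("*", "")
    text = re.sub(r"\s+", "", text.strip())
    return text


def load_alias_table() -> dict[str, str]:
    """Known-bad labels -> canonical labels, from packaged ``label_aliases.tsv``."""
    aliases: dict[str, str] = {}
    path = resources.files("lipidqual.data").joinpath("label_aliases.tsv")
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")
        aliases[raw] = canonical
    return aliases


_ALIASES: Optional[dict[str, str]] = None


def _aliases() -> dict[str, str]:
    global _ALIASES
    if _ALIASES is None:
        _ALIASES = load_alias_table()
    return _ALIASES


def parse_fatty_acid(label: str) -> FattyAcid:
    """Parse a shorthand fatty-acid label into a :class:`FattyAcid`.

    Tolerates surrounding whitespace, a lowercase leading ``c``, unicode
    dash variants in the ``n-`` suffix, and markdown-italic asterisks.
    Labels listed in the packaged alias table (notably the truncated
    ``C20:5n-``, which is EPA, ``C20:5n-3``) are resolved before parsing.

    Raises
    ------
    FattyAcidParseError
        If the label (after normalization and alias resolution) does not
        match ``C<carbons>:<double_bonds>[n-<series>]`` or violates the
        structural bounds.
    """
    if not isinstance(label, str) or not label.strip():
        raise FattyAcidParseError(f"empty or non-text fatty-acid label: {label!r}")
    text = _normalize(label)
    text = _aliases().get(text, text)
    m = _LABEL_RE.match(text)
    if m is None:
        raise FattyAcidParseError(f"unparseable fatty-acid label: {label!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    series = int(m.group(3)) if m.group(3) is not None else None
    try:
        return FattyAcid(carbons, double_bonds, series)
    except ValueError as exc:
        raise FattyAcidParseError(f"invalid fatty acid {label!r}: {exc}") from exc


def classify(fa: FattyAcid) -> FattyAcidClass:
    """Saturation class from the double-bond count (0 SFA, 1 MUFA, >=2 PUFA)."""
    if fa.double_bonds == 0:
        return FattyAcidClass.SFA
    if fa.double_bonds == 1:
        return FattyAcidClass.MUFA
    return FattyAcidClass.PUFA


def omega_membership(
    fa: FattyAcid, convention: OmegaConvention = OmegaConvention.DEFAULT
) -> str:
    """Omega-series membership of a PUFA: ``"n3"``, ``"n6"`` or ``"neither"``.

    Explicitly labelled acids go by their series.  The series-less C22:4 is
    counted as n-6 under the DEFAULT convention (adrenic acid) and as
    ``neither`` under STRICT.  Non-PUFA input is a contract violation.
    """
    if classify(fa) is not FattyAcidClass.PUFA:
        raise ValueError(f"{fa.label} is not a PUFA")
    if fa.omega_series == 3:
        return "n3"
    if fa.omega_series == 6:
        return "n6"
    if (
        fa.omega_series is None
        and (fa.carbons, fa.double_bonds) == (22, 4)
        and convention is OmegaConvention.DEFAULT
    ):
        return "n6"
    return "neither"
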