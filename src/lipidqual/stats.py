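"""Statistical stages: group summaries, trophic-level correlation, ANOVA.

The analysis operates at the species level: each species enters as the
published mean of n = 10 individuals, so a correlation over the study
dataset has n = 22.  Summary statistics use the sample (n-1) standard
deviation.  One-way ANOVA across Ackman lipid categories is followed by
Tukey's HSD at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .composition import ClassSummary, LipidCategory, ackman_category, summarize
from .dataset_io import StudyDataset
from .nomenclature import OmegaConvention

__all__ = [
    "SummaryStat",
    "CorrelationResult",
    "AnovaResult",
    "UndefinedCorrelationError",
    "DegenerateDesignError",
    "CLASS_QUANTITIES",
    "class_sum",
    "class_means",
    "correlate_with_trophic_level",
    "anova_by_lipid_class",
]

#: quantities selectable by name in the stats stages
CLASS_QUANTITIES = ("sfa", "mufa", "pufa", "n3", "n6", "epa", "dpa", "dha")


class UndefinedCorrelationError(ArithmeticError):
    """Correlation undefined (zero variance in one of the variables)."""


class DegenerateDesignError(ValueError):
    """Fewer than two non-empty groups left for a group comparison."""


@dataclass(frozen=True)
class SummaryStat:
    """Across-species mean and sample SD of one quantity."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value."""

    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 or not 0.0 <= self.p_value <= 1.0 or self.n < 3:
            raise ValueError("invalid correlation result")


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with a Tukey HSD pairwise table."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    #: (group_a, group_b, mean difference a-b, Tukey-adjusted p)
    tukey: list[tuple[str, str, float, float]]


def class_sum(
    ds: StudyDataset,
    quantity: str,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> np.ndarray:
    """The selected class sum for every species, in dataset order."""
    if quantity not in CLASS_QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; use one of {CLASS_QUANTITIES}")
    values = []
    for name in ds.species:
        summary = summarize(ds.profile(name), convention)
        values.append(getattr(summary, quantity))
    return np.asarray(values, dtype=float)


def class_means(
    ds: StudyDataset,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
    quantities: tuple[str, ...] = ("sfa", "mufa", "pufa", "epa", "dpa", "dha"),
) -> dict[str, SummaryStat]:
    """Across-species mean and sample SD of the class sums."""
    if len(ds) < 2:
        raise ValueError("need at least two species")
    out = {}
    for q in quantities:
        vals = class_sum(ds, q, convention)
        out[q] = SummaryStat(
            mean=float(np.mean(vals)), sd=float(np.std(vals, ddof=1)), n=len(vals)
        )
    return out


def correlate_with_trophic_level(
    ds: StudyDataset,
    quantity: str,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> CorrelationResult:
    """Pearson correlation of a class sum against species trophic level.

    Trophic levels enter as point values (their published SDs are not
    modelled).  The two-sided p-value comes from the exact t transform with
    n-2 degrees of freedom.
    """
    y = class_sum(ds, quantity, convention)
    x = np.array([ds.record(name).trophic_level_mean for name in ds.species])
    if len(x) < 3:
        raise ValueError("need at least three species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {'trophic level' if np.ptp(x) == 0 else quantity}"
        )
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def anova_by_lipid_class(
    ds: StudyDataset,
    quantity: str,
    convention: OmegaConvention = OmegaConvention.DEFAULT,
) -> AnovaResult:
    """One-way ANOVA of a class sum across Ackman lipid categories.

    Empty categories are dropped; fewer than two remaining categories raise
    :class:`DegenerateDesignError`.  The Tukey HSD table uses the
    studentized-range distribution at alpha = 0.05 (reported p-values are
    adjusted; significance is p < 0.05).
    """
    values = class_sum(ds, quantity, convention)
    cats = [ackman_category(r.lipid_content) for r in ds.records]
    groups: dict[LipidCategory, list[float]] = {}
    for cat, v in zip(cats, values):
        groups.setdefault(cat, []).append(v)
    groups = {c: g for c, g in groups.items() if len(g) >= 1}
    if len(groups) < 2:
        raise DegenerateDesignError("need at least two non-empty lipid categories")
    names = sorted(groups, key=lambda c: c.value)
    samples = [np.asarray(groups[c], dtype=float) for c in names]
    n_total = sum(len(s) for s in samples)
    df_between = len(samples) - 1
    df_within = n_total - len(samples)

    if np.ptp(np.concatenate(samples)) == 0:  # all observations identical
        f_stat, p_value = 0.0, 1.0
    else:
        f_res = sps.f_oneway(*samples)
        f_stat, p_value = float(f_res.statistic), float(f_res.pvalue)
        if math.isnan(f_stat):
            f_stat, p_value = 0.0, 1.0

    tukey_rows: list[tuple[str, str, float, float]] = []
    if all(len(s) >= 2 for s in samples):
        res = sps.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                tukey_rows.append(
                    (
                        names[i].value,
                        names[j].value,
                        float(np.mean(samples[i]) - np.mean(samples[j])),
                        float(res.pvalue[i, j]),
                    )
                )
    return AnovaResult(
        f_stat=f_stat,
        p_value=p_value,
        df_between=df_between,
        df_within=df_within,
        tukey=tukey_rows,
    )
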