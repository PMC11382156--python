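"""Dataset-level descriptive statistics.

Covers the numbers a characterization table reports for one spectrum:
the heteroatom class-group distribution (counts and percentages), the
derivatized/raw assignment ratio per group, the intensity-weighted mean
element content (e.g. the mean oxygen number O_mean rendered as a class
label like ``"O14"``), and the number- and weight-average molecular
weights derived from relative intensities I_i and m/z values M_i:

    Mn = sum(I_i * M_i) / sum(I_i)
    Mw = sum(I_i * M_i**2) / sum(I_i * M_i)

Rendered percentages and ratios use round-half-away-from-zero at one
decimal place, the convention of printed characterization tables; exact
values are always retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .dataset_io import SpectrumDataset
from .formula_core import heteroatom_class

__all__ = [
    "CLASS_GROUPS",
    "ClassDistribution",
    "MolecularWeightSummary",
    "UndefinedStatisticError",
    "class_distribution",
    "derivatization_ratio",
    "mean_element_content",
    "molecular_weight_summary",
    "render_1dp",
    "summary_report",
]

#: Coarse class-group keys in table order.
CLASS_GROUPS = ("Oo", "OoSs", "NnOo", "NnOoSs", "HC")


class UndefinedStatisticError(ValueError):
    """A statistic was requested on a dataset where it is undefined."""


def render_1dp(value: float) -> float:
    """Round half away from zero to one decimal (printed-table convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassDistribution:
    """Heteroatom class-group counts for one dataset.

    ``fine_classes`` maps each (n, o, s) label to its assignment count and
    summed relative intensity.
    """

    group_counts: Mapping[str, int]
    fine_classes: Mapping[str, tuple[int, float]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.group_counts.values()))

    @property
    def group_percentages(self) -> dict[str, float]:
        """Exact percentages; empty dict when the distribution is empty."""
        total = self.total
        if total == 0:
            return {}
        return {g: 100.0 * c / total for g, c in self.group_counts.items() if c > 0}

    @property
    def rendered_percentages(self) -> dict[str, float]:
        return {g: render_1dp(p) for g, p in self.group_percentages.items()}

    @classmethod
    def from_group_counts(cls, counts: Mapping[str, int]) -> "ClassDistribution":
        """Build directly from printed per-group assignment counts."""
        unknown = set(counts) - set(CLASS_GROUPS)
        if unknown:
            raise ValueError(f"unknown class groups: {sorted(unknown)}")
        if any(c < 0 for c in counts.values()):
            raise ValueError("group counts must be >= 0")
        return cls(group_counts={g: int(c) for g, c in counts.items()})


def class_distribution(ds: SpectrumDataset) -> ClassDistribution:
    """Tabulate assignments by class group and by fine (n, o, s) class."""
    groups: dict[str, int] = {}
    fine: dict[str, list] = {}
    for a in ds.assignments:
        key = heteroatom_class(a.composition)
        groups[key.group] = groups.get(key.group, 0) + 1
        entry = fine.setdefault(key.label, [0, 0.0])
        entry[0] += 1
        entry[1] += a.relative_intensity
    return ClassDistribution(
        group_counts=groups,
        fine_classes={label: (count, intensity) for label, (count, intensity) in fine.items()},
    )


def derivatization_ratio(raw: ClassDistribution, deriv: ClassDistribution, group: str) -> float:
    """Ratio of derivatized to raw assignment counts for one class group."""
    if group not in CLASS_GROUPS:
        raise ValueError(f"unknown class group {group!r}")
    raw_count = raw.group_counts.get(group, 0)
    if raw_count == 0:
        raise UndefinedStatisticError(f"raw count for group {group!r} is zero; ratio undefined")
    return deriv.group_counts.get(group, 0) / raw_count


def mean_element_content(
    ds: SpectrumDataset, element: str = "O", *, weighted: bool = True
) -> tuple[float, str]:
    """Mean element count across assignments, intensity-weighted by default.

    Returns the exact mean together with the nearest-integer class-style
    label (e.g. ``"O14"``).  With ``weighted=False`` the plain arithmetic
    mean of the counts is used instead (a sensitivity-check option).
    """
    element = element.upper()
    if element not in ("C", "H", "N", "O", "S"):
        raise ValueError(f"unknown element {element!r}")
    if len(ds) == 0:
        raise UndefinedStatisticError("mean element content undefined on an empty dataset")
    counts = [a.composition.counts[element] for a in ds.assignments]
    if weighted:
        total = ds.total_intensity
        if total <= 0:
            raise UndefinedStatisticError("total intensity is zero; weighted mean undefined")
        mean = sum(a.relative_intensity * c for a, c in zip(ds.assignments, counts)) / total
    else:
        mean = sum(counts) / len(counts)
    label = f"{element}{int(Decimal(repr(mean)).quantize(Decimal('1'), rounding=ROUND_HALF_UP))}"
    return mean, label


@dataclass(frozen=True)
class MolecularWeightSummary:
    """Number- and weight-average molecular weight of a spectrum (Da)."""

    mn: float
    mw: float

    def __post_init__(self) -> None:
        # mw >= mn holds mathematically (Cauchy-Schwarz); allow float slack
        if not (self.mn > 0 and self.mw >= self.mn * (1.0 - 1e-12)):
            raise ValueError(f"expected mw >= mn > 0, got mn={self.mn}, mw={self.mw}")


def molecular_weight_summary(ds: SpectrumDataset) -> MolecularWeightSummary:
    """Intensity-based Mn and Mw from the assigned peak list."""
    total = ds.total_intensity
    if len(ds) == 0 or total <= 0:
        raise UndefinedStatisticError("Mn/Mw undefined without positive total intensity")
    s1 = sum(a.relative_intensity * a.mz for a in ds.assignments)
    s2 = sum(a.relative_intensity * a.mz ** 2 for a in ds.assignments)
    return MolecularWeightSummary(mn=s1 / total, mw=s2 / s1)


def summary_report(ds: SpectrumDataset) -> dict:
    """One-stop JSON-serializable summary of a dataset."""
    dist = class_distribution(ds)
    report: dict = {
        "sample_id": ds.sample_id,
        "treatment": ds.treatment,
        "aging_time_h": ds.aging_time_h,
        "n_assignments": len(ds),
        "class_groups": {
            g: {
                "count": dist.group_counts.get(g, 0),
                "percent_exact": dist.group_percentages.get(g),
                "percent": dist.rendered_percentages.get(g),
            }
            for g in CLASS_GROUPS
            if dist.group_counts.get(g)
        },
        "fine_classes": {
            label: {"count": c, "intensity": i} for label, (c, i) in sorted(dist.fine_classes.items())
        },
    }
    if len(ds) and ds.total_intensity > 0:
        mean_o, label = mean_element_content(ds, "O")
        mw = molecular_weight_summary(ds)
        report["mean_oxygen"] = {"exact": mean_o, "label": label}
        report["mn"] = mw.mn
        report["mw"] = mw.mw
    return report
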