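"""Raw vs. derivatized dataset matching by chemoselective mass deltas.

DMSO-Ac2O (Albright-Goldman) treatment transforms hydroxyl-bearing
molecules in two formula-resolvable ways:

* **Oxidation** of a primary or secondary alcohol to the aldehyde or
  ketone: elemental delta -H2 per event (benzyl alcohol C7H8O ->
  benzaldehyde C7H6O).  Repeated events are possible on polyols.
* **Methylthiomethyl (MTM) attachment**: CH2SCH3 replacing one H on an
  aromatic ring, or O-MTM on a hindered hydroxyl; either way the
  elemental delta is +C2H4S per attachment, so ring-MTM and O-MTM are
  indistinguishable by formula alone and only the multiplicity m is
  recorded.

A product with delta (m attachments, n oxidations) relative to its raw
precursor therefore satisfies, element-wise,

    dC = 2m,  dH = 4m - 2n,  dS = m,  dN = dO = 0,

which pins (m, n) uniquely: m = dS and n = (4m - dH)/2.  Acetylation
(+C2H2O) is disabled by default and available as an optional third
channel.

In VK space, oxidation lowers H/C at fixed O/C, which reads as movement
below the slope-2 reference line through the origin ("hydration line");
the sign convention of the slope is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .dataset_io import Assignment, SpectrumDataset, log
from .formula_core import (
    ElementalComposition,
    VKPoint,
    heteroatom_class,
    render_formula,
    vk_point,
)

__all__ = [
    "DerivatizationMatch",
    "LinePosition",
    "MatchResult",
    "apply_reaction",
    "infer_reaction",
    "match_datasets",
    "hydration_line_position",
    "shift_report",
]


@dataclass(frozen=True)
class DerivatizationMatch:
    """A raw -> product formula pair with inferred reaction multiplicities."""

    raw: ElementalComposition
    product: ElementalComposition
    mtm_count: int
    oxidation_count: int

    def __post_init__(self) -> None:
        m, n = self.mtm_count, self.oxidation_count
        if m < 0 or n < 0 or (m == 0 and n == 0):
            raise ValueError("need m >= 0, n >= 0 and not both zero")
        if (
            self.product.c - self.raw.c != 2 * m
            or self.product.h - self.raw.h != 4 * m - 2 * n
            or self.product.s - self.raw.s != m
            or self.product.o != self.raw.o
            or self.product.n != self.raw.n
        ):
            raise ValueError("product - raw delta inconsistent with (m, n)")

    @property
    def delta_label(self) -> str:
        parts = []
        if self.mtm_count:
            parts.append(f"+{self.mtm_count}·C2H4S")
        if self.oxidation_count:
            parts.append(f"−{self.oxidation_count}·H2")
        return " ".join(parts)


@dataclass(frozen=True)
class LinePosition:
    """Position of a VK point relative to a reference line."""

    point: VKPoint
    side: str  # above | on | below
    offset: float


def apply_reaction(
    comp: ElementalComposition, mtm_count: int = 0, oxidation_count: int = 0
) -> ElementalComposition:
    """Product composition after m MTM attachments and n oxidations."""
    if mtm_count < 0 or oxidation_count < 0:
        raise ValueError("reaction multiplicities must be >= 0")
    h = comp.h + 4 * mtm_count - 2 * oxidation_count
    if h < 0:
        raise ValueError(f"reaction would drive hydrogen below zero on {comp!r}")
    return ElementalComposition(
        c=comp.c + 2 * mtm_count, h=h, n=comp.n, o=comp.o, s=comp.s + mtm_count
    )


def infer_reaction(
    raw: ElementalComposition,
    product: ElementalComposition,
    max_mtm: int = 5,
    max_ox: int = 3,
) -> DerivatizationMatch | None:
    """Infer the unique (m, n) linking raw to product, or None.

    Requires dN = dO = 0, m = dS = dC/2 within [0, max_mtm], and
    n = (4m - dH)/2 a nonnegative integer within [0, max_ox]; (0, 0)
    (no reaction) is not a match.
    """
    dc, dh = product.c - raw.c, product.h - raw.h
    dn, do, ds = product.n - raw.n, product.o - raw.o, product.s - raw.s
    if dn != 0 or do != 0:
        return None
    m = ds
    if m < 0 or m > max_mtm or dc != 2 * m:
        return None
    num = 4 * m - dh
    if num < 0 or num % 2 != 0:
        return None
    n = num // 2
    if n > max_ox or (m == 0 and n == 0):
        return None
    return DerivatizationMatch(raw=raw, product=product, mtm_count=m, oxidation_count=n)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a derivatized dataset against its raw parent.

    Every product falls into exactly one category: *matched* (at least
    one raw precursor yields a valid reaction delta), *unreacted* (the
    product composition itself occurs in the raw dataset and no reaction
    explains it), or *unexplained*.
    """

    matches: pd.DataFrame  # product_formula, raw_formula, mtm_count, oxidation_count, n_candidates
    unexplained: tuple[ElementalComposition, ...]
    unreacted: tuple[ElementalComposition, ...]
    counts_by_reaction: Mapping[tuple[int, int], int]
    n_products: int

    @property
    def explained_share_pct(self) -> float:
        """Percent of products that are matched or unreacted."""
        if self.n_products == 0:
            return float("nan")
        return 100.0 * (self.n_products - len(self.unexplained)) / self.n_products


def match_datasets(
    raw_ds: SpectrumDataset,
    deriv_ds: SpectrumDataset,
    max_mtm: int = 5,
    max_ox: int = 3,
) -> MatchResult:
    """Explain every derivatized composition as raw + m*C2H4S - n*H2.

    For each product, all raw precursors compatible with some
    ``(m, n)`` within bounds are enumerated (a product explained by more
    than one precursor is reported with all candidates).
    ``counts_by_reaction`` counts each product once under its minimal
    ``(m, n)`` (smallest m, then smallest n).
    """
    if raw_ds.treatment != "raw":
        raise ValueError(f"raw_ds.treatment must be 'raw', got {raw_ds.treatment!r}")
    if deriv_ds.treatment != "DMSO-Ac2O":
        raise ValueError(
            f"deriv_ds.treatment must be 'DMSO-Ac2O', got {deriv_ds.treatment!r}"
        )
    raw_index = {a.composition for a in raw_ds.assignments}
    rows = []
    unexplained: list[ElementalComposition] = []
    unreacted: list[ElementalComposition] = []
    counts: dict[tuple[int, int], int] = {}
    for a in deriv_ds.assignments:
        product = a.composition
        candidates: list[tuple[int, int, ElementalComposition]] = []
        for m in range(0, max_mtm + 1):
            c = product.c - 2 * m
            s = product.s - m
            if c < 1 or s < 0:
                continue
            for n in range(0, max_ox + 1):
                if m == 0 and n == 0:
                    continue
                h = product.h - 4 * m + 2 * n
                if h < 0:
                    continue
                raw = ElementalComposition(c=c, h=h, n=product.n, o=product.o, s=s)
                if raw in raw_index:
                    candidates.append((m, n, raw))
        if not candidates:
            if product in raw_index:
                unreacted.append(product)
            else:
                unexplained.append(product)
            continue
        m0, n0, _ = candidates[0]
        counts[(m0, n0)] = counts.get((m0, n0), 0) + 1
        for m, n, raw in candidates:
            rows.append(
                {
                    "product_formula": render_formula(product),
                    "raw_formula": render_formula(raw),
                    "mtm_count": m,
                    "oxidation_count": n,
                    "n_candidates": len(candidates),
                }
            )
    matches = pd.DataFrame(
        rows,
        columns=["product_formula", "raw_formula", "mtm_count", "oxidation_count", "n_candidates"],
    )
    result = MatchResult(
        matches=matches,
        unexplained=tuple(unexplained),
        unreacted=tuple(unreacted),
        counts_by_reaction=counts,
        n_products=len(deriv_ds),
    )
    log.info(
        "match_datasets: %d/%d products explained (%d matched, %d unreacted, %d unexplained)",
        result.n_products - len(unexplained), result.n_products,
        result.n_products - len(unexplained) - len(unreacted),
        len(unreacted), len(unexplained),
    )
    return result


def hydration_line_position(
    point: VKPoint, slope: float = 2.0, intercept: float = 0.0, tol: float = 1e-9
) -> LinePosition:
    """Side of a VK point relative to the line hc = slope*oc + intercept."""
    offset = point.hc - (slope * point.oc + intercept)
    side = "on" if abs(offset) <= tol else ("above" if offset > 0 else "below")
    return LinePosition(point=point, side=side, offset=offset)


def shift_report(
    raw_ds: SpectrumDataset,
    deriv_ds: SpectrumDataset,
    result: MatchResult,
    *,
    slope: float = 2.0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Per-stratum VK position of matched products relative to the line.

    Strata are (class group of the product, m, n); within each stratum
    the counts below/on/above the reference line and their shares (in
    percent, summing to 100) are reported.  Each product contributes
    once, under its minimal (m, n) match.
    """
    if result.matches.empty:
        return pd.DataFrame(
            columns=["class_group", "mtm_count", "oxidation_count",
                     "below", "on", "above", "below_pct", "on_pct", "above_pct"]
        )
    by_product: dict[str, Assignment] = {
        render_formula(a.composition): a for a in deriv_ds.assignments
    }
    first = result.matches.drop_duplicates(subset="product_formula", keep="first")
    records = []
    for _, row in first.iterrows():
        a = by_product[row["product_formula"]]
        pos = hydration_line_position(vk_point(a.composition), slope=slope, intercept=intercept)
        records.append(
            {
                "class_group": heteroatom_class(a.composition).group,
                "mtm_count": row["mtm_count"],
                "oxidation_count": row["oxidation_count"],
                "side": pos.side,
            }
        )
    frame = pd.DataFrame(records)
    out = (
        frame.groupby(["class_group", "mtm_count", "oxidation_count"])["side"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["below", "on", "above"], fill_value=0)
        .reset_index()
    )
    totals = out[["below", "on", "above"]].sum(axis=1)
    for col in ("below", "on", "above"):
        out[f"{col}_pct"] = 100.0 * out[col] / totals
    return out
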