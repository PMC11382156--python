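"""Reading, writing and quality-filtering of formula-assignment tables.

An assignment table is the delimited-text export of formula-assignment
software: one row per assigned monoisotopic peak carrying the elemental
composition (either a formula string or per-element count columns), the
measured m/z, a relative intensity and optionally the assignment error in
ppm.  The exact export schema varies between tools, so columns are mapped
through a small column-mapping dict (loadable from YAML config).

Quality filtering follows standard ultrahigh-resolution practice: discard
assignments whose |error| exceeds 0.5 ppm, then discard every heteroatom
class whose combined relative intensity falls below 0.15 % of the
post-error-filter total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formula_core import (
    ElementalComposition,
    FormulaError,
    VKPoint,
    dbe,
    heteroatom_class,
    parse_formula,
    render_formula,
    vk_point,
)

__all__ = [
    "Assignment",
    "SpectrumDataset",
    "StandardCompound",
    "SchemaError",
    "TableParseError",
    "DEFAULT_COLUMN_MAP",
    "ELEMENT_WINDOW",
    "read_assignment_table",
    "write_assignment_table",
    "apply_quality_filters",
    "validate_element_window",
    "read_standards_table",
    "load_default_standards",
    "configure_logging",
]

log = logging.getLogger("biooilms")

TREATMENTS = ("raw", "DMSO-Ac2O")

#: Canonical column names; a column-mapping config maps these onto the
#: actual header names of a given export.  Either ``formula`` or the five
#: element-count columns must resolve.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "formula": "formula",
    "c": "c",
    "h": "h",
    "n": "n",
    "o": "o",
    "s": "s",
    "mz": "mz",
    "relative_intensity": "relative_intensity",
    "error_ppm": "error_ppm",
    "is_monoisotopic": "is_monoisotopic",
}

#: Typical assignment window of the upstream software (warn-only check):
#: (min, max) inclusive per element.  The sulfur floor of the printed
#: window is relaxed to 0 because sulfur-free classes dominate raw
#: bio-oil spectra.
ELEMENT_WINDOW: dict[str, tuple[int, int]] = {
    "c": (4, 500),
    "h": (6, 200),
    "n": (0, 4),
    "o": (0, 40),
    "s": (0, 5),
}


class SchemaError(ValueError):
    """A required column is missing or a table is structurally invalid."""


class TableParseError(ValueError):
    """Too many rows of a table failed to parse."""


@dataclass(frozen=True)
class Assignment:
    """One assigned monoisotopic peak."""

    composition: ElementalComposition
    mz: float
    relative_intensity: float
    error_ppm: float = 0.0
    is_monoisotopic: bool = True

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"mz must be positive, got {self.mz!r}")
        if self.relative_intensity < 0:
            raise ValueError(f"relative_intensity must be >= 0, got {self.relative_intensity!r}")


@dataclass(frozen=True)
class SpectrumDataset:
    """A labeled collection of assignments from one spectrum."""

    sample_id: str
    assignments: tuple[Assignment, ...]
    treatment: str = "raw"
    aging_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.aging_time_h is not None and self.aging_time_h < 0:
            raise ValueError("aging_time_h must be >= 0")
        object.__setattr__(self, "assignments", tuple(self.assignments))

    def __len__(self) -> int:
        return len(self.assignments)

    def __iter__(self):
        return iter(self.assignments)

    @property
    def total_intensity(self) -> float:
        return float(sum(a.relative_intensity for a in self.assignments))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived descriptors (DBE, O/C, H/C, class)."""
        rows = []
        for a in self.assignments:
            comp = a.composition
            key = heteroatom_class(comp)
            point = vk_point(comp)
            rows.append(
                {
                    "formula": render_formula(comp),
                    "c": comp.c,
                    "h": comp.h,
                    "n": comp.n,
                    "o": comp.o,
                    "s": comp.s,
                    "mz": a.mz,
                    "relative_intensity": a.relative_intensity,
                    "error_ppm": a.error_ppm,
                    "is_monoisotopic": a.is_monoisotopic,
                    "dbe": dbe(comp),
                    "oc": point.oc,
                    "hc": point.hc,
                    "class_label": key.label,
                    "class_group": key.group,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardCompound:
    """A named reference chemical located in van Krevelen space."""

    name: str
    vk: VKPoint
    composition: ElementalComposition | None = None
    literature_class: str | None = None

    def __post_init__(self) -> None:
        if not (pd.notna(self.vk.oc) and pd.notna(self.vk.hc)):
            raise ValueError(f"standard {self.name!r} has non-finite VK coordinates")
        if self.composition is not None:
            derived = vk_point(self.composition)
            if abs(derived.oc - self.vk.oc) > 1e-9 or abs(derived.hc - self.vk.hc) > 1e-9:
                raise ValueError(
                    f"standard {self.name!r}: vk {self.vk} inconsistent with formula-derived {derived}"
                )


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    log.setLevel(level.upper())
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


def _resolve(colmap: Mapping[str, str] | None) -> dict[str, str]:
    resolved = dict(DEFAULT_COLUMN_MAP)
    if colmap:
        unknown = set(colmap) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise SchemaError(f"unknown canonical column keys in mapping: {sorted(unknown)}")
        resolved.update(colmap)
    return resolved


def _composition_from_row(row: pd.Series, cm: Mapping[str, str], has_formula: bool,
                          has_counts: bool) -> ElementalComposition:
    if has_formula and pd.notna(row[cm["formula"]]):
        return parse_formula(str(row[cm["formula"]]))
    if has_counts:
        return ElementalComposition(
            c=int(row[cm["c"]]),
            h=int(row[cm["h"]]),
            n=int(row[cm["n"]]) if cm["n"] in row.index and pd.notna(row[cm["n"]]) else 0,
            o=int(row[cm["o"]]) if cm["o"] in row.index and pd.notna(row[cm["o"]]) else 0,
            s=int(row[cm["s"]]) if cm["s"] in row.index and pd.notna(row[cm["s"]]) else 0,
        )
    raise FormulaError("row has neither a formula string nor element counts")


def read_assignment_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sample_id: str | None = None,
    treatment: str = "raw",
    aging_time_h: float | None = None,
    sep: str | None = None,
    max_bad_fraction: float = 0.0,
) -> SpectrumDataset:
    """Load a delimited-text assignment table into a :class:`SpectrumDataset`.

    ``column_map`` maps canonical names (see :data:`DEFAULT_COLUMN_MAP`)
    to the file's header names.  ``error_ppm`` defaults to 0 when absent.
    Unparseable rows are collected with their line numbers; the load fails
    when their fraction exceeds ``max_bad_fraction``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cm = _resolve(column_map)
    frame = pd.read_csv(path, sep=sep, engine="python")
    has_formula = cm["formula"] in frame.columns
    has_counts = cm["c"] in frame.columns and cm["h"] in frame.columns
    if not has_formula and not has_counts:
        raise SchemaError(
            f"{path.name}: need either a {cm['formula']!r} column or element-count "
            f"columns {cm['c']!r}/{cm['h']!r}"
        )
    for required in ("mz", "relative_intensity"):
        if cm[required] not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {cm[required]!r} ({required})")
    has_err = cm["error_ppm"] in frame.columns
    has_mono = cm["is_monoisotopic"] in frame.columns

    assignments: list[Assignment] = []
    bad: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            comp = _composition_from_row(row, cm, has_formula, has_counts)
            assignments.append(
                Assignment(
                    composition=comp,
                    mz=float(row[cm["mz"]]),
                    relative_intensity=float(row[cm["relative_intensity"]]),
                    error_ppm=float(row[cm["error_ppm"]]) if has_err and pd.notna(row[cm["error_ppm"]]) else 0.0,
                    is_monoisotopic=bool(row[cm["is_monoisotopic"]]) if has_mono else True,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((lineno, str(exc)))
    if bad:
        frac = len(bad) / max(len(frame), 1)
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:5])
        if frac > max_bad_fraction:
            raise TableParseError(
                f"{path.name}: {len(bad)}/{len(frame)} rows unparseable ({detail})"
            )
        log.warning("%s: skipped %d unparseable rows (%s)", path.name, len(bad), detail)
    log.info(
        "%s: read %d rows, loaded %d assignments, skipped %d",
        path.name, len(frame), len(assignments), len(bad),
    )
    return SpectrumDataset(
        sample_id=sample_id if sample_id is not None else path.stem,
        assignments=tuple(assignments),
        treatment=treatment,
        aging_time_h=aging_time_h,
    )


def write_assignment_table(ds: SpectrumDataset, path: str | Path, *, sep: str = ",") -> None:
    """Write a dataset in the canonical column layout (re-readable)."""
    frame = ds.to_frame()
    cols = ["formula", "c", "h", "n", "o", "s", "mz", "relative_intensity",
            "error_ppm", "is_monoisotopic"]
    out = frame[cols] if len(frame) else pd.DataFrame(columns=cols)
    # default float rendering is shortest-roundtrip, so re-reading restores
    # the exact values
    out.to_csv(path, sep=sep, index=False)


def apply_quality_filters(
    ds: SpectrumDataset,
    max_error_ppm: float = 0.5,
    min_class_rel_abundance_pct: float = 0.15,
) -> SpectrumDataset:
    """Apply the two standard assignment-quality filters, in fixed order.

    1. Remove assignments with ``|error_ppm| > max_error_ppm``.
    2. Remove every heteroatom class whose summed relative intensity is
       below ``min_class_rel_abundance_pct`` percent of the
       post-error-filter total intensity.

    Duplicate compositions (if any survive) are collapsed to the most
    intense occurrence so that compositions are unique afterwards.  The
    whole operation is idempotent.
    """
    if max_error_ppm <= 0 or min_class_rel_abundance_pct <= 0:
        raise ValueError("filter thresholds must be positive")
    kept = [a for a in ds.assignments if abs(a.error_ppm) <= max_error_ppm]
    n_err = len(ds.assignments) - len(kept)

    total = sum(a.relative_intensity for a in kept)
    if total > 0:
        class_sums: dict[str, float] = {}
        for a in kept:
            label = heteroatom_class(a.composition).label
            class_sums[label] = class_sums.get(label, 0.0) + a.relative_intensity
        cutoff = min_class_rel_abundance_pct / 100.0 * total
        low = {label for label, s in class_sums.items() if s < cutoff}
        kept = [a for a in kept if heteroatom_class(a.composition).label not in low]
        if low:
            log.info("class-abundance filter removed classes: %s", sorted(low))

    seen: dict[ElementalComposition, Assignment] = {}
    dupes = 0
    for a in kept:
        prev = seen.get(a.composition)
        if prev is None or a.relative_intensity > prev.relative_intensity:
            if prev is not None:
                dupes += 1
            seen[a.composition] = a
        elif prev is not None:
            dupes += 1
    if dupes:
        log.warning("collapsed %d duplicate composition rows (kept most intense)", dupes)
    deduped = [a for a in kept if seen[a.composition] is a]
    log.info(
        "quality filters: %d -> %d assignments (%d ppm-filtered, %d class-filtered, %d duplicates)",
        len(ds.assignments), len(deduped), n_err,
        len(ds.assignments) - n_err - len(deduped) - dupes, dupes,
    )
    return replace(ds, assignments=tuple(deduped))


def validate_element_window(
    ds: SpectrumDataset, window: Mapping[str, tuple[int, int]] = ELEMENT_WINDOW
) -> list[Assignment]:
    """Return (and log) assignments outside the typical assignment window.

    This is a plausibility warning, never a rejection: real exports
    occasionally contain species just outside the advertised window.
    """
    offenders = []
    for a in ds.assignments:
        counts = a.composition.counts
        for elem, (lo, hi) in window.items():
            value = counts[elem.upper()]
            if not (lo <= value <= hi):
                offenders.append(a)
                break
    if offenders:
        log.warning(
            "%d/%d assignments outside the element window %s",
            len(offenders), len(ds.assignments), dict(window),
        )
    return offenders


def _standards_from_frame(frame: pd.DataFrame, origin: str) -> list[StandardCompound]:
    cols = {c.lower().strip(): c for c in frame.columns}
    if "name" not in cols:
        raise SchemaError(f"{origin}: standards table needs a 'name' column")
    standards: list[StandardCompound] = []
    names_seen: set[str] = set()
    for idx, row in frame.iterrows():
        name = str(row[cols["name"]]).strip()
        if name in names_seen:
            raise SchemaError(f"{origin}: duplicate standard name {name!r}")
        names_seen.add(name)
        comp = None
        formula_val = row[cols["formula"]] if "formula" in cols else None
        if formula_val is not None and pd.notna(formula_val) and str(formula_val).strip():
            comp = parse_formula(str(formula_val).strip())
            point = vk_point(comp)
        elif "oc" in cols and "hc" in cols and pd.notna(row[cols["oc"]]) and pd.notna(row[cols["hc"]]):
            oc, hc = float(row[cols["oc"]]), float(row[cols["hc"]])
            if not (pd.notna(oc) and pd.notna(hc)) or oc != oc or hc != hc:
                raise ValueError(f"{origin}: non-finite VK coordinates for {name!r}")
            point = VKPoint(oc=oc, hc=hc)
        else:
            raise SchemaError(
                f"{origin}: standard {name!r} (row {idx + 2}) has neither a formula nor (oc, hc)"
            )
        if not (point.oc >= 0 and point.hc >= 0 and point.oc < float("inf") and point.hc < float("inf")):
            raise ValueError(f"{origin}: invalid VK coordinates {point} for {name!r}")
        lit = None
        if "literature_class" in cols and pd.notna(row[cols["literature_class"]]):
            lit = str(row[cols["literature_class"]]).strip() or None
        standards.append(StandardCompound(name=name, vk=point, composition=comp, literature_class=lit))
    return standards


def read_standards_table(path: str | Path, *, sep: str | None = None) -> list[StandardCompound]:
    """Load a reference-standards table.

    Each row needs a ``name`` plus either a ``formula`` string or explicit
    ``oc``/``hc`` coordinates; an optional ``literature_class`` column
    carries the literature family label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=sep, engine="python")
    standards = _standards_from_frame(frame, path.name)
    log.info("%s: loaded %d standards", path.name, len(standards))
    return standards


def load_default_standards() -> list[StandardCompound]:
    """Load the packaged bio-oil standards table.

    The shipped table is a synthetic reconstruction assembled from
    compounds named in the bio-oil literature (the original supplementary
    standards list is not publicly deposited); see the file header.
    """
    from importlib.resources import files

    resource = files("biooilms.data").joinpath("standards_synthetic.csv")
    with resource.open("r") as handle:
        frame = pd.read_csv(handle, comment="#")
    return _standards_from_frame(frame, "standards_synthetic.csv")
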