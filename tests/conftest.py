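"""Shared fixtures: tiny in-memory datasets and composition builders."""

from __future__ import annotations

import pytest

from biooilms.dataset_io import Assignment, SpectrumDataset
from biooilms.formula_core import ElementalComposition, monoisotopic_mass, parse_formula


def make_assignment(
    formula: str,
    intensity: float = 1.0,
    error_ppm: float = 0.0,
    mz: float | None = None,
    monoisotopic: bool = True,
) -> Assignment:
    comp = parse_formula(formula)
    return Assignment(
        composition=comp,
        mz=mz if mz is not None else monoisotopic_mass(comp),
        relative_intensity=intensity,
        error_ppm=error_ppm,
        is_monoisotopic=monoisotopic,
    )


def make_dataset(
    rows: list[tuple],
    sample_id: str = "test",
    treatment: str = "raw",
) -> SpectrumDataset:
    """Rows are (formula, intensity[, error_ppm]) tuples."""
    assignments = [make_assignment(*row) for row in rows]
    return SpectrumDataset(sample_id=sample_id, assignments=tuple(assignments), treatment=treatment)


@pytest.fixture
def oxygenated_dataset() -> SpectrumDataset:
    """Five oxygenated formulas (3 sulfur/nitrogen-free + 2 N-containing)."""
    return make_dataset(
        [
            ("C9H12O2", 10.0),
            ("C7H8O", 5.0),
            ("C6H10O5", 8.0),
            ("C9H13N1O2", 2.0),
            ("C10H15N1O3", 1.0),
        ]
    )
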