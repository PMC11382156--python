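"""Synthetic assignment tables with the structure the method assumes.

Real ultrahigh-resolution bio-oil assignment lists are not publicly
deposited, so every pipeline stage is exercised against generated data:

* planted Gaussian point sets in the VK plane, for clustering oracles;
* whole assignment tables drawn from a :class:`FractionProfile` — a
  mixture of compositional *archetypes*, each a fuzzy (O/C, H/C) center
  with carbon-number range, heteroatom bounds and a log-normal intensity
  model, integerized to real CHNOS formulas with m/z computed from the
  exact monoisotopic mass;
* simulated DMSO-Ac2O counterparts, where each molecule independently
  draws an MTM-attachment count and oxidation events, with a ledger of
  the true per-molecule reactions for round-trip tests.

All generators are deterministic under their seed.  What this emulates
— homologous CH2 series, oxygen-class spreads, log-normal intensities,
m/z 150-1800 — is the *statistical* shape of a bio-oil spectrum, not
instrument physics: no noise peaks, isotopic envelopes, resolution
limits or aging kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import Assignment, SpectrumDataset, log
from .formula_core import ElementalComposition, monoisotopic_mass, render_formula

__all__ = [
    "Archetype",
    "FractionProfile",
    "GenerationError",
    "generate_planted_clusters",
    "generate_fraction_dataset",
    "simulate_derivatization",
    "demo_ws_profile",
]


class GenerationError(RuntimeError):
    """A generator could not produce a valid dataset within its retry budget."""


@dataclass(frozen=True)
class Archetype:
    """One compositional component of a fraction profile."""

    name: str
    center: tuple[float, float]  # (oc, hc)
    sd: tuple[float, float] = (0.04, 0.04)
    weight: float = 1.0
    c_range: tuple[int, int] = (6, 60)
    n_range: tuple[int, int] = (0, 0)
    s_range: tuple[int, int] = (0, 0)
    o_bounds: tuple[int, int] = (0, 40)
    log_intensity_mean: float = 13.0
    log_intensity_sd: float = 1.0

    def __post_init__(self) -> None:
        oc, hc = self.center
        if not (0.0 <= oc <= 1.2 and 0.0 <= hc <= 2.4):
            raise ValueError(f"archetype {self.name!r} center {self.center} outside the VK window")
        if self.weight <= 0:
            raise ValueError("archetype weight must be positive")
        if self.sd[0] <= 0 or self.sd[1] <= 0:
            raise ValueError("archetype spreads must be positive")
        if self.c_range[0] < 1 or self.c_range[0] > self.c_range[1]:
            raise ValueError(f"bad carbon range {self.c_range}")


@dataclass(frozen=True)
class FractionProfile:
    """A named mixture of archetypes emulating one bio-oil fraction."""

    name: str
    archetypes: tuple[Archetype, ...]

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise ValueError("profile needs at least one archetype")
        object.__setattr__(self, "archetypes", tuple(self.archetypes))

    @property
    def weights(self) -> np.ndarray:
        w = np.array([a.weight for a in self.archetypes], dtype=float)
        return w / w.sum()


def generate_planted_clusters(
    centers: Sequence[tuple[float, float]],
    n_per_cluster: int,
    sd: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian point clouds around known centers.

    Points are truncated to the physical quadrant (oc >= 0, hc >= 0) by
    resampling.  Returns ``(points, true_labels)``.
    """
    centers = np.asarray(centers, dtype=float)
    if len(np.unique(centers, axis=0)) != len(centers):
        raise ValueError("planted centers must be distinct")
    if sd <= 0 or n_per_cluster < 1:
        raise ValueError("need sd > 0 and n_per_cluster >= 1")
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for j, center in enumerate(centers):
        got = 0
        while got < n_per_cluster:
            draw = rng.normal(center, sd, size=(n_per_cluster - got, 2))
            ok = draw[(draw >= 0).all(axis=1)]
            points.append(ok)
            got += len(ok)
        labels.append(np.full(n_per_cluster, j))
    return np.vstack(points)[: n_per_cluster * len(centers)], np.concatenate(labels)


def _draw_composition(arch: Archetype, rng: np.random.Generator) -> ElementalComposition | None:
    c = int(rng.integers(arch.c_range[0], arch.c_range[1] + 1))
    oc = rng.normal(arch.center[0], arch.sd[0])
    hc = rng.normal(arch.center[1], arch.sd[1])
    o = int(round(oc * c))
    h = int(round(hc * c))
    if not (arch.o_bounds[0] <= o <= arch.o_bounds[1]) or o < 0:
        return None
    if not (6 <= h <= 200):
        return None
    n = int(rng.integers(arch.n_range[0], arch.n_range[1] + 1))
    s = int(rng.integers(arch.s_range[0], arch.s_range[1] + 1))
    return ElementalComposition(c=c, h=h, n=n, o=o, s=s)


def generate_fraction_dataset(
    profile: FractionProfile,
    n_assignments: int,
    seed: int | None = None,
    *,
    sample_id: str | None = None,
    error_ppm_sd: float = 0.15,
    mz_range: tuple[float, float] = (150.0, 1800.0),
    max_tries_per_row: int = 200,
) -> SpectrumDataset:
    """Draw a synthetic assignment table from a fraction profile.

    Per assignment: an archetype is chosen by weight, a carbon number is
    drawn uniformly from its range, and the nearest integer (h, o) to
    the archetype's fuzzed (hc, oc) at that carbon number is taken
    (rejecting element-window or m/z violations).  Compositions are
    unique within the dataset (collisions are resampled).  m/z is the
    exact neutral monoisotopic mass; intensity is log-normal; the
    assignment error is Gaussian truncated to +/-0.5 ppm.
    """
    rng = np.random.default_rng(seed)
    weights = profile.weights
    seen: set[ElementalComposition] = set()
    assignments: list[Assignment] = []
    for _ in range(n_assignments):
        comp = None
        for _try in range(max_tries_per_row):
            arch = profile.archetypes[int(rng.choice(len(weights), p=weights))]
            candidate = _draw_composition(arch, rng)
            if candidate is None or candidate in seen:
                continue
            mass = monoisotopic_mass(candidate)
            if not (mz_range[0] <= mass <= mz_range[1]):
                continue
            comp = candidate
            break
        if comp is None:
            raise GenerationError(
                f"profile {profile.name!r}: no valid unique composition after "
                f"{max_tries_per_row} tries ({len(assignments)} generated)"
            )
        seen.add(comp)
        error = float(np.clip(rng.normal(0.0, error_ppm_sd), -0.5, 0.5))
        assignments.append(
            Assignment(
                composition=comp,
                mz=monoisotopic_mass(comp),
                relative_intensity=float(rng.lognormal(arch.log_intensity_mean, arch.log_intensity_sd)),
                error_ppm=error,
                is_monoisotopic=True,
            )
        )
    log.info("generated %d synthetic assignments for profile %r", len(assignments), profile.name)
    return SpectrumDataset(
        sample_id=sample_id if sample_id is not None else f"synthetic-{profile.name}",
        assignments=tuple(assignments),
        treatment="raw",
    )


def simulate_derivatization(
    ds: SpectrumDataset,
    p_ox: float = 0.3,
    mtm_distribution: Sequence[float] = (0.5, 0.3, 0.1, 0.05, 0.03, 0.02),
    seed: int | None = None,
) -> tuple[SpectrumDataset, pd.DataFrame]:
    """Simulate the DMSO-Ac2O reaction on a raw dataset.

    Per molecule, the MTM-attachment count m is drawn from
    ``mtm_distribution`` (probabilities over m = 0..5) and an oxidation
    event n is drawn Bernoulli(``p_ox``), capped so hydrogen stays
    nonnegative.  Returns the derivatized dataset plus a ledger frame
    with the true per-molecule ``(m, n)`` for round-trip tests.
    Molecules whose product would violate element bounds are left
    unreacted (ledger records m = n = 0).
    """
    if ds.treatment != "raw":
        raise ValueError("simulate_derivatization expects a raw dataset")
    if not (0.0 <= p_ox <= 1.0):
        raise ValueError("p_ox must be a probability")
    mtm_p = np.asarray(mtm_distribution, dtype=float)
    if (mtm_p < 0).any() or abs(mtm_p.sum() - 1.0) > 1e-9:
        raise ValueError("mtm_distribution must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    products: list[Assignment] = []
    ledger_rows = []
    seen: set[ElementalComposition] = set()
    from .derivatization import apply_reaction

    for a in ds.assignments:
        raw = a.composition
        product = m = n = None
        for _try in range(20):  # redraw (m, n) if the product formula collides
            m_try = int(rng.choice(len(mtm_p), p=mtm_p))
            n_try = int(rng.random() < p_ox) if p_ox > 0 else 0
            if raw.h + 4 * m_try - 2 * n_try < 0:
                n_try = 0
            try:
                candidate = apply_reaction(raw, m_try, n_try) if (m_try or n_try) else raw
            except ValueError:
                log.warning("product of %s violates bounds; left unreacted", render_formula(raw))
                candidate, m_try, n_try = raw, 0, 0
            if candidate not in seen:
                product, m, n = candidate, m_try, n_try
                break
        if product is None:
            # every draw collided: leave unreacted, or drop the row if even
            # the raw formula is taken
            if raw in seen:
                continue
            product, m, n = raw, 0, 0
        seen.add(product)
        products.append(
            Assignment(
                composition=product,
                mz=monoisotopic_mass(product),
                relative_intensity=a.relative_intensity,
                error_ppm=a.error_ppm,
                is_monoisotopic=True,
            )
        )
        ledger_rows.append(
            {
                "raw_formula": render_formula(raw),
                "product_formula": render_formula(product),
                "mtm_count": m,
                "oxidation_count": n,
            }
        )
    deriv = SpectrumDataset(
        sample_id=f"{ds.sample_id}-DMSO-Ac2O",
        assignments=tuple(products),
        treatment="DMSO-Ac2O",
        aging_time_h=ds.aging_time_h,
    )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["raw_formula", "product_formula", "mtm_count", "oxidation_count"],
    )
    return deriv, ledger


def demo_ws_profile() -> FractionProfile:
    """Illustrative five-archetype water-soluble-fraction profile.

    The archetypes are positioned at well-separated, near-equidistant
    VK locations loosely evoking the compound families seen in
    water-soluble bio-oil (sugar-like, carbohydrate-like, humin-like,
    lignin-monomer-like, terpenoid-like).  They are illustrative test
    geometry, not measured data.  The spread (sd 0.12 per axis, about a
    quarter of the minimum center separation) emulates the broad,
    partially overlapping families of real spectra; it is also the
    regime in which the between-SS criterion resolves all five families
    rather than saturating at a coarser partition.
    """
    common = dict(sd=(0.12, 0.12), log_intensity_mean=13.0, log_intensity_sd=0.9)
    return FractionProfile(
        name="demo-WS",
        archetypes=(
            Archetype(name="carbohydrate-like", center=(0.5, 1.75), c_range=(6, 70), **common),
            Archetype(name="terpenoid-like", center=(0.072, 1.439), c_range=(8, 80), **common),
            Archetype(name="lignin-monomer-like", center=(0.235, 0.936), c_range=(7, 80), **common),
            Archetype(name="humin-like", center=(0.765, 0.936), c_range=(6, 50), **common),
            Archetype(name="sugar-alcohol-like", center=(0.928, 1.439), c_range=(6, 40), **common),
        ),
    )
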