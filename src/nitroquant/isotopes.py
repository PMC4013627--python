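"""Isotope fine structure, Gaussian FWHM profiles, and minimum-resolution search.

The quantitation scheme rests on two near-isobaric doublets:

* at the reporter ions, the heavy (15N) monoisotopic peak at m/z 182.0578 and
  the 13C satellite of the light reporter at m/z 182.0641, split by
  0.00632 Da (the 13C-12C minus 15N-14N mass difference);
* at the precursor, the heavy monoisotopic peak and the light peptide's 13C
  isotope peak, split by 0.00632/z Da.

This module computes exact isotopologue fine structure from an elemental
composition, synthesises Gaussian peak profiles at a given FWHM resolution,
and finds the minimum resolution at which a doublet is separated under a
named criterion (two distinct maxima, or a valley below a fraction of the
smaller apex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    C13_C12_DELTA,
    DEFAULT_CATALOG,
    ElementCatalog,
    ElementalComposition,
    N15_N14_DELTA,
    immonium,
    MODIFICATIONS,
    monoisotopic_mass,
)

__all__ = [
    "IsotopePattern",
    "PeakShapeModel",
    "ResolutionCriterion",
    "Doublet",
    "fine_structure",
    "profile",
    "count_local_maxima",
    "min_resolution",
    "reporter_interference_fractions",
]


@dataclass(frozen=True)
class IsotopePattern:
    """Fine-structure stick pattern: (mass, abundance) sorted by mass."""

    masses: tuple[float, ...]
    abundances: tuple[float, ...]
    composition: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if list(self.masses) != sorted(self.masses):
            raise ValueError("masses must be ascending")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def base_index(self) -> int:
        return int(np.argmax(self.abundances))

    def sticks(self) -> list[tuple[float, float]]:
        return list(zip(self.masses, self.abundances))

    def abundance_near(self, mass: float, window: float = 0.002) -> float:
        """Summed abundance of sticks within +-window of *mass*."""
        return float(
            sum(a for m, a in zip(self.masses, self.abundances) if abs(m - mass) <= window)
        )


def _element_pattern(
    isotopes: Sequence, count: int, prune: float
) -> dict[float, float]:
    """Multinomial isotope pattern of ``count`` atoms of one element.

    Built iteratively one atom at a time (binary/k-ary convolution), pruning
    species below ``prune`` of the running maximum to keep the expansion small
    for large atom counts.
    """
    pattern: dict[float, float] = {0.0: 1.0}
    single = [(iso.mass, iso.abundance) for iso in isotopes]
    for _ in range(count):
        nxt: dict[float, float] = {}
        for m0, p0 in pattern.items():
            for m1, p1 in single:
                key = round(m0 + m1, 9)
                nxt[key] = nxt.get(key, 0.0) + p0 * p1
        if len(nxt) > 1:
            top = max(nxt.values())
            nxt = {m: p for m, p in nxt.items() if p >= top * prune}
        pattern = nxt
    return pattern


def fine_structure(
    composition: Mapping[str, int],
    prune_below: float = 1e-6,
    catalog: ElementCatalog = DEFAULT_CATALOG,
) -> IsotopePattern:
    """Exact isotopologue fine structure of *composition*.

    Per-element multinomial expansions are convolved across elements; species
    below ``prune_below`` of the base (most abundant) peak are dropped and the
    remainder renormalised to sum to 1.  Fixed-isotope tokens (``N15`` etc.)
    contribute a single mass at abundance 1, so labeled species keep exact
    patterns.
    """
    if not 0 <= prune_below < 1:
        raise ValueError("prune_below must be in [0, 1)")
    for token in composition:
        if token not in catalog:
            raise KeyError(f"unknown element or isotope token: {token!r}")

    # prune intermediates far below the final threshold to avoid edge loss;
    # prune_below = 0 requests the exact, unpruned expansion
    partial_prune = 0.0 if prune_below == 0 else max(prune_below * 1e-3, 1e-15)
    total: dict[float, float] = {0.0: 1.0}
    for token, count in composition.items():
        if count == 0:
            continue
        elem = _element_pattern(catalog.isotopes(token), count, partial_prune)
        nxt: dict[float, float] = {}
        for m0, p0 in total.items():
            for m1, p1 in elem.items():
                key = round(m0 + m1, 9)
                nxt[key] = nxt.get(key, 0.0) + p0 * p1
        top = max(nxt.values())
        total = {m: p for m, p in nxt.items() if p >= top * partial_prune}

    top = max(total.values())
    kept = {m: p for m, p in total.items() if p >= top * prune_below}
    norm = sum(kept.values())
    masses = sorted(kept)
    return IsotopePattern(
        masses=tuple(masses),
        abundances=tuple(kept[m] / norm for m in masses),
        composition=dict(composition),
    )


# ---------------------------------------------------------------------------
# Peak shapes and profiles
# ---------------------------------------------------------------------------

_SIGMA_PER_FWHM = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PeakShapeModel:
    """Gaussian peak shape at FWHM resolution ``R``.

    ``at_peak`` reads R at the peak's own m/z: FWHM(m) = m/R.  ``orbitrap_sqrt``
    models the Orbitrap's sqrt(m) resolution falloff with R quoted at m/z 400:
    FWHM(m) = m / (R * sqrt(400/m)).
    """

    resolution: float
    mode: str = "at_peak"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.mode not in ("at_peak", "orbitrap_sqrt"):
            raise ValueError(f"unknown shape mode {self.mode!r}")

    def fwhm(self, m: float) -> float:
        if self.mode == "at_peak":
            return m / self.resolution
        return m / (self.resolution * math.sqrt(400.0 / m))


@dataclass(frozen=True)
class ResolutionCriterion:
    """When are two peaks 'separated'?

    ``two_maxima``: the summed profile shows two distinct local maxima.
    ``valley``: additionally, the minimum between them is at most
    ``valley_fraction`` of the smaller apex.
    """

    kind: str = "two_maxima"
    valley_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in ("two_maxima", "valley"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not 0 < self.valley_fraction < 1:
            raise ValueError("valley_fraction must be in (0, 1)")


@dataclass(frozen=True)
class Doublet:
    """Two near-isobaric sticks (m/z, relative intensity)."""

    mz1: float
    i1: float
    mz2: float
    i2: float

    def __post_init__(self) -> None:
        if self.mz1 == self.mz2:
            raise ValueError("doublet m/z values must be distinct")
        if self.i1 <= 0 or self.i2 <= 0:
            raise ValueError("doublet intensities must be positive")

    def sticks(self) -> list[tuple[float, float]]:
        return sorted([(self.mz1, self.i1), (self.mz2, self.i2)])

    @property
    def spacing(self) -> float:
        return abs(self.mz2 - self.mz1)


def profile(
    sticks: IsotopePattern | Iterable[tuple[float, float]],
    shape: PeakShapeModel,
    grid_step: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum-of-Gaussians profile of a stick spectrum.

    Each stick becomes a Gaussian centred at its m/z with apex height equal to
    its intensity and FWHM from *shape*.  The grid spans the sticks +- 5 FWHM;
    the default step is min(FWHM)/50 (and a supplied step must be at most
    min(FWHM)/10).
    """
    if isinstance(sticks, IsotopePattern):
        sticks = sticks.sticks()
    sticks = list(sticks)
    if not sticks:
        raise ValueError("empty stick list")
    fwhms = [shape.fwhm(m) for m, _ in sticks]
    min_fwhm, max_fwhm = min(fwhms), max(fwhms)
    if grid_step is None:
        grid_step = min_fwhm / 50.0
    elif grid_step > min_fwhm / 10.0:
        raise ValueError(
            f"grid_step {grid_step:g} too coarse for FWHM {min_fwhm:g} (need <= FWHM/10)"
        )
    lo = min(m for m, _ in sticks) - 5.0 * max_fwhm
    hi = max(m for m, _ in sticks) + 5.0 * max_fwhm
    x = np.arange(lo, hi + grid_step, grid_step)
    y = np.zeros_like(x)
    for (m, h), fwhm in zip(sticks, fwhms):
        sigma = fwhm * _SIGMA_PER_FWHM
        y += h * np.exp(-0.5 * ((x - m) / sigma) ** 2)
    return x, y


def count_local_maxima(y: np.ndarray) -> int:
    """Number of interior local maxima (strict rise, non-strict fall)."""
    y = np.asarray(y)
    if y.size < 3:
        return 0
    return int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])))


def _separated(
    doublet: Doublet, resolution: float, criterion: ResolutionCriterion, mode: str
) -> bool:
    shape = PeakShapeModel(resolution, mode)
    x, y = profile(doublet.sticks(), shape)
    idx = np.where((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
    if len(idx) < 2:
        return False
    if criterion.kind == "two_maxima":
        return True
    i1, i2 = idx[0], idx[-1]
    valley = float(y[i1 : i2 + 1].min())
    smaller_apex = float(min(y[i1], y[i2]))
    return valley <= criterion.valley_fraction * smaller_apex


def min_resolution(
    doublet: Doublet,
    criterion: ResolutionCriterion = ResolutionCriterion(),
    mode: str = "at_peak",
    grid: Sequence[float] | None = None,
    r_max: float = 1e7,
) -> float:
    """Smallest FWHM resolution at which *doublet* satisfies *criterion*.

    With ``grid``, evaluates each listed resolution and returns the smallest
    satisfying one.  Otherwise bisects on log R to 3 significant figures.
    Raises if the criterion is not reached by ``r_max`` (non-separable input).
    """
    if grid is not None:
        for r in sorted(grid):
            if _separated(doublet, r, criterion, mode):
                return float(r)
        raise ValueError(
            f"criterion not satisfied at any grid resolution up to {max(grid):g}"
        )

    r_lo = 100.0
    r_hi = r_lo
    while not _separated(doublet, r_hi, criterion, mode):
        r_hi *= 2.0
        if r_hi > r_max:
            raise ValueError(
                f"doublet not separable under criterion within R <= {r_max:g}"
            )
    if r_hi == r_lo:
        return r_hi
    r_lo = r_hi / 2.0
    while r_hi / r_lo > 1.0 + 1e-3:
        mid = math.sqrt(r_lo * r_hi)
        if _separated(doublet, mid, criterion, mode):
            r_hi = mid
        else:
            r_lo = mid
    return r_hi


# ---------------------------------------------------------------------------
# Reporter-channel interference
# ---------------------------------------------------------------------------


def reporter_interference_fractions(
    catalog: ElementCatalog = DEFAULT_CATALOG,
) -> tuple[float, float, float]:
    """Isotopic interference of the light reporter on the heavy channel.

    Returns ``(f15N, f13C, delta13C15N)``:

    * ``f15N`` — height of the light reporter's single-15N isotopologue
      relative to its monoisotopic peak.  This species is exactly isobaric
      with the heavy reporter and is unresolvable; it is what the n15 ratio
      correction subtracts.
    * ``f13C`` — height of the single-13C isotopologue relative to
      monoisotopic.  It sits ``delta13C15N`` = 0.00632 Da above the heavy
      reporter and is resolved away at sufficient FWHM resolution.
    """
    light = immonium("Y", [MODIFICATIONS["nitro_light"]])
    # cation composition: neutral imine + one H (the charge-carrying proton)
    cation = light.composition + ElementalComposition(H=1)
    pattern = fine_structure(cation, prune_below=1e-9, catalog=catalog)
    mono = monoisotopic_mass(cation, catalog)
    base = pattern.abundance_near(mono, window=0.0005)
    f15n = pattern.abundance_near(mono + N15_N14_DELTA, window=0.0005) / base
    f13c = pattern.abundance_near(mono + C13_C12_DELTA, window=0.0005) / base
    return f15n, f13c, C13_C12_DELTA - N15_N14_DELTA
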