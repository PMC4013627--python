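"""Elemental compositions, monoisotopic masses and ion m/z arithmetic.

Everything downstream — isotope fine structure, reporter-ion targets, the
synthetic DDA generator — is built on the small algebra defined here:
integer elemental compositions, a pinned isotope catalog, peptide /
fragment / immonium composition bookkeeping, and the proton-adduct m/z
convention ``m/z = (M + z * m_p) / z``.

Modifications are carried as composition add/remove pairs rather than bare
mass deltas so that isotope patterns of modified species are exact.  The
nitration pair is built in: ``nitro_light`` adds N + 2O and removes one H
from tyrosine; ``nitro_heavy`` does the same with a fixed-``15N`` token, so
the heavy-light spacing is the exact 15N-14N mass difference (0.9970349 Da).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "Isotope",
    "ElementCatalog",
    "DEFAULT_CATALOG",
    "ElementalComposition",
    "Modification",
    "MODIFICATIONS",
    "Peptide",
    "IonSpecies",
    "monoisotopic_mass",
    "peptide_composition",
    "mz",
    "immonium",
    "fragment_ions",
    "NITRO_LIGHT_DELTA",
    "NITRO_HEAVY_DELTA",
    "N15_N14_DELTA",
    "C13_C12_DELTA",
    "LIGHT_REPORTER_MZ",
    "HEAVY_REPORTER_MZ",
]

#: Proton mass used for all charge arithmetic, Da.  The electron mass is not
#: tracked separately; printed reporter and precursor m/z values match this
#: convention to four decimals.
PROTON_MASS = 1.0072765


@dataclass(frozen=True)
class Isotope:
    """One isotope of an element: nominal mass number, exact mass, abundance."""

    nominal: int
    mass: float
    abundance: float


class ElementCatalog:
    """Pinned isotope masses and natural abundances.

    Values are from the standard IUPAC/NIST atomic-weight compilation and are
    kept in-code so results are stable and require no downloads.  Fixed-isotope
    pseudo-element tokens (``N15`` etc.) carry a single isotope at abundance 1
    and are how stable-isotope labels enter composition arithmetic.
    """

    def __init__(
        self,
        elements: Mapping[str, list[Isotope]],
        fixed: Mapping[str, float],
    ) -> None:
        for sym, isos in elements.items():
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {sym} sum to {total}, not 1")
            masses = [i.mass for i in isos]
            if any(m <= 0 for m in masses) or masses != sorted(masses):
                raise ValueError(f"isotope masses for {sym} must be positive and increasing")
        self.elements = {s: list(isos) for s, isos in elements.items()}
        self.fixed = dict(fixed)

    def monoisotopic(self, token: str) -> float:
        """Mass of the lightest isotope of *token* (fixed tokens: their mass)."""
        if token in self.fixed:
            return self.fixed[token]
        if token in self.elements:
            return self.elements[token][0].mass
        raise KeyError(f"unknown element or isotope token: {token!r}")

    def isotopes(self, token: str) -> list[Isotope]:
        if token in self.fixed:
            return [Isotope(0, self.fixed[token], 1.0)]
        if token in self.elements:
            return self.elements[token]
        raise KeyError(f"unknown element or isotope token: {token!r}")

    def __contains__(self, token: str) -> bool:
        return token in self.fixed or token in self.elements


DEFAULT_CATALOG = ElementCatalog(
    elements={
        "H": [Isotope(1, 1.0078250319, 0.999885), Isotope(2, 2.0141017780, 0.000115)],
        "C": [Isotope(12, 12.0, 0.9893), Isotope(13, 13.0033548378, 0.0107)],
        "N": [Isotope(14, 14.0030740052, 0.996358), Isotope(15, 15.0001088984, 0.003642)],
        "O": [
            Isotope(16, 15.9949146221, 0.99757),
            Isotope(17, 16.9991315, 0.00038),
            Isotope(18, 17.9991604, 0.00205),
        ],
        "S": [
            Isotope(32, 31.97207069, 0.9493),
            Isotope(33, 32.97145850, 0.0076),
            Isotope(34, 33.96786683, 0.0429),
            Isotope(36, 35.96708088, 0.0002),
        ],
    },
    fixed={
        "N15": 15.0001088984,
        "C13": 13.0033548378,
        "H2": 2.0141017780,
        "O18": 17.9991604,
    },
)

#: 15N - 14N exact mass difference, Da (the heavy-light nitro spacing).
N15_N14_DELTA = DEFAULT_CATALOG.fixed["N15"] - DEFAULT_CATALOG.elements["N"][0].mass
#: 13C - 12C exact mass difference, Da.
C13_C12_DELTA = DEFAULT_CATALOG.fixed["C13"] - DEFAULT_CATALOG.elements["C"][0].mass

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?\d*(?<=[A-Za-z])\d*|\d+)")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?\d*)|(\d+)")


class ElementalComposition(dict):
    """Map of element-or-fixed-isotope token to a non-negative integer count.

    Supports ``+`` and ``-`` element-wise; subtraction that would drive any
    count negative raises.  Zero counts are dropped.
    """

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kwargs:
            for token, n in src.items():
                merged[token] = merged.get(token, 0) + int(n)
        for token, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for {token}: {n}")
        super().__init__({t: n for t, n in merged.items() if n != 0})

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula like ``C8H9N2O3`` or ``C2H3N15O``.

        A two-character token that matches a fixed-isotope label (``N15``) is
        read as that label, so write natural nitrogen-15-free formulas without
        a trailing digit ambiguity: ``N15`` always means the heavy label.
        """
        counts: dict[str, int] = {}
        pos = 0
        pat = re.compile(r"(N15|C13|H2(?![0-9])|O18|[A-Z][a-z]?)(\d*)")
        while pos < len(formula):
            m = pat.match(formula, pos)
            if not m:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            token, digits = m.group(1), m.group(2)
            counts[token] = counts.get(token, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for t, n in other.items():
            out[t] = out.get(t, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for t, n in other.items():
            out[t] = out.get(t, 0) - n
            if out[t] < 0:
                raise ValueError(
                    f"composition subtraction drives {t} negative ({out[t]})"
                )
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({t: n * k for t, n in self.items()})

    __rmul__ = __mul__


def monoisotopic_mass(
    composition: Mapping[str, int], catalog: ElementCatalog = DEFAULT_CATALOG
) -> float:
    """Monoisotopic mass in Da: count times lightest-isotope mass per token."""
    total = 0.0
    for token, n in composition.items():
        total += n * catalog.monoisotopic(token)
    return total


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of the ``[M + zH]^z+`` ion."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# Residues and modifications
# ---------------------------------------------------------------------------

_C = ElementalComposition

#: Residue (dehydrated amino-acid) compositions of the twenty standard
#: residues; a peptide is the residue sum plus one water.
RESIDUES: dict[str, ElementalComposition] = {
    "G": _C(C=2, H=3, N=1, O=1),
    "A": _C(C=3, H=5, N=1, O=1),
    "S": _C(C=3, H=5, N=1, O=2),
    "P": _C(C=5, H=7, N=1, O=1),
    "V": _C(C=5, H=9, N=1, O=1),
    "T": _C(C=4, H=7, N=1, O=2),
    "C": _C(C=3, H=5, N=1, O=1, S=1),
    "L": _C(C=6, H=11, N=1, O=1),
    "I": _C(C=6, H=11, N=1, O=1),
    "N": _C(C=4, H=6, N=2, O=2),
    "D": _C(C=4, H=5, N=1, O=3),
    "Q": _C(C=5, H=8, N=2, O=2),
    "K": _C(C=6, H=12, N=2, O=1),
    "E": _C(C=5, H=7, N=1, O=3),
    "M": _C(C=5, H=9, N=1, O=1, S=1),
    "H": _C(C=6, H=7, N=3, O=1),
    "F": _C(C=9, H=9, N=1, O=1),
    "R": _C(C=6, H=12, N=4, O=1),
    "Y": _C(C=9, H=9, N=1, O=2),
    "W": _C(C=11, H=10, N=2, O=1),
}

WATER = _C(H=2, O=1)
CO = _C(C=1, O=1)


@dataclass(frozen=True)
class Modification:
    """A residue modification as a composition add/remove pair."""

    name: str
    add: ElementalComposition
    remove: ElementalComposition
    targets: frozenset[str]

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.add) - monoisotopic_mass(self.remove)

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


MODIFICATIONS: dict[str, Modification] = {
    "nitro_light": Modification(
        "nitro_light", _C(N=1, O=2), _C(H=1), frozenset("Y")
    ),
    "nitro_heavy": Modification(
        "nitro_heavy", _C(N15=1, O=2), _C(H=1), frozenset("Y")
    ),
    "cam": Modification(  # carbamidomethyl (iodoacetamide alkylation)
        "cam", _C(C=2, H=3, N=1, O=1), _C(), frozenset("C")
    ),
    "ox": Modification("ox", _C(O=1), _C(), frozenset("MW")),
}

NITRO_LIGHT_DELTA = MODIFICATIONS["nitro_light"].delta_mass
NITRO_HEAVY_DELTA = MODIFICATIONS["nitro_heavy"].delta_mass


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peptide:
    """A peptide: one-letter sequence plus positioned modifications.

    The text notation accepted by :meth:`parse` is the sequence followed by
    whitespace-separated ``pos:modname`` items with 1-based positions, e.g.
    ``"YLYEIAR 1:nitro_heavy"`` or ``"YICDNQDTISSK 1:nitro_light 3:cam"``.
    """

    sequence: str
    modifications: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        for aa in self.sequence:
            if aa not in RESIDUES:
                raise ValueError(f"unknown residue {aa!r} in {self.sequence!r}")
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if not mod.applies_to(residue):
                raise ValueError(
                    f"{mod.name} does not apply to {residue} at position {pos}"
                )

    @classmethod
    def parse(cls, text: str) -> "Peptide":
        parts = text.split()
        if not parts:
            raise ValueError("empty peptide notation")
        seq = parts[0]
        mods = []
        for i, item in enumerate(parts[1:], start=1):
            try:
                pos_str, name = item.split(":", 1)
                pos = int(pos_str)
            except ValueError as exc:
                raise ValueError(
                    f"bad modification token {item!r} (item {i}): expected pos:modname"
                ) from exc
            if name not in MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r} (item {i})")
            mods.append((pos, MODIFICATIONS[name]))
        return cls(seq, tuple(mods))

    def notation(self) -> str:
        items = [self.sequence]
        items += [f"{pos}:{mod.name}" for pos, mod in self.modifications]
        return " ".join(items)

    def composition(self) -> ElementalComposition:
        return peptide_composition(self)

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.composition())

    def mz(self, charge: int) -> float:
        return mz(self.neutral_mass(), charge)

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_composition(peptide: Peptide) -> ElementalComposition:
    """Neutral composition: residue sum + H2O + modification deltas."""
    comp = ElementalComposition(WATER)
    for aa in peptide.sequence:
        comp = comp + RESIDUES[aa]
    for _pos, mod in peptide.modifications:
        comp = (comp + mod.add) - mod.remove
    return comp


# ---------------------------------------------------------------------------
# Ion species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """An ion: neutral-equivalent composition, charge and series kind.

    ``composition`` is the neutral composition whose protonated form is the
    observed ion, so ``mz = (M + z m_p)/z`` throughout (b ions are the residue
    sum, y ions residue sum + H2O, a = b - CO, immonium = residue - CO).
    """

    composition: ElementalComposition
    charge: int
    kind: str  # precursor | b | y | a | immonium
    label: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def mz(self) -> float:
        return mz(self.neutral_mass, self.charge)


def immonium(residue: str, mods: Iterable[Modification] = ()) -> IonSpecies:
    """The immonium ion of *residue* with *mods* applied (singly charged).

    The immonium ion ``H2N+=CH-R`` is the residue composition minus CO; its
    m/z is the neutral imine mass plus one proton.
    """
    if residue not in RESIDUES:
        raise ValueError(f"unknown residue {residue!r}")
    comp = RESIDUES[residue] - CO
    for mod in mods:
        if not mod.applies_to(residue):
            raise ValueError(f"{mod.name} does not apply to residue {residue}")
        comp = (comp + mod.add) - mod.remove
    return IonSpecies(comp, 1, "immonium", label=f"imm({residue})")


#: The light (14N) nitrotyrosine immonium/a1 reporter ion m/z.
LIGHT_REPORTER_MZ = immonium("Y", [MODIFICATIONS["nitro_light"]]).mz
#: The heavy (15N) nitrotyrosine reporter ion m/z (internal-standard channel).
HEAVY_REPORTER_MZ = immonium("Y", [MODIFICATIONS["nitro_heavy"]]).mz


def fragment_ions(
    peptide: Peptide,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[IonSpecies]:
    """All b/y/a fragments of *peptide* at charges 1..max_charge.

    Modification deltas travel with the fragment that contains the modified
    position, so nitro-containing fragments of a light/heavy pair differ by
    exactly 0.9970349/z while the others coincide.
    """
    series = set(series)
    unknown = series - {"a", "b", "y"}
    if unknown:
        raise ValueError(f"unknown fragment series: {sorted(unknown)}")
    if len(peptide) == 0:
        raise ValueError("empty peptide")
    n = len(peptide)
    mods_at = {pos: mod for pos, mod in peptide.modifications}

    def span_comp(lo: int, hi: int) -> ElementalComposition:
        # residues lo..hi inclusive, 1-based, with their modifications
        comp = ElementalComposition()
        for pos in range(lo, hi + 1):
            comp = comp + RESIDUES[peptide.sequence[pos - 1]]
            if pos in mods_at:
                comp = (comp + mods_at[pos].add) - mods_at[pos].remove
        return comp

    out: list[IonSpecies] = []
    for i in range(1, n):  # fragment lengths 1..n-1
        prefix = span_comp(1, i)
        suffix = span_comp(n - i + 1, n) + WATER
        for z in range(1, max_charge + 1):
            if "b" in series:
                out.append(IonSpecies(prefix, z, "b", label=f"b{i}" + ("" if z == 1 else f"^{z}")))
            if "a" in series:
                out.append(IonSpecies(prefix - CO, z, "a", label=f"a{i}" + ("" if z == 1 else f"^{z}")))
            if "y" in series:
                out.append(IonSpecies(suffix, z, "y", label=f"y{i}" + ("" if z == 1 else f"^{z}")))
    return out
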