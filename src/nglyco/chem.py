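"""Composition algebra for linkage-specifically derivatized plasma N-glycans.

A released plasma N-glycan is described here by counts of five residue
letters:

======  =============================================  =================
letter  residue                                        elemental formula
======  =============================================  =================
H       hexose                                         C6H10O5
N       N-acetylhexosamine                             C8H13NO5
F       deoxyhexose (fucose)                           C6H10O4
L       lactonized alpha2,3-linked NeuAc               C11H15NO7
E       ethyl-esterified alpha2,6-linked NeuAc         C13H21NO8
======  =============================================  =================

The two sialic-acid letters encode the chemical derivatization that makes
the linkage isomers mass-distinguishable: lactonization removes one water
from the N-acetylneuraminic-acid residue (C11H17NO8), ethyl esterification
adds C2H4.  A neutral glycan is the sum of its residues plus one terminal
water; the detected ion is the sodium adduct [M+Na]+.

This module provides parsing of composition codes ("H5N4F1L1E1"),
monoisotopic masses, molecular formulas, isotopic envelopes (by polynomial
convolution of per-element isotope distributions) and rule-based inference
of the structural features (class, antennae, galactoses, sialylation,
fucosylation, bisection) that the derived-trait engine consumes.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementCounts",
    "GlycanComposition",
    "StructuralFeatures",
    "CompositionParseError",
    "StructureError",
    "SialylationWarning",
    "parse_composition",
    "molecular_formula",
    "monoisotopic_mass",
    "isotopic_distribution",
    "min_isotopologues",
    "classify_structure",
    "enumerate_compositions",
    "ISOTOPE_SPACING",
]

# CODATA/IUPAC monoisotopic atomic masses (Da)
MONO_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}
NA_MASS = 22.9897692809
ELECTRON_MASS = 0.00054857990907

#: m/z spacing between successive isotopologue peaks (13C - 12C)
ISOTOPE_SPACING = 1.0033548378

# Natural isotope abundances, index = number of extra neutron-mass units.
ISOTOPES = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
}


class CompositionParseError(ValueError):
    """Raised when a composition code does not conform to the grammar."""


class StructureError(ValueError):
    """Raised when a composition cannot be a releasable N-glycan."""


class SialylationWarning(UserWarning):
    """Sialic-acid count exceeds the available galactoses of a complex glycan."""


@dataclass(frozen=True)
class ElementCounts:
    """Atom counts (C, H, N, O) of a neutral molecule."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.n, self.o) < 0:
            raise ValueError("negative atom count")

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(self.c + other.c, self.h + other.h,
                             self.n + other.n, self.o + other.o)

    def __mul__(self, k: int) -> "ElementCounts":
        return ElementCounts(self.c * k, self.h * k, self.n * k, self.o * k)

    __rmul__ = __mul__

    def as_dict(self) -> dict:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o}

    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return (self.c * MONO_MASS["C"] + self.h * MONO_MASS["H"]
                + self.n * MONO_MASS["N"] + self.o * MONO_MASS["O"])

    def formula(self) -> str:
        """Hill-ish formula string, e.g. ``C34H58N2O26``."""
        parts = []
        for sym, cnt in self.as_dict().items():
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


RESIDUE_FORMULAS = {
    "H": ElementCounts(6, 10, 0, 5),
    "N": ElementCounts(8, 13, 1, 5),
    "F": ElementCounts(6, 10, 0, 4),
    "L": ElementCounts(11, 15, 1, 7),
    "E": ElementCounts(13, 21, 1, 8),
}
WATER = ElementCounts(0, 2, 0, 1)

RESIDUE_ORDER = "HNFLE"


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue counts of one glycan composition.

    Counts are nonnegative; a releasable N-glycan additionally requires
    n >= 2 and h >= 3 (the chitobiose + trimannosyl core), which is
    enforced by :func:`classify_structure`, not by the constructor.
    """

    h: int = 0
    n: int = 0
    f: int = 0
    l: int = 0
    e: int = 0

    def __post_init__(self) -> None:
        if min(self.h, self.n, self.f, self.l, self.e) < 0:
            raise ValueError("negative residue count")

    def counts(self) -> dict:
        return {"H": self.h, "N": self.n, "F": self.f, "L": self.l, "E": self.e}

    @property
    def code(self) -> str:
        """Canonical composition code with letters in H, N, F, L, E order."""
        return "".join(f"{sym}{cnt}" for sym, cnt in self.counts().items() if cnt > 0)

    def merge(self, other: "GlycanComposition") -> "GlycanComposition":
        """Residue-wise sum (glycosidic condensation of two glycans)."""
        return GlycanComposition(self.h + other.h, self.n + other.n,
                                 self.f + other.f, self.l + other.l,
                                 self.e + other.e)


_TOKEN_RE = re.compile(r"([A-Za-z])(\d+)")


def parse_composition(code: str) -> GlycanComposition:
    """Parse a composition code such as ``"H5N4F1L1E1"``.

    Omitted letters mean a count of zero.  Unknown letters, duplicated
    letters, malformed tokens and empty codes raise
    :class:`CompositionParseError` naming the offending token.
    """
    if not code:
        raise CompositionParseError("empty composition code")
    counts: dict = {}
    pos = 0
    while pos < len(code):
        m = _TOKEN_RE.match(code, pos)
        if m is None:
            raise CompositionParseError(
                f"malformed token at position {pos}: {code[pos:]!r}")
        letter, num = m.group(1), int(m.group(2))
        if letter not in RESIDUE_ORDER:
            raise CompositionParseError(f"unknown residue letter {letter!r} in {code!r}")
        if letter in counts:
            raise CompositionParseError(f"duplicate residue letter {letter!r} in {code!r}")
        counts[letter] = num
        pos = m.end()
    return GlycanComposition(h=counts.get("H", 0), n=counts.get("N", 0),
                             f=counts.get("F", 0), l=counts.get("L", 0),
                             e=counts.get("E", 0))


def molecular_formula(comp: GlycanComposition) -> ElementCounts:
    """Elemental formula of the neutral derivatized glycan (residues + H2O)."""
    total = WATER
    for sym, cnt in comp.counts().items():
        total = total + RESIDUE_FORMULAS[sym] * cnt
    return total


def monoisotopic_mass(comp: GlycanComposition, adduct: str = "sodiated") -> float:
    """Monoisotopic mass in Da of the neutral glycan or its [M+Na]+ ion."""
    m = molecular_formula(comp).mass()
    if adduct == "neutral":
        return m
    if adduct == "sodiated":
        return m + NA_MASS - ELECTRON_MASS
    raise ValueError(f"unknown adduct {adduct!r}; use 'neutral' or 'sodiated'")


def _power_truncated(single: np.ndarray, n: int, k: int) -> np.ndarray:
    """Distribution of the sum of ``n`` iid atoms, truncated to ``k`` shifts.

    Exponentiation by squaring of the single-atom isotopologue polynomial.
    """
    out = np.zeros(k)
    out[0] = 1.0
    base = np.zeros(k)
    base[: min(k, single.size)] = single[:k]
    while n:
        if n & 1:
            out = np.convolve(out, base)[:k]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:k]
    return out


def _raw_distribution(formula: ElementCounts, k: int) -> np.ndarray:
    dist = np.zeros(k)
    dist[0] = 1.0
    for sym, cnt in formula.as_dict().items():
        if cnt:
            dist = np.convolve(dist, _power_truncated(np.asarray(ISOTOPES[sym]), cnt, k))[:k]
    return dist


def isotopic_distribution(formula: ElementCounts, k: int) -> np.ndarray:
    """Relative abundances of the M+0 ... M+(k-1) isotopologues.

    Computed by polynomial convolution of per-element isotope
    distributions and normalized so the returned k values sum to one.
    The sodium of the [M+Na]+ adduct is monoisotopic and does not alter
    the envelope.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = _raw_distribution(formula, k)
    return dist / dist.sum()


def min_isotopologues(formula: ElementCounts, coverage: float = 0.95,
                      kmax: int = 12) -> int:
    """Smallest number of isotopologues whose cumulative abundance >= coverage."""
    dist = _raw_distribution(formula, kmax)
    cum = np.cumsum(dist)
    idx = np.searchsorted(cum, coverage)
    return int(min(idx + 1, kmax))


def isotopic_distribution_enumerated(formula: ElementCounts, k: int) -> np.ndarray:
    """Exhaustive-enumeration isotopologue distribution for tiny formulas.

    Walks every assignment of an isotope to every atom; exponential cost,
    intended only as an independent oracle for formulas with a handful of
    atoms.
    """
    atoms = []
    for sym, cnt in formula.as_dict().items():
        atoms.extend([ISOTOPES[sym]] * cnt)
    dist = np.zeros(k)
    for assignment in itertools.product(*(range(len(a)) for a in atoms)):
        shift = sum(assignment)
        if shift < k:
            p = 1.0
            for a, i in zip(atoms, assignment):
                p *= a[i]
            dist[shift] += p
    return dist / dist.sum()


@dataclass(frozen=True)
class StructuralFeatures:
    """Structural features of one composition used by the trait engine.

    ``antennae`` is defined only for the complex class (``None`` otherwise);
    ``galactoses`` counts antenna galactoses for complex glycans (the
    trimannosyl-core hexoses are excluded).
    """

    glycan_class: str            # "high-mannose" | "hybrid" | "complex"
    antennae: int | None
    galactoses: int
    l: int
    e: int
    fucosylated: bool
    bisected: bool

    @property
    def sialic_total(self) -> int:
        return self.l + self.e


def classify_structure(comp: GlycanComposition, *,
                       glycan_class: str | None = None,
                       bisected: bool = False) -> StructuralFeatures:
    """Infer structural features from a composition.

    Default rules (overridable per composition via the registry annotation
    columns ``class`` and ``bisected``):

    * high-mannose  iff n == 2 and f + l + e == 0;
    * hybrid        iff n == 3 and h >= 5;
    * otherwise complex, with antennae = min(n - 2, 4)
      (n - 3 when annotated bisected) and
      galactoses = max(0, min(h - 3, antennae)).

    Compositions with n < 2 or h < 3, or whose complex antenna count falls
    below 2, raise :class:`StructureError`.  A complex glycan whose sialic
    acids exceed its galactoses triggers a :class:`SialylationWarning`;
    the counts are retained.
    """
    if comp.n < 2 or comp.h < 3:
        raise StructureError(f"{comp.code or comp!r}: not a releasable N-glycan "
                             f"(requires n >= 2 and h >= 3)")
    if glycan_class is None:
        if comp.n == 2 and comp.f + comp.l + comp.e == 0:
            glycan_class = "high-mannose"
        elif comp.n == 3 and comp.h >= 5:
            glycan_class = "hybrid"
        else:
            glycan_class = "complex"
    if glycan_class == "high-mannose":
        return StructuralFeatures("high-mannose", None, 0, comp.l, comp.e,
                                  comp.f >= 1, False)
    if glycan_class == "hybrid":
        gal = min(max(comp.h - 4, 0), 1)
        return StructuralFeatures("hybrid", None, gal, comp.l, comp.e,
                                  comp.f >= 1, bisected)
    if glycan_class != "complex":
        raise StructureError(f"unknown glycan class {glycan_class!r}")
    antennae = comp.n - 3 if bisected else comp.n - 2
    antennae = min(antennae, 4)
    if antennae < 2:
        raise StructureError(f"{comp.code}: complex glycan with fewer than two antennae")
    galactoses = max(0, min(comp.h - 3, antennae))
    if comp.l + comp.e > galactoses:
        warnings.warn(
            f"{comp.code}: sialic-acid count {comp.l + comp.e} exceeds "
            f"galactoses {galactoses}", SialylationWarning, stacklevel=2)
    return StructuralFeatures("complex", antennae, galactoses, comp.l, comp.e,
                              comp.f >= 1, bisected)


def enumerate_compositions(h_max: int = 9, n_max: int = 7, f_max: int = 3,
                           sialic_max: int = 4):
    """Yield all chemically plausible compositions within the given bounds.

    Used as the search space of composition discovery.  Plausibility rules:
    the core constraint (h >= 3, n >= 2); for complex glycans sialic acids
    limited by galactoses and hexoses limited to core + antennae; hybrids
    carry at most one fucose and one sialic acid; high-mannose structures
    carry neither.
    """
    for h in range(3, h_max + 1):
        for n in range(2, n_max + 1):
            for f in range(0, f_max + 1):
                for l in range(0, sialic_max + 1):
                    for e in range(0, sialic_max + 1 - l):
                        comp = GlycanComposition(h, n, f, l, e)
                        try:
                            with warnings.catch_warnings():
                                warnings.simplefilter("error", SialylationWarning)
                                feats = classify_structure(comp)
                        except (StructureError, SialylationWarning):
                            continue
                        if feats.glycan_class == "hybrid" and (f > 1 or l + e > 1):
                            continue
                        if feats.glycan_class == "complex" and h > 3 + feats.antennae:
                            continue
                        yield comp
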