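"""Derived glycosylation trait grammar and computation.

A derived trait summarizes one structural feature over a subset of the
directly detected glycan compositions.  Trait names follow the field's
compact convention: the *last* letter is the subject of the calculation
and the preceding letters select the glycan subset.  ``A3FS`` is therefore
the sialylation (S) within triantennary (A3) fucosylated (F) species.

Grammar accepted by :func:`parse_trait_name`::

    name    := "TM" | "THy" | "TC" | [scope] [antenna] token*
    scope   := "T"            (denominator: all compositions)
             | "C"            (denominator: complex-type compositions)
    antenna := "A2" | "A3" | "A4"
    token   := "F" | "F0" | "S" | "S0" | "B" | "B0"
             | "L" | "L0" | "E" | "E0" | "G"

Semantics of the final token:

* ``G``            -> galactosylation per antenna of the subset;
* ``S``/``L``/``E``-> sialylation per antenna, or per galactose when the
                      immediately preceding token is ``G`` (``A4GE``);
* ``F``/``B``      -> abundance fraction of fucosylated / bisected species
                      within the subset;
* with a scope prefix and a terminal subset token (``CA4``, ``TA2FS0``),
  the trait is the abundance fraction of the subset within the scope.

Zero-suffixed tokens select absence (``F0`` = non-fucosylated, ``S0`` =
non-sialylated); bare tokens in non-terminal position select presence.
``S`` at the count level is always ``L + E``.

Trait values are ratios of abundance-weighted sums, so they are invariant
to global rescaling of the abundance vector; a trait whose denominator
subset has zero abundance in a sample is *undefined* (NaN), not an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .chem import StructuralFeatures
from .registry import CompositionRegistry, DEFAULT_TRAIT_NAMES

__all__ = ["TraitKind", "TraitDefinition", "TraitGrammarError",
           "parse_trait_name", "compute_trait", "compute_all",
           "trait_weights", "load_trait_registry", "DEFAULT_TRAIT_NAMES"]


class TraitGrammarError(ValueError):
    """Raised when a trait name does not conform to the grammar."""


class TraitKind(Enum):
    FRACTION = "abundance-fraction"
    PRESENCE = "presence-fraction"
    ANTENNA_DEGREE = "per-antenna-degree"
    GALACTOSE_DEGREE = "per-galactose-degree"


_SUBJECT_COUNTS = {
    "G": lambda ft: ft.galactoses,
    "S": lambda ft: ft.l + ft.e,
    "L": lambda ft: ft.l,
    "E": lambda ft: ft.e,
}

_ANT_RE = re.compile(r"A([234])")
_TOKEN_RE = re.compile(r"(F0|S0|B0|L0|E0|G|F|S|B|L|E)")


@dataclass(frozen=True)
class TraitDefinition:
    """Formal definition of one derived trait.

    ``subset`` predicates are conjunctive; ``None`` means unconstrained.
    """

    name: str
    kind: TraitKind
    subject: str | None = None          # terminal feature letter
    scope: str | None = None            # "T" (all) or "C" (complex) for fractions
    glycan_class: str | None = "complex"
    antennae: int | None = None
    fucosylated: bool | None = None
    sialylated: bool | None = None
    bisected: bool | None = None
    l_present: bool | None = None
    e_present: bool | None = None
    galactosylated: bool | None = None

    def in_subset(self, ft: StructuralFeatures) -> bool:
        if self.glycan_class is not None and ft.glycan_class != self.glycan_class:
            return False
        if self.antennae is not None and ft.antennae != self.antennae:
            return False
        if self.fucosylated is not None and ft.fucosylated != self.fucosylated:
            return False
        if self.sialylated is not None and (ft.sialic_total >= 1) != self.sialylated:
            return False
        if self.bisected is not None and ft.bisected != self.bisected:
            return False
        if self.l_present is not None and (ft.l >= 1) != self.l_present:
            return False
        if self.e_present is not None and (ft.e >= 1) != self.e_present:
            return False
        if self.galactosylated is not None and (ft.galactoses >= 1) != self.galactosylated:
            return False
        return True

    def weights(self, ft: StructuralFeatures) -> tuple[float, float]:
        """(numerator, denominator) abundance weights for one composition."""
        if self.kind is TraitKind.FRACTION:
            if self.scope == "T":
                in_scope = True
            else:  # "C"
                in_scope = ft.glycan_class == "complex"
            num = 1.0 if (in_scope and self.in_subset(ft)) else 0.0
            den = 1.0 if in_scope else 0.0
            return num, den
        if not self.in_subset(ft):
            return 0.0, 0.0
        if self.kind is TraitKind.PRESENCE:
            flag = ft.fucosylated if self.subject == "F" else ft.bisected
            return (1.0 if flag else 0.0), 1.0
        count = float(_SUBJECT_COUNTS[self.subject](ft))
        if self.kind is TraitKind.ANTENNA_DEGREE:
            return count, float(ft.antennae or 0)
        # per-galactose degree
        return count, float(ft.galactoses)


_CLASS_FRACTIONS = {
    "TM": "high-mannose",
    "THy": "hybrid",
    "TC": "complex",
}

_FILTER_FIELDS = {
    "F": ("fucosylated", True), "F0": ("fucosylated", False),
    "S": ("sialylated", True), "S0": ("sialylated", False),
    "B": ("bisected", True), "B0": ("bisected", False),
    "L": ("l_present", True), "L0": ("l_present", False),
    "E": ("e_present", True), "E0": ("e_present", False),
    "G": ("galactosylated", True),
}


def _tokenize(body: str, name: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None:
            raise TraitGrammarError(
                f"{name!r}: unparseable at position {len(name) - len(body) + pos} "
                f"({body[pos:]!r})")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _apply_filters(name: str, tokens: list[str], filters: dict) -> None:
    for tok in tokens:
        fld, val = _FILTER_FIELDS[tok]
        if fld in filters and filters[fld] != val:
            raise TraitGrammarError(f"{name!r}: conflicting modifier {tok!r}")
        filters[fld] = val


def parse_trait_name(name: str) -> TraitDefinition:
    """Parse a derived-trait name into a formal :class:`TraitDefinition`."""
    if not name:
        raise TraitGrammarError("empty trait name")
    if name in _CLASS_FRACTIONS:
        return TraitDefinition(name=name, kind=TraitKind.FRACTION, scope="T",
                               glycan_class=_CLASS_FRACTIONS[name])
    scope = None
    body = name
    if body[0] in "TC":
        scope, body = body[0], body[1:]
        if not body:
            raise TraitGrammarError(f"{name!r}: scope prefix without a body")
    antennae = None
    m = _ANT_RE.match(body)
    if m:
        antennae = int(m.group(1))
        body = body[m.end():]
    tokens = _tokenize(body, name)
    filters: dict = {}

    if scope is not None:
        terminal_degree = bool(tokens) and tokens[-1] in ("G", "S", "L", "E")
        if not terminal_degree:
            # abundance fraction of the subset within the scope
            _apply_filters(name, tokens, filters)
            return TraitDefinition(name=name, kind=TraitKind.FRACTION,
                                   scope=scope, glycan_class="complex",
                                   antennae=antennae, **filters)
        subject = tokens.pop()
        if subject != "G" and tokens and tokens[-1] == "G":
            kind = TraitKind.GALACTOSE_DEGREE
            tokens.pop()
        else:
            kind = TraitKind.ANTENNA_DEGREE
        _apply_filters(name, tokens, filters)
        return TraitDefinition(name=name, kind=kind, subject=subject,
                               glycan_class="complex", antennae=antennae,
                               **filters)

    if not tokens:
        if antennae is None:
            raise TraitGrammarError(f"{name!r}: no subject letter")
        raise TraitGrammarError(
            f"{name!r}: bare antenna subset needs a scope prefix (e.g. C{name})")
    subject = tokens.pop()
    if subject.endswith("0"):
        raise TraitGrammarError(
            f"{name!r}: terminal {subject!r} selects absence; absence subsets "
            f"need a scope prefix (e.g. T{name})")
    if subject in ("F", "B"):
        kind = TraitKind.PRESENCE
    elif subject == "G":
        kind = TraitKind.ANTENNA_DEGREE
    elif subject in ("S", "L", "E"):
        if tokens and tokens[-1] == "G":
            kind = TraitKind.GALACTOSE_DEGREE
            tokens.pop()
        else:
            kind = TraitKind.ANTENNA_DEGREE
    else:  # pragma: no cover - tokenizer guarantees membership
        raise TraitGrammarError(f"{name!r}: invalid subject {subject!r}")
    _apply_filters(name, tokens, filters)
    return TraitDefinition(name=name, kind=kind, subject=subject,
                           glycan_class="complex", antennae=antennae, **filters)


# ---------------------------------------------------------------------------
# computation


@dataclass(frozen=True)
class ExplicitTrait:
    """Trait defined by an explicit sum-ratio over composition codes.

    Supports registry lines of the form
    ``name = CODE1 + CODE2 / CODE3 + CODE4`` so that exact curated
    formulas can replace grammar-derived ones.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]


def trait_weights(defn, registry: CompositionRegistry) -> tuple[np.ndarray, np.ndarray]:
    """Numerator/denominator abundance-weight vectors over the registry."""
    p = len(registry)
    w_num = np.zeros(p)
    w_den = np.zeros(p)
    if isinstance(defn, ExplicitTrait):
        idx = {code: i for i, code in enumerate(registry.codes)}
        for code in defn.numerator:
            w_num[idx[code]] += 1.0
        for code in defn.denominator:
            w_den[idx[code]] += 1.0
        return w_num, w_den
    for i, rec in enumerate(registry):
        w_num[i], w_den[i] = defn.weights(rec.features)
    return w_num, w_den


def compute_trait(defn, abundances, registry: CompositionRegistry) -> float:
    """Trait value for one sample; NaN when the denominator is zero."""
    a = np.asarray(pd.Series(abundances).reindex(registry.codes).fillna(0.0),
                   dtype=float)
    w_num, w_den = trait_weights(defn, registry)
    den = float(a @ w_den)
    if den == 0.0:
        return float("nan")
    return float(a @ w_num) / den


def _parse_registry_line(line: str):
    if "=" in line:
        name, expr = (s.strip() for s in line.split("=", 1))
        try:
            num_s, den_s = expr.split("/")
        except ValueError as exc:
            raise TraitGrammarError(f"{line!r}: explicit formula needs one '/'") from exc
        strip = lambda s: tuple(t.strip() for t in s.strip().strip("()").split("+") if t.strip())
        return ExplicitTrait(name, strip(num_s), strip(den_s))
    return line.strip()


def load_trait_registry(path) -> list:
    """Read a trait registry: one name (or ``name = num/den`` override) per line."""
    entries = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                entries.append(_parse_registry_line(line))
    return entries


def compute_all(matrix: pd.DataFrame, registry: CompositionRegistry,
                trait_names=None) -> pd.DataFrame:
    """Trait matrix (samples x traits) from a normalized abundance matrix.

    All registry names are parsed before any computation, so an
    unparseable name fails fast.  Missing compositions (columns absent
    from ``matrix``) contribute zero abundance.  Undefined trait values
    (zero-abundance denominator subset) are NaN.
    """
    if trait_names is None:
        trait_names = DEFAULT_TRAIT_NAMES
    defs = [entry if isinstance(entry, (TraitDefinition, ExplicitTrait))
            else parse_trait_name(entry) for entry in trait_names]
    codes = registry.codes
    A = matrix.reindex(columns=codes, fill_value=0.0).to_numpy(dtype=float)
    W_num = np.column_stack([trait_weights(d, registry)[0] for d in defs])
    W_den = np.column_stack([trait_weights(d, registry)[1] for d in defs])
    num = A @ W_num
    den = A @ W_den
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(vals, index=matrix.index, columns=[d.name for d in defs])
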