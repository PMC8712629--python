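"""Composition and trait registries.

The composition registry is the curated list of N-glycan compositions that
targeted extraction quantifies, together with the structural annotations
(class override, bisection) that composition-only inference cannot supply.
It round-trips through a tab-separated text file with columns ``code``,
``class``, ``bisected`` and ``include`` so that a curated table can be
dropped in without code changes.

The default registry bundled here is a conventional 58-composition plasma
N-glycome panel: the high-mannose series, sialylated hybrids, the fucosyl-
and sialyl-variants of di-, tri- and tetra-antennary complex glycans, and
the bisected (N5, low-hexose) diantennary series.  The default trait
registry enumerates 82 derived-trait names over the trait grammar (see
:mod:`nglyco.traits`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import (GlycanComposition, StructuralFeatures, classify_structure,
                   molecular_formula, monoisotopic_mass, parse_composition)

__all__ = ["CompositionRecord", "CompositionRegistry",
           "DEFAULT_COMPOSITIONS", "DEFAULT_TRAIT_NAMES"]


# (code, bisected) pairs; bisected diantennary structures cannot be told
# from triantennary ones by composition alone, so they are annotated.
DEFAULT_COMPOSITIONS: list[tuple[str, bool]] = [
    # high-mannose
    ("H5N2", False), ("H6N2", False), ("H7N2", False), ("H8N2", False), ("H9N2", False),
    # hybrid
    ("H5N3", False), ("H6N3", False), ("H5N3E1", False), ("H6N3E1", False),
    # diantennary complex
    ("H3N4", False), ("H3N4F1", False), ("H4N4", False), ("H4N4F1", False),
    ("H5N4", False), ("H5N4F1", False), ("H4N4E1", False), ("H4N4F1E1", False),
    ("H5N4E1", False), ("H5N4L1", False), ("H5N4F1E1", False), ("H5N4F1L1", False),
    ("H5N4E2", False), ("H5N4L1E1", False), ("H5N4L2", False),
    ("H5N4F1E2", False), ("H5N4F1L1E1", False),
    # bisected diantennary
    ("H3N5", True), ("H3N5F1", True), ("H4N5", True), ("H4N5F1", True),
    ("H5N5", True), ("H5N5F1", True), ("H5N5F1E1", True),
    # triantennary complex
    ("H6N5", False), ("H6N5F1", False), ("H6N5E1", False),
    ("H6N5E2", False), ("H6N5L1E1", False), ("H6N5E3", False), ("H6N5L1E2", False),
    ("H6N5L2E1", False), ("H6N5F1E1", False),
    ("H6N5F1E2", False), ("H6N5F1L1E1", False), ("H6N5F1E3", False),
    ("H6N5F1L1E2", False),
    # tetraantennary complex
    ("H7N6", False), ("H7N6F1", False), ("H7N6E1", False), ("H7N6E2", False),
    ("H7N6E3", False), ("H7N6L1E2", False), ("H7N6E4", False),
    ("H7N6L1E3", False), ("H7N6L2E2", False), ("H7N6F1E2", False),
    ("H7N6F1E3", False), ("H7N6F1L1E2", False),
]


def _per_antenna_names(k: int) -> list[str]:
    a = f"A{k}"
    return [
        f"{a}G", f"{a}S", f"{a}L", f"{a}E",
        f"{a}GS", f"{a}GL", f"{a}GE",
        f"{a}F", f"{a}B",
        f"{a}FG", f"{a}FS", f"{a}FL", f"{a}FE",
        f"{a}F0G", f"{a}F0S", f"{a}F0L", f"{a}F0E",
        f"{a}F0GL", f"{a}F0GE",
        f"{a}SG", f"{a}LF",
    ]


#: Default registry of 82 derived glycan trait names.  The grammar-driven
#: engine makes the list editable text; see :mod:`nglyco.traits`.
DEFAULT_TRAIT_NAMES: list[str] = (
    ["TM", "THy", "TC", "CA2", "CA3", "CA4",
     "TA2", "TA3", "TA4", "TA2F", "TA2FS0", "TA2B",
     "TG", "TS", "TL", "TE", "TF"]
    + _per_antenna_names(2) + _per_antenna_names(3) + _per_antenna_names(4)
    + ["A3EF", "A4EF"]
)


@dataclass(frozen=True)
class CompositionRecord:
    """One registry entry with derived masses and structural features."""

    code: str
    composition: GlycanComposition
    features: StructuralFeatures
    mass_neutral: float
    mass_sodiated: float
    include: bool = True


@dataclass
class CompositionRegistry:
    """Ordered collection of curated glycan compositions."""

    records: list[CompositionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_code = {r.code: r for r in self.records}
        if len(self._by_code) != len(self.records):
            raise ValueError("duplicate composition codes in registry")

    @classmethod
    def build(cls, entries, include_only: bool = True) -> "CompositionRegistry":
        """Build from (code, bisected[, class, include]) tuples/dicts."""
        records = []
        for entry in entries:
            if isinstance(entry, dict):
                code = entry["code"]
                bisected = bool(entry.get("bisected", False))
                klass = entry.get("class") or None
                include = bool(entry.get("include", True))
            else:
                code, bisected = entry[0], bool(entry[1])
                klass, include = None, True
            comp = parse_composition(code)
            feats = classify_structure(comp, glycan_class=klass, bisected=bisected)
            records.append(CompositionRecord(
                code=comp.code, composition=comp, features=feats,
                mass_neutral=monoisotopic_mass(comp, "neutral"),
                mass_sodiated=monoisotopic_mass(comp, "sodiated"),
                include=include))
        if include_only:
            records = [r for r in records if r.include]
        return cls(records)

    @classmethod
    def default(cls) -> "CompositionRegistry":
        return cls.build(DEFAULT_COMPOSITIONS)

    @classmethod
    def from_table(cls, path) -> "CompositionRegistry":
        """Read a registry from tab-separated text.

        Columns: ``code`` (required), optional ``class``, ``bisected``,
        ``include``.
        """
        df = pd.read_csv(path, sep="\t", dtype={"code": str})
        if "code" not in df.columns:
            raise ValueError(f"{path}: registry table needs a 'code' column")
        entries = []
        for _, row in df.iterrows():
            entry = {"code": row["code"]}
            if "class" in df.columns and pd.notna(row.get("class")):
                entry["class"] = str(row["class"])
            if "bisected" in df.columns and pd.notna(row.get("bisected")):
                entry["bisected"] = bool(row["bisected"])
            if "include" in df.columns and pd.notna(row.get("include")):
                entry["include"] = bool(row["include"])
            entries.append(entry)
        return cls.build(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "code": r.code,
                "class": r.features.glycan_class,
                "bisected": r.features.bisected,
                "include": r.include,
                "antennae": r.features.antennae,
                "galactoses": r.features.galactoses,
                "mass_neutral": r.mass_neutral,
                "mass_sodiated": r.mass_sodiated,
                "formula": molecular_formula(r.composition).formula(),
            })
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    # -- access helpers -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> CompositionRecord:
        return self._by_code[code]

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self.records]

    def features(self, code: str) -> StructuralFeatures:
        return self._by_code[code].features

    def mass(self, code: str) -> float:
        return self._by_code[code].mass_sodiated
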