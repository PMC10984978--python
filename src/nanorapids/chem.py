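"""Molecular formulas, monoisotopic masses, RDBE and homolog-series checks.

The annotation steps of the pipeline reason about small-molecule ions:
a protonated natural product ``[M+H]+``, its in-source fragments
(water loss, deoxysugar loss) and solvent adducts.  All of that reduces
to exact arithmetic over molecular formulas, which this module provides.

Conventions
-----------
* "Calculated" ion masses follow the natural-products reporting
  convention: the printed formula is the *ion* formula (proton included
  as one extra H) and the mass is a plain sum of neutral atomic
  monoisotopic masses, without subtracting the electron mass.  An
  electron-corrected variant is available via
  :func:`protonated_mz` ``electron_correction=True``.
* RDBE (ring and double-bond equivalents, a.k.a. degrees of
  unsaturation) is ``C - H/2 + N/2 + 1``; divalent O/S and P are ignored
  (P treated as trivalent would add N-like terms, but natural-product
  reporting uses the simple formula, which we follow).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "CH2_MASS",
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "rdbe",
    "homolog_spacing",
    "HomologSpacing",
]

#: Monoisotopic atomic masses in Da (most abundant isotope), frozen from
#: the AME2020/CODATA evaluation so results are reproducible offline.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "F": 18.99840322,
    "I": 126.904473,
    "Si": 27.97692653,
}

#: Proton mass in Da.
PROTON_MASS = 1.00727646688
#: Electron mass in Da.
ELECTRON_MASS = 0.00054857990946
#: Exact mass of one CH2 unit — the spacing of a fatty-acid homolog series.
CH2_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element→count map with exact-mass semantics.

    Instances are immutable and hashable; addition composes formulas
    (useful for adduct arithmetic).
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for el, n in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 1:
                raise FormulaError(f"non-positive count for {el}: {n}")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        return cls(tuple(sorted((e, int(n)) for e, n in counts.items() if n)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula.from_dict(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Serialize in Hill order: C first, then H, then alphabetical.

        Formulas without carbon are fully alphabetical, per the Hill
        convention.
        """
        d = self.as_dict()
        parts: list[str] = []
        if "C" in d:
            order = ["C"] + (["H"] if "H" in d else [])
            order += sorted(e for e in d if e not in ("C", "H"))
        else:
            order = sorted(d)
        for el in order:
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular-formula string like ``"C36H40NO15S"``.

    Typographic subscript markup (underscores, whitespace) is stripped
    before parsing, so strings copied from publication tables such as
    ``"C_25_H_27_O_10_"`` parse as well.  Omitted counts mean 1;
    repeated element symbols accumulate.
    """
    cleaned = re.sub(r"[^A-Za-z0-9]", "", text or "")
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula at {cleaned[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {el!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(cleaned):
        raise FormulaError(f"cannot parse formula at {cleaned[pos:]!r}")
    return MolecularFormula.from_dict(counts)


def _as_formula(f: "MolecularFormula | str") -> MolecularFormula:
    return parse_formula(f) if isinstance(f, str) else f


def monoisotopic_mass(f: "MolecularFormula | str") -> float:
    """Sum of atom-count × monoisotopic atomic mass, in Da."""
    f = _as_formula(f)
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts)


def protonated_mz(
    neutral: "MolecularFormula | str | None",
    electron_correction: bool = False,
) -> float:
    """m/z of ``[M+H]+`` for a neutral formula.

    With ``electron_correction`` off (default) the proton adds the mass
    of one hydrogen *atom* — matching how "calcd." values are reported
    for protonated-ion formulas in the natural-products literature.
    With it on, the true proton mass (H minus one electron) is added.
    """
    base = 0.0 if neutral is None else monoisotopic_mass(neutral)
    if electron_correction:
        return base + PROTON_MASS
    return base + MONOISOTOPIC_MASS["H"]


def rdbe(f: "MolecularFormula | str") -> float:
    """Ring and double-bond equivalents: ``C - H/2 + N/2 + 1``.

    O, S and P do not contribute; halogens count like hydrogen.
    Returns an integer or half-integer float (half-integral RDBE for an
    even-electron ion formula).
    """
    f = _as_formula(f)
    d = f.as_dict()
    c = d.get("C", 0) + d.get("Si", 0)
    h = d.get("H", 0) + sum(d.get(x, 0) for x in ("F", "Cl", "Br", "I"))
    n = d.get("N", 0)
    return c - h / 2.0 + n / 2.0 + 1.0


@dataclass
class HomologSpacing:
    """Consecutive m/z differences of a putative homolog series."""

    differences: list[float]
    rounded: list[int]
    is_ch2_series: bool
    tolerance: float


def homolog_spacing(
    mz_values: Sequence[float], tolerance: float = 0.03
) -> HomologSpacing:
    """Check an ascending m/z list for CH2 homolog spacing.

    A CH2 (methylene) series — e.g. lipopeptides differing in fatty-acid
    chain length — shows consecutive differences of 14.01565 Da.  The
    series flag requires every rounded difference to equal 14 *and*
    every exact difference to lie within ``tolerance`` of the exact CH2
    mass.
    """
    if len(mz_values) < 2:
        raise ValueError("need at least two m/z values")
    if any(b < a for a, b in zip(mz_values, mz_values[1:])):
        raise ValueError("m/z values must be sorted ascending")
    diffs = [float(b - a) for a, b in zip(mz_values, mz_values[1:])]
    rounded = [round(d) for d in diffs]
    is_series = all(r == 14 for r in rounded) and all(
        abs(d - CH2_MASS) <= tolerance for d in diffs
    )
    return HomologSpacing(diffs, rounded, is_series, tolerance)
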