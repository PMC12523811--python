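"""Elemental-formula arithmetic for small-molecule HRMS.

Monoisotopic masses, adduct m/z, ppm mass errors, and theoretical isotope
envelopes computed by exact convolution of per-element isotopologue
distributions. Envelope peaks are aggregated by neutron count (A, A+1, ...)
rather than resolved into fine structure: at the 120k-FWHM resolution of an
Orbitrap full scan, the ~2 mDa splitting between e.g. a one-(13C) and a
one-(37Cl) isotopologue at m/z 500 is not resolved, so the observable peak
is the abundance-weighted centroid of all isotopologues sharing a neutron
excess.

Isotope masses and natural abundances come from a bundled CSV (NIST values,
frozen in the repository so envelopes are bit-reproducible).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "Adduct",
    "IsotopeEnvelope",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_envelope",
    "get_adduct",
    "isotope_table",
    "ELECTRON_MASS",
    "PROTON_MASS",
]

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.00727646677


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid elemental formulas."""


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float       # Da
    abundance: float  # natural abundance, fraction


_ISOTOPE_CACHE: dict[str, tuple[Isotope, ...]] | None = None


def isotope_table() -> Mapping[str, tuple[Isotope, ...]]:
    """Bundled isotope table: element symbol -> isotopes sorted by mass number."""
    global _ISOTOPE_CACHE
    if _ISOTOPE_CACHE is None:
        table: dict[str, list[Isotope]] = {}
        text = resources.files("residuescreen.data").joinpath("isotopes.csv").read_text()
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        for row in csv.DictReader(lines):
            table.setdefault(row["element"], []).append(
                Isotope(int(row["mass_number"]), float(row["mass_da"]), float(row["abundance"]))
            )
        _ISOTOPE_CACHE = {e: tuple(sorted(v, key=lambda i: i.mass_number)) for e, v in table.items()}
    return _ISOTOPE_CACHE


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts of a neutral molecule or ion skeleton.

    Every symbol must be present in the bundled isotope table and every
    count must be a positive integer; the formula must contain at least
    one atom.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        table = isotope_table()
        if not self.counts:
            raise FormulaError("formula must contain at least one atom")
        for sym, n in self.counts.items():
            if sym not in table:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, (int, np.integer)) or n <= 0:
                raise FormulaError(f"atom count for {sym} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def adjusted(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Counts shifted by ``delta`` (e.g. adduct atoms); may remove atoms."""
        merged = dict(self.counts)
        for sym, d in delta.items():
            new = merged.get(sym, 0) + d
            if new < 0:
                raise FormulaError(f"adduct removes more {sym} atoms than the formula has")
            if new == 0:
                merged.pop(sym, None)
            else:
                merged[sym] = new
        return ElementalFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        syms = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self.counts[s] if self.counts[s] > 1 else ''}" for s in syms)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)|(.)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string, e.g. ``"C18H14BrCl2N5O2"``.

    Parenthesized groups with integer multipliers are accepted
    (``"Fe(NO3)3"``-style). Element symbols are case-sensitive.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    stack: list[dict[str, int]] = [{}]
    pos = 0
    s = text.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        assert m is not None
        if m.group(1):  # element
            sym, digits = m.group(1), m.group(2)
            n = int(digits) if digits else 1
            if digits and n == 0:
                raise FormulaError(f"zero atom count for {sym} in {text!r}")
            stack[-1][sym] = stack[-1].get(sym, 0) + n
        elif m.group(3):  # (
            stack.append({})
        elif m.group(4):  # )
            if len(stack) == 1:
                raise FormulaError(f"unbalanced ')' in {text!r}")
            mult = int(m.group(5)) if m.group(5) else 1
            if mult == 0:
                raise FormulaError(f"zero group multiplier in {text!r}")
            group = stack.pop()
            for sym, n in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0) + n * mult
        else:
            raise FormulaError(f"unexpected character {m.group(6)!r} in formula {text!r}")
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in {text!r}")
    return ElementalFormula(stack[0])


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of count x most-abundant-isotope mass, in Da."""
    table = isotope_table()
    return sum(n * max(table[sym], key=lambda i: i.abundance).mass for sym, n in f.counts.items())


@dataclass(frozen=True)
class Adduct:
    """An ionized form of a neutral molecule, e.g. ``[M+H]+``.

    ``mass_shift`` includes the electron gained/lost, so observed m/z is
    ``(M + mass_shift) / |charge|``. ``atom_delta`` records the atoms added
    to (or removed from) the neutral formula, used when building the
    envelope of the ionized species.
    """

    name: str
    mass_shift: float
    charge: int
    atom_delta: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        object.__setattr__(self, "atom_delta", dict(self.atom_delta))

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


_H = 1.007825032
_N = 14.003074005
_NA = 22.989769281

ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", _H - ELECTRON_MASS, +1, {"H": +1}),
    "[M-H]-": Adduct("[M-H]-", -(_H - ELECTRON_MASS), -1, {"H": -1}),
    "[M+Na]+": Adduct("[M+Na]+", _NA - ELECTRON_MASS, +1, {"Na": +1}),
    "[M+NH4]+": Adduct("[M+NH4]+", _N + 4 * _H - ELECTRON_MASS, +1, {"N": +1, "H": +4}),
}


def get_adduct(name: str) -> Adduct:
    """Look up an adduct by token; the Unicode minus sign is accepted."""
    key = name.strip().replace("−", "-")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise FormulaError(f"unknown adduct: {name!r}") from None


def adduct_mz(m: float, a: Adduct) -> float:
    """m/z of the adduct of a neutral molecule of monoisotopic mass ``m``."""
    if m <= 0:
        raise ValueError("neutral mass must be positive")
    return (m + a.mass_shift) / abs(a.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Neutron-aggregated isotopologue distribution of an ion.

    ``peaks`` are (m/z, relative abundance) sorted by m/z, with exactly one
    base peak of relative abundance 1. Note the base peak need not be the
    monoisotopic peak (e.g. BrCl2 species, where A+2 is the most abundant).
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("envelope must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("envelope peaks must be strictly sorted by m/z")
        rels = [p[1] for p in self.peaks]
        if sum(abs(r - 1.0) < 1e-12 for r in rels) != 1 or any(not 0 < r <= 1 for r in rels):
            raise ValueError("relative abundances must lie in (0, 1] with exactly one base peak")

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def rel_abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def _element_distribution(sym: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n atoms of one element over neutron offsets.

    Returns (p, w): p[k] is the probability of a total neutron excess k above
    the lightest isotope; w[k] is the probability-weighted total mass, so
    w[k]/p[k] is the centroid mass of that aggregate. Computed by binary
    exponentiation of the single-atom distribution; exact up to float
    rounding.
    """
    isos = isotope_table()[sym]
    base_num = isos[0].mass_number
    span = isos[-1].mass_number - base_num
    p1 = np.zeros(span + 1)
    w1 = np.zeros(span + 1)
    for iso in isos:
        p1[iso.mass_number - base_num] += iso.abundance
        w1[iso.mass_number - base_num] += iso.abundance * iso.mass
    p, w = np.array([1.0]), np.array([0.0])
    pk, wk = p1, w1
    e = n
    while e:
        if e & 1:
            p, w = np.convolve(p, pk), np.convolve(w, pk) + np.convolve(p, wk)
        e >>= 1
        if e:
            pk, wk = np.convolve(pk, pk), 2 * np.convolve(pk, wk)
    return p, w


def isotope_envelope(
    f: ElementalFormula,
    adduct: Adduct | None = None,
    prune: float = 0.001,
    max_peaks: int | None = None,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of ``f`` (ionized by ``adduct`` if given).

    Exact convolution of per-element isotopologue distributions, aggregated
    by neutron count; each aggregate's m/z is the abundance-weighted centroid
    of its fine-structure components. Abundances are normalized to the base
    peak and pruned below ``prune``; if ``max_peaks`` is given, only the
    most abundant peaks are kept. The default prune of 0.1% of base is the
    floor at which the envelope of a BrCl2 pesticide like chlorantraniliprole
    carries nine reportable peaks and a C37 macrolide like erythromycin five,
    matching vendor-software isotope counts at typical Orbitrap dynamic range.
    """
    if not 0 < prune < 1:
        raise ValueError("prune must lie in (0, 1)")
    species = f if adduct is None else f.adjusted(adduct.atom_delta)
    p, w = np.array([1.0]), np.array([0.0])
    for sym, n in species.counts.items():
        pe, we = _element_distribution(sym, n)
        p, w = np.convolve(p, pe), np.convolve(w, pe) + np.convolve(p, we)
    keep = p > 1e-15 * p.max()
    prob = p[keep]
    mass = w[keep] / prob
    if adduct is not None:
        mass = (mass - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)
    rel = prob / prob.max()
    sel = rel >= prune
    mass, rel = mass[sel], rel[sel]
    if max_peaks is not None and len(rel) > max_peaks:
        top = np.sort(np.argsort(rel)[::-1][:max_peaks])
        mass, rel = mass[top], rel[top]
    # guard against float drift on the base peak
    rel = rel / rel.max()
    return IsotopeEnvelope(tuple(zip(mass.tolist(), rel.tolist())))
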