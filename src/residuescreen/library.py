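"""Data model and CSV I/O for the suspect-screening library.

A library row holds everything needed to screen one compound in one
ionization mode: elemental formula, adduct, expected retention time on the
17.1-min reversed-phase gradient, and the characteristic product-ion m/z
values used for confirmation. The package bundles a reconstructed
121-compound quality-control panel (63 pesticides + 58 veterinary drugs)
whose calibration parameters, SDLs and LOQs come from a published
leafy-vegetable validation study; its retention times and fragment lists
are synthetic (see the bundled file header).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .formula import (
    Adduct,
    ElementalFormula,
    FormulaError,
    adduct_mz,
    get_adduct,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "CompoundRecord",
    "SuspectLibrary",
    "LibraryError",
    "Finding",
    "load_library",
    "write_library",
    "validate_library",
    "bundled_panel_path",
    "load_bundled_panel",
]

GRADIENT_END_MIN = 17.1  # end of the LC gradient window

REQUIRED_COLUMNS = ("name", "class", "formula", "adduct", "rt_min", "fragments")
OPTIONAL_COLUMNS = ("mrl_ugkg",)


class LibraryError(ValueError):
    """Schema or row-level error while reading or validating a library."""


@dataclass(frozen=True)
class CompoundRecord:
    """One suspect-library entry."""

    name: str
    compound_class: str  # "pesticide" | "veterinary_drug"
    formula: ElementalFormula
    adduct: Adduct
    expected_rt: float  # minutes
    fragments: tuple[float, ...] = ()
    reference_ms2: tuple[tuple[float, float], ...] | None = None
    mrl: float | None = None  # optional regulatory limit, ug/kg

    def __post_init__(self) -> None:
        if self.compound_class not in ("pesticide", "veterinary_drug"):
            raise LibraryError(
                f"{self.name}: compound class must be pesticide or veterinary_drug, "
                f"got {self.compound_class!r}"
            )
        if self.expected_rt < 0:
            raise LibraryError(f"{self.name}: expected RT must be >= 0")
        limit = self.precursor_mz + 0.5
        bad = [f for f in self.fragments if not 0 < f < limit]
        if bad:
            raise LibraryError(
                f"{self.name}: fragment m/z {bad} outside (0, precursor + 0.5 = {limit:.4f})"
            )

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(monoisotopic_mass(self.formula), self.adduct)

    @property
    def polarity(self) -> str:
        return self.adduct.polarity


@dataclass
class SuspectLibrary:
    records: list[CompoundRecord]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryError("library must contain at least one record")
        seen: set[str] = set()
        for r in self.records:
            if r.name in seen:
                raise LibraryError(f"duplicate compound name: {r.name!r}")
            seen.add(r.name)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def subset(self, names: Iterable[str]) -> "SuspectLibrary":
        wanted = set(names)
        return SuspectLibrary(
            [r for r in self.records if r.name in wanted], dict(self.metadata)
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for r in self.records:
            h.update(
                f"{r.name}|{r.formula}|{r.adduct.name}|{r.expected_rt}|{r.fragments}".encode()
            )
        return h.hexdigest()[:16]


def _parse_fragments(cell: str, row_no: int) -> tuple[float, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    try:
        return tuple(float(tok) for tok in cell.split(";") if tok.strip())
    except ValueError as exc:
        raise LibraryError(f"row {row_no}: unparseable fragment list {cell!r}") from exc


def load_library(path: str | Path, ms2_path: str | Path | None = None) -> SuspectLibrary:
    """Load a suspect library from CSV (optionally with reference MS2 in MGF).

    Required columns: name, class, formula, adduct, rt_min, fragments
    (semicolon-separated m/z). Optional: mrl_ugkg. ``#``-prefixed lines are
    comments. Row numbers (1-based, excluding comments/header) are reported
    in error messages; malformed rows fail the load rather than being
    skipped.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines)
    cols = reader.fieldnames or []
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise LibraryError(f"{path.name}: missing required columns {missing}")
    ref_ms2 = _read_reference_ms2(ms2_path) if ms2_path else {}
    records: list[CompoundRecord] = []
    for row_no, row in enumerate(reader, start=1):
        name = (row["name"] or "").strip()
        if not name:
            raise LibraryError(f"row {row_no}: empty compound name")
        try:
            formula = parse_formula(row["formula"])
            adduct = get_adduct(row["adduct"])
        except FormulaError as exc:
            raise LibraryError(f"row {row_no} ({name}): {exc}") from exc
        try:
            rt = float(row["rt_min"])
        except (TypeError, ValueError) as exc:
            raise LibraryError(f"row {row_no} ({name}): bad rt_min {row['rt_min']!r}") from exc
        mrl_cell = (row.get("mrl_ugkg") or "").strip()
        try:
            rec = CompoundRecord(
                name=name,
                compound_class=(row["class"] or "").strip(),
                formula=formula,
                adduct=adduct,
                expected_rt=rt,
                fragments=_parse_fragments(row["fragments"], row_no),
                reference_ms2=ref_ms2.get(name),
                mrl=float(mrl_cell) if mrl_cell else None,
            )
        except LibraryError as exc:
            raise LibraryError(f"row {row_no}: {exc}") from exc
        records.append(rec)
    return SuspectLibrary(records, {"source": str(path)})


def _read_reference_ms2(path: str | Path) -> dict[str, tuple[tuple[float, float], ...]]:
    from pyteomics import mgf

    out: dict[str, tuple[tuple[float, float], ...]] = {}
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"].get("title", "")
            peaks = tuple(zip(spec["m/z array"].tolist(), spec["intensity array"].tolist()))
            out[title] = peaks
    return out


def write_library(lib: SuspectLibrary, path: str | Path) -> None:
    """Write a library back to the canonical CSV schema (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        for r in lib.records:
            writer.writerow(
                [
                    r.name,
                    r.compound_class,
                    str(r.formula),
                    r.adduct.name,
                    repr(r.expected_rt),
                    ";".join(repr(f) for f in r.fragments),
                    "" if r.mrl is None else repr(r.mrl),
                ]
            )


@dataclass(frozen=True)
class Finding:
    level: str  # "warning" | "error"
    compound: str
    message: str


def validate_library(lib: SuspectLibrary) -> list[Finding]:
    """Non-destructive QC pass over a loaded library.

    Warnings: empty fragment list (compound can be screened but never
    confirmed), expected RT outside the LC gradient window. Duplicate names
    are impossible in a constructed SuspectLibrary, but duplicated precursor
    identities within a polarity are flagged as warnings.
    """
    findings: list[Finding] = []
    for r in lib.records:
        if not r.fragments:
            findings.append(
                Finding("warning", r.name, "no product ions: can be screened but never confirmed")
            )
        if r.expected_rt > GRADIENT_END_MIN:
            findings.append(
                Finding(
                    "warning",
                    r.name,
                    f"expected RT {r.expected_rt:.2f} min beyond gradient end "
                    f"({GRADIENT_END_MIN} min)",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# bundled 121-compound panel

PANEL_EXTRA_COLUMNS = (
    "range_lo_ugkg",
    "range_hi_ugkg",
    "slope",
    "intercept",
    "r2",
    "sdl_ugkg",
    "loq_ugkg",
)


def bundled_panel_path() -> Path:
    return Path(str(resources.files("residuescreen.data").joinpath("residue_panel.csv")))


def load_bundled_panel() -> tuple[SuspectLibrary, "object"]:
    """Load the bundled 121-compound panel.

    Returns the suspect library plus a pandas DataFrame (indexed by compound
    name) with the per-compound method parameters: linear range, calibration
    slope/intercept, reported R2, SDL and LOQ (all in ug/kg or area units
    per ug/kg).
    """
    import pandas as pd

    path = bundled_panel_path()
    lib = load_library(path)
    frame = pd.read_csv(path, comment="#").set_index("name")
    return lib, frame[list(PANEL_EXTRA_COLUMNS)]
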