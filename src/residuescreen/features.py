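"""Observed-feature model and feature-table I/O.

A Feature is one centroided chromatographic peak from a full-scan
acquisition: monoisotopic m/z, retention time, integrated area, apex
height, the accompanying isotope cluster, and (when a data-dependent scan
fired) the linked MS2 spectrum. The engine consumes feature tables; peak
picking from raw data is out of scope.

On disk a feature table is a CSV with columns
``sample_id, mz, rt_min, area, height, cluster, ms2_id, polarity`` where
``cluster`` packs the isotope peaks as semicolon-separated ``mz:intensity``
pairs and ``ms2_id`` keys into a companion MGF file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Feature", "FeatureTableError", "read_feature_table", "write_feature_table"]

Spectrum = tuple[tuple[float, float], ...]


class FeatureTableError(ValueError):
    """Malformed feature-table row; carries the offending row number."""


@dataclass(frozen=True)
class Feature:
    mz: float                     # monoisotopic peak of the isotope cluster
    rt: float                     # minutes
    area: float
    height: float
    isotope_cluster: Spectrum = ()
    ms2: Spectrum | None = None
    sample_id: str = ""
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.area < 0 or self.height < 0:
            raise ValueError("area and height must be >= 0")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if any(i < 0 for _, i in self.isotope_cluster):
            raise ValueError("isotope-cluster intensities must be >= 0")
        if self.ms2 is not None and any(i < 0 for _, i in self.ms2):
            raise ValueError("MS2 intensities must be >= 0")
        if self.isotope_cluster and not any(
            abs(mz - self.mz) <= 1e-6 for mz, _ in self.isotope_cluster
        ):
            raise ValueError("isotope cluster must contain the feature's monoisotopic peak")

    @property
    def intensity(self) -> float:
        """Height, falling back to area when no height was recorded."""
        return self.height if self.height > 0 else self.area


def _encode_peaks(peaks: Spectrum) -> str:
    return ";".join(f"{mz:.6f}:{inten:.6g}" for mz, inten in peaks)


def _decode_peaks(cell: str, row_no: int) -> Spectrum:
    cell = (cell or "").strip()
    if not cell:
        return ()
    try:
        out = []
        for pair in cell.split(";"):
            mz_s, int_s = pair.split(":")
            out.append((float(mz_s), float(int_s)))
        return tuple(out)
    except ValueError as exc:
        raise FeatureTableError(f"row {row_no}: unparseable cluster {cell!r}") from exc


FEATURE_COLUMNS = ("sample_id", "mz", "rt_min", "area", "height", "cluster", "ms2_id", "polarity")


def write_feature_table(
    features: Sequence[Feature], csv_path: str | Path, mgf_path: str | Path | None = None
) -> None:
    """Write features to CSV, with MS2 spectra in a companion MGF keyed by ms2_id."""
    from pyteomics import mgf

    spectra = []
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_COLUMNS)
        for i, f in enumerate(features):
            ms2_id = ""
            if f.ms2:
                ms2_id = f"{f.sample_id}:{i}"
                mzs, ints = zip(*f.ms2)
                spectra.append(
                    {
                        "m/z array": np.array(mzs),
                        "intensity array": np.array(ints),
                        "params": {
                            "title": ms2_id,
                            "pepmass": f.mz,
                            "rtinseconds": f.rt * 60.0,
                        },
                    }
                )
            writer.writerow(
                [
                    f.sample_id,
                    f"{f.mz:.6f}",
                    f"{f.rt:.4f}",
                    f"{f.area:.6g}",
                    f"{f.height:.6g}",
                    _encode_peaks(f.isotope_cluster),
                    ms2_id,
                    f.polarity,
                ]
            )
    if mgf_path is not None:
        mgf.write(spectra, output=str(mgf_path), file_mode="w")


def read_feature_table(
    csv_path: str | Path, mgf_path: str | Path | None = None
) -> list[Feature]:
    """Read a feature table; strict parse — malformed rows raise, never skip."""
    from pyteomics import mgf

    ms2_by_id: dict[str, Spectrum] = {}
    if mgf_path is not None and Path(mgf_path).exists():
        with mgf.MGF(str(mgf_path)) as reader:
            for spec in reader:
                title = spec["params"].get("title", "")
                ms2_by_id[title] = tuple(
                    zip(spec["m/z array"].tolist(), spec["intensity array"].tolist())
                )
    features: list[Feature] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.startswith("#"))
        cols = reader.fieldnames or []
        missing = [c for c in FEATURE_COLUMNS if c not in cols]
        if missing:
            raise FeatureTableError(f"{Path(csv_path).name}: missing columns {missing}")
        for row_no, row in enumerate(reader, start=1):
            try:
                ms2_id = (row["ms2_id"] or "").strip()
                features.append(
                    Feature(
                        mz=float(row["mz"]),
                        rt=float(row["rt_min"]),
                        area=float(row["area"]),
                        height=float(row["height"]),
                        isotope_cluster=_decode_peaks(row["cluster"], row_no),
                        ms2=ms2_by_id.get(ms2_id) if ms2_id else None,
                        sample_id=row["sample_id"],
                        polarity=row["polarity"],
                    )
                )
            except FeatureTableError:
                raise
            except (TypeError, ValueError) as exc:
                raise FeatureTableError(f"row {row_no}: {exc}") from exc
    return features
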