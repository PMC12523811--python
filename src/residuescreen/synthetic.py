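"""Synthetic Orbitrap-style data with the statistical structure the
screening and validation stages assume.

No public raw data accompanies the study conditions this package targets,
so every pipeline stage is exercised on generated feature tables. The
generator emulates centroided full-scan acquisition of spiked vegetable
extracts:

* peak areas follow each compound's matrix-matched calibration line, scaled
  by a per-compound matrix-effect factor and multiplicative lognormal noise
  (areas are positive and heteroscedastic, so noise is CV-parameterized,
  default 5%);
* m/z values carry Gaussian relative error (default 1 ppm, consistent with
  a 120k-FWHM Orbitrap after external calibration) and retention times
  Gaussian jitter (default 0.02 min);
* isotope clusters are the theoretical envelope scaled by the area with
  independent per-peak m/z and intensity jitter;
* MS2 spectra contain the library product ions with intensity jitter and
  optional per-fragment dropout.

Everything is driven by numpy Generators; replicate r of spike level l uses
``SeedSequence([base_seed, level_index, r])`` so any replicate table can be
regenerated in isolation. What the generator does NOT emulate: co-eluting
isobaric interference, chromatographic peak shape, detector saturation and
real matrix-dependent fragmentation — tests passing on this model show the
decision logic is correct, not that real extracts behave this simply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import Feature
from .formula import isotope_envelope
from .library import CompoundRecord, SuspectLibrary, load_bundled_panel
from .quantitation import CalibrationCurve

__all__ = [
    "NoiseModel",
    "SpikeDesign",
    "simulate_feature",
    "simulate_spike_experiment",
    "simulate_calibration_set",
    "simulate_coextract_weights",
    "panel_curves",
    "demo_dataset",
    "CALIBRATION_LEVELS",
]

CALIBRATION_LEVELS = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)  # ug/kg

# envelopes depend only on (formula, adduct, prune); cache across replicates
_ENV_CACHE: dict[tuple[str, str, float], object] = {}


def _envelope(c: CompoundRecord, prune: float):
    key = (str(c.formula), c.adduct.name, prune)
    env = _ENV_CACHE.get(key)
    if env is None:
        env = _ENV_CACHE.setdefault(key, isotope_envelope(c.formula, c.adduct, prune=prune))
    return env


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition-noise parameters; all-zero values give exact data."""

    mass_sigma: float = 1.0        # ppm
    rt_sigma: float = 0.02         # minutes
    area_cv: float = 0.05          # fraction
    me_factor: float = 1.0         # multiplicative matrix-effect factor
    fragment_dropout: float = 0.0  # probability per fragment
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mass_sigma, self.rt_sigma, self.area_cv) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0 <= self.fragment_dropout <= 1:
            raise ValueError("fragment_dropout must lie in [0, 1]")
        if self.me_factor <= 0:
            raise ValueError("me_factor must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SpikeDesign:
    """Replicated spike experiment: levels (ug/kg, ascending) x n_reps."""

    levels: tuple[float, ...]
    n_reps: int
    compounds: tuple[str, ...] = ()  # empty = whole library

    def __post_init__(self) -> None:
        if not self.levels or any(l <= 0 for l in self.levels):
            raise ValueError("spike levels must be positive")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("spike levels must be ascending")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _lognorm_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(0.0, 1.0) * sigma - 0.5 * sigma * sigma))


def simulate_feature(
    c: CompoundRecord,
    conc: float,
    curve: CalibrationCurve,
    nm: NoiseModel,
    rng: np.random.Generator,
    sample_id: str = "",
    envelope_prune: float = 0.001,
) -> Feature | None:
    """One observed feature for a compound spiked at ``conc`` ug/kg.

    Returns None when the spike produces no signal: zero concentration, or
    a calibration-line response at or below zero (below-detection
    emulation for compounds whose fitted intercept is negative).
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    true_area = curve.predict(conc) * nm.me_factor
    if conc == 0 or true_area <= 0:
        return None
    area = true_area * _lognorm_factor(rng, nm.area_cv)
    env = _envelope(c, envelope_prune)
    cluster = []
    for mz, rel in env:
        jmz = mz * (1.0 + rng.normal(0.0, nm.mass_sigma) * 1e-6)
        jint = area * rel * _lognorm_factor(rng, nm.area_cv)
        cluster.append((jmz, jint))
    rt = c.expected_rt + rng.normal(0.0, nm.rt_sigma)
    ms2 = []
    for i, frag in enumerate(c.fragments):
        drop = rng.random() < nm.fragment_dropout
        jmz = frag * (1.0 + rng.normal(0.0, nm.mass_sigma) * 1e-6)
        jint = 0.2 * area / (1 + i) * _lognorm_factor(rng, nm.area_cv)
        if not drop:
            ms2.append((jmz, jint))
    return Feature(
        mz=cluster[0][0],  # monoisotopic peak of the cluster
        rt=rt,
        area=area,
        height=area,
        isotope_cluster=tuple(cluster),
        ms2=tuple(ms2) if ms2 else None,
        sample_id=sample_id,
        polarity=c.polarity,
    )


def simulate_spike_experiment(
    design: SpikeDesign,
    lib: SuspectLibrary,
    curves: Mapping[str, CalibrationCurve],
    nm: NoiseModel,
    base_seed: int | None = None,
) -> dict[float, list[list[Feature]]]:
    """Replicated spike tables: level -> list over replicates of feature lists.

    Replicate r of level index l is generated from
    ``SeedSequence([base_seed, l, r])``, so tables are reproducible
    independently of evaluation order.
    """
    names = design.compounds or tuple(c.name for c in lib)
    missing = [n for n in names if n not in curves]
    if missing:
        raise KeyError(f"no calibration curve for: {missing[:5]}")
    base = nm.seed if base_seed is None else base_seed
    out: dict[float, list[list[Feature]]] = {}
    for li, level in enumerate(design.levels):
        reps: list[list[Feature]] = []
        for r in range(design.n_reps):
            rng = np.random.default_rng(np.random.SeedSequence([base, li, r]))
            sample_id = f"L{level:g}_r{r}"
            table = []
            for name in names:
                f = simulate_feature(lib[name], level, curves[name], nm, rng, sample_id)
                if f is not None:
                    table.append(f)
            reps.append(table)
        out[level] = reps
    return out


def simulate_calibration_set(
    c: CompoundRecord,
    curve: CalibrationCurve,
    levels: Sequence[float],
    nm: NoiseModel,
    rng: np.random.Generator,
    n_reps: int = 1,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Matrix-matched and solvent calibration points for one compound.

    Matrix points carry the matrix-effect factor, solvent points do not, so
    a matrix/solvent area ratio at equal concentration recovers
    ``100 x me_factor`` in expectation.
    """
    lo, hi = curve.level_range
    if any(not lo <= l <= hi for l in levels):
        raise ValueError(f"{c.name}: calibration levels outside declared range {lo}-{hi}")
    matrix, solvent = [], []
    for level in levels:
        base = curve.predict(level)
        for _ in range(n_reps):
            matrix.append((level, base * nm.me_factor * _lognorm_factor(rng, nm.area_cv)))
            solvent.append((level, base * _lognorm_factor(rng, nm.area_cv)))
    return matrix, solvent


def simulate_coextract_weights(
    base_mg: float,
    material_efficiencies: Mapping[str, float],
    rng: np.random.Generator,
    sigma_mg: float = 0.0,
    n_reps: int = 3,
):
    """Gravimetric co-extract weights for a sorbent comparison (a DataFrame).

    Purified weight = base x (1 - removal efficiency) + Gaussian weighing
    noise; a removal-rate computation on the mean weights recovers
    ``100 x efficiency`` in expectation.
    """
    import pandas as pd

    if base_mg <= 0:
        raise ValueError("base co-extract weight must be positive")
    rows = []
    for material, eff in material_efficiencies.items():
        if not 0 <= eff < 1:
            raise ValueError(f"{material}: efficiency must lie in [0, 1)")
        for rep in range(n_reps):
            w = base_mg * (1.0 - eff) + rng.normal(0.0, sigma_mg)
            rows.append({"material": material, "replicate": rep + 1,
                         "weight_mg": max(w, 0.0)})
    return pd.DataFrame(rows)


def panel_curves(frame) -> dict[str, CalibrationCurve]:
    """Calibration curves from the bundled panel's slope/intercept columns.

    Points are placed exactly on the line at the standard levels inside
    each compound's declared range, so the stored r2 of these nominal
    curves is 1; the study-reported R2 stays in the panel frame.
    """
    curves: dict[str, CalibrationCurve] = {}
    for name, row in frame.iterrows():
        lo, hi = float(row["range_lo_ugkg"]), float(row["range_hi_ugkg"])
        levels = [l for l in CALIBRATION_LEVELS if lo <= l <= hi]
        slope, intercept = float(row["slope"]), float(row["intercept"])
        pts = tuple((l, slope * l + intercept) for l in levels)
        curves[name] = CalibrationCurve(
            compound=name, slope=slope, intercept=intercept, r2=1.0,
            level_range=(lo, hi), points=pts,
        )
    return curves


def demo_dataset() -> tuple[SuspectLibrary, "object", dict[str, CalibrationCurve]]:
    """Bundled 121-compound panel: library, parameter frame, nominal curves."""
    lib, frame = load_bundled_panel()
    return lib, frame, panel_curves(frame)
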