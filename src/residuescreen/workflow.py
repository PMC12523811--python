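"""End-to-end runs binding screening, quantitation and validation.

These are the functions the command-line interface wraps: screen a feature
batch against a library and summarize the tiers, run a full method
validation (calibration, SDL, LOQ, three-level recovery, matrix effect) on
simulated spike data, and turn a screening report plus calibration curves
into a per-compound quantitation table.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import Feature
from .library import SuspectLibrary
from .quantitation import (
    CalibrationCurve,
    ValidationSummary,
    classify_me,
    determine_loq,
    fit_calibration,
    matrix_effect,
    quantify,
    recovery_stats,
)
from .screening import (
    MatchResult,
    ScreeningConfig,
    STATUS_ORDER,
    determine_sdl,
    screen_batch,
)
from .synthetic import (
    CALIBRATION_LEVELS,
    NoiseModel,
    SpikeDesign,
    simulate_calibration_set,
    simulate_feature,
    simulate_spike_experiment,
)

__all__ = [
    "results_to_frame",
    "screening_summary",
    "run_screening",
    "run_validation",
    "validation_to_frame",
    "run_quantitation",
]


def results_to_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    """One row per (sample, compound) with every MatchResult field."""
    import dataclasses

    columns = [f.name for f in dataclasses.fields(MatchResult)]
    return pd.DataFrame([asdict(r) for r in results], columns=columns)


def screening_summary(results: Sequence[MatchResult]) -> pd.DataFrame:
    """Per-sample counts and percentages of each identification tier."""
    frame = results_to_frame(results)
    if frame.empty:
        return pd.DataFrame(columns=["sample_id", "n_compounds"])
    rows = []
    for sample_id, grp in frame.groupby("sample_id"):
        n = len(grp)
        counts = grp["status"].value_counts()
        row = {"sample_id": sample_id, "n_compounds": n}
        for status in STATUS_ORDER:
            k = int(counts.get(status, 0))
            row[f"n_{status}"] = k
            row[f"pct_{status}"] = round(100.0 * k / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def run_screening(
    features: Sequence[Feature],
    lib: SuspectLibrary,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a batch; returns (per-pair report, per-sample summary)."""
    results = screen_batch(features, lib, cfg)
    return results_to_frame(results), screening_summary(results)


def run_validation(
    lib: SuspectLibrary,
    curves: Mapping[str, CalibrationCurve],
    nm: NoiseModel,
    cfg: ScreeningConfig = ScreeningConfig(),
    sdl_design: SpikeDesign | None = None,
    loq_candidates: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 20.0),
    n_recovery_reps: int = 3,
    base_seed: int = 0,
    detect_fraction_min: float = 0.95,
) -> list[ValidationSummary]:
    """Full method validation on simulated spike/calibration data.

    Per compound: fit a matrix-matched calibration from a simulated
    standard series; determine the SDL from a replicated spike screen;
    gate candidate levels on confirmation + recovery + precision for the
    LOQ; report three-level recoveries (LOQ, 2x, 20x) and the matrix
    effect with its band.
    """
    if sdl_design is None:
        sdl_design = SpikeDesign(levels=(0.5, 1.0, 2.0, 5.0, 10.0), n_reps=20)
    spike = simulate_spike_experiment(sdl_design, lib, curves, nm, base_seed)
    screened: dict[str, dict[float, list[bool]]] = {c.name: {} for c in lib}
    for level, reps in spike.items():
        per_rep: dict[str, list[bool]] = {c.name: [] for c in lib}
        for table in reps:
            results = screen_batch(table, lib, cfg)
            for r in results:
                per_rep[r.compound].append(STATUS_ORDER[r.status] >= 1)
        for name, dets in per_rep.items():
            screened[name][level] = dets

    summaries: list[ValidationSummary] = []
    for ci, c in enumerate(lib):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 10_000 + ci]))
        nominal = curves[c.name]
        lo, hi = nominal.level_range
        cal_levels = [l for l in CALIBRATION_LEVELS if lo <= l <= hi]
        matrix_pts, solvent_pts = simulate_calibration_set(
            c, nominal, cal_levels, nm, rng
        )
        curve = fit_calibration(matrix_pts, c.name)
        # matrix effect from the mid-range standard pair
        mid = len(cal_levels) // 2
        me = matrix_effect(matrix_pts[mid][1], solvent_pts[mid][1])

        sdl = determine_sdl(screened[c.name], detect_fraction_min)

        level_data = []
        for level in loq_candidates:
            if not lo <= level <= hi:
                continue
            measured, confirmed_all = [], True
            for rep in range(n_recovery_reps):
                f = simulate_feature(c, level, nominal, nm, rng, sample_id=f"rec{rep}")
                if f is None:
                    confirmed_all = False
                    measured.append(0.0)
                    continue
                res = screen_batch([f], lib.subset([c.name]), cfg)[0]
                if res.status != "confirmed":
                    confirmed_all = False
                # matrix-matched curve: the ME factor is shared between
                # standards and samples, so it cancels in back-calculation
                measured.append(quantify(f.area, curve).concentration)
            level_data.append((level, confirmed_all, measured))
        loq = determine_loq(level_data) if level_data else None

        recs = []
        if loq is not None:
            for mult in (1.0, 2.0, 20.0):
                level = loq * mult
                if not lo <= level <= hi:
                    continue
                measured = []
                for rep in range(n_recovery_reps):
                    f = simulate_feature(c, level, nominal, nm, rng)
                    conc = 0.0 if f is None else quantify(f.area, curve).concentration
                    measured.append(conc)
                recs.append(recovery_stats(measured, level, c.name))

        summaries.append(
            ValidationSummary(
                compound=c.name,
                sdl=sdl,
                loq=loq,
                curve=curve,
                recoveries=tuple(recs),
                me=me,
                me_band=classify_me(me),
            )
        )
    return summaries


def validation_to_frame(summaries: Sequence[ValidationSummary]) -> pd.DataFrame:
    """Validation-report table: range, curve, R2, SDL, LOQ, recoveries, ME."""
    rows = []
    for s in summaries:
        row: dict = {"compound": s.compound}
        if s.curve is not None:
            row.update(
                linear_range=f"{s.curve.level_range[0]:g}-{s.curve.level_range[1]:g}",
                slope=s.curve.slope,
                intercept=s.curve.intercept,
                r2=s.curve.r2,
            )
        row.update(sdl_ugkg=s.sdl, loq_ugkg=s.loq)
        for label, rec in zip(("loq", "2xloq", "20xloq"), s.recoveries):
            row[f"recovery_{label}"] = round(rec.mean_recovery, 1)
            row[f"rsd_{label}"] = None if rec.rsd is None else round(rec.rsd, 1)
        row.update(me_pct=None if s.me is None else round(s.me, 1), me_band=s.me_band)
        rows.append(row)
    return pd.DataFrame(rows)


def run_quantitation(
    report: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    loqs: Mapping[str, float],
) -> pd.DataFrame:
    """Per-compound quantitation table from a screening report.

    A sample counts as *screened* at tier screened or better; it counts as
    *quantified* only when confirmed and the back-calculated concentration
    reaches the compound's LOQ. Sub-LOQ detections appear in the detection
    count but never in the quantified count; confirmed compounds without a
    curve are reported as screened-only.
    """
    rows = []
    for name, grp in report.groupby("compound", sort=False):
        hits = grp[grp["status"].isin(["screened", "confirmed"])]
        if hits.empty:
            continue
        concs, quant_samples = [], []
        curve = curves.get(name)
        loq = loqs.get(name, math.inf)
        for _, r in hits.iterrows():
            if r["status"] != "confirmed" or curve is None:
                continue
            conc = quantify(r["area"], curve).concentration
            if conc >= loq:
                concs.append(conc)
                quant_samples.append(r["sample_id"])
        rows.append(
            {
                "compound": name,
                "n_screened": int(len(hits)),
                "n_quantified": int(len(concs)),
                "mean_ugkg": round(float(np.mean(concs)), 2) if concs else None,
                "min_ugkg": round(min(concs), 2) if concs else None,
                "max_ugkg": round(max(concs), 2) if concs else None,
                "samples": ";".join(sorted(set(hits["sample_id"]))),
                "quantifiable": curve is not None,
            }
        )
    return pd.DataFrame(rows)
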