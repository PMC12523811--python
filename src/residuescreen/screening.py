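"""Tiered suspect identification under restriction conditions.

A feature identifies a library compound at one of three tiers:

* ``screened`` — precursor m/z within a ppm tolerance of the theoretical
  adduct m/z, retention time within a window of the library value, and
  precursor intensity above the acquisition trigger threshold;
* ``confirmed`` — additionally at least one characteristic product ion
  matched within the fragment ppm tolerance and an isotope-pattern score
  strictly above the score threshold.

Default tolerances are +/-5 ppm on precursor and product ions, +/-0.1 min
on retention time (both closed intervals), an isotope score threshold of 75
(strict inequality), a 5e4 precursor-intensity trigger and a 1e3
product-ion intensity floor. The isotope score is the abundance-weighted
fraction of theoretical envelope peaks recovered in the observed cluster,
scaled to 0-100, so an observed cluster identical to the theoretical
envelope scores exactly 100.

The module also derives the screening detection limit (SDL) from replicated
spike experiments: the lowest spike level at which a compound is screened
in at least a given fraction of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .features import Feature, Spectrum
from .formula import IsotopeEnvelope, isotope_envelope, ppm_error
from .library import CompoundRecord, SuspectLibrary

__all__ = [
    "ScreeningConfig",
    "MatchResult",
    "match_precursor_rt",
    "match_fragments",
    "isotope_score",
    "ms2_similarity",
    "classify_match",
    "screen_batch",
    "determine_sdl",
    "STATUS_ORDER",
]

STATUS_ORDER = {"none": 0, "screened": 1, "confirmed": 2}


@dataclass(frozen=True)
class ScreeningConfig:
    """Restriction conditions and intensity filters for identification."""

    precursor_tol: float = 5.0        # ppm, closed interval
    rt_tol: float = 0.1               # minutes, closed interval
    fragment_tol: float = 5.0         # ppm, closed interval
    min_fragments_confirm: int = 1
    isotope_score_min: float = 75.0   # strict: score must exceed this
    min_precursor_intensity: float = 5e4
    min_fragment_intensity: float = 1e3
    envelope_prune: float = 0.001     # rel. abundance floor for expected isotopes
    intensity_dev_max: float = 0.25   # max |obs-theo| rel. abundance, 0-1 scale

    def __post_init__(self) -> None:
        if min(self.precursor_tol, self.rt_tol, self.fragment_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.envelope_prune < 1:
            raise ValueError("envelope_prune must lie in (0, 1)")


@dataclass(frozen=True)
class MatchResult:
    """Identification outcome for one (compound, sample) pair."""

    compound: str
    sample_id: str
    status: str                        # none | screened | confirmed
    precursor_ppm: float = math.nan
    delta_rt: float = math.nan         # minutes
    n_fragments_matched: int = 0
    n_fragments_expected: int = 0
    isotope_score: float = math.nan    # 0-100
    isotopes_matched: int = 0
    isotopes_expected: int = 0
    ms2_similarity: float | None = None
    area: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUS_ORDER:
            raise ValueError(f"bad status {self.status!r}")
        if self.isotopes_matched > self.isotopes_expected:
            raise ValueError("isotopes_matched cannot exceed isotopes_expected")


def match_precursor_rt(
    f: Feature, c: CompoundRecord, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[bool, float, float]:
    """Precursor m/z + RT + intensity gate.

    Returns ``(passed, precursor_ppm, delta_rt)``; tolerance boundaries are
    inclusive. A polarity mismatch fails the gate without raising.
    """
    ppm = ppm_error(f.mz, c.precursor_mz)
    drt = f.rt - c.expected_rt
    if f.polarity != c.polarity:
        return False, ppm, drt
    passed = (
        abs(ppm) <= cfg.precursor_tol
        and abs(drt) <= cfg.rt_tol
        and f.intensity >= cfg.min_precursor_intensity
    )
    return passed, ppm, drt


def _greedy_assign(
    targets: Sequence[float], observed: Spectrum, tol_ppm: float, min_intensity: float
) -> list[tuple[int, int, float]]:
    """One-to-one greedy ppm assignment of observed peaks to target m/z values.

    Candidates are ranked by |ppm|, ties broken toward the lower target m/z;
    each observed peak satisfies at most one target and vice versa. Returns
    (target_index, observed_index, ppm) triples.
    """
    candidates = []
    for ti, tmz in enumerate(targets):
        for oi, (omz, ointen) in enumerate(observed):
            if ointen < min_intensity:
                continue
            ppm = ppm_error(omz, tmz)
            if abs(ppm) <= tol_ppm:
                candidates.append((abs(ppm), tmz, ti, oi, ppm))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_t: set[int] = set()
    used_o: set[int] = set()
    out = []
    for _, _, ti, oi, ppm in candidates:
        if ti in used_t or oi in used_o:
            continue
        used_t.add(ti)
        used_o.add(oi)
        out.append((ti, oi, ppm))
    return out


def match_fragments(
    ms2: Spectrum | None, c: CompoundRecord, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[int, list[tuple[float, float, float]]]:
    """Count library product ions recovered in an observed MS2 spectrum.

    A library fragment is matched when some observed peak at or above the
    product-ion intensity floor lies within the fragment ppm tolerance;
    assignment is one-to-one. Returns ``(n_matched, matches)`` with matches
    as (library m/z, observed m/z, ppm).
    """
    if not ms2 or not c.fragments:
        return 0, []
    assigned = _greedy_assign(c.fragments, ms2, cfg.fragment_tol, cfg.min_fragment_intensity)
    return len(assigned), [
        (c.fragments[ti], ms2[oi][0], ppm) for ti, oi, ppm in sorted(assigned)
    ]


def isotope_score(
    cluster: Spectrum,
    env: IsotopeEnvelope,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> tuple[float, int, int]:
    """Abundance-weighted isotope-pattern match score on a 0-100 scale.

    The observed cluster is normalized to its own base peak. A theoretical
    peak (relative abundance >= the envelope prune) is matched when an
    observed peak lies within the precursor ppm tolerance and its relative
    intensity deviates from the theoretical one by at most
    ``intensity_dev_max`` (absolute difference on the 0-1 scale). The score
    is 100 x (matched abundance) / (total theoretical abundance).
    """
    theo = [(mz, rel) for mz, rel in env if rel >= cfg.envelope_prune]
    n_expected = len(theo)
    if not cluster or n_expected == 0:
        return 0.0, 0, n_expected
    base = max(inten for _, inten in cluster)
    if base <= 0:
        return 0.0, 0, n_expected
    obs = [(mz, inten / base) for mz, inten in cluster]
    matched_ab = 0.0
    n_matched = 0
    for tmz, trel in theo:
        hit = any(
            abs(ppm_error(omz, tmz)) <= cfg.precursor_tol
            and abs(orel - trel) <= cfg.intensity_dev_max
            for omz, orel in obs
        )
        if hit:
            matched_ab += trel
            n_matched += 1
    total_ab = sum(rel for _, rel in theo)
    return 100.0 * matched_ab / total_ab, n_matched, n_expected


def ms2_similarity(
    observed: Spectrum | None, reference: Spectrum | None, tol_ppm: float = 5.0
) -> float | None:
    """Spectral-library match score on a 0-100 scale (None if either side empty).

    Peaks are ppm-aligned one-to-one (greedy, as in fragment matching) and
    the score is the NIST-style square-root-intensity dot product
    ``(sum sqrt(Io*Ir))^2 / (sum Io * sum Ir)`` — the squared cosine of the
    sqrt-intensity vectors — scaled to 100. Identical spectra score 100;
    spectra with no aligned peaks score 0.
    """
    if not observed or not reference:
        return None
    assigned = _greedy_assign([mz for mz, _ in reference], observed, tol_ppm, 0.0)
    dot = sum(
        math.sqrt(reference[ti][1] * observed[oi][1]) for ti, oi, _ in assigned
    )
    denom = sum(i for _, i in observed) * sum(i for _, i in reference)
    if denom <= 0:
        return 0.0
    return 100.0 * dot * dot / denom


def _envelope_for(c: CompoundRecord, cfg: ScreeningConfig,
                  cache: dict[str, IsotopeEnvelope] | None = None) -> IsotopeEnvelope:
    if cache is not None and c.name in cache:
        return cache[c.name]
    env = isotope_envelope(c.formula, c.adduct, prune=cfg.envelope_prune)
    if cache is not None:
        cache[c.name] = env
    return env


def classify_match(
    f: Feature | None,
    c: CompoundRecord,
    cfg: ScreeningConfig = ScreeningConfig(),
    _env_cache: dict[str, IsotopeEnvelope] | None = None,
) -> MatchResult:
    """Full tiered classification of one candidate feature against one compound.

    ``screened`` requires the precursor/RT/intensity gate; ``confirmed``
    additionally requires enough matched product ions and an isotope score
    strictly above the threshold. All sub-scores are recorded regardless of
    the resulting tier. ``f=None`` yields a ``none`` result with empty
    metrics.
    """
    if f is None:
        return MatchResult(compound=c.name, sample_id="", status="none")
    passed, ppm, drt = match_precursor_rt(f, c, cfg)
    env = _envelope_for(c, cfg, _env_cache)
    n_frag, _ = match_fragments(f.ms2, c, cfg)
    iso, n_iso, n_iso_exp = isotope_score(f.isotope_cluster, env, cfg)
    sim = ms2_similarity(f.ms2, c.reference_ms2, cfg.fragment_tol)
    if not passed:
        status = "none"
    elif n_frag >= cfg.min_fragments_confirm and iso > cfg.isotope_score_min:
        status = "confirmed"
    else:
        status = "screened"
    return MatchResult(
        compound=c.name,
        sample_id=f.sample_id,
        status=status,
        precursor_ppm=ppm,
        delta_rt=drt,
        n_fragments_matched=n_frag,
        n_fragments_expected=len(c.fragments),
        isotope_score=iso,
        isotopes_matched=n_iso,
        isotopes_expected=n_iso_exp,
        ms2_similarity=sim,
        area=f.area,
    )


def screen_batch(
    features: Sequence[Feature],
    lib: SuspectLibrary,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> list[MatchResult]:
    """Screen every library compound in every sample of a feature batch.

    For each (sample, compound) pair the best candidate among features
    passing the precursor/RT gate is reported — smallest |ppm|, ties broken
    by smallest |delta RT| then by larger area — so exactly one MatchResult
    per pair is emitted; pairs with no passing feature yield status ``none``.
    """
    by_sample: dict[str, list[Feature]] = {}
    for f in features:
        by_sample.setdefault(f.sample_id, []).append(f)
    env_cache: dict[str, IsotopeEnvelope] = {}
    results: list[MatchResult] = []
    for sample_id in sorted(by_sample):
        sample_features = by_sample[sample_id]
        for c in lib:
            best: tuple[float, float, float] | None = None
            best_f: Feature | None = None
            for f in sample_features:
                passed, ppm, drt = match_precursor_rt(f, c, cfg)
                if not passed:
                    continue
                key = (abs(ppm), abs(drt), -f.area)
                if best is None or key < best:
                    best, best_f = key, f
            if best_f is None:
                results.append(
                    MatchResult(compound=c.name, sample_id=sample_id, status="none")
                )
            else:
                results.append(classify_match(best_f, c, cfg, env_cache))
    return results


def determine_sdl(
    detections: Mapping[float, Sequence[bool]],
    detect_fraction_min: float = 0.95,
) -> float | None:
    """Screening detection limit from replicated spike outcomes.

    ``detections`` maps spike level (ug/kg) to per-replicate booleans
    (screened or better). The SDL is the lowest level whose detection
    fraction reaches ``detect_fraction_min``; None when no level qualifies.
    All levels must carry the same replicate count.
    """
    if not detections:
        return None
    counts = {len(v) for v in detections.values()}
    if len(counts) != 1 or 0 in counts:
        raise ValueError("all spike levels must have the same non-zero replicate count")
    for level in sorted(detections):
        reps = detections[level]
        if sum(bool(d) for d in reps) / len(reps) >= detect_fraction_min:
            return level
    return None
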