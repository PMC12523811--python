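# Methods

## Scope and model

`residuescreen` implements the data-analysis half of a magnetic-QuEChERS /
UHPLC-Orbitrap multi-residue workflow: suspect screening of pesticide and
veterinary-drug residues against a self-built library, followed by
matrix-matched quantitation and full method validation. Everything
upstream of a centroided feature table — extraction chemistry, sorbent
synthesis, chromatography, peak picking — is out of scope; the engine
consumes features (m/z, RT, area, height, isotope cluster, optional MS2)
and a library (formula, adduct, expected RT, product-ion m/z list).

## Isotope envelopes

Theoretical envelopes are computed by exact convolution of per-element
isotopologue distributions, indexed by neutron excess above the lightest
isotope. Per element, the n-atom distribution is obtained by binary
exponentiation of the single-atom distribution; element distributions are
then convolved together. Alongside each aggregate's probability we carry
its probability-weighted mass, so the reported m/z is the
abundance-weighted centroid of the fine structure it contains.

Aggregation by neutron count (rather than resolved fine structure) matches
what a 120k-FWHM Orbitrap full scan actually shows: the ~2 mDa splitting
between a one-¹³C and a one-³⁷Cl isotopologue at m/z ≈ 500 is unresolved,
and the instrument centroids the composite peak. Fine-structure envelopes
and |z| > 1 species are non-goals (the screen covers small molecules at
m/z 100–900 as singly charged adducts).

Isotope masses and abundances are a bundled CSV (NIST values) frozen in
the repository, so envelopes are bit-reproducible regardless of upstream
library updates. Ion envelopes are built from the adduct-adjusted formula
(e.g. +H for [M+H]⁺) with the electron mass applied, using the standard
proton-mass convention (1.007276 Da) required for ±5 ppm work.

**Abundance floor.** The user-facing prune defaults to 0.001 (0.1 % of the
base peak). This is the floor at which the two benchmark residues carry
their reported isotope counts — protonated chlorantraniliprole
(C₁₈H₁₅BrCl₂N₅O₂⁺) has exactly nine reportable peaks and protonated
erythromycin (C₃₇H₆₈NO₁₃⁺) exactly five — consistent with vendor-software
isotope counting at typical Orbitrap dynamic range. At a 1 % floor those
envelopes would carry only eight and four peaks. The floor is a config
field (`ScreeningConfig.envelope_prune`), not a constant. An internal
floor of 10⁻¹⁵ relative merely guards against denormal accumulation and is
far below anything matchable.

## Matching and tiers

* Precursor gate: |ppm| ≤ 5, |ΔRT| ≤ 0.1 min, intensity ≥ 5×10⁴. Tolerance
  boundaries are closed (a feature at exactly 5 ppm passes), mirroring the
  "±" reading of the restriction conditions; the isotope-score threshold
  (75) is strict, mirroring "higher than".
* Fragment gate: a library product ion is matched when an observed MS2
  peak ≥ 10³ lies within ±5 ppm; assignment is one-to-one, greedy by
  smallest |ppm| with ties to the lower target m/z. One matched product
  ion suffices for confirmation by default (`min_fragments_confirm`),
  the weakest defensible reading; set 2 for SANTE-style strictness.
* Isotope score: observed cluster normalized to its own base peak; an
  expected peak is matched when an observed peak lies within the precursor
  ppm tolerance and its relative intensity deviates by ≤ 0.25 (absolute,
  0–1 scale). Score = 100 × matched abundance / total expected abundance.
  This abundance weighting makes the score robust: missing the A+8 peak of
  a BrCl₂ compound costs ~0.2 points, missing A+2 costs ~19.
* MS2 library similarity (optional, reported but not gated): the
  square-root-intensity dot product (Σ√(I_o·I_r))²/(ΣI_o·ΣI_r) × 100 —
  the squared cosine of the √-intensity vectors, the classic library-search
  form. Identical spectra score 100; an observed spectrum containing one
  of two equal reference peaks scores 50.
* Batch rule: per (sample, compound) the best gate-passing feature wins —
  smallest |ppm|, then smallest |ΔRT|, then larger area — so outputs are
  deterministic regardless of input order.

## Validation logic

* **SDL**: lowest spike level screened in ≥ 95 % of replicates. The
  replicate pass-fraction is not standardized anywhere in the source
  conditions (the design is 5 levels × 20 replicates); 95 % follows common
  screening-validation practice and is a parameter
  (`detect_fraction_min`).
* **LOQ**: lowest calibration level that is simultaneously confirmed,
  recovers 60–120 % on average, and shows RSD ≤ 20 % over ≥ 3 replicates.
  The 60–120 % band is the level-wise gate; reported per-compound means
  may legitimately fall slightly outside it at other levels.
* **Calibration**: unweighted OLS of area on concentration (R² as 1 −
  SS_res/SS_tot). 1/x weighting is deliberately not applied — the
  reference curves are plain linear fits — but the fit function accepts
  any point set, so weighted schemes can be layered on top.
  Back-calculation flags rather than suppresses: areas below the intercept
  report 0 µg/kg with `below_curve`; concentrations outside the calibrated
  range are flagged `extrapolated` (real surveillance samples exceed top
  standards; a 1184 µg/kg hit on a 1–50 curve is still information).
* **Matrix effect**: ME(%) = 100·B/A (matrix-matched over solvent area at
  equal concentration). Bands closed on the negligible side: 80 and 120
  are negligible, 50 and 150 moderate, strictly beyond is strong.
* **Percentages** (removal rates, in-range fractions) are reported at one
  decimal, matching the convention of validation reports; full precision
  is kept internally.

## Synthetic data

The generator produces the study conditions the analysis assumes:

| parameter | default | rationale |
| --- | --- | --- |
| mass error σ | 1 ppm | externally calibrated 120k-FWHM Orbitrap |
| RT jitter σ | 0.02 min | UHPLC stability well inside the ±0.1 min window |
| area noise CV | 5 % | multiplicative lognormal; areas are positive and heteroscedastic |
| ME factor | 1.0 | per-compound multiplier; matrix points carry it, solvent points do not |
| fragment dropout | 0 | probability a product ion is absent from the dd-MS² spectrum |

Spike designs follow the validation protocol: SDL from 0.5/1/2/5/10 µg/kg
× 20 replicates; calibration from the 1–200 µg/kg standard series
restricted to each compound's declared linear range; recoveries at LOQ,
2×LOQ and 20×LOQ with n = 3. Replicate r of level index l derives its RNG
from `SeedSequence([base_seed, l, r])`, so any table regenerates in
isolation and runs are bit-reproducible.

Peak areas follow each compound's calibration line. A consequence worth
knowing: compounds whose fitted intercept is strongly negative produce no
signal at low spike levels (the line crosses zero above the spike), and
compounds with very shallow slopes fall below the 5×10⁴ intensity trigger
— both emulate below-detection behavior and give the SDL/LOQ machinery
something real to decide. True instrument noise magnitudes for the source
conditions are unreported; the defaults above are stated assumptions, all
configurable.

Not emulated: chromatographic peak shape, co-eluting isobaric
interference, detector saturation, matrix-dependent fragmentation.
Passing tests therefore demonstrate that the decision logic is correct
under the stated noise model, not that real extracts behave this simply.

## Bundled panel

`data/residue_panel.csv` is a reconstructed 121-compound quality-control
panel (63 pesticides, 58 veterinary drugs): calibration slopes/intercepts,
R², linear ranges, SDLs and LOQs transcribed from a published
leafy-vegetable validation table; elemental formulas from standard
structure references; retention times and fragment m/z synthetic,
generated once and frozen. It is not the original authors' library file.
The SDL column reproduces the published level distribution (87 compounds
at 1 µg/kg, 21 at 2, 13 at 5).

## Numerical choices and degenerate inputs

* Envelope convolution is exact (no sampling); equivalence with exhaustive
  isotopologue enumeration is tested to 1e-9 in abundance and 1e-6 Da in
  mass for small formulas, and element processing order is immaterial to
  1e-12.
* The envelope centroid of the monoisotopic aggregate and the directly
  summed monoisotopic mass agree only to float rounding (~1e-10 Da);
  "exact" pipeline checks therefore use a 1e-6 ppm tolerance rather than
  bit equality.
* Degenerate calibration designs (fewer than 3 distinct levels) and
  ragged SDL replicate sets raise; empty MS2 spectra and empty clusters
  yield zero scores rather than errors; polarity mismatches fail matching
  without raising.
* Ties in fragment assignment resolve toward the lower target m/z; ties
  in batch screening toward larger area — both purely for determinism.

## Known limitations

* Confirmation requires library product ions; compounds without fragments
  can never exceed the screened tier (flagged by `validate_library`).
* The isotope-score formula is this package's own re-specification of an
  unpublished vendor score; it reproduces the boundary behaviors (identical
  cluster → 100, meaningful 75 threshold) but is not a reverse-engineered
  Trace Finder implementation.
* Regulatory MRL handling is a passthrough column, not a rules engine.
* mzML ingestion is out of scope; upstream tools should export the
  documented feature-table CSV + MGF dialect.
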