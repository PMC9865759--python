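# Methods

This note documents the models, formulas and design choices behind
`toxscreen`: what each module computes, which parameters matter, what the
simulator does and does not emulate, and the numerical conventions.

## Mass and isotope arithmetic (`chem`)

Accurate masses and isotopic abundances come from an embedded, versioned
element table (`data/elements.json`, CIAAW representative isotopic
composition).  Monoisotopic mass is the sum of most-abundant-isotope
masses.  Protonation and deprotonation add/subtract the **proton** mass
1.00727646677 Da — not the hydrogen-atom mass — which is what makes
computed [M+H]⁺ values agree with instrument software to 5 decimals.
Only [M+H]⁺/[M−H]⁻ singly charged species are supported; other adducts,
multiple charging and in-source fragments are out of scope.

Isotope patterns are computed by convolving elemental isotope vectors
(binary powering per element, abundance pruning at 1e-10) and then
aggregating to unit-mass bins: at 35,000 FWHM (the MS1 resolving power the
engine assumes) fine structure within a nominal mass is not resolved, so
each bin is centroided at its abundance-weighted mean m/z.  Patterns are
normalised to base peak 100 and truncated at 8 peaks / 0.1 % by default.
Formulas are flat element–count strings (no parentheses, charges or
isotope brackets); deuterated internal standards use the explicit `D`
token.

## Scan model and mzML (`spectra_io`)

Retention time is stored in **seconds** internally; minutes appear only in
reports and the MSP `RT` field.  The engine is centroid-only: profile-mode
spectra are rejected on read rather than centroided.  Polarity-switching
runs are a single scan list with per-scan polarity; matching filters scans
by the library entry's polarity.

mzML writing emits a minimal standard-conformant document (64-bit
little-endian uncompressed arrays); the reader is a streaming parser that
understands the controlled-vocabulary terms the engine needs, plus 32-bit
and zlib-compressed arrays, and is gzip-transparent.  Round trips preserve
m/z and intensity to better than 1e-6 relative.

## Library (`speclib`)

An entry stores name, formula, polarity, precursor m/z, optional retention
time, a formula-derived isotope pattern and the reference MS/MS spectrum as
relative intensities (base peak 100).  Entries validate that the declared
precursor lies within 5 ppm of the computed adduct m/z.

The canonical on-disk format is a JSON dialect; MSP is supported for
interchange (it has no standard slot for isotope patterns, which are
recomputed from the formula on import).  MSP records that fail to parse are
routed to a rejects report instead of being dropped silently.

The fixture library contains the six isomeric pairs used to demonstrate
specificity.  Reference spectra include the precursor survivor as a regular
peak alongside the five fragment ions, with intensities normalised so the
largest peak is 100 — for morphine-type compounds that largest peak *is*
the survivor.

## Peak detection (`detect`)

XICs sum all MS1 peak intensities inside the ±tol ppm window per scan
(zero when empty) and carry the per-scan intensity-weighted m/z.  Peak
detection grows candidate local maxima into contiguous regions above
baseline + 2σ (minimum 3 points), re-estimates baseline (median) and noise
σ (1.4826 × MAD) from the off-peak remainder, and scores
S/N = (apex − baseline)/σ.  On zero-inflated traces where the off-peak MAD
degenerates to zero, σ falls back to the MAD of the non-zero off-peak
samples; a trace with no off-peak variation at all yields S/N = ∞, i.e. a
noiseless detection.  Area is a plain trapezoid over the raw points of the
region — no smoothing, for determinism.  S/N is scale-invariant and area
and height scale linearly with intensity.

The "signal-to-noise threshold of 10 a.u." of the original processing
parameters is interpreted as a dimensionless ratio of 10.

## Identification engine (`ident`)

Defaults are the published operating point: 5 ppm precursor tolerance,
10 mmu fragment tolerance, ≥1 fragment at ≥5000 a.u., 60 s RT window with
"ignore if not defined", isotope fit ≥70 at 5 ppm / 30 % deviation,
SI ≥ 500, RSI ≥ 600, library score ≥ 20, S/N ≥ 10.

**Precursor.**  Among detected XIC peaks, the peak nearest the entry's
retention time is evaluated when an RT is defined (co-eluting isomers share
the XIC; the tallest peak may belong to the partner), otherwise the
tallest.  The reported mass error is the ppm difference between the
intensity-weighted observed m/z and the library precursor.

**MS2 scan selection.**  Candidate scans are DDA spectra whose precursor
annotation lies inside the precursor ppm window and whose RT falls within
the detected peak bounds (± one MS1 cycle).  SI/RSI are taken from the scan
with the highest SI (ties → earlier scan).  Fragment *presence* may be
satisfied by any candidate scan: the 5000 a.u. floor is absolute and
favours near-apex scans, whereas SI is intensity-normalised and indifferent
to them.

**Match factors.**  Both spectra first drop peaks within 2 × fragment
tolerance of the precursor ("ignore precursor").  Peaks are weighted
w = I^0.6·(m/z)³ (the classic identity-search weighting) and paired
greedily by nearest m/z within tolerance, each peak used once, ties toward
the higher intensity product.  Each matched product in the cosine is
damped by the pair's intensity consistency min(r_q/r_l, r_l/r_q)^0.5 on
the base-100 relative intensities: without this, the m/z³ weight lets an
m/z coincidence between a trace peak (≤1 % of base) and a partner's major
fragment dominate the score, which is exactly the failure mode
isomer-pair discrimination must avoid.  With C that consistency-damped
weighted cosine, R = (1 + Σ min(yᵢ, 1/yᵢ))/N_m the adjacent-pair
intensity-ratio consistency, N_q query peaks and N_m matched pairs:

    SI  = 999 · (N_q·C² + N_m·R) / (N_q + N_m)
    RSI = 999 · (C_rev² + R) / 2

where C_rev restricts the query norm to matched peaks.  Self-match gives
999/999; disjoint spectra 0/0; a query that is a superset of the library
keeps RSI at 999 while SI drops.  These formulas are this module's own,
frozen by its tests; the published thresholds are applied to them, but
score-for-score parity with commercial software is not claimed.  The
"library score" threshold (20) is applied to SI; the hit-probability
threshold of the original setup needs a full commercial-library hit
distribution and is not evaluated.

**Isotope fit.**  For each predicted isotopologue ≥5 % relative intensity,
the observed MS1 spectrum at the peak apex is searched within 5 ppm.  After
normalising both patterns to base 100, per-peak deviations in percentage
points are capped at the 30 % tolerance (unmatched peaks count the full
cap; an unmatched base peak zeroes the score) and

    fit = 100 · (1 − mean(min(dᵢ, 30))/30).

**Decision.**  identified = all three major criteria; minor criteria are
reported and never veto (an entry with a wrong RT but matching spectrum is
still identified — the RT column flags it for review).

## Simulator (`simulate`)

The simulator generates what the engine consumes, not instrument physics:

- MS1 full scans every 0.5 s (the real cycle time is not published; this is
  a free parameter) over m/z 70–1000 for a 915 s gradient by default.
- Each spiked compound elutes as a Gaussian (FWHM 6 s) centred at its
  library RT with apex intensity = concentration × response factor
  (default 1000 a.u. per µg/L — linear, no saturation).  Its isotope
  pattern is emitted with 1 ppm truncated-Gaussian m/z jitter so 5 ppm
  windows capture essentially all true peaks.
- Noise: additive Gaussian intensity noise (σ = 200 a.u., clipped at 0) on
  signal peaks, chemical background at every inclusion-list channel (so
  XICs have a realistic noise floor), uniform random noise peaks, and 20
  random matrix pseudo-compounds with log-normal apex intensities and
  random fragment sets.
- DDA: after each MS1 scan the top-3 most intense inclusion-list ions above
  1000 a.u. are fragmented, with 3 s dynamic exclusion per target.  MS2
  spectra are the library reference spectra scaled to the precursor's
  momentary intensity with multiplicative log-normal noise (σ = 0.05), a
  100 a.u. centroid floor, and co-isolation mixing across the 2 m/z
  isolation window — closely co-eluting isomers produce mixed spectra.
- Ionisation suppression and extraction losses are modelled by scaling the
  response factor (e.g. 0.12 for a strongly suppressed biguanide-like
  compound).
- One seeded generator drives every draw: a fixed seed reproduces a run
  bit for bit.  Dilution series derive per-(level, replicate) seeds
  deterministically from the base seed.

What this does **not** emulate: chromatographic retention prediction, peak
asymmetry and tailing, fragment-intensity dependence on collision energy,
AGC/injection-time dynamics, detector saturation, and real biological
matrix composition.  Consequently, passing tests demonstrate the
*processing logic* — criteria, thresholds, scores, statistics — not
instrument-level figures of merit; simulated LOIs and matrix effects are
properties of the simulator's response model, not predictions for real
plasma.

## Validation statistics (`validate`)

Matrix effect (spiked-after/neat), recovery (spiked-before/spiked-after)
and process efficiency (spiked-before/neat) are computed
replicate-pairwise — ratio of replicate *i* to replicate *i*, then mean and
RSD (sd/mean, ddof 1) — matching the paired two-set design (n = 6) and
preserving PE = ME × RE as an exact algebraic identity per replicate.
Internal-standard normalisation is deliberately outside these ratios.

The limit of identification is the lowest level of an ascending ladder at
which **all** replicates meet the three major criteria, with a configurable
guard requiring all higher levels to pass too (protects against
non-monotone flukes in simulation).  Spectra reproducibility is the mean
and RSD of the library score (SI) across replicate runs.

`run_validation_campaign` orchestrates the whole design over a compound
panel: per-condition response factors (neat / post-extraction spike /
pre-extraction spike), replicate simulation, area extraction (detected
peak area near the library RT, falling back to window integration at low
signal so area tables stay complete), the three ratio tables at the
configured levels (both 50 and 500 µg/L are reported, not pooled), the LOI
ladder and reproducibility table.

## Problem sizes and tolerances

The test suite and acceptance script use a 420 s gradient (covering the
fixture's latest eluter at 6.42 min), 200 µg/L spikes for
discrimination/selectivity checks, 3 replicates per level for campaign
checks and a 4-level LOI ladder — sizes chosen so the whole suite runs in
well under a minute while every decision path is exercised.  Printed-mass
checks are exact at 5 decimals; window checks exact at the printed digits;
the PE = ME × RE identity is asserted at 1e-9; mzML round trips at 1e-6
relative.

## Known limitations

- Score formulas are documented surrogates for proprietary ones; absolute
  score values are comparable only within this package.
- Only ±H adducts, single charge, no fine isotope structure.
- No co-elution deconvolution inside one XIC window: co-eluting isomers
  closer than the peak width are separated only by their MS/MS evidence.
- The MSP dialect covers NIST-style Name/Formula/PrecursorMZ/RT/Num Peaks
  records; exotic field variants are routed to the rejects report.
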