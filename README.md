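# toxscreen

Non-targeted drug screening for clinical and forensic toxicology by liquid
chromatography coupled to high-resolution mass spectrometry (LC–HRMS).

Toxicology laboratories screen blood and plasma for hundreds of drugs at
once by acquiring full-scan HRMS data plus data-dependent MS/MS (DDA) and
matching every detected ion against a curated spectral library.  `toxscreen`
implements that workflow as open, testable software: the compound library
with HR–MS/MS reference spectra, the identification engine with its
major/minor criteria, a DDA run simulator that generates realistic spiked
acquisitions for testing, and the guideline validation statistics (matrix
effect, recovery, process efficiency, limit of identification, spectra
reproducibility).

It is aimed at laboratory scientists and method developers who want a
transparent re-implementation of the screening logic usually locked inside
vendor software, and at developers who need reproducible synthetic LC–HRMS
fixtures.

## The identification model

A compound is **identified** when all three *major* criteria hold:

1. **Precursor presence** — the extracted-ion chromatogram (XIC) at the
   library precursor *m/z*, within ±5 ppm, contains a chromatographic peak
   with S/N ≥ 10.  Noise is 1.4826 × MAD of the off-peak XIC.
2. **Fragment ions** — at least one library fragment is matched in a DDA
   MS2 scan within 10 mmu at ≥ 5000 a.u.
3. **Library spectrum match** — forward search index SI ≥ 500, reverse
   search index RSI ≥ 600, and library score ≥ 20 against the reference
   spectrum.

Retention time (±60 s, "ignore if not defined") and isotope-pattern fit
(threshold 70, ±5 ppm, 30 % intensity deviation) are *minor* criteria:
reported, never vetoing.

SI/RSI are match factors on a 0–999 scale.  With peak weights
*w* = *I*^0.6 · (*m/z*)³ and greedy pairing inside the fragment tolerance,

    SI  = 999 · (N_q · C² + N_m · R) / (N_q + N_m)

where *C* is the weighted cosine between the paired spectra (each matched
product damped by the pair's intensity consistency, so an m/z coincidence
between peaks of very different relative abundance cannot dominate), *R*
is the intensity-ratio consistency of adjacent matched peaks, *N_q* the
number of query peaks and *N_m* the number of matched pairs; the reverse
index RSI ignores query peaks absent from the library spectrum.  Peaks within 2 ×
fragment tolerance of the precursor are excluded ("ignore precursor").

The built-in fixture library holds twelve compounds forming six isomeric
pairs that share their precursor *m/z* exactly (e.g. tramadol and
*O*-demethylvenlafaxine at 264.19581): precursor mass alone cannot separate
them, the MS/MS spectrum match does.

## Worked example

Build the fixture library, simulate a plasma run spiked with tramadol at
200 µg/L, and screen it:

```
$ toxscreen lib build-fixture fixture.json
wrote fixture.json (12 entries)

$ toxscreen simulate --library fixture.json --spike "Tramadol:200" \
      --out . --sample-id spiked --seed 4 --gradient-length 420
wrote ./spiked.mzML (846 scans)

$ toxscreen screen spiked.mzML --library fixture.json --out .
spiked: 1 identified of 12 library entries
```

The JSON/TSV report ranks tramadol first and shows the evidence per
criterion:

| compound | identified | RT (min) | Δm (ppm) | SI | RSI | isotope fit |
|---|---|---|---|---|---|---|
| Tramadol | yes | 4.4167 | −0.252 | 964 | 964 | 99.9 |
| O-Demethylvenlafaxine | no | 4.4167 | −0.252 | 500 | 500 | 99.9 |

*O*-demethylvenlafaxine shares the exact precursor mass, so its precursor,
retention-time (4.13 vs 4.42 min, inside the 60 s window) and isotope
criteria all pass — but the MS/MS spectrum match fails (RSI 500 < 600), so
it is not identified.  That is the isomer-discrimination behaviour the
method is built around.

The same workflow is available as a library API (`build_fixture_library`,
`simulate_run`, `identify`, `run_validation_campaign`, …) — see
`docs/methods.md` for the model details and parameter meanings.

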