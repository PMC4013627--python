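# Methods

## Mass and composition conventions

All ion arithmetic uses the proton-adduct convention m/z = (M + z·m_p)/z with
m_p = 1.0072765 Da and no separate electron-mass bookkeeping; reporter and
precursor values printed at 4 and 2 decimals respectively match this
convention. Isotope masses and natural abundances are pinned in-code from the
standard IUPAC/NIST compilation (H, C, N, O, S), so results are stable and
need no downloads. Stable-isotope labels are fixed-isotope pseudo-element
tokens (`N15`, `C13`, `H2`, `O18`) carrying a single mass at abundance 1;
the nitro modifications are composition add/remove pairs (+N+2O, −H on Y for
the light form; +¹⁵N+2O, −H for the heavy form), so the heavy−light spacing
is exactly m(¹⁵N) − m(¹⁴N) = 0.9970349 Da and isotope patterns of modified
species are exact rather than mass-shifted approximations.

Fragment conventions: b = residue sum, y = residue sum + H₂O, a = b − CO,
immonium = residue − CO, each protonated per the formula above.
Modifications travel with the fragment containing the modified position.

## Isotope fine structure

`fine_structure` expands each element's multinomial isotope distribution by
iterated convolution and convolves across elements, pruning species below
`prune_below` of the base peak (default 10⁻⁶; intermediate pruning is three
orders stricter to avoid edge loss, and `prune_below = 0` requests the exact
unpruned expansion) before renormalising to unit total abundance.
Isotopologue masses are binned at 10⁻⁹ Da; distinct fine-structure species
(e.g. ¹³C₁ vs ¹⁵N₁ at nominal A+1, 0.00632 Da apart) are never merged.

Derived interference constants for the light reporter cation C₈H₉N₂O₃⁺:

- f(¹⁵N₁) = 2·(0.003642/0.996358) ≈ 0.0073 of the monoisotopic height —
  exactly isobaric with the heavy reporter, never resolvable;
- f(¹³C₁) = 8·(0.0107/0.9893) ≈ 0.0865 — sits 0.00632 Da above the heavy
  reporter and is resolved at sufficient resolution.

## Peak shape and resolution criteria

Peaks are Gaussians with FWHM = m/R (resolution read at the peak's own m/z).
An `orbitrap_sqrt` mode, FWHM = m/(R·√(400/m)), is provided for instruments
whose resolution is quoted at m/z 400; the default is `at_peak` because the
resolution statements the method rests on ("≥50,000", ">400,000") are read at
the stated m/z. Lorentzian/Voigt shapes are not modeled — the argument is
made purely in FWHM terms.

"Separated" is not uniquely defined, so two named criteria are exposed:
`two_maxima` (the summed profile shows two distinct local maxima) and
`valley` (additionally the minimum between them is at most a fraction,
default 0.10, of the smaller apex). Profiles are sampled at min(FWHM)/50
over the sticks ± 5 FWHM; a user-supplied grid step coarser than FWHM/10 is
rejected. `min_resolution` either evaluates an explicit resolution grid
(smallest satisfying member) or bisects on log R to 3 significant figures,
raising for doublets not separable by R = 10⁷.

Doublet intensities for the precursor case default to (1.0 heavy
monoisotopic, 0.67 light ¹³C₁), the ¹³C₁ fraction of the 62 carbons of
nitrated angiotensin I at a 1:1 mixture; both are overridable. For the
reporter-region doublet at a 1:1 mixture the satellite is 0.087 of the
heavy peak. The resolution grid {15,000, 30,000, 50,000, 120,000, 240,000}
mirrors typical FT instrument settings; it is a stated choice of this
package.

## Detection and quantitation

`find_reporter_pair` matches each reporter target to the most intense peak
within ±tolerance (default 10 ppm; ties broken by smaller |ppm error|). The
light ¹³C satellite lies ~35 ppm above the heavy target, so the default
window rejects it by an order of magnitude. Heavy-only hits (no light
channel) are retained as identifications with undefined ratio — the heavy
reporter alone is a diagnostic marker for nitration sites. Diagnostic
chromatograms sum, per MS2 scan, the intensity inside a narrow window
(default ±0.001 Da) around a marker m/z.

Per-scan ratios use peak heights, not areas. Corrections:

- `n15` (default on): I_heavy_corrected = I_heavy − f(¹⁵N₁)·I_light. Always
  raises the ratio, by the factor 1/(1 − f·r_raw) at raw ratio r_raw; scans
  whose corrected heavy intensity is non-positive are flagged invalid,
  logged, and excluded from aggregation.
- `c13` (default off): additionally subtracts the Gaussian leakage of the
  light ¹³C satellite into the heavy channel,
  f(¹³C₁)·I_light·exp(−4 ln2 (δ/FWHM)²) at the scan's resolution setting. At
  R = 120,000 this is ~10⁻²¹ of the satellite — numerically nil; the option
  exists to make that negligibility checkable rather than asserted.

Grouping is single-linkage over precursor m/z (ppm tolerance, with the exact
0.9970349/z heavy−light offset allowed as a link, so scans triggered on
either pair member merge), then split at retention-time gaps (default 0.5
min). Aggregation reports the unweighted mean and sample SD of valid scan
ratios (scan-to-scan variability); an intensity-weighted mean is available
by flag. Normalisation divides a condition group's mean by the matched
reference group's mean, with first-order SD propagation assuming
independence. Normalising per scan before averaging gives the same mean (it
is a linear rescaling), so only the aggregate order is implemented.

## The synthetic generator

`generate_run` emulates the targeted acquisition regime: survey scans over
m/z 400–2000 at a nominal 240,000 resolution, MS/MS at 120,000 on the top 3
precursors per cycle with a 5 m/z isolation window, 30 s dynamic exclusion
after one repeat, 3 s cycle time. Species elute as Gaussians (σ = 0.15 min
for the fixture nitropeptides); MS1 carries the monoisotopic plus two
aggregated isotope sticks per species; MS2 sums singly charged b/y fragments
(flat base intensity) of every species whose monoisotopic precursor falls in
the isolation window, plus the nitrotyrosine reporter at a higher yield
reflecting its strong immonium production under beam-type fragmentation.
Reporter intensities are proportional to species abundances, so noise-free
per-scan ratios equal the mixing ratio exactly; an `isotope_interference`
flag additionally plants the light reporter's ¹⁵N and ¹³C satellites for
exercising the corrections. Noise (all seeded): 1.5 ppm Gaussian m/z jitter,
8% log-normal multiplicative intensity noise, 30 exponential background
peaks per MS2 scan drawn uniformly in m/z but excluding ±0.02 Da around the
reporters (an adversarial mode instead plants decoys 0.01–0.05 Da from the
reporters to stress tolerance logic). The manifest records, per MS2 scan,
the true contributing species and true pre-noise reporter intensities.

`table1_fixture` builds the five-run mixing design — a 1:1 reference, three
0.25:1 replicates with distinct seeds, one 0.10:1 — each containing the two
BSA nitropeptides Y*LYEIAR (+2, RT 2.0 min) and Y*IC(cam)DNQDTISSK (+2, RT
4.0 min) as co-eluting light/heavy pairs over a 6-minute run, with three
unmodified background peptides competing for selection. The 6-minute length
and these elution parameters are this package's desk-scale design: they
yield ~12 quantifiable scans per nitropeptide per run, enough for stable
scan-to-scan statistics while keeping simulation cheap.

What the generator does *not* emulate: real chromatographic peak shapes
(tailing), charge-state envelopes beyond three isotope sticks, collision-
energy-dependent fragment intensities, co-eluting isobaric interference, or
detector saturation. Passing recovery tests therefore demonstrates the
correctness of the detection/correction/aggregation logic under the stated
acquisition geometry and noise, not performance on real matrices.

## Numerical and degenerate-input choices

- Spectra must be centroided, strictly ascending in m/z; profile input is
  flagged and can be centroided by local-maximum picking with 3-point
  parabolic apex refinement.
- mzML is written as indexed mzML 1.1.0 with uncompressed 64-bit float
  arrays, so write→read round-trips are bit-identical; reading accepts
  zlib-compressed and 32-bit arrays and normalises retention times to
  minutes.
- Empty runs, empty spectra, and empty hit sets flow through as empty
  outputs with warnings, not errors; a missing reference when normalisation
  is requested is an error before any I/O.
- Ratio-correction floor: corrected heavy intensity must exceed 10⁻¹²
  (guards division blow-ups from over-correction).
- All randomness flows from a single integer seed per run; fixture runs
  derive per-run seeds as (seed·10 + k) mod 2³¹.

## Known limitations

- Quantitation is MS/MS-level only; full-scan (MS1) doublet quantitation is
  out of scope because the precursor doublet needs >400,000 FWHM resolution
  (the package computes this bound but does not attempt MS1 quantitation).
- No peptide-spectrum matching, database search, FDR control, or de novo
  sequencing: identification beyond the reporter-ion filter is delegated to
  external search engines.
- a₁ and internal immonium ions of N-terminal nitrotyrosine are not
  distinguished; both appear at the reporter m/z and are treated as one.
- The ppm tolerance for "high mass accuracy" detection is a package default
  (10 ppm), chosen to sit ~3× above realistic FT mass error while rejecting
  the 35-ppm-distant ¹³C satellite.
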