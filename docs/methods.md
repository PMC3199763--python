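# Methods

This note documents the models, numerical choices and defaults behind
`vocbin`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Retention-index model

Retention times drift over months of column use (seconds per month, more
after a column change), so positions are expressed on a retention-index
grid defined by a spiked C4–C24 fatty acid methyl ester (FAME) series.
FAMEs are used instead of n-alkanes because their electron-ionisation
fragments (the McLafferty ion m/z 74 and m/z 87) allow unambiguous
automated detection. The FAME RI scale is deliberately distinct from
Kovats units: RI(C4) = 262,214 and RI(C24) = 980,934, with alkane-scale
equivalents 726 and 2712. Only these four anchor constants are
authoritative; the intermediate marker RI values (C6–C22) in the default
table interpolate linearly in chain length and are placeholders meant to
be overridden from an instrument marker file, as is the nominal
elution-time grid used for inter-marker offsets.

### Marker location

No retention-time prior is used to find the markers. Peaks whose base
peak is in {74, 87} form the candidate set; the candidate/marker pair
with the highest spectral similarity fixes the anchor, and the remaining
markers are assigned walking outward in RT, each step referenced to the
nearest already-assigned marker plus the expected inter-marker offset
(tolerance ±15 s), gated at similarity ≥ 700/1000. The outward walk
tracks slowly accumulating drift; the tolerance is wide relative to
observed drifts (~3 s) but narrow relative to marker spacing (≥40 s).

### Curve fitting

With all 12 markers found, the RT→RI map is piecewise: an exact line
through markers 1–2 (evaluated for rt ≤ rt₂), an exact line through
markers 11–12 (rt ≥ rt₁₁), and a least-squares fifth-order polynomial in
between, with the end lines extrapolating linearly outside the marker
span (high-degree polynomials extrapolate poorly — that is the point of
the linear ends).

Two numerical choices matter here:

- **The middle fit includes the boundary markers (2–11).** Fitting the
  polynomial on the inner eight markers only would force it to
  *extrapolate* across the (marker 2, marker 3) and (marker 10,
  marker 11) gaps. A degree-5 polynomial pushed one inter-marker gap
  beyond its fit span amplifies marker-RT noise roughly 25-fold
  (Chebyshev growth), turning ±0.05 s of apex jitter (~±45 RI units)
  into segment-join steps of 500–1500 RI units and spurious fit
  failures. Anchoring the fit at the boundary markers makes the
  polynomial interpolate-only; joins shrink to noise scale. On collinear
  markers every fit is exact regardless.
- **The polynomial is fitted in centred/scaled RT.** A raw Vandermonde
  over RTs of hundreds of seconds at degree 5 is catastrophically
  ill-conditioned; coefficients are stored with their centre/scale.

Monotonicity is enforced per segment (positive end slopes, strictly
increasing polynomial over its span on a 2001-point grid). Join steps
are tolerated up to 500 RI units — the model has no continuity
constraint, and noise-scale steps are expected — flagged above 50, and a
*downward* step beyond 500 fails the fit, sending the sample to the
fallback ladder. `ri_to_rt` inverts the map by bracketed root-finding
(Brent, xtol 10⁻⁹ s), refusing indices more than 100,000 RI units beyond
the calibrated span.

### Fallback ladder

A sample whose own fit fails borrows, in order: the nearest same-day
sample's own curve; the nearest own curve within ±10 days; failing that,
a piecewise-linear partial curve through whatever markers were found
(≥2). A sample with fewer than two marker hits and no neighbour is
skipped with a logged reason. Every fallback branch disables new-Bin
generation for the sample — a borrowed or partial index is good enough
to match known Bins (the matching window is wide) but not to define a
new compound's reference RI.

## Spectral validation

Four per-spectrum checks, accumulated without short-circuiting: unique
ion present; unique-ion intensity ≥ 5% of the base peak; all apex masses
present; ≥3 fragments ≥500 counts. The thresholds are engine defaults
(config block `validation:`) chosen to be stringent yet satisfiable by
clean spectra; the model names the checks but fixes no numbers. A
chromatogram with more than 20% invalid spectra — overloaded peaks,
deconvolution errors — is kept for matching but barred from Bin
generation. Saturation is not modelled separately; overloading surfaces
through the relative-abundance and strong-peak checks.

## Similarity and the tiered matcher

Similarity is the cosine between √intensity vectors on the union m/z
grid, ×1000, rounded: 1000 for proportional spectra, 0 for disjoint
ones. Square-root weighting damps base-peak dominance so diagnostic
minor fragments count; the weighting is a config hook.

Candidate Bins must satisfy |ΔRI| ≤ 2,000 FAME RI units (≈2 s) and share
the peak's unique ion or an apex ion with the Bin's unique-mass list.
The similarity gate adapts to peak quality — default schedule, first
match wins: purity < 0.15 and S/N ≥ 50 → 800; purity < 1.5 → 700;
otherwise 600 (purity is a co-elution estimate; lower is purer). The
schedule grid is an engine default honouring the required monotonicity
(cleaner peaks face higher thresholds); only its shape, not its exact
values, is prescribed by the underlying model. Among gated candidates
the closest RI wins unless another exceeds it by ≥50 similarity points
("significantly greater", config-exposed); RI ties break by similarity,
then lower bin id. Peaks are processed by decreasing unique-ion height
and a Bin claimed in a sample is removed from later peaks' candidate
sets, which realises the feedback rule: a peak losing an isomer contest
falls through to its next-best neighbour. On small instances the
sequential engine is provably identical to a global brute-force
enumeration with the same greedy order (tested on 100 random problems).

## New Bins, post-matching, replacement, reports

A new Bin requires purity < 1.0 (strict), S/N > 25 (strict), and
detection in ≥80% of the samples of one experimental class. Because
not-yet-binned spectra have no database key, candidates are first
clustered across samples — same unique mass, RI within one matching
window of the cluster seed — and the class-presence test runs on cluster
membership; the cluster's most intense peak donates the spectrum, the
mean RI becomes the Bin RI. This clustering rule is an implementation
choice; the underlying model does not specify cross-sample grouping.
Bin ids come from an autoincrementing SQLite store and are never reused;
re-running an experiment against its store creates no duplicates because
the first annotation pass now claims the existing Bins.

Post-matching re-runs annotation per sample against the full Bin list at
annotation (not generation) thresholds, keeping first-pass claims.
Cells still missing are replaced: the Bin's mean observed RI is
back-transformed through each sample's own curve, and the value is
max(trace within ±2 s) − background, clipped at zero, where the trace is
the quantifier-ion intensity from the raw ANDI-MS file (nearest centroid
within ±0.5 Th) and background is the 5th percentile of the ±5 s flank
excluding the core — a formula chosen because "local background noise"
is otherwise unspecified. Unreadable raw files yield a zero cell plus a
warning.

Reports include a Bin when its best class reaches the level (0.80, and a
companion 0.50 sheet); replaced cells do **not** count toward detection
— they are estimates, not detections — and are flagged in provenance
columns rather than by colour. Values are quantifier-ion peak heights,
never areas. Artifact Bins (flag suggested automatically when the base
peak is a siloxane bleed fragment 207/221/281/355, but applied only by
explicit confirmation) never appear in reports.

## Synthetic experiments

The generator emulates what the engine consumes, with full ground truth:
per-sample peak tables containing the 12 FAME markers (idealised
reference patterns, base peak 74, ±2% intensity jitter), 20 terpene-like
compounds placed at RTs consistent with their true RI under the sample's
drift, and decoy peaks; raw ANDI-MS files at 25 scans/s with Gaussian
quantifier traces (σ = 1.5 s) on a noisy baseline of 100 counts,
including traces for occurrences deliberately dropped from the peak
tables. Defaults — 3 classes × 5 samples, compounds 32,000 RI units
apart with two sharing unique ion m/z 93, 3 s linear drift across the
sequence (matching observed monthly drift magnitude), RT noise 0.05 s
(~1 scan), 10% dropout, 25 decoys per sample — define the standard test
conditions; the seed fully determines the output. Drift models `none`,
`linear`, `polynomial` (RT-dependent warp) and `jitter` are available.

What it does not emulate: deconvolution behaviour (shared fragments
between co-eluting peaks, split peaks, saturation), non-Gaussian peak
shapes, within-class biological structure, or real spectral libraries.
Passing tests therefore demonstrate the correctness of the filtering
logic and numerics under controlled drift and dropout — not robustness
to deconvolution artefacts, which in production is what the validation
gates and the manual artifact workflow absorb.

## Problem sizes and determinism

Tests and the acceptance script run the default experiment (15 samples,
~55 peaks each plus raw files) in a few seconds; the matcher/oracle
comparison uses 100 instances of ≤20 Bins × ≤50 peaks, and round-trip
checks use 1,000 random indices. All randomness flows from explicit
seeds; fixed inputs yield byte-identical outputs, including the
generated raw files.

## Known limitations

- Alkane (Kovats) markers are supported only as an RI conversion target,
  not as a primary detection system; isotope-labelled markers are not
  supported.
- The cross-sample candidate clustering is greedy in RI order; pathological
  chains of candidates spaced just under one window apart could merge.
- Report output is TSV/JSON; spreadsheet-native formats are out of scope.
- The similarity threshold schedule and validation thresholds are
  defaults to be tuned per instrument, not universal constants.
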