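# vocbin

Automated annotation and compound tracking for GC-TOF-MS volatile
profiles.

Untargeted volatile metabolomics produces thousands of deconvoluted mass
spectra per study, most of them from compounds with no library identity.
`vocbin` turns those per-sample peak lists into a study-spanning data
matrix by (1) locking retention times to a retention-index (RI) grid of
spiked fatty acid methyl ester (FAME) markers, (2) assigning each
spectrum to a database entry — a **Bin**: one unique compound defined by
its mass spectrum, RI, quantifier mass, unique-mass list and a stable id
— through a multi-tiered filter, (3) creating new Bins for recurring
unknowns under stringent quality gates, so unidentified compounds remain
trackable across studies, and (4) filling residual gaps from the raw
ion chromatograms.

## The method

**RI correction.** Every sample carries the FAME series C4–C24. The
markers are located with a base-peak filter (m/z 74/87) and spectral
matching — no retention-time priors — and the correction curve maps RT
(s) to FAME RI units: a line through the first two and last two markers,
a fifth-order polynomial across the middle, linear extrapolation beyond
the span. The scale is anchored at RI(C4) = 262,214 and
RI(C24) = 980,934 (alkane-scale equivalents 726 and 2712). Samples whose
markers cannot be fitted borrow a neighbouring curve (same day, then up
to ten days) or fall back to a partial curve, and are then barred from
seeding new Bins.

**Annotation.** Peaks are processed by decreasing unique-ion height.
Candidates must lie within ±2,000 FAME RI units (≈2 s) and share the
peak's unique or apex ion with the Bin's unique-mass list; a
spectral-similarity gate (cosine of √intensity vectors, 0–1000) then
adapts to peak quality — a pure, abundant peak must score higher than a
small or co-eluting one. Isomer-style ties go to the closest RI unless
another candidate scores significantly higher; a Bin claimed in a sample
is withdrawn from weaker peaks, which fall through to their next
neighbour.

**New Bins, post-matching, replacement.** An unannotated spectrum seeds
a Bin only if purity < 1.0, S/N > 25, and the candidate is detected in
≥80% of the samples of one experimental class. All samples are then
re-matched against the enlarged Bin list, and still-missing cells are
replaced by the background-subtracted maximum of the quantifier-ion raw
trace within ±2 s of the expected RT (background from the ±5 s flank).
Result sheets report every Bin detected in ≥80% (and, separately, ≥50%)
of a class — peak heights, never areas — with column-bleed artifact Bins
(m/z 207/221/281/355) excluded.

## Worked example

`examples/01_full_pipeline.py` simulates a 3-class × 5-sample experiment
(20 terpene-like compounds, 3 s drift, 10% dropout) and runs the whole
engine:

```
run summary: {'n_imported': 830, 'n_skipped_rows': 0, 'n_discarded': 0,
              'n_marker': 180, 'n_annotated': 275, 'n_unannotated': 375}
new Bins created: 20
80% report: 20 Bins x 15 samples
 bin_id    name  quantifier_mass            ri
      1 unknown               55 843967.122939
      2 unknown               69 811976.889503
      ...
```

Of 830 imported spectra, 180 are consumed as FAME markers, 275 are
annotated to Bins (the decoy peaks remain unannotated), and exactly one
Bin is created per simulated compound; the report lists each as an
`unknown` with its quantifier ion and FAME RI. The other examples show
RI correction and inversion (`02`), the tiered isomer filter on a
linalool/terpinolene-style case (`03`), and MSP-library identification
with Kovats→FAME RI conversion (`04`).

A thin CLI wraps the same library:

```bash
vocbin simulate --out data/ --seed 1
vocbin run --design data/design.txt --tables-dir data/ --store bins.db --out reports/
vocbin bins list --store bins.db
vocbin convert-ri 726        # -> 262214
```

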