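# Methods

## Stringent interactor calling

The calling model treats a pull-down table as a list of protein groups,
each with an overall search score, a percent sequence coverage and a
list of peptide abundance areas.  Four rules are evaluated per record:

| rule | keep iff | default | boundary |
| --- | --- | --- | --- |
| distinct peptides | count ≥ `min_distinct_peptides` | 2 | 1 distinct peptide removed |
| coverage | coverage ≥ `min_coverage` | 20% | exactly 20% retained |
| score | score > `min_score_exclusive` | 50 | exactly 50 removed |
| blacklist | accession ∉ false-positive DB | — | exact string match |

The score rule is strict ("above 50") while the coverage rule is
inclusive (the removal criterion is "< 20%"); both conventions are
deliberate and exercised by boundary tests.  "Distinct peptides" counts
unique peptide sequences, not PSMs: duplicate spectral matches to the
same sequence add no sequence-level evidence.  The false-positive
database is the plain union of accessions over the supplied
negative-control runs — no frequency weighting — and matching is exact
string equality with no isoform collapsing (a grouping rule could be
layered on top, but none is assumed).

Surviving records are quantified by T3PQ: the mean of the three largest
*present* peptide areas.  Missing areas are `None`, never 0 — a zero
would both shift the mean and corrupt the abundance ranking.  With only
one or two present areas the mean of the available areas is used and
the call is flagged `t3pq_degraded`; with none the quantity is
undefined and the record is rejected with an explicit audit flag rather
than silently scored 0.  Ranking is by descending T3PQ mean, with ties
broken by descending score and then lexicographic accession so reports
are byte-reproducible.  The bait stays in the ranked report flagged
`is_bait` and is excluded from the specific-interactor count; a sanity
check verifies it holds rank 1.

Upstream concerns — spectral search, FDR control of peptide matches,
protein grouping — are assumed already applied to the input tables and
are out of scope.

## Disc-stack quantification

All measurements are made on per-channel maximum-intensity projections
of the z-stack, not per-plane.

* **Disc segmentation** (method not standardized across imaging
  software; this package's choice): Otsu global threshold on the DAPI
  MIP, largest 8-connected foreground component, interior holes filled.
  Area = pixel count × pixel_size².  Pixel size (µm/pixel) is a
  required calibration input; the 0.325 µm/pixel default in example
  configs is an illustrative mid-magnification value, not a measured
  constant.
* **Elav fraction**: percent of disc pixels at or above an Otsu
  threshold computed from the in-mask Elav intensities.  Two guards
  make this robust where raw Otsu degenerates: a background floor
  (out-of-mask median + 3 robust sigmas, MAD-based) prevents a
  signal-free disc from having its noise distribution split in half,
  and a constant in-mask signal (all-Elav or all-background) is decided
  directly against that floor.
* **Basal fluorescence**: the median Caspase intensity inside the disc
  mask, estimated per disc.  The median is insensitive to the sparse
  bright foci themselves (a few percent of disc area at most), so the
  focus threshold does not drift upward in heavily apoptotic discs.
  Per-disc (rather than per-batch) estimation keeps discs independent.
* **Focus calling**: pixels inside the disc at ≥ 3× basal ("starting
  from 3×", hence inclusive) are labeled with 8-connectivity;
  components are kept iff their area is strictly between 1 and 60 µm².
  The gate bounds are areas in µm² and both are strict ("greater
  than … less than"), so a component of exactly 1 or exactly 60 µm² is
  rejected.  The threshold is applied only within the disc mask: foci
  are a per-disc readout.  Each kept focus reports its area and mean
  fluorescence; the per-disc summary reports the focus count and the
  mean focus area.
* **Size classification**: a test disc is below/within/above the
  control mean ± 2 × SD, with the sample (n−1) standard deviation and
  bounds counted as within.  For test discs drawn from the control law
  the expected outside fraction is the normal two-tail mass 0.0455.

All area outputs scale exactly with pixel_size², which is tested as an
invariant.

## Eye-size classes

Classes are the categorical labels {0, 25, 50, 75, 100} assigned by
visual inspection (0 = absent, 100 = normal, k = smaller than k% of
wild type); no image-based eye measurement is attempted.  A dubious eye
between two adjacent classes is resolved conservatively with respect to
the hypothesis: to the **higher** class when scoring an RNAi phenotype
without a rescue construct (never overstating the knockdown phenotype)
and to the **lower** class when a rescue construct is present (never
overstating the rescue).  Tallies are emitted per genotype in input
order, as counts plus percentages (one decimal in CSV for display; raw
fractions are exact in memory), in both wide and tidy long formats
ready for any statistics package.  Significance testing (ANOVA,
Kruskal-Wallis) is intentionally left to standard tools.

## Synthetic data: what it emulates, what it does not

The AP-MS generator emulates the *structure* of a spike-in experiment:
one bait run containing the bait, `n_true_interactors` = 12 proteins
present only in the bait run, and `n_contaminants` = 200 background
proteins that also appear in each of `n_control_runs` = 8 negative
controls independently with probability 0.9.  Peptide abundances are
log-normal — true interactors ln-N(12, 1), contaminants ln-N(8, 1.5),
arbitrary units — and the filter statistics are drawn from
class-specific uniform laws chosen so that true interactors clear every
threshold with a margin (scores 120–400, coverage 25–80%, 3–9
peptides) while contaminants straddle all three cut-offs (scores
20–120, coverage 5–45%, single-peptide with probability 0.3).  Because
the laws are uniform and independent, the probability that a
contaminant clears the thresholds is closed-form
(0.7 × 0.625 × 0.7 ≈ 0.306), and the expected number of false
positives, `n_contaminants · (1−p)^8 · P(clear) ≈ 6 × 10⁻⁷`, is an
analytic oracle for recovery tests.  The bait's peptide areas are
pinned above every other area in the run, so the bait-is-top check has
deterministic truth.  The generator does not emulate retention times,
spectra, shared-peptide ambiguity, isoforms, or correlated
contamination across controls.

The disc generator draws an elliptical disc (aspect 1.3) covering
`disc_fraction` = 0.35 of a 256 × 256 frame, an Elav sub-region taken
as the rightmost disc columns holding `elav_fraction_of_disc` = 0.40 of
the disc pixels (posterior-to-the-furrow geometry), and a Caspase
channel at `basal_level` = 100 everywhere with optional Gaussian noise
per voxel.  Stacks have 15 z-planes at a 0.5 µm step, matching the
acquisition protocol emulated.  Planted foci are rasterized filled
disks written into one z-plane each at a stated multiple of basal; the
recorded truth area is the rasterized pixel count × pixel area, not the
ideal πr², so exact-count and exact-area assertions are possible.  The
generator does not simulate optical PSFs, z-blur, photobleaching,
tissue autofluorescence gradients or touching/overlapping foci
(configurations with overlapping foci are rejected), so passing tests
demonstrate correctness of the measurement chain, not robustness to
every real-microscopy artifact.

A single integer seed drives one named PRNG (numpy PCG64) per
generator call, so identical configs produce identical fixtures across
platforms.

## Numerical choices and degenerate inputs

* Ranking and report writing use a total order (T3PQ, score,
  accession), so identical inputs give byte-identical reports.
* Floats are serialized with Python's shortest round-tripping repr;
  table round-trips compare areas exactly.
* A constant DAPI projection raises a no-disc error; an empty disc mask
  is a contract error for every downstream measurement; zero called
  foci is a legal result (mean focus area reported as missing).
* `classify_disc_sizes` requires ≥ 2 control areas (the SD is
  undefined below that).
* Readers reject invalid rows with row-indexed diagnostics and never
  silently drop them (rows in = records out + diagnostics out);
  duplicate accessions and missing mandatory columns abort the read.

## Problem sizes in the shipped checks

The recovery and acceptance checks use 100 generator seeds for the
spike-in and noisy-disc studies, 500 random tables (≤ 50 records) for
brute-force equivalence, 100 random configurations for monotonicity,
and 10,000 normal draws for the ± 2 SD tail check — sizes at which the
binomial/analytic bands are tight while the whole suite runs in well
under a minute per stage on one CPU.

## Known limitations

* Blacklist matching is exact-accession; isoform or paralog collapsing
  must be handled upstream if required.
* The XLSX adapter reads only the first worksheet and requires a
  user-supplied column map, since search-engine workbook schemas vary.
* Focus calling is 2-D on the MIP; overlapping foci in z merge, and
  genuinely touching foci merge in-plane (8-connectivity).
* The Elav background floor assumes some out-of-disc background is
  visible in the frame; a disc filling the entire frame falls back to
  pure in-mask Otsu.
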