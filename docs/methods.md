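# Methods

This note documents the models behind `clonegrid`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Plate geometry and seeding

A plate is `n_wells` wells, each with a `grid_rows × grid_cols`
acquisition grid (default 20 × 20) of circular adhesive features of
`feature_diameter_um` (default 300 μm) at `feature_pitch_um` spacing
(default 450 μm, which must exceed the diameter). One image is acquired
per feature per day at `pixels_per_um` (default 0.65 px/μm, a typical 10×
epifluorescence scale), giving 227 × 227 px images with a 16-px background
margin. The defaults yield 400 features per well and 2400 per 6-well
plate.

Clonal seeding is limiting dilution: the number of cells landing on a
feature is Poisson(λ). `poisson_seeding` reports
P(0 or 1 cell) = (1 + λ)·e^(−λ) and the expected number of exactly-1-cell
features, n·λ·e^(−λ). The simulator's default λ = 1 keeps
P(0 or 1) ≈ 0.74 — the regime where most occupied features are clonal.

## Growth model

Colony growth is a discrete-time Galton–Watson branching process evaluated
once per day, matching the daily imaging cadence (no within-day dynamics
are modelled). Each cell independently survives the day with probability
1 − `death_prob_per_day`, then divides with probability
p = e^r − 1 where r = `growth_rate_per_day`, so the expected count
multiplies by e^r per day. This parameterisation requires r ≤ ln 2 (at
most one division per cell per day). The default r = ln 2 corresponds to
a 24-hour doubling time, typical of cultured human pluripotent stem
cells; at this default p = 1, so growth from a single cell is the
deterministic sequence 1, 2, 4, 8, … which makes the default plate a
clean reference for count-recovery checks.

Growth rates are estimated per feature by ordinary least squares on
(day, ln count). Zero counts are excluded from the log fit (no
pseudocounts — this avoids bias and the excluded days are recorded on the
result). Doubling time is ln 2 / r for r > 0 and +∞ otherwise; slopes
below 1e−12 in magnitude are clamped to exactly 0. R² is reported only
for fits with ≥ 3 points.

Classification into low / intermediate / high growth uses explicit
thresholds on a chosen statistic (final-day count by default; fitted rate
optionally). The original screening practice this replaces was manual
curation, which is not reproducible; when no thresholds are given the
tertiles of the observed statistic are used, and boundary values go to
the higher class. If the default tertiles collapse (all values equal),
everything is classified intermediate rather than erroring.

Group comparison is a two-sample two-tailed Student t-test with pooled
variance (Welch by flag), via `scipy.stats.ttest_ind`. The degenerate
case of two constant, equal groups returns p = 1 by convention. No
multiple-testing correction is applied by default (single planned
comparisons); users running many comparisons should apply their own
correction.

## Image formation and quantification

Nuclei are rendered as 2-D Gaussian spots (σ = nucleus radius / 2,
default radius 4 px) with per-cell amplitudes ~ N(12000, 2000²) (16-bit
scale, truncated at 25% of the mean), placed uniformly in the feature
disk with a minimum separation of one nucleus diameter (relaxed
automatically if the disk crowds), clipped to the disk, on a constant
background (800) with additive Gaussian read-out noise (σ = 120; SNR
≈ 90 at the spot peak, far above the ≥ 5 regime the segmenter is
specified for). Positions are re-drawn each day: the simulator models
counts, not cell identity, so no motion or lineage continuity is
emulated. Other features of real data deliberately not modelled:
focus drift, uneven illumination beyond what `correct_illumination`
removes, debris, apoptotic morphology, and overlap in z. Passing tests
therefore demonstrate correctness of the quantification logic under
controlled difficulty, not robustness to every real-world artefact.

`correct_illumination` estimates a smooth multiplicative field by a coarse
Gaussian blur (σ = 25% of the image side), normalises it to unit mean and
divides it out; flat images pass through unchanged and the operation is
idempotent to within ~5%. `segment_nuclei` lightly smooths (σ = 1 px),
thresholds by Otsu guarded by a robust floor (median + 5·MAD-σ — without
the guard Otsu splits pure background noise in half), labels connected
components, optionally declumps by distance-transform watershed seeded at
local maxima ≥ one nucleus diameter apart, and discards components below
`min_area_px` (default 25% of the expected nucleus area) as debris. The
count store is a keyed CSV table with upsert semantics — a deliberate
file-backed replacement for a database server, preserving the
keyed-replace and join contracts.

## Amplicon read simulation and indel quantification

Each simulated read is wild type with probability 1 − `edit_fraction`,
else it carries one indel: a deletion with probability 0.85 (the
empirical deletion:insertion mixture in Cas9-edited human cells), else an
insertion. Lengths are uniform on 1–30 nt by default (no consensus
empirical length law; uniform makes the by-chance in-frame rate exactly
10/30 ≈ 33%). The event is centred on the blunt cut between the 3rd and
4th nt upstream of the PAM with signed Gaussian jitter (σ = 1 nt).
Sequencing errors are substitutions only by default so that every called
indel is attributable to an edit; a flag adds rare 1-nt error indels for
robustness experiments.

Alignment is semi-global with affine gaps: the read aligns end to end,
reference overhangs are free. Scores default to match +2, mismatch −4,
gap open −8, gap extend −1, with a length-L gap costing
open + (L−1)·extend. The aligner is `Bio.Align.PairwiseAligner` with free
end gaps on the read row; ties are broken by taking the first optimal
alignment in its canonical order, after which indels are left-aligned
within repeats to a canonical form. The test suite checks score
equivalence against an independent brute-force enumeration oracle on
hundreds of small random instances.

Indel calling counts insertion/deletion events whose reference footprint
intersects the window [cut − w/2, cut + w/2), w = 100 nt by default (the
"~100-nucleotide window" is read as a total width of 100, i.e. ±50;
configurable). Substitutions never classify a read as an indel. The net
length (insertions positive, deletions negative) decides frame: in frame
iff divisible by 3. A read with balancing events (net 0) counts as an
in-frame indel but is excluded from the deletion/insertion tallies, with
a log note. Per-base profiles report, for each reference position, the
fraction of covering reads that match the reference base (gap or
substitution = non-match); primer-binding margins are flagged masked
because priming forces apparent matches there.

Gel genotyping: a band within tolerance of the full amplicon is a WT
band; within tolerance of any design's edited amplicon, a deletion band.
WT only → WT; WT + deletion → monoallelic; deletion only → biallelic;
nothing recognised → no_call. Default tolerance is 10% of each predicted
size — agarose sizing is semi-quantitative and repair can shift products;
unrecognised bands never affect the call. Homozygous biallelic clones
show a single deletion band.

## sgRNA design

Target scanning enumerates every 23-nt window ending in NGG on both
strands; windows containing ambiguous bases are skipped with a warning.
Cut sites are reported in + strand coordinates (for a − strand target the
break falls between `pam_start + 5` and `pam_start + 6`). The one-pot
forward primer is minimal T7 promoter + spacer + scaffold overlap, with a
G prefixed to spacers not starting with G (T7 initiates on G). The
default minimal T7 promoter is TAATACGACTCACTATAG and the default
scaffold is the canonical S. pyogenes sgRNA conserved region (82 bp,
including the poly-T terminator) with a 15-nt primer overlap — both are
configurable stand-ins, not a claim about any particular published
template. Order plates fill column-major (A1, B1, …) with replicate
expansion and spill onto further plates past 96 wells.

## Problem sizes and reproducibility

All generators take an explicit `rng_seed` and are bit-reproducible. The
shipped checks use: 10,000 reads for editing-spectrum recovery (binomial
99% CI half-width ≈ 1.3 percentage points on the deletion share); a full
400-feature plate over 4 days for count and doubling-time recovery; and a
120-feature plate (40 clones per class, seeded at λ = 20 so branching
noise in the fitted rate stays well inside the class gaps) with rates
0.05 / 0.40 / ln 2 per day for three-way classification. Classification
thresholds there are (0.20, 0.52): midpoints between adjacent true rates,
with the upper midpoint shaded down because dense high-growth colonies
are slightly undercounted, biasing their fitted rates low. These scales
were chosen as the package's reference conditions; rerunning at other
scales only changes confidence-interval widths.

## Known limitations

* The growth model caps r at ln 2/day and has no within-day dynamics or
  lineage tracking between days.
* Segmentation assumes roughly circular, similar-size nuclei; heavy
  overlap (confluent features) is undercounted.
* Read simulation places at most one indel per read; complex multi-event
  alleles arise only through alignment of noisy reads, not by design.
* Gel genotyping cannot distinguish a homozygous biallelic clone from a
  hemizygous one, and compound calls outside the predicted size set are
  returned as no_call rather than guessed.
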