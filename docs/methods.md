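# Methods

`seedquant` quantifies seeded aggregation of serum amyloid A (SAA) from
fluorescence micrographs and relates species-level seeding activity to
SAA sequence homology.  Every stage is exercised against synthetic data
with known ground truth, so this note describes both the analysis
methods and the generative models behind the synthetic data, together
with the design decisions that were genuinely open.

## The SD-of-brightness statistic

The amount of aggregate in a grayscale fluorescence micrograph is
estimated as the population standard deviation of pixel brightness over
the raw grid.  A uniform field (free fluorophore, no aggregates) has an
SD close to the camera read noise; bright puncta or filaments on that
background raise the SD with the amount of bound fluorophore.  Choices
fixed for reproducibility:

- **Population SD** (divide by N), not sample SD.  Frames have >= 10^4
  pixels so the difference is far below noise, but the convention must
  be fixed for bit-identical outputs.
- **No background subtraction or flat-fielding.**  The statistic is
  computed on the raw grid; a preprocessing hook exists but is off by
  default.
- **Color frames** are reduced to grayscale by channel mean before the
  SD (relevant only for RGB exports of single-channel data).

Replicate time courses are summarised per time point as mean +/- SEM,
with SEM = sample SD over replicate values / sqrt(n) and reported as NaN
for n = 1.

## Kinetic model

Seeding is modelled by the minimal two-species nucleation-elongation
system

    dF/dt = k_n (c_tot - F) + k_plus (c_tot - F) F,   F(0) = s0 c_tot,

with F fibril mass, c_tot total monomer, k_n a primary nucleation rate
(1/h), k_plus an elongation rate (1/(unit h)), and s0 the seed fraction.
Monomer is c_tot - F by construction, so mass conservation is exact.
Secondary nucleation and fragmentation are deliberately omitted: the
model is the simplest one in which seed mass monotonically shortens the
aggregation half-time, which is the qualitative behaviour the imaging
pipeline must detect.  Integration uses `scipy.integrate.solve_ivp`
(LSODA, rtol 1e-9); tests compare it against an independent fixed-step
RK4 integrator at a 10x finer step.

Defaults: `nucleation_rate = 0`, reflecting that unseeded mSAA at assay
concentration does not detectably aggregate within a week; seeding
enters purely through s0.  The relative amount of amyloid-enhancing
factor (AEF) in a well maps linearly onto s0 with a configurable ceiling
(default 0.1): absolute seed concentrations are not identifiable from
relative dose designs, so the ceiling is an explicit convention rather
than an estimate.

## Curve fits

- **Time courses** are fitted with a Boltzmann sigmoid
  `y = baseline + (plateau - baseline) / (1 + exp(-slope (t - t50)))`;
  the lag time is the standard tangent construction `t50 - 2/slope`,
  floored at zero.  Both the functional form and the lag definition are
  conventions of the amyloid-kinetics literature, not estimates of
  mechanism.
- **Dose-response** endpoints are fitted with a rising four-parameter
  logistic in the AEF fraction; `half_max_fraction` is the EC50
  analogue on the dose axis.  A constant response is flagged
  unidentifiable instead of being assigned a number.
- Both fits use deterministic multistart least squares (fixed grids of
  starting values, best residual sum of squares wins, ties broken by
  grid order), so results are reproducible bit-for-bit given the data.
- Half-max recovery is only meaningful when the dose design brackets
  the response: the validation panels use slow kinetics
  (k_plus = 0.03/(unit h), 168 h endpoint) and a dose grid anchored at
  fraction 0, giving the logistic a real bottom plateau.  The ground
  truth is computed numerically as the midpoint crossing of the
  expected-SD-versus-fraction curve (noise-free kinetics, SD averaged
  over 30 render seeds per fraction).

## Micrograph renderer

The renderer maps a fibril mass fraction to an image through a fixed
intensity budget: aggregates contribute `signal_scale x mass_fraction`
mean intensity per pixel (default 150 counts at 16 bit on a background
of 500 +/- 20), split into elements of fixed per-element amplitude, so
the image SD grows monotonically with mass.  Two morphologies:

- **dotted** - a Poisson point process of Gaussian puncta (40 blobs at
  full conversion, sigma 2.5 px);
- **mesh** - one branched, connected filament network drawn as a
  correlated random walk on the pixel lattice (unit 8-neighbour steps,
  border reflection, branches restarting from visited pixels), with
  per-pixel deposition capped at twice the nominal amplitude so
  revisited pixels saturate instead of dominating the histogram.

Both are blurred with a Gaussian point-spread function (sigma 1.2 px),
overlaid on Gaussian read noise, and quantised to the bit depth.  The
mesh uses a shorter total path (1200 px at full conversion) than a
naive equal-split of the budget: concentrating the same fluorescence
into fewer, brighter pixels gives the mesh an SD response comparable to
the dotted form, matching assays in which mesh-form aggregates produce
SD values as high as or higher than punctate ones.

Z-stacks place the same aggregate pattern into a centred slab of
`round(mass_fraction x z_slices)` slices over per-slice background
noise, so the occupied z-extent grows monotonically with mass.

## Thickness and morphology readouts

A global threshold (Otsu, floored at a robust background estimate) marks
aggregate voxels.  The background floor is estimated from the 10th/40th
intensity percentiles (Gaussian quantile inversion), not median + MAD:
dense aggregates can elevate more than half of all pixels, which breaks
median-based estimates.  Per xy position, thickness = number of
above-threshold slices x z-step (micrometers), averaged over the
above-threshold footprint; an all-background stack yields 0.

Morphology classification thresholds the frame the same way, applies a
disk(2) morphological closing (bridging 1-2 px threshold dropouts along
thin filaments), then computes connected components (8-connectivity) and
the skeleton.  "mesh" requires both a dominant largest component
(>= 0.5 of the foreground) and a dense skeleton (>= 0.01 px/px^2); both
cutoffs live in configuration and were calibrated on the renderer at
default parameters, where held-out renders classify at >= 95% accuracy
across mass fractions 0.3-1.0.  A frame with no above-threshold pixels
is labelled "none".

## Species panel defaults

Species differences are encoded only through kinetic parameters and
morphology, all in configuration: elongation rates cat 0.100, mouse
0.085, goat 0.012, cattle 0.011, camel 0.010 (1/(unit h)); mouse renders
mesh-form, all others dotted.  These defaults express the empirical
pattern the pipeline is designed to recover - cat and mouse AEFs seed
much more strongly than camel/cattle/goat, with cat slightly above
mouse - and produce endpoint conversions of ~1.0 for the fast pair and
0.35-0.5 for the slow trio at the default 168 h endpoint.  The panel
grid is 5 species x AEF fractions (0.2-1.0) x 8 times (0-168 h) x 3
replicates.

## Sequence family generator

Families evolve along a rooted tree (newick, branch lengths in expected
substitutions/site) under an i.i.d. jump process: per branch and site,
Poisson(branch length) substitution events, each replacing the residue
uniformly with one of the other 19.  The default six-species tree is
ultrametric with root height 0.14, a very short mouse-cat split (0.03),
human joining that clade at 0.10, and a ruminant/camel clade on the
other side - giving mouse-cat the highest pairwise identity and a
minimum family-wide identity in the high 70s%, as in real SAA families.

Planted discriminative sites are excluded from substitution and carry an
exact per-group side-chain pattern; the defaults mirror the real
contrast: column 48 Gln/Ile in the high-seeding group versus basic Lys
in the low group, and column 125 acidic (Asp/Glu) versus Ala.  A cleanup
pass re-evolves (rejection-samples) any background column whose pattern
happens to separate the groups into disjoint side-chain classes, so the
planted columns are provably the only discriminative ones.  This
conditioning suppresses patterns in which the high clade diverged
jointly and therefore inflates cross-clade identities by a fraction of a
percent; the path-length/identity invariant is accordingly tested on the
unconditioned process.

## Homology analysis

- **Pairwise alignment**: affine-gap global alignment (Gotoh's
  three-state recurrence) with BLOSUM62; a gap run of length L costs
  `gap_open + (L-1) gap_extend`; traceback ties prefer diagonal, then
  up, then left, making alignments deterministic.  Defaults
  gap_open -12, gap_extend -1: under a weaker opening penalty (-10),
  indel-free families occasionally acquire paired compensating gaps
  that shift all downstream columns by one, breaking the exact
  column-correspondence contract the site scan relies on.
- **Progressive MSA**: UPGMA guide tree on pairwise identity distances;
  profile-profile merges with the same affine DP, scoring column pairs
  by mean substitution score (gap symbols score 0).  Gap-only columns
  cannot arise, and de-gapping any row reproduces its input exactly.
- **Percent identity** uses pairwise deletion: columns where either row
  is gapped are excluded from the denominator.  The family-level
  "homology" headline is the minimum pairwise identity (the "at least
  X%" summary), reported with the fraction of fully conserved columns.
- **Conservation classes** per column, from the fraction of rows
  carrying the modal residue (gaps count against): full = 100%,
  high = (75, 100), mid = (50, 75], low = <= 50; boundary values fall to
  the lower class.
- **Tree building**: UPGMA with deterministic ties (lexicographically
  smallest label pair merges first), node heights = half the merge
  distance.  `clade_check` tests monophyly of a label set.
- **Discriminative-site scan** over two disjoint sequence groups, at
  three strictness levels: `class` (each group uniform in side-chain
  class, classes differ), `residue` (uniform residue), and `disjoint`
  (the groups' class sets do not overlap, allowing chemically mixed
  groups such as Gln/Ile versus Lys).  Columns with a gap in any group
  member are excluded; positions are 1-based alignment columns.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
monotone SD-mass coupling, replicate noise, dose-dependent seeding,
dotted/mesh texture contrast, clade structure and planted sites.  It
does not model fluorophore photophysics, uneven illumination, focus
drift, aggregate size distributions, insertions/deletions, or
rate-across-site variation.  Passing tests therefore demonstrate that
the estimators recover known truth under their stated assumptions - not
that those assumptions hold for any particular microscope or protein
family.

## Problem sizes

Defaults were chosen so a full test run stays interactive: 128x128
16-bit frames (48x48 in pipeline round-trip tests), 600-image default
panels, 130-residue six-species families, 50-replicate recovery studies,
and 30-panel Monte-Carlo dose recoveries.  All randomness flows from
explicit integer seeds; CSV outputs use a fixed float format and row
order so reruns are byte-identical.
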