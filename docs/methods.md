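# Methods

This note documents the models, estimators and design choices behind
`taskpotency`, in the order the pipeline applies them, together with the
defaults, the rationale for each choice where the choice was genuinely
open, and the limits of what the synthetic experiments demonstrate.

## Per-scan connectivity

Each scan is a region × time matrix. Partial correlations are computed
from the inverse of a Ledoit-Wolf shrinkage covariance
(`sklearn.covariance.LedoitWolf`): with 179-region parcellations and a
few hundred timepoints the raw sample covariance is ill-conditioned or
singular, and shrinkage keeps the precision matrix defined for any
timepoints/regions ratio while remaining invariant to global rescaling of
the data. The estimator choice is ours; nothing in the method depends on
it beyond requiring a well-defined, symmetric partial-correlation matrix.
Constant (zero-variance) regions are rejected by index rather than
silently dropped, since a region's identity matters downstream.

Fisher-Z (atanh) stabilizes the correlation scale; inputs with |r| ≥ 1
(possible only through duplicated signals) are clipped to 1 − 1e-7 with a
warning.

### Null-mixture normalization

Edge values of a single scan are modelled as a three-component mixture: a
central Gaussian for the null bulk plus two Gamma components on (x − c)
and (c − x), mirrored about an anchor c frozen at the per-scan median.
Fitting is EM with deterministic moment-based initialization (location =
median, scale = 1.4826·MAD, tail weights = exceedance fractions beyond
2.5 robust SDs floored at 0.5%, Gamma shape 3); Gamma updates use
weighted method-of-moments with the shape clipped to [1.01, 300] so tail
densities vanish at the anchor instead of diverging into the centre.
Convergence is |Δ mean log-likelihood| < 1e-6, at most 500 iterations; a
non-convergent fit falls back to the robust median/MAD location-scale
with `converged=False` flagged. Freezing the anchor makes the fit exactly
location-equivariant and lets a batched kernel refit thousands of edge
distributions cheaply (the bootstrap refits every group × task × stream
cell of every iteration; columns are retired from the working set as they
converge).

The scan's edge matrix is then standardized against the central
component, (z − μ₀)/σ₀. Normalization is strictly per scan and per
subject; no information crosses subjects or conditions. Where the choice
"pool edge values per scan vs per subject" was open, per-scan pooling was
adopted: it is the unit at which residual autocorrelation acts, and it
keeps rest and task normalizations independent. The three-component form
(rather than some other heavy-tailed family) is likewise a documented
package choice.

On 10,000 null values with 5% planted contamination at ±6 the fitted
centre is accurate to |Δμ| < 0.05 and |Δσ| < 0.1 of the uncontaminated
moments (verified in the acceptance suite). With only ~100 values the
central scale is biased low by up to ~15% because the tails absorb
genuine null extremes — a known small-sample limitation; matrices below
~60 regions should be interpreted accordingly.

## Task potency

Potency is the signed elementwise difference task z\* − rest z\*, defined
only for subjects with both scans. Group-level potency is the elementwise
mean over the group's subjects. Amplitude metrics take |potency| and
average within subject first (over the designated edges and that
subject's available task scans), then across subjects, so a subject's
contribution does not depend on how many task scans it has; the paperless
alternative (pooling all subject × edge values) would overweight
multi-task subjects. When an edge stratum is empty in a bootstrap draw
the amplitude is recorded as missing, never as zero, to avoid biasing
null distributions toward zero.

## Edge selection and classification

Each group × task mean-potency edge distribution gets the same mixture
fit; the two-tailed cutoffs sit at the first points, moving outward from
the fitted centre, where the posterior probability of the null component
drops below 0.5 (resolved by a coarse-then-fine deterministic grid over
±12 fitted SDs, final resolution ~0.002 SD). A degenerate fit falls back
to μ ± 2σ with a warning. The "most conservative limit across groups" is
interpreted as the strictest limit per tail (most positive upper cutoff,
most negative lower cutoff), which selects the fewest edges and therefore
compares groups at equal information.

Classification is a pure function of the per-task sensitivity pattern:
one task → P_single, more than one but not all → P_mix, all tasks →
P_all. For unique/shared status the default rule asks whether another
group assigns the *same class* to the edge; a config switch
(`uniqueness_rule="any-sensitive"`) relaxes this to any sensitivity in
another group, since either reading of "also modulated by one or both of
the other groups" is defensible.

## Bootstrap inference

Each iteration draws a stratified 80% subsample without replacement
(floor(0.8·n) per group, minimum 2) and computes all metrics with true
labels; the null stream repeats this on an independently drawn subsample
whose labels are permuted uniformly with group sizes preserved (subjects
keep their scan sets, so missing-scan structure moves with the subject).
An option (`null_subsample="same"`) reuses the observed subsample
instead. Observed and null streams consume independent RNG streams
derived from one seed, so runs are exactly reproducible.

The empirical p-value is two-tailed add-one,
p = 2·min(#{null ≤ obs}+1, #{null ≥ obs}+1)/(N+1) capped at 1, where
"obs" is the mean of the observed stream. Significance is
Benjamini-Hochberg within each diagnostic group's family of tests at
q = 0.05.

**Calibration caveat.** Comparing the observed *mean* (an average over
all subsamples, hence nearly free of draw noise) against null *samples*
(each carrying subsampling, relabeling and threshold-refit noise) makes
the test conservative: under exchangeable groups the observed mean varies
across datasets only through the group assignment, which is strictly less
variable than a null draw. At desk scale (15 regions, 10 subjects/group)
the per-draw discreteness of percentage metrics dominates and the
realized type-I error is far below the nominal q — the procedure
under-rejects, it never over-rejects. The effect shrinks as the edge
count and group sizes grow. The calibration study in the test suite uses
the four primary percentage metrics per group as the tested family: with
200 iterations the add-one p-value floor is 2/201 ≈ 0.01, and larger
families would make rejections arithmetically impossible rather than
merely conservative.

## Reproducibility metrics

Per-edge selection rates are counted from the observed bootstrap stream
per group and class; shared rates count simultaneous selection within the
same iteration (not products of marginals). For a group pair, an edge's
coordinates are x = rate_A − rate_B and y = shared rate, confined to the
triangle y ≤ 1 − |x|. Reproducible-edge extraction uses a selection floor
of 0.5 and a rate-difference band of 0.25: edges above the floor (in at
least one group by default; a `require_both` switch tightens this) with
|Δrate| < 0.25 form the shared core, and edges above the floor with a
signed difference beyond 0.25 toward a group are preferred by it. "Ratio
difference" is read as the absolute difference of selection rates, the
same quantity as the triangle's x-axis.

## Synthetic cohorts

The generator emulates a three-group, three-task-plus-rest design with
incomplete task coverage. The rest architecture is one random sparse
symmetric precision matrix (default edge density 0.10, weights
±U(0.05, 0.20), spectral norm of the off-diagonal capped at 0.7 on a unit
diagonal) shared by all subjects, plus per-subject Gaussian jitter
(SD 0.02) on its support — jitter cancels in potency because it is common
to a subject's rest and task scans, which is precisely the baseline-
subtraction rationale. Scans are multivariate-normal draws from the
inverse precision with white observation noise (SD 0.5); an optional
AR(1) filter (off by default) adds temporal autocorrelation, since
preprocessing is out of scope.

Task modulation is an additive perturbation of the precision matrix on
planted edges (re-regularized to a minimum eigenvalue of 0.05 if needed),
which keeps the ground truth expressed in partial-correlation space — the
quantity the pipeline estimates; a partial correlation is a local
function of precision entries, so noise-free potency is nonzero exactly
on the planted edges. Planted amplitudes are specified in units of the
subject-level potency null SD; that unit is calibrated once per baseline
by simulating a few subjects through the full per-scan pipeline with a
probe perturbation, yielding the null SD σ (≈ √2, since potency
subtracts two unit-scale normalized scans) and the gain ρ from precision
perturbation to normalized potency. This makes amplitudes portable across
region counts, scan lengths and noise levels. Group-level detectability
then grows as √n with group size: amplitude 3 at n = 30 corresponds to a
≈16 SD group-mean effect, which is why the recovery criterion (≥90%
correct class labels) is comfortably met.

Plan keys name a single group, `"shared"` (identical edges, tasks and
signs in every group) or a `+`-joined subset such as
`"control+sibling"`. The subset form is what gives relabeling nulls their
bite: a class planted in one group only is diluted ~1/G under relabeling
but — at the amplitudes used here — remains detected, so the null
composition tracks the union of all groups' structure, and a group can
only fall below its null on P_all% by lacking structure that other groups
share. Scan availability is drawn per group × task (round(availability·n)
subjects each), then greedily rebalanced so the fraction of subjects with
two or more task scans differs by at most 5 percentage points between
groups, mirroring the design check that multi-acquisition percentages
were comparable.

The generator does **not** emulate hemodynamics, motion, scanner/site
effects, atlas geometry or graded individual effect sizes; planted
effects are binary (an edge is modulated or not) and homogeneous within a
group. Passing tests therefore demonstrate the statistical machinery —
normalization accuracy, threshold false-positive control, classification
and reproducibility semantics, bootstrap behaviour — not performance on
real fMRI data, where effects are weaker, graded and heterogeneous.

## Problem sizes and numerical choices

Default scales are chosen for a desk-scale workflow: 60 regions
(1770 edges) for recovery/contrast experiments, 30 subjects per group,
200 timepoints, 200–500 bootstrap iterations (10,000 in a production
analysis at full 179-region scale; `BootstrapConfig.n_iterations` is the
only knob that changes). The calibration study runs 200 cohorts of
15 regions × 10 subjects/group with 200 iterations each. Edges are
indexed by the strict upper triangle in row-major order everywhere, all
stage outputs are plain text, every stochastic stage derives its seed
deterministically from the master seed and stage name, and metrics JSON
files round floats to 10 decimals so byte-identity of re-runs is
meaningful.

## Known limitations

- Mixture-fit scale bias on very small edge counts (< ~200 values)
  inflates selection rates; group thresholds are reliable from roughly
  40 regions upward.
- The bootstrap test is conservative by construction (see above); null
  results at small scale are weaker evidence than the nominal q
  suggests.
- The unique/shared dichotomy and the reproducible-edge thresholds
  (0.5 / 0.25) are the field's reporting conventions, not optimized
  quantities.
- Amplitude calibration assumes approximate linearity of the precision →
  potency gain around the probe perturbation (0.3); amplitudes far above
  ~6 null SDs leave that regime and additionally stress positive-
  definiteness, which the generator guards with a per-node planted-degree
  cap and ridge re-regularization.
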