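# Methods

## Q-score computation

The Q-score of a heavy atom is the Pearson correlation, about the mean,
between map values sampled around the atom and a reference Gaussian
`g(r) = exp(−r²/2σ_ref²)` evaluated at the sample radii.  Sampling uses
concentric shells at r = 0, 0.1, …, 2.0 Å with up to 8 points per shell
(σ_ref = 0.6 Å); all three knobs are parameters of `QScoreParams` with these
defaults.  Shell points are placed by rejection sampling of uniformly random
directions: a candidate is kept only if its nearest heavy atom is the centre
atom, so density belonging to a neighbour is never attributed to the atom
being scored.  Each (seed, atom, shell) triple has its own deterministic
random stream, which makes scores independent of scoring order and
bit-reproducible for a fixed seed.  At most 96 candidate directions are
drawn per shell; in crowded regions a shell may contribute fewer than 8
points or none.

Because Pearson correlation is invariant to affine transforms of either
series, the reference profile's amplitude and offset are immaterial (they
are fixed at 1 and 0), and rescaling the map `v → a·v + b` (a > 0) leaves
every Q unchanged exactly — trilinear interpolation is itself affine in the
map values.

Edge and degeneracy policy: samples falling outside the grid interpolate to
NaN and are excluded (zero-filling would drag Q down at map borders); an
atom with fewer than 10 valid samples, or whose samples are constant to
within a 1e−10 relative spread, gets an *undefined* Q (NaN) rather than 0 —
"unmeasurable" and "uncorrelated" are different findings.  Undefined atoms
are excluded from all aggregates.

Atom selection: hydrogens are never scored; occupancy-0 atoms are skipped;
of alternate conformers only the highest-occupancy altloc per atom site is
scored (ties prefer altloc 'A'), so the same density is not sampled twice.
The model average is the unweighted mean over defined atom scores.

## Group aggregation

Group means are unweighted means of defined member-atom Q values.  Protein
backbone is {N, CA, C, O, OXT} (CB counts as sidechain); nucleotide
phosphate is {P, OP1, OP2, OP3, O5'}, sugar {C1'–C5', O2', O3', O4'}, and
base everything else.  O5' belongs to the phosphate and O3' to the sugar —
the dominant convention; the sets are module constants and can be swapped.
Empty partitions (glycine sidechain, 5'-terminal phosphate) are absent from
the output, not reported as 0.  Waters and ions are treated as single-atom
small molecules.  With these conventions every defined atom lands in
exactly one whole-residue group, so the model average equals the
atom-count-weighted mean of whole-group means (tested).

## Statistical model of Q versus resolution

The trend `Q_mean(d)` is an ordinary least-squares cubic in reported
resolution d.  The shipped default constants are the archive-wide
calibration (coefficients −0.0016, 0.0434, −0.3956, 1.3366; offsets +0.024,
−0.126, +0.109; domain 1–10 Å); any (resolution, Q) table can be refitted
with `fit_regression` + `calibrate_offsets`.

Offset calibration works on the fit residuals.  The *peak* offset is the
vertical shift of the trend capturing the most residuals inside a window of
total width 0.01 in Q; the search runs over a grid at 0.001 steps spanning
the residual range, ties resolved toward the smallest |offset| (the window
width is the only documented constant of this construction; grid step and
tie-break are this package's choices).  The 95% band uses *equal-tail*
residual quantiles (2.5%/97.5%).  The archived offsets (−0.126/+0.109) are
asymmetric because the residual distribution is skewed toward low Q; the
equal-tail reading reproduces exactly that sign pattern on skewed synthetic
data.  A mode-anchored tail split would be an alternative reading; it is
not implemented because the equal-tail version already matches the
published asymmetry and has a cleaner coverage guarantee.

The rolling-window alternative computes the same three statistics (mode,
2.5%, 97.5%) directly from the Q values within ±w/2 of each query
resolution, with no polynomial; windows holding fewer than 20 points are
reported as gaps (NaN).  On data generated from the cubic-plus-noise model
the two constructions agree to within noise plus the trend's within-window
slope; the polynomial route gives smoother curves.

Classification compares an entry's Q to the closed interval
[Q_low_95%, Q_high_95%] at its d: below → `outlier_low` (typically a
misfitted model), above → `outlier_high` (over-sharpening or an
underestimated reported resolution), a value exactly on a bound is
`typical`.  Evaluation outside the calibrated domain warns and
extrapolates.

## Percentile ranks

Both ranks use the strict inequality `Q_ref < Q` in the numerator.  Window
membership for Q-relative-resolution is `|d_ref − d| ≤ w/2` with w the
*total* window width (a half-width mode exists as an option).  Default
w = 0.5 Å: the window-size diagnostic shows that for entries at ≥5 Å
resolution, wider windows make the rank increasingly anti-correlated with
resolution (the trend's slope leaks into the rank), while the window must
still hold enough entries for a stable percentile; 0.5 Å balances the two.
When the scored entry's id is present in the reference table it is excluded
from numerator and denominator, so an entry never ranks against itself
(this package's choice; with archive-sized tables it changes nothing
material).  Advisories: `suspect_low` below 5%, `suspect_high` at or above
95%, `as_expected` between.

## B-factor estimation

`B = (1 − Q_atom)·f` with one scaling factor f for the whole model.  The
scan renders, for each f in 0…300 step 10, a model-map with the implied
per-atom B-factors and scores it against the experimental map by Pearson
correlation about the mean over voxels within 3 Å of any heavy atom;
f_opt is the argmax (ties → smallest f, so a sharp map gives f_opt = 0 and
all-zero B).  The scan range and the CC criterion are the published
procedure; the step of 10, the 3 Å mask and the rendering base width are
this package's documented choices (masking keeps empty solvent regions from
swamping the correlation; results on synthetic fixtures are insensitive to
the exact radius).

Model-map rendering: each heavy atom contributes an isotropic normalised
Gaussian with variance σ₀² + B/(8π²) and integral equal to its electron
count, evaluated out to 4σ (negligible truncation at the default widths).
σ₀ = 0.6 Å ties a zero-B atom to the Q-score reference width, so "B = 0"
means "as sharp as a fully resolved atom" in the same sense the Q-score
uses.  Normalising the integral (rather than the amplitude) conserves each
atom's mass as B grows, which is what makes heterogeneous-B maps
discriminable in the scan; the overall scale is immaterial to CC.  Atoms
with undefined Q receive the median defined Q before conversion; Q > 1 is
clamped with a warning.

## Synthetic fixtures: what they emulate, what they do not

Toy models carry correct residue/atom nomenclature and sensible spacing for
every molecule class, but simplified geometry (regular-polygon rings,
idealised bond lengths).  That suffices for everything this package reads
from a model — names, elements, classes, non-clashing coordinates — and
keeps all fixtures generated in code.  Maps rendered from them are
noise-free sums of Gaussians plus optional white Gaussian voxel noise;
real cryo-EM maps additionally have CTF effects, solvent, masking artefacts
and spatially correlated noise, so passing tests demonstrate correctness of
the computations, not performance claims on experimental data.  The
`GaussianField` object evaluates the analytic density with no voxelisation,
which is the right oracle for identities of the correlation kernel itself
(Q = 1 on the exact reference profile); on a voxelised grid the same
identity holds only to interpolation error (Q ≈ 0.999 at 0.25 Å voxels).

Synthetic calibration tables draw resolutions uniformly over 1–10 Å and add
mean-centred skew-normal residuals (shape −4, scale 0.065, chosen once to
give a low-Q skew of realistic magnitude) to the default cubic trend,
clamping Q to [−1, 1].  This reproduces the qualitative structure that the
statistics modules consume — a smooth trend plus skewed scatter — not the
archive's exact residual law.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small
instances: toy models of ~60 atoms, maps of ~10⁵ voxels, calibration tables
of 10⁴ rows, 31-point scaling scans — sizes at which every quantity is
recomputable in seconds while exercising the full code path.  Coverage
checks use two independent 10,000-row tables (calibrate on one, measure on
the other), where the binomial sampling error of the 95% coverage is ~0.2
percentage points.  Floating-point policy: correlations are clipped to
[−1, 1]; quantiles use numpy's default linear interpolation; map I/O writes
float32 (MRC mode 2) while all computation is float64.
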