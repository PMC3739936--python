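# Methods

## Curve model

A helix trace of n Cα positions (nm) is modelled as one polynomial space
curve c(t): three coordinate polynomials over a shared scalar parameter,
all of one degree d.  The parameter assigns each residue its ordinal
offset from the first residue, with gaps in the residue numbering kept
as skipped integers so that a missing residue stretches, rather than
compresses, the parameterization (a chord-length alternative is
available).  The fit is (weighted) least squares per coordinate;
internally a Chebyshev basis mapped to the fit domain keeps high-degree
fits well conditioned, but the model is an ordinary polynomial and all
derivatives are analytic.

The degree is selected by the corrected Akaike criterion

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n − k − 1),

where rss is the joint residual sum over all three coordinates, k = 3(d+1)
counts all fitted coefficients, and n = 3·n_res counts all scalar
observations.  Counting scalar observations (rather than residues) is
the package's convention: it is the standard sample size for a joint
multivariate least-squares fit, and it admits the degrees (d ≈ 25–30)
needed for a polynomial to follow several turns of an actual coil, which
the validation fixtures exploit.  Candidate degrees run 1..min(max_degree,
n_res − 2); degrees with n ≤ k + 1 are excluded (the correction term is
undefined).  A numerically perfect fit (rss below a scaled floor of
~1e-22·n·‖x‖²) short-circuits the sweep at the smallest such degree, so
exact low-degree data are never over-fit on floating-point noise.

The default max_degree is 12: for protein-scale traces this smooths the
periodic backbone coil away and models the helix as a whole object,
which is the intended reading for all downstream descriptors — the
handedness of the backbone turns deliberately does not appear in the
fitted curve.  Fixtures that must *follow* a coil (closed-form
curvature/torsion recovery) pass max_degree = n_res − 2 explicitly.

B-factor weighting (weights = 1/B) enters only the curve fit, never the
surface construction; equal weights reproduce the unweighted fit
exactly.

### Helical ends

Fitting always uses all residues of the configured range.  The frayed
terminal turn is excluded at the *definition* level: helix ranges should
be delimited to the well-formed part of the helix, and profile position
bookkeeping then runs over all n − w + 1 windows (a 32-residue helix
gives 29 positions, a 41-residue helix 38, position j spanning residues
j..j+3).  For ranges that are not pre-trimmed, `drop_end_windows` (and
the `trim_tail_windows` config knob) removes windows overlapping a
chosen number of terminal residues while keeping the original position
numbering; the CLI applies no trimming by default.  No smoothing beyond
the polynomial fit itself is applied — the low-degree fit is the
smoother.

## Frenet profiles

κ = |c′ × c″|/|c′|³ and τ = det(c′, c″, c‴)/|c′ × c″|² are evaluated
from analytic derivatives; τ > 0 means right-handed twisting of the
fitted curve.  The turn-averaged value at position j is the
arc-length-weighted mean (1/L_j)∫ κ |c′| dt over the parameter span of
residues j..j+3, which normalizes the window average to curve length;
it is computed by Simpson quadrature on a 129-point window grid (the
integrand is a smooth low-degree rational function of polynomials, so
this is accurate far beyond the reported precision, and the average of
a constant field is exact up to rounding).  Points with a degenerate
tangent (|c′| < 1e-9 nm) or, for τ, vanishing curvature are excluded
from the mean; if more than half of a window's arc is undefined the
position is reported missing (NaN).

## Ruled surface

Both curves are discretized by the same number of points placed at equal
arc-length fractions (inverted from the quadrature arc-length function),
and matched points are connected: rulings with unit directions e_k
oriented from helix A to helix B.  A fixed orientation and one common
superposition reference for all structures are required for the *signs*
of τ, λ and J to be comparable across structures; the reference is a
user-supplied structure, and which atoms enter the superposition is
configurable (default: the Cα atoms of both configured helices — the
choice only ever flips signs globally).

* Striction points: the foot of the common perpendicular of rulings k
  and k+1 on ruling k, by the standard two-line closed form.  A pair
  with |e_k × e_{k+1}| < 1e-6 is torsal (parallel-ruling case): no
  striction point, λ = 0 by convention, and the computation would be
  unstable there anyway.  Rulings through a common point (the cone
  case) are torsal in the geometric sense too; they get a well-defined
  striction point (the apex) and λ = 0 emerges numerically.
* Distribution parameter: λ_k = det(Δa_k, e_k, Δe_k)/|Δe_k|² with Δ the
  forward difference to the next ruling.  The directrix points a_k are
  used instead of striction points: substituting any directrix
  a + w·e changes the determinant by a term with two proportional
  columns, i.e. not at all — discretely as well as continuously — and
  keeps the estimate finite near torsal stretches.  The difference-step
  scale cancels in the ratio; the estimator converges at second order
  on closed-form families (measured ≈ 2.0 on the helicoid).
* Conical curvature: J_k = det(e_k, Δe_k, Δ²e_k)/|Δe_k|³ with central
  first/second differences in the interior and one-sided stencils at
  the two end rulings (lower confidence); |Δe| below the torsal
  threshold reports the position missing.  Second-order convergence on
  the cone family (measured ≈ 2.0); J ≡ 0 on conoidal surfaces.
  The arctan transform maps J into (−π/2, π/2) for display — a
  logarithm would not do, J takes both signs.
* λ and J are invariant under rigid motion of both curves and negate
  under reflection; reversing traversal negates J.

Both λ (per adjacent pair) and J (per ruling) profiles are averaged by a
sliding unweighted mean over 4 consecutive positions (one average turn),
m positions giving m − 3 averages.  The default ruling count is the
rounded mean of the two helices' retained residue counts; it is a config
knob, since no single rule reproduces every published position count.

## Groove area

One curve point per retained residue (the last 3 C-terminal residues of
each helix are excluded by default to avoid end artifacts), strip
triangulated as (a_i, b_i, a_{i+1}) and (b_i, a_{i+1}, b_{i+1}), total
area = Σ ½|u × v|, per-residue area = total/(n_A + n_B).  A planar
strip triangulates exactly; degenerate triangles contribute zero.  If
the two helices retain different residue counts, both curves are
resampled at max(n_A, n_B) evenly spaced parameter values (the index
parameter ticks once per residue) and the normalization still uses the
retained residue counts.

## Group statistics

Percentiles use linear interpolation between closest ranks (type 7);
the convention is configurable since cohort results are mildly sensitive
to it.  Overlap percentages measure interval intersection against the
*measure* of the union (|A|+|B|−|A∩B|), each single interval, always in
[0, 100] (clamped against floating-point overshoot); degenerate
point-interval denominators give 100 for identical intervals, else 0.
Super-score classes: 1 = all three < 90, 2 = exactly two < 90, 3 = at
least two ≥ 90 — exhaustive and mutually exclusive over all threshold
patterns.  ΣIPR sums IPR lengths per group over maximal runs of constant
class; run totals add up to the column totals exactly.

Hampel screen: at each position, extreme ⇔ |x − median| > 3·1.4826·MAD
across structures (1.4826 makes the MAD a consistent normal-σ estimate;
3 is the classical cutoff, recorded in output metadata); a structure is
flagged when extreme at more than two positions of at least one
descriptor.  MAD = 0 positions are skipped with a warning.  The rule is
meant for cohort-scale groups: with fewer than ~30 structures the
small-sample MAD fluctuates enough that chance flags appear, which the
validation simulations account for by using 60-structure groups.

## Synthetic fixtures

Fixtures provide every operator's oracle without downloads: circular
helices (κ = r/(r²+c²), τ = ±c/(r²+c²) by handedness), the helicoid
(λ = b, J = 0), the cylinder (torsal everywhere), the cone (|J| = cot α)
and an offset-helix pair whose λ(u), J(u) come from a dense central
finite-difference oracle on the continuous parameterization — never from
the estimators under test.  The realistic helix preset (radius 0.23 nm,
rise 0.15 nm and 100° of phase per residue) mimics an α-helix Cα trace;
noise is iid isotropic Gaussian (default σ 0.005 nm), seeded and
bit-reproducible.  What the fixtures do not emulate: side chains,
B-factor structure correlated with disorder, missing residues beyond
what tests construct explicitly, lattice contacts — so passing tests
validate the geometry and statistics machinery, not crystallographic
data quality handling.

## Problem sizes and validation scope

The validation suite runs entirely on fixtures: ruled-surface
convergence uses 50–400 rulings, Frenet recovery 35-point/3.5-turn
helices, Monte-Carlo fit checks 100 seeds, outlier recovery 60×34
matrices — sizes at which every closed form is resolved to well below
the asserted tolerances.  Reproduction of published per-structure values
(groove areas and helix RMSDs of specific MH complexes) requires the
corresponding PDB files under `data/pdb/`, which are not redistributed
with the package; cohort-scale tables additionally depend on a
historical snapshot of the PDB and are out of scope.

## Known limitations

* Helix ranges are configuration; the shipped MH1/MH2 presets are
  approximations and should be adjusted per allele.
* The polynomial model is global: a severe local disruption (a broken
  helix) spreads into neighbouring windows through the fit.
* Descriptor signs are only comparable across structures superposed on
  one common reference; mixing references flips signs.
* End rulings of the J profile use one-sided stencils and are less
  reliable; first/last striction positions inherit forward-difference
  (first-order) error where the surface geometry changes quickly.
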