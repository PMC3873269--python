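# Methods

## The model

`bclswitch` implements a mass-action model of the protein-interaction
network through which the Bcl-2 family decides mitochondrial outer
membrane permeabilization (MOMP), the commitment step of intrinsic
apoptosis. Sixteen proteins are represented individually rather than as
functional groups:

* six **anti-apoptotic guardians** (Mcl-1, A1, Bcl-xL, Bcl-2, Bcl-w,
  Bcl-B), which inhibit pro-apoptotic relatives by heterodimerization;
* six **enablers** (BH3-only sensitizers: Noxa, Bad, Puma, Hrk, Bmf, Bik),
  which only sequester guardians;
* two **activators** (tBid, Bim), which sequester guardians *and*
  catalytically convert effectors to their active conformations;
* two **effectors** (Bax, Bak), whose activated forms aBax/aBak pair into
  the three dimers aBax~aBax, aBak~aBak, aBax~aBak.

The readout is the **MAC abundance** — the summed abundance of the three
activated-effector dimers, a deliberate simplification of the real
mitochondrial apoptosis channel, which comprises up to tens of monomers.
The reaction system has 62 entries (4 catalytic activations, 38 guardian
bindings, 3 effector dimerizations, 16 zeroth-order productions and a
catch-all first-order degradation of every species) over 59 species, and
is shipped as a YAML data file, not code. Two weak-affinity pairs
(Bcl-2 with Hrk and with Bik) appear in the reaction table although the
qualitative binds-and-inhibits summary omits them; the cross-check in
`ReactionNetwork.check_interaction_table` carries them as documented
extras.

Semantics are deterministic mass action: homodimerization flux is
`kd*x^2`, not the combinatorial `x(x-1)/2`; a degraded complex removes
both partners; catalytic activations are irreversible. Abundances are
molecules per abstract reaction volume with 1 nM = 600 molecules; time is
in hours.

Each produced species starts at its production/degradation balance
`kp/kdeg`; activated effectors and complexes start at zero. The sixteen
production rates are the model's only independent inputs — they stand in
for all transcriptional and post-translational up-/down-regulation,
including, for tBid, caspase-8 cleavage of Bid.

## Parameters

Production rates (molecules/h): activators 0.1, enablers 1.0, guardians
10.0, effectors 60.0. Degradation: `kdeg = ln2/10 per h`, a common ~10 h
half-life for every species (real Bcl-2 half-lives range from tens of
minutes to a day; the single catch-all rate is a deliberate reduction).

The kinetic constants are **calibrated estimates**, not literature
measurements: the sources behind the model give affinity *classes*
(strong/intermediate/weak, `ks:ki:kw = 1:10:100` in dissociation
constant), not printed rate values. We set

| constant | value | units | meaning |
|---|---|---|---|
| ks | 0.5 | molecule^-1 h^-1 | strong binding on-rate |
| ki | 0.05 | molecule^-1 h^-1 | intermediate |
| kw | 0.005 | molecule^-1 h^-1 | weak |
| ka | 0.5 | molecule^-1 h^-1 | activation efficiency |
| kd | 0.5 | molecule^-1 h^-1 | effector dimerization |
| km | 0.2 | h^-1 | complex dissociation |

The absolute scale was chosen once, against the qualitative response
taxonomy the model is meant to exhibit (see below), and is generous by
solution-phase standards (`ks` corresponds to ~8e7 M^-1 s^-1 at the
600 molecules/nM convention; the dissociation constants are sub-pM).
These are effective rates for membrane-localized reactions, where
two-dimensional confinement concentrates reactants far beyond their
cytosolic levels. The structural requirement they encode is twofold:
sequestration of activators must outrun protein turnover
(`ks * guardian pool >> kdeg`), or free activator levels respond only
weakly to guardian availability and the switch loses its two branches;
and complex dissociation must remain slow enough (`km` within a few
multiples of `kdeg`) that binding is closer to consumption than to
equilibrium exchange, which is what lets the on-state effector flux
saturate the guardian supply. All constants are configuration-overridable,
and every analysis records the parameter set it used.

## Steady states

The right-hand side and its Jacobian are assembled analytically from the
channel structure (reversible reactions expand to two irreversible
channels; the catch-all degradation to one channel per species). Steady
states are found by stiff integration (LSODA) in time chunks growing by
2.5x from 50 h, until `max|dx/dt|` falls below a scale-aware tolerance of
1e-9 times the total monomer pool `sum(kp)/kdeg`, with a 10^4 h cap.  A
Newton polish (`scipy.optimize.root`) is attempted once the residual is
within 10^3 of tolerance and is accepted only if it stays nonnegative and
within 5% of the integrated state — integration, not root search, chooses
the *attracting* branch, which the hysteresis protocol depends on.
Stability is classified from the eigenvalues of the analytic Jacobian.
Abundances dipping below -1e-9 (relative) are treated as integrator
failures; smaller excursions are clamped to zero.

Two identities guard every solve: monomer balance (each non-production,
non-degradation reaction conserves monomer content, so the weighted total
`sum(w_i x_i)` with `w=2` for complexes must equal `sum(kp)/kdeg` at any
steady state, to 1e-6 relative) and closed-form agreement on three toy
networks (pure production/degradation, a single reversible binding, and
activation plus dimerization) solved independently by algebraic root
search in the tests.

## Stimulus-response sweeps

A sweep varies one production rate (or a linked pair — Hrk & Bik and
Bad & Bmf are co-varied with equal multipliers) over 60 log-spaced points
spanning three decades, holding everything else at default.  The first
point starts from the recomputed initial condition; every later point
starts from the previous converged state.  Up- and down-sweeps therefore
trace the two attracting branches; the system is called bistable where
the branches differ by a factor of at least 5 (conservative against grid
noise: real branch separations here are 10^2-10^4).  Thresholds are the
largest log-response steps of each branch, and refinement moves them by
less than one coarse grid step (asserted in tests).

Curves without a branch gap are summarized by an effective Hill fit,
`basal + vmax * s^n / (k^n + s^n)` (or its repressive mirror), least
squares on the response scale — the scale on which such dose-response
curves are conventionally displayed.  `n_H > 1.5` reads as sigmoid
("push-button"), smaller as hyperbolic ("tuner"); non-monotone gap-free
curves are reported "unresolved" rather than forced into a class.

Under the default calibration the suite exhibits: robust wide hysteresis
for Bax and narrower for Bak; hysteresis for tBid, Bim, Puma, Bad & Bmf;
a very narrow bistable window for Hrk & Bik; monotone suppression by the
guardians (with hysteresis in the A1 direction); and a graded saturating
response to Noxa with no hysteresis anywhere in its range.  The Noxa
"tuner" response deserves a caveat: its dynamic range sits at 30-3000x
the default Noxa production (Noxa must outcompete the strong-class
ligands of Mcl-1 and A1, which it binds only with intermediate/weak
rates, so its titration knee sits near the combined Mcl-1+A1 production),
and the knee steepens any Hill fit that includes it.  Over the canonical
replication range (multipliers 10^1.5 to 10^4.5) the fitted Hill
coefficient is ~1.2 — hyperbolic by the classifier's cutoff, but the
curve is a titration shoulder feeding a hyperbola, not a textbook
Michaelis-Menten form.

## Monte-Carlo co-variation and the MOMP threshold

Each iteration multiplies all 16 production rates by independent random
factors `q` and solves to steady state from the recomputed initial
condition.  The default law is log-uniform over two decades,
`q = 10^U(-1,1)`, the natural symmetric reading of up-/down-regulation;
linear-uniform sampling over an interval is available as an alternative
mode, and the interval is configurable.  Non-converged iterations are
excluded from the distribution, counted and reported.

The response distribution is strongly bimodal (Hartigan dip test;
implemented in-package from the convex-minorant characterization and
validated against an exact linear-programming oracle, with the null
calibrated by Monte Carlo from the uniform distribution).  The threshold
between the pro-survival and pro-MOMP classes is the density minimum
between the two dominant modes of a Gaussian KDE of `log10(MAC + 1e-3)`
(Silverman bandwidth x1.5); responses strictly above it are labelled
pro-MOMP.  The estimator refuses to return a number when the smoothed
density does not have exactly two dominant maxima.

A structural caveat: in every calibration of this network that is
bistable at all, the pro-survival mode sits essentially at zero MAC —
with ~900 free guardian molecules and fast binding, trace activated
effectors are absorbed long before they dimerize, so the off-branch
cannot "leak" dimers at the tens-to-hundreds scale.  The log-density
valley bottom therefore falls at units-to-tens of dimers, orders of
magnitude below the on-branch.  A threshold quoted in the hundreds of
dimers corresponds to the *onset of the pro-MOMP mode* (the valley's
right edge, which is also what a linear-axis histogram minimum finds),
not to the log-scale valley bottom; the two notions differ by roughly two
orders of magnitude here, and the choice matters when comparing
commitment thresholds across studies.  The package reports the log-scale
valley bottom and exposes the density diagnostics so either convention
can be read off.

The threshold is consistent with the sweeps: it lies strictly between the
two branches at every grid point of every detected bistable region.

## Input-pattern analysis

The stimuli matrix is mean-normalized per column and projected by
standard centered PCA (sign fixed by the largest-loading-positive
convention).  Class separability in the PC1-PC2 plane is quantified as
the 5-fold cross-validated balanced accuracy of a linear discriminant,
with the silhouette score exported alongside.  One mathematical fact
shapes expectations here: with independently sampled, identically
distributed multipliers, the mean-normalized stimuli have an isotropic
population covariance, so the leading sample PCs are sampling-noise
directions and carry, in expectation, only 2/16 of any linear
discriminant structure the labels induce.  Plane separability scores for
this design therefore hover near chance regardless of how sharply the
full 16-dimensional input space separates the classes, and differences
between models in this score are weakly identified at 10^3-10^4
iterations.

Input potency is the point-biserial correlation of each *raw* production
rate with the dichotomous response class, with the population
(divide-by-n) standard deviation, making the identity with Pearson
correlation on 0/1 labels exact (asserted to 1e-12 on a thousand random
instances).  Under the default calibration tBid carries the largest
positive coefficient and A1 and Bcl-xL the most negative, with all six
guardians negative and all activators/effectors/Puma positive.  Bim's
coefficient is positive but well below tBid's: Bim is sequestered by five
guardians at the strong rate class whereas tBid faces one strong and two
intermediate sinks, so equal up-regulation buys less free Bim than free
tBid.  Likewise Noxa and Bmf rival Puma among the enablers through the
leverage of the Bak channel (guarded by only three proteins, two of which
Noxa removes).  These orderings are calibration-dependent wherever
coefficients are close.

## Topology mutation

Alternative networks are generated by adding absent or deleting existing
inhibitory bindings (any guardian x any BH3-only or activated effector;
22 addable, 38 deletable in the default network) and activator-effector
activations (all 4 exist by default, so initially only deletable).
Dimerizations, production and degradation are immutable — the first
defines the readout, the others the input structure.  Group consistency
is enforced: every guardian keeps at least one inhibitory edge, every
effector at least one activation.  Added bindings default to the strong
class (maximally perturbing, configurable).  Mutations are distinct
(never undoing an earlier one), so the reaction-set symmetric difference
equals the mutation count, and the recorded list is exactly invertible.

The alternative-models experiment runs the Monte-Carlo analysis on ten
networks carrying five mutations each (10^3 iterations per model at the
default experiment scale), extracts each model's own threshold, and
scores PC-plane separability per model.  Bimodality survives every
mutated topology we have examined — the toggle mechanism is robust to
edge-level rewiring — while the separability comparison inherits the
weak identification discussed above.

## What the synthetic conditions do and do not show

All inputs are generated in silico from the network definition and the
calibrated constants; there is no external data.  Passing tests show that
the implementation faithfully realizes this model and that the model, so
calibrated, reproduces the qualitative switching phenomenology.  They do
not validate the rate constants against measured kinetics, the common
half-life against per-protein turnover, the dimer-level MAC readout
against channel stoichiometry, or the independence of production rates
from Bcl-2 family activity — all deliberate simplifications carried by
the model itself.

## Problem sizes

The shipped analyses use 10^4 Monte-Carlo iterations for the single-model
experiment, 60-point/3-decade sweeps, and 10 mutated models x 10^3
iterations for the topology panel; all are arguments, and the unit-test
suite exercises the same code paths at reduced sizes.
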