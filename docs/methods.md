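# Methods

This note documents the models, estimators and design choices behind
`protonpocket`, in the spirit of a simulation-analysis package's methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The system and the ensemble

The gastric H⁺,K⁺-ATPase binds K⁺ in a transmembrane pocket of five acidic
residues — E343, E795, E820, D824 and D942 — plus the basic K791. In
classical MD a protonation state is a fixed assignment of protons to these
carboxylates; it stands in for a pH regime (more pocket protons ≈ lower
luminal pH). The standard ensemble enumerates all C(5,2) = 10 two-proton
and C(5,3) = 10 three-proton states (20 total) and runs three replicates of
each: 60 trajectories, 250 ns of production each, 750 ns per state. States
with 1, 4 or 5 protons are enumerable through the API but excluded from the
default ensemble: one proton leaves the pocket with a destabilising net
charge, and four or five essentially abolish K⁺ binding. State labels
concatenate the protonated residues in fixed pocket order with a `+` suffix
(`E343+E795+`), and labels round-trip through parsing; the fixed order makes
labels canonical join keys across modules.

## Per-frame pKa values

Production workflows compute per-frame pKa values with an external
empirical predictor on trajectory snapshots (typically every 1 ns); the
`pka` module ingests those tables (CSV with header
`time_ns,E343,E795,E820,D824,D942`), validating monotone unique times,
numeric cells, and completeness. Missing values are tolerated up to 10% per
residue and dropped pairwise in the correlation stage — silent imputation
would bias r; more missingness is a hard error.

For fully synthetic end-to-end runs the module provides a deliberately
simple stand-in estimator (it is *not* a re-implementation of any published
predictor; only the downstream correlation structure matters):

    pKa = pKa_model(class) + burial + Σⱼ charge(dⱼ)

with model values 3.80 (Asp) and 4.50 (Glu); burial = w_b · (N_heavy within
r_b − N_ref) clamped to [0, 2.0] with w_b = 0.02 per atom, r_b = 0.9 nm,
N_ref = 10; and ±w_c/d Coulomb-like shifts (w_c = 2.4 pKa·nm, cutoff
r_c = 1.2 nm) — positive neighbours (K⁺, the K791 amine) lower the pKa,
negative neighbours (deprotonated carboxylates) raise it. The estimator
uses heavy-atom geometry only (matching the external predictor's
convention), depends only on interatomic distances (hence is exactly
invariant under rigid motions), and is monotone in the approach of a
positive charge. All weights are configuration-exposed.

## Correlation analysis

For each trajectory the pairwise Pearson coefficient is computed on the
trailing window (default 100 ns, i.e. n = 100 samples at 1 ns). Both the
sums and the means use only the windowed data: mixing full-trajectory sums
with windowed means would not be a correlation coefficient. If the window
is not a whole multiple of the sampling interval the sample count is
floored (logged). Zero-variance input raises an explicit error rather than
returning NaN. Confidence intervals use the Fisher z-transform
(tanh(atanh r ± z_crit/√(n−3))), two-sided at a configurable level
(default 99%); empirical coverage of the 99% interval over thousands of
null simulations is verified to sit in [0.985, 0.995]. The top-k pair
report sorts by |r| with ties broken in canonical pocket order so output is
stable across runs.

## Transfer-network inference

A directed proton-transfer hypothesis requires, per trajectory:

1. exactly one protonated member in the pair (the donor) — both-protonated
   and both-deprotonated pairs are excluded regardless of r;
2. r strictly below the threshold (default −0.5);
3. spatial proximity — time-averaged minimum carboxyl O–O distance within a
   cutoff, default 0.6 nm (typical carboxylate H-bond/water-bridge reach;
   the cutoff is a package choice, configuration-exposed);
4. depth below the luminal access point, reported as a per-residue
   annotation rather than an automatic filter, since no quantitative rule
   exists for release to bulk.

The donor is defined operationally as the protonated member; the
low-pKa→high-pKa direction expectation is recorded per pair as a
consistency flag (a protonated donor with the higher windowed mean pKa is
flagged, not dropped). An *instance* is one (state, replicate) trajectory
contributing a directed pair; duplicate entries are deduplicated with a
warning, so edge counts sum exactly to the number of accepted
(trajectory, pair) tuples. Edges are ranked by instance count as the
transfer-likelihood proxy and exported as JSON, DOT (edge weight = count)
and a donor/acceptor/instances CSV.

## Ion binding and occupancy

No universal geometric definition of "bound" exists for a promiscuous,
hydrated pocket, so a coordination criterion is used: an ion is bound iff
at least 2 pocket carboxylate oxygens lie within 0.35 nm (a typical K⁺–O
coordination distance); both parameters are exposed. Site classification is
a pure function of the coordination multiset: site III iff a strict
majority of coordinating oxygens come from D824/D942 (the deeper aspartate
locus), ties falling to site I/II with a logged flag — sites I and II
themselves are not distinguishable. First binding during equilibration is
reported as t = 0. Occupancy summaries use the *end-of-trajectory* bound
count (the convention for the ensemble bar charts), with mean and standard
error (n−1 denominator) over replicates, plus time-averaged diagnostics.
Group means over the two- and three-proton states probe the
stoichiometry-variation hypothesis (fewer K⁺ at lower pH).

A caveat on the occupancy-vs-composition correlation: within a fixed
proton-count group the protonated-Glu and protonated-Asp counts are exactly
complementary (they sum to the group's proton count), so the aspartate
correlation within the three-proton group is forced to mirror the glutamate
one. The aspartate null check is therefore computed over all 20 states
(`n_protons=None`), where a glutamate-driven occupancy leaves it near zero.

## Umbrella sampling and WHAM

Window planning follows the production layout: 47 equidistant centers from
0.20 to 2.50 nm at 0.05 nm spacing (counted float-safely), harmonic force
constant 5000 kJ/mol·nm², T = 310 K. Initial frames per window are the
earliest frames of a pull trace nearest each center. WHAM solves

    P(z_b) ∝ Σᵢ nᵢ(b) / Σᵢ Nᵢ exp(β(fᵢ − Uᵢ(z_b))),
    exp(−βfᵢ) = Σ_b P(z_b) exp(−βUᵢ(z_b))

by self-consistent iteration on 200 equal-width bins until
max|Δβfᵢ| < 10⁻⁷ (max 100 000 iterations; non-convergence raises with the
residual). Two numerical details matter at stiff biases:

* the bias Boltzmann factor is evaluated as its exact *bin average* (an erf
  closed form for harmonic biases) rather than the bin-center value —
  βk·h² is not small at k = 5000 and bin-center evaluation accumulates a
  visible stitching drift across 47 windows;
* since the bias factors never change across iterations they are
  precomputed once and the loop runs in linear space (with a log-space
  fallback if window constants approach float range), making a full solve
  a fraction of a second.

Adjacent-window histogram overlap is checked before solving (a named gap
raises an error). With a single unbiased window the estimator reduces
exactly to Boltzmann inversion, −k_BT ln(counts). Profiles are shifted so
the mean over a bulk region is zero; the binding free energy is the well
minimum on that scale, reported in kJ/mol and k_BT. Note that k_BT at
310 K is 0.616 kcal/mol; quotes equating it with 0.8 kcal/mol are not used
here. Errors come from a moving-block bootstrap over each window's time
series (default block 50 samples, 200 replicates, warm-started from the
full-data solution and recentred per replicate before taking per-bin
standard deviations) — block resampling because window samples are
autocorrelated; errors scale as ~1/√N in the samples per window. The
flat-bottom cylindrical lateral restraint used when generating window
samples (radius 1 nm) shapes only the sampled data and does not enter the
1-D estimator.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
analysis assumes and no more physical realism than that:

* **pKa ensembles**: stationary Gaussian AR(1) (autocorrelation time 5 ns,
  so the 100 ns window carries ~10–20 effective samples and genuinely
  stresses the interval machinery), cross-residue correlation imposed by a
  Cholesky factor of a positive-semidefinite target matrix (identity plus
  planted pair coefficients such as −0.923 for E795/E820). Protonated
  residues sit 2 pKa units above their model value so donor-consistency
  flags behave sensibly. A change-point mode swaps a pair's means
  mid-trajectory to mimic abrupt pKa exchanges.
* **Pocket geometry**: a fixed toy arrangement with the three glutamates
  ringing the site I/II locus near the luminal mouth, the aspartates deeper
  at site III, K791 between, and E795/E820 proximal (min O–O < 0.6 nm) by
  construction; a scale parameter stretches it to exercise the proximity
  filter's rejection branch.
* **Ion trajectories**: endpoint occupancy targets per state — a flat 1.87
  for two-proton states (with a 0.5 site III share when both aspartates are
  deprotonated) and 1.91 − 0.45·(#protonated Glu) for three-proton states,
  whose state-weighted mean is 1.10 and which plants the negative
  glutamate-protonation/occupancy trend. floor(target) ions bind for sure
  plus one with the fractional probability (low endpoint dispersion, which
  is the generator's contract), with truncated-exponential binding times
  and optional unbinding.
* **Umbrella windows**: inverse-CDF sampling of exp(−β[U(z) + bias]) on a
  10⁴-point grid. The discrete CDF is mass-centred on its nodes — a naive
  cumulative sum shifts every sample by half a grid cell, which the stiff
  bias converts into a systematic tilt of the stitched profile. An optional
  Gaussian-copula AR(1) stream imposes a stated autocorrelation time while
  preserving the marginal exactly. The default generator potential is a sum
  of Gaussians: a −12 kJ/mol binding well at 0.5 nm and a +6 kJ/mol barrier
  at 1.1 nm, flat in bulk (barrier ≈ 7 k_BT from the well bottom).

All generators are bit-reproducible given (seed, spec); per-stream seeds
derive from the master seed through `numpy` `SeedSequence` spawn keys.

## Problem sizes in the checks

The test suite and acceptance script run at desk scale by choice:
correlation recovery uses 100 replicates of n = 100 windows; the
transfer-motif recovery uses the full 60-trajectory ensemble with a motif
planted in 12; occupancy group means average 24 replicates per state of
25-frame trajectories; the WHAM round trip uses the production 47-window
layout at 2·10⁴–4·10⁴ samples per window; interval coverage uses 2000 null
datasets. With these sizes the whole acceptance run takes seconds on one
CPU.

## Limitations

Passing tests demonstrate the *estimators* are correct and calibrated on
data satisfying their assumptions; they say nothing about force fields,
sampling convergence of real MD, or the accuracy of empirical pKa
predictors on membrane proteins. Proton transfer itself is never simulated
(classical MD cannot), only inferred as a hypothesis from correlation
structure; the proximity cutoff and binding criterion are package defaults
where the underlying physics offers no sharp definition; and real
trajectory ensembles have richer noise (conformational substates, drift)
than the stationary AR(1) generator emulates.
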