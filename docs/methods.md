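# Methods

This note records the models, numerical choices and deliberate
simplifications behind `doseuq`, and what the synthetic-data tests do and
do not demonstrate.

## Biokinetic model

Radionuclide transport in the body is a first-order linear compartmental
system: for compartment *i*,

    dq_i/dt = −(Σ_j k_{j←i} + λ_p) q_i + Σ_j k_{i←j} q_j ,

with q_i the activity (Bq), k the transfer coefficients (d⁻¹) and λ_p the
physical decay constant.  Intake is modelled as an acute unit bolus at
t = 0 into the intake compartment (ingestion through the mouth/oesophagus),
i.e. the inflow term İ(t) becomes an initial condition.  With all losses
represented by explicit sink compartments (cumulative urine and faeces),
every column of the rate matrix sums to −λ_p, which the tests assert.

The packaged cerium model has 26 compartments: blood exchanging with a
two-stage liver, three soft-tissue pools of increasing half-time, cortical
and trabecular bone (surface → volume → marrow → blood), kidneys (a
urinary-path compartment and a slow "other tissue" compartment), gonads,
and the alimentary-tract transit chain mouth → oesophagus (fast/slow) →
stomach → small intestine → right/left colon → rectosigmoid → faeces, with
urinary excretion via the urinary bladder.  Transfer coefficients are the
packaged nominal means with 2.5th/97.5th-percentile bounds
(`data/cerium_parameters.csv`).  The single printed rate for the mouth →
oesophagus step is split 0.9/0.1 between the fast and slow oesophageal
columns, the standard alimentary-tract fast/slow fraction.  Cumulative
urine and faeces are excluded from the dosimetric source regions; the
urinary bladder *content* is a source region.

### Decay chains

The ¹⁴⁴Ce chain couples three copies of the compartment model into one
block lower-triangular system.  Because the state is activity rather than
atom number, ingrowth of daughter *d* from parent *p* enters with rate
λ_d · branching(p→d) (substituting q = λN into the atom-based Bateman
production term b·λ_p·N_p).  An independent atom-count formulation in the
test suite confirms this convention on toy chains with branching.  Parent
and progeny share the cerium compartment model and parameter values (the
light lanthanides are chemically similar enough for a common model).
¹⁴⁴Nd is treated as stable.  The ¹⁴⁴Ce/¹⁴⁴ᵐPr branching fractions and all
praseodymium emission lines are provenance placeholders in the packaged
chain file, intended to be overridden from an evaluated decay database;
every chain-arithmetic test uses toy chains with stated branchings.

### Solvers and residence times

The system is linear, so the primary solution path is exact: activities by
matrix exponential, and time-integrated activities (residence times) from
the identity A·x = q(T_D) − q(0).  When that difference cancels to noise
(quasi-stable nuclide, closed kinetics) or A is singular, the augmented
exponential exp([[A, I], [0, 0]]) supplies ∫₀^T e^{At} dt exactly.  A stiff
implicit Runge-Kutta backend (scipy's Radau, rtol 1e-8 / atol 1e-12,
analytic Jacobian) is retained as an alternative and must agree with the
closed form to 1e-6 of solution scale — asserted on 50 randomized 5–30
compartment chain systems.  The commitment period defaults to
T_D = 50 × 365.25 = 18262.5 d.  Solver output is clipped at −1e-10
(relative) for negativity; anything below that tolerance raises.

## Parameter uncertainty and sampling

A normal parameter with mean μ and coefficient of variation c_v has
σ = c_v·μ and 95% bounds μ ∓ 1.96σ; a lognormal parameter with geometric
mean μ* and geometric SD σ* has bounds μ*·(σ*)^∓1.96.  Transfer
coefficients derive from removal half-times and deposition fractions as
k = ln2/T · F, with first-order propagation c_v(k) = √(Σ c_v²) over the
multiplicative factors.  The default biokinetic c_v is 0.20, overridable
per parameter; where a packaged table prints explicit bounds, the loader
infers the distribution scale from the upper bound, σ = (max − μ)/1.96,
and truncates at the printed [min, max] *as printed*, even when the bounds
are asymmetric about the mean (several packaged rows are; forcing symmetry
would discard printed information, so the asymmetry is honoured rather
than resolved).

Latin hypercube sampling operates per parameter on the [min, max]-truncated
distribution: the truncated probability mass is divided into n
equal-probability strata, one value is drawn per stratum through the
inverse CDF of a uniform point in the stratum, and columns are paired by
independent random permutations from the seeded generator.  Parameters are
sampled independently — no correlation structure, matching the procedure
being modelled; rank-correlation control is a deliberate non-goal.
Biokinetic and S-value designs use independent substreams (independently
permuted, not rank-paired).  Truncating at the 95% bounds means the
sampled distribution is slightly narrower than its untruncated parent; the
empirical UF of a truncated lognormal is (σ*)^1.66 rather than (σ*)^1.96.
This is a property of the procedure, not an artefact, and the known-truth
tests that compare against the closed form widen the truncation to ±6
log-σ so the comparison is exact.

## S values

Per phantom, S_w(r_T ← r_S) = Σ_R w_R Σ_i E_i·Y_i·Φ(r_T ← r_S, E_i), with
energies in MeV converted by 1 MeV = 1.602176634e−13 J and w_R = 1 for
photons and electrons (low-LET convention).  Emission spectra are discrete
lines: mean β energies with branch yields, not full β spectra — a
documented simplification; full spectral folding belongs to evaluated-
database tooling.  Photon SAFs come from per-phantom grids, log-log
linearly interpolated in energy (standard practice for SAF grids), exact
at nodes, constant-extrapolated beyond the grid ends with a logged
warning.  Electron SAFs use grids when present, otherwise the
local-absorption approximations: 1/M_T for self-irradiation, 0.5/M_c for a
wall irradiated by its content, 1/M_TB for a total-body source, zero for
other cross-fire.  Unsegmented targets resolve deterministically through a
per-phantom surrogate map (e.g. heart wall → total heart).

Across a phantom ensemble, each organ pair's S values are fitted first as
normal (sample mean, n−1 SD).  If the normal 2.5th percentile
μ − 1.96σ is non-positive — the normal model would admit negative
S values — the pair is refitted as lognormal (geometric mean, geometric SD
from the n−1 SD of the logs).  The n−1 estimator matters because ensembles
are small (3 or 7 phantoms) and is asserted in the tests.  Organ pairs are
sampled independently; the inter-organ correlation induced by phantom
identity (a large phantom is large everywhere) is deliberately not
modelled — a known fidelity limit.  A "phantom-resampling" mode that would
preserve those correlations is out of scope.

## Dose pipeline

Per sample: one LHS row of the biokinetic parameters rebuilds the transfer
coefficients, the chain system is solved and residence times aggregated to
source regions; one LHS row of every organ pair's S value is taken; the
sample's sex is a fair Bernoulli draw from a third substream.  Organ
equivalent-dose coefficients follow from h = Σ Ã·86400·S_w (86400
transformations per Bq·d), the colon dose is the mass-fraction-weighted
mean of the right-colon/left-colon/rectosigmoid wall doses (reference wall
masses 150/145/70 g; the legacy 0.57·ULI + 0.43·LLI rule is available as a
reporting transform only), and e_DW applies the ICRP 103 tissue weights
with the gonad target and the prostate/uterus remainder member resolved by
the sample's sex.  The remainder is the arithmetic mean of its 13 member
organs at weight 0.12.  Uncertainty in w_T and w_R is excluded by design.
n defaults to 500 samples.

Summaries use linear-interpolation empirical quantiles (numpy default); at
n = 500 the estimator choice shifts UF by well under 1%.  UF requires
strictly positive samples.  Reproducibility is exact: a run is a pure
function of (configuration, seed), with the three substreams derived from
the seed by a seed sequence.

## Synthetic phantoms and known-truth scenarios

The synthetic generator exists to exercise the plumbing and the statistics,
not to approximate radiation transport.  Its photon SAF kernel is a
mass-scaled self term (0.3/M, softly decaying with energy), a wall←content
term (0.15/M_c), and distance-class cross terms (0.03/d², d ∈ {1,2,3}
assigned deterministically per pair); per phantom, organ masses and
per-pair SAFs are multiplied by lognormal draws with geometric SDs
`mass_gsd` (default 1.15) and `saf_gsd` (default 1.30).  The defaults put
the fitted inter-phantom S-value spread in the few-tens-of-percent CV
regime reported for real voxel-phantom ensembles; they are study
conditions, set once.  Sexes alternate female-first.  What passing tests
show: the propagation machinery is exact (closed forms), unbiased
(truth-scenario UF recovery within 5% at n = 5000) and reproducible.  What
they cannot show: anything about real anatomies — synthetic SAF magnitudes
are placeholders, inter-organ correlations are absent, and bone dosimetry
enhancement effects are out of scope.

The known-truth scenario is a decay-only compartment holding a single-line
electron emitter, so every stage has a closed form: Ã = (1 − e^{−λT_D})/λ,
h = Ã·86400·E·Y·(1/M)·1.602176634e−13, and with lognormal S-value
variability of geometric SD g the sampled dose is lognormal with
UF = g^1.96.

## Degenerate inputs and edge policies

Zero-spread parameters and single-value or all-zero S-value fits collapse
to point masses (sampled as constants, with a warning for single-value
fits).  A phantom ensemble of identical phantoms therefore yields UF ≡ 1
end to end, which is asserted.  Negative transfer coefficients, branching
sums above 1, non-positive masses or energies, NaNs in any reader, and
configs without a seed are rejected at validation time — no silent
nondeterminism and no silent sign errors.

## Problem sizes

Default analyses use n = 500 samples, three synthetic phantoms and the
26-compartment model (a three-member chain for ¹⁴⁴Ce, a 78-dimensional
system); the truth-recovery check uses n = 5000 on the one-compartment
scenario; solver-oracle equivalence uses 50 randomized systems of 5–30
compartments.  These sizes were chosen so the full suite and the
reproduction script each run in seconds to a few minutes on a single core
while keeping Monte Carlo error well inside the asserted tolerances.
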