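# Methods

## Circuit model

The model couples six sources with eight neural-mass subpopulations:
cortex (glutamatergic spiny stellate and pyramidal cells, GABAergic
interneurons), striatum, GPe, STN, EPN and thalamus. EPN and thalamus are
*hidden* — no recording channel — but their parameters remain inferable
through the influence they exert on the recorded nodes. Nine extrinsic
connections close the loop: cortex→striatum, cortex→STN (hyperdirect),
striatum→GPe (indirect), striatum→EPN (direct), the reciprocal GPe↔STN
pair, STN→EPN, EPN→thalamus and thalamus→cortex; four intrinsic cortical
connections couple the three cortical subpopulations. Two pallidofugal
variants (adding GPe→EPN or GPe→striatum) are available for evidence-based
model comparison.

Each subpopulation carries one alpha-kernel synapse pair (voltage and
current state), i.e. 16 states in all. The kernel class follows the
population's transmitter: excitatory populations use the fast kernel
(prior means H = 8 mV, τ = 1/κ = 4 ms), inhibitory populations the slow
one (32 mV, 16 ms). This one-kernel-per-population simplification (rather
than separate excitatory/inhibitory channels per population) keeps the
state dimension at 2N while preserving the loop phase structure that sets
the resonant frequencies. Mixed excitatory/inhibitory afferents onto one
population therefore share that population's kernel; their transmitter
signs enter through the connection weights.

**Sigmoid.** The firing nonlinearity is a centred logistic
`S(v) = σ(ρ(v − v₀)) − σ(−ρv₀)` with ρ = 0.56 mV⁻¹ and v₀ = 6 mV
(conventional neural-mass values, recorded in `circuit.py`). Centring
makes the origin an exact fixed point of the noise-free dynamics, so the
linearisation point is analytic; the damped-Newton fixed-point solver
(zero start, tolerance 1e−9, ≤ 100 iterations) exists to guard future
non-centred configurations.

**Connection strengths.** Prior-mean gains are specified as dimensionless
*link gains*: the steady-state gain of one connection is
`(H/κ)·strength·S′(0)`, so raw strengths are normalised by the receiving
population's DC gain (which differs 16-fold between kernel classes).
Default link gains are 0.8 (intrinsic cortical) and 0.6 (extrinsic),
placing every loop product below one at the prior mean (stable, weakly
resonant).

**Delays.** Conduction delays (2 ms intrinsic, 4 ms extrinsic prior
means, each with a global log-scale multiplier) enter the linearised
model through a first-order correction, `J_d = (I − D∘J)⁻¹J`, with `D`
the matrix of pairwise delays. This keeps the transfer function rational
(hence the pole-zero analysis exact) at the cost of accuracy for
ω·delay ≫ 1; all calibrated operating points keep delays and frequencies
inside the regime where the correction is monotone and stable.

**Innovations.** Five sites receive neuronal noise: spiny stellate
cortex, striatum, GPe, STN and thalamus — the four recorded sources plus
the thalamic driver. The choice of thalamus over EPN for the fifth site
is a convention recorded in the circuit builder; innovation sites are
data, not code, and alternatives are testable.

## Forward spectra and observation model

Innovation spectra are white + pink mixtures `g_u(f) = scale·(w + p/f)`,
shared in shape across sites with a per-site scale. Channel noise has
three independent white+pink components: cortex electrode, per-BG
electrode, and a common BG term (volume conduction) entering every BG×BG
entry with unit coherence. The observation matrix reads population
voltages through per-channel electrode gains; the cortical channel mixes
pyramidal (60%), interneuron (20%) and stellate (20%) depolarisations.
Predicted CSDs are Hermitian by construction and positive semidefinite
frequency-by-frequency.

The z-domain characterisation maps s-plane poles (eigenvalues of the
delay-corrected Jacobian) through the bilinear transform at 250 Hz
sampling (125 Hz Nyquist), the rate used for all unit-circle readings;
pole frequencies quoted "on the unit circle" are therefore warped by
`f → (Fs/π)·atan(πf/Fs)`. The sampling rate is an argument everywhere it
matters.

## Data features

Cross-spectra are extracted from time series by an ordinary least-squares
vector autoregression (statsmodels) of default order p = 8 — enough
coefficients for at least four spectral peaks across the band — followed
by the standard VAR spectral formula `G(f) = H(f) Σ H(f)ᴴ / Fs` (two-sided
density). A variational-Bayes AR estimator would refine this at short data
lengths; at the 30 s epochs used here the least-squares spectra are
asymptotically equivalent, and they admit closed-form unit tests.

## Inversion

The CSD is vectorised as real auto-spectra plus real and imaginary parts
of the unique cross-spectra (416 features for 4 channels × 26
frequencies), preserving phase. The error covariance is
`exp(λ)·S(I⊗K)S`:

- `K` mixes an independent component with a squared-exponential
  correlation over nearby frequencies (length 2 bins, weight 0.5). A
  purely smooth kernel would assert that the error is smooth across
  frequency, which periodogram-style sampling error is not; the diagonal
  share keeps the kernel honest and well conditioned.
- `S` holds per-feature scales proportional to `sqrt(G_ii G_jj)` computed
  from the data — the Wishart sampling SD of an averaged cross-spectrum
  grows with signal power, and without this weighting the beta peak
  dominates the fit by orders of magnitude.
- `λ` is a single log-scale hyperparameter with a broad prior
  (variance 32).

Variational Laplace then alternates Levenberg–Marquardt-damped
Gauss–Newton updates of the parameter means (forward Jacobians by central
finite differences, step 1e−3 on the log scale, with one-sided fallback at
the stability boundary) with closed-form re-estimation of λ, accepting a
step only if the free energy increases, until the improvement stays below
1e−2 twice in a row. λ starts at an optimistic 5%-relative-noise value and
is held for the first 8 iterations: matching it to the gross initial
misfit instead would weight the data so weakly that the scheme rests at
the trivial optimum (posterior = prior). On a linear-Gaussian surrogate
the scheme reproduces the conjugate posterior and the exact log marginal
likelihood to better than 1e−6 (tested).

**Priors.** All parameters are positive scale parameters with Gaussian
priors on their logs, zero-centred on the prior means above. Class
variances (versioned in `data/priors.yaml`): connectivity (ln 10/4)² —
±2 SD spans one order of magnitude; synaptic H, κ, ρ (ln 4/4)² — ±2 SD
spans a factor of four; noise 0.5; gains and delays 1/16. Zero prior
variance fixes a parameter.

**Model comparison.** Free energies of models fitted to the same data
(checked by hash) are compared as ΔF = log Bayes factors, with softmax
posterior model probabilities under a flat model prior.

**Group inference.** Bayesian parameter averaging combines subject
posteriors by precision weighting; group differences are Gaussian tail
probabilities `Φ((μ_A−μ_B)/√(σ_A²+σ_B²))` under an independence
assumption, with the 0.9999 decision threshold surfaced in the run
configuration.

## Contribution analysis

The beta contribution of a connection is the central finite-difference
derivative (step 1e−3, validated against a quadratic-fit oracle) of
band-limited power — neuronal auto-spectra summed over 16–18 Hz and
averaged over the four recorded channels, channel noise omitted — with
respect to the log-connection strength. The band definition follows the
17 Hz-centred beta peak; band power sums auto-spectra only (the
channel-averaged reading), not cross terms. Gamma-band contributions
(59–61 Hz) use an extended 1 Hz grid to 100 Hz. Cohort summaries are a
one-way ANOVA over connections implemented from sums of squares
(df = (n_conn − 1, n_subj·n_conn − n_conn); 9 × 9 gives (8, 72)) plus
per-connection one-sample t tests, Bonferroni-corrected for the 9
extrinsic connections.

## Synthetic cohort and fixture calibration

The study's recordings are not deposited, so ground truth is synthetic.
Two regimes are frozen in `data/fixtures.yaml` (versioned; values are
log-deviations from the prior means):

- a shared base that (i) quickens the cortical interneurons and shortens
  intrinsic delays so the pyramidal–interneuron loop resonates near 50 Hz
  as read on the unit circle, (ii) quickens striatal/pallidal kinetics
  and strengthens corticostriatal/striatopallidal gains so the indirect
  pathway participates in the beta mode, and (iii) sensitises the long
  cortex→STN→EPN→thalamus→cortex loop whose gain rides on the hyperdirect
  connection;
- regime deltas: the parkinsonian circuit differs from control **only**
  in a stronger hyperdirect connection (+1.4 log units over the control
  value) and a weaker STN→GPe connection (−0.8); noise levels are
  identical.

Calibration was a one-off grid search over these knobs until the
parkinsonian channel-averaged spectrum peaked at exactly 17 Hz on the
1 Hz grid, the control spectrum had no beta local maximum, and the
control system's dominant supra-30 Hz pole read 50 Hz (nearest 5 Hz) on
the unit circle. The fixtures are calibrated constructs: the source study
prints no posterior parameter values, so these numbers are not estimates
of rat physiology, only a regime pair that reproduces the qualitative and
printed spectral targets.

Subjects add Gaussian between-subject deviations (SD 0.1 log units,
connectivity and synaptic classes only) to a regime; unstable draws are
resampled with a count recorded. Data are synthesised in the frequency
domain — complex Gaussian innovations shaped by the innovation spectra
and transfer functions, channel noise added, inverse FFT — which is exact
for the spectral target; `sample_csd` instead averages rank-one
complex-Wishart draws around the forward CSD (default 60 segments,
emulating Welch averaging of a 30 s epoch, relative noise ≈ 13%).

**What the generator does not emulate.** Real LFPs are nonstationary
(anaesthesia state changes, movement), contain line noise and artifacts,
and their electrode mixing is uncertain; the generator is stationary,
artifact-free and uses the model's own observation equation. Passing
tests therefore demonstrate the pipeline's internal consistency and
statistical power at the study's size, not robustness to real-world
recording pathology.

**Variability caveat.** Near-resonant circuits have heavy-tailed power
across subjects (power scales like the inverse square of the stability
margin), so single channel-bin contrasts between 8- and 9-subject cohort
averages fluctuate: the parkinsonian > control beta contrast at 16–18 Hz
holds deterministically at the regime ground truths and in most, but not
every, random cohort; the seeded cohort used in the test suite is
representative of the typical case.

## Problem sizes in routine testing

Routine runs use the reduced sizes that keep a full test cycle to a few
minutes: (4, 4) mini-cohorts for end-to-end parameter recovery across 5
seeded repetitions, 60 Wishart segments per subject CSD, inversion capped
at 48–64 iterations, and 100 prior draws for the Hermitian/PSD property.
The cohort generator defaults to the study's 8 + 9 layout; nothing in the
code depends on the reduced sizes.

## Known limitations

- The first-order delay correction degrades above ~60 Hz at the default
  delays; pole readings far above the beta band are qualitative.
- A single noise hyperparameter scales one structured error covariance;
  per-channel or per-component hyperparameters would refine the weighting.
- Forward-model gradients are finite differences; analytic derivatives
  would cut inversion time roughly in half.
- Posterior means shrink toward the prior at realistic noise (correct
  Bayesian behaviour, but absolute connection strengths are recovered
  compressed; group *differences* are the reliable readout).
- One cortical source; no plasticity; no conductance-based dynamics.
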