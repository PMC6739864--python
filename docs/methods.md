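# Methods

## The model

A population of N = 500 model V1 simple cells encodes a static full-field
sine grating parameterised by orientation ϑ ∈ [0°, 180°), phase ϕ,
spatial period λ_s and contrast c.  Each cell is a circular Gabor filter
with center (x, y) uniform over a 90° disk, carrier period λ = 3°,
envelope SD δ = 2°, preferred orientation θ_n = 180°·(n−1)/N, and a filter
phase drawn without replacement from an even grid over [0°, 360°).  The
noise-free membrane potential is the filter–stimulus inner product,
affinely calibrated so that the phase-averaged response is u_DC = −60 mV
and the modulation amplitude at the preferred orientation and period at
100% contrast is u_AC = 12 mV:

u = u_DC + c·u_AC·[cos(ψ + φ − ϕ)·E₋ + cos(ψ − φ − ϕ)·E₊],

with location phase ψ = 2π(x sin ϑ − y cos ϑ)/λ_s and, for unequal filter
and stimulus periods, E∓ = exp(−δ²|k_f ∓ k_s|²/2) in terms of the two wave
vectors.  For equal periods this reduces to
E∓ = exp[−(2πδ/λ)²(1 ∓ cos(θ − ϑ))].  The counter-rotating E₊ term is
≤ e^(−17.5) of u_AC at default geometry.  The closed form is the standard
Gaussian-windowed plane-wave integral; because published statements of the
two cosine arguments are easy to typeset inconsistently, the test suite
validates the expression against an independent pixel-grid quadrature
oracle (truncation 4δ, step λ/40, tolerance 1% of u_AC), including unequal
periods.  Contrast multiplies only the modulated (AC) component: response
manifolds under contrast variation are radial lines through u_DC.

Stochastic membrane potentials add zero-mean Gaussian noise of SD
σ = 3 mV (25% of u_AC), drawn i.i.d. per 20 ms bin — each stimulus
presentation in a response matrix is one bin snapshot.  Optional uniform
correlations Σ_ij = ρσ² are realised with a shared latent factor.  Firing
rates follow the threshold-power-law nonlinearity r = Φ·⌊u − u_th⌋₊^κ with
Φ = 16.7 Hz/mV^κ and κ = 1 by default (κ ∈ [1, 2] scanned where stated).
Two sparseness measures are computed.  The *zero fraction* (fraction of
exactly-zero rate entries across all stimulus–neuron pairs) is the
quantity rectification directly controls; it is monotone in the threshold
with limits 0 and 1, both property-tested.  The *activity sparseness* is
the population Treves–Rolls measure averaged over stimuli,
(1 − a)/(1 − 1/N) with a = ⟨r⟩²/⟨r²⟩, which also counts weakly-driven
cells as inactive.  The published analyses reference an unprinted
"population sparseness" formula; empirically the activity measure is the
one whose scaled ideal-observer prediction tracks linear decodability at
the published strength (r ≈ 0.97 here vs. ≈ 0.93 for the zero fraction),
so the prediction uses it, and both curves are reported by every sweep.

Control populations keep the V1 geometry but change the filters: "retina"
cells sample the grating value at their center pixel; "LGN" cells are
balanced differences of two Gaussian envelopes (center SD 1.5°, surround
SD 4°; whether the published center/surround strengths were balanced is
unstated, so a balanced difference is used).  Both are gain-calibrated per
neuron so their noise-free response variance over a reference
orientation × phase ensemble equals that of the matched V1 cell.

## Stimulus banks

The decoded variable is partitioned into K = 10 classes with M_ϑ = 10
within-class orientation bins; a variable phase contributes an M_ϕ = 50
grid; non-uniform nuisance priors — spatial period lognormal(μ = 0.95,
σ = 0.55), contrast Beta(2.4, 3.6) — are laid out by inverse-CDF
("distorted grid"), so nodes carry equal probability mass.  Fixed values
are λ_s = 3°, c = 0.5, ϕ₀ = 180°.  (The beta contrast prior has mean 0.4
while the fixed contrast is 0.5 as published; the published fixed value is
honoured.)  Train and test banks share the stimulus grid and differ only
in membrane-potential noise (M_rep vs. M_rep′ repetitions).  At full scale
the training bank is M = K·M_ϑ·M_ϕ·M_rep = 10⁵ rows.

## Decoders

The linear decoder is a K-class multinomial logistic regression (weights
and bias, features standardised to the training set) trained by
Barzilai–Borwein gradient descent on the cross-entropy with a weak ridge
(10⁻⁸) fixing the softmax gauge; the optimum is unique and
solver-independent, which the tests confirm against an independent convex
solver.  Decisions take the maximum class probability, ties to the lowest
index.

The optimal (Bayes) decoder inverts the generative model: for every grid
stimulus s the likelihood of a rate vector multiplies, per neuron, either
the subthreshold point mass P(u < u_th | s) (zero rate) or the Gaussian
density of the inverted rate u = u_th + (r/Φ)^{1/κ} (the change-of-variables
Jacobian is class-independent and cancels).  Class posteriors marginalise
the nuisance grid (J equals the bank's M_ϕ; the same within-class
orientation grid as the banks is used — the published grid is not stated).
All accumulation is log-domain with log-sum-exp.  κ < 1 is rejected (the
rate density would need an unbounded derivative at threshold); at κ = 1
dr/du = Φ is the one-sided derivative.  The information-limiting-correlation
variant models correlated variability as stimulus jitter: encoded
orientations are wrapped-normal draws of width σ_ϑ around the true value,
and the posterior over the true orientation mixes the stimulus posterior
through that kernel; the explicit published covariance construction is in
unavailable supplementary material, so this printed mechanism is the one
implemented.

Performance measures: fraction correct (FC); probabilistic fraction
correct, PFC = (∏_m p(ϑ_m | r_m))^{1/M}, whose log is the Monte-Carlo
estimate of the negative conditional entropy; and the mutual-information
estimate I = log₂K + ⟨log₂ p(ϑ_true | r)⟩ bits.  The sparseness-scaled
prediction of linear performance is (FC_opt − chance)·sparseness + chance.

## Experiments

Threshold sweeps reuse one set of membrane-potential draws across the
threshold grid (so the lowest grid point reproduces membrane-potential
decoding exactly), retrain the linear decoder per point, and optionally
refine a coarse grid around the peak; the optimal threshold is the grid
argmax — no curve fitting.  The default grid spans
[u_DC − c·u_AC − 3σ, u_DC + c·u_AC + 3σ] at 1–2 mV.

Robust regimes: per noise-to-signal ratio σ/u_AC, the set of normalised
thresholds (u_th − u_DC)/u_AC retaining ≥ 90% of peak performance over the
realistic FRNL-exponent range κ ∈ [1, 2] (five values).  The measure is
linear FC for the untangling criterion and the ideal observer's
mutual-information estimate for infomax; the infomax band is unbounded
below because total information only falls as the threshold rises.  A
measured cell's exponent is unknown, so the default band is the union of
the per-κ admissible sets — a threshold is consistent with near-optimality
if some realistic exponent makes it near-optimal; the stricter
every-exponent intersection is available as an option.  Band membership
interpolates the band edges linearly in σ/u_AC.

The heterogeneous-population experiment assigns 20 cells to each of 25
(κ, σ) combinations (κ ∈ {1, 1.2, 1.4, 1.6, 1.8},
σ ∈ {2, 2.5, 3, 3.5, 4} mV), sets each cell's threshold to the optimum of
the matched homogeneous population, perturbs the threshold vector by
random directions of fixed Euclidean norm, retrains, and fits a quadratic
to FC versus distance.

Nuisance-feature decoding (spatial period or contrast) uses an encoder
whose carrier periods sample the stimulus period distribution, classes of
equal probability mass from the target prior's quantiles, and treats all
other stimulus parameters — including orientation — as variable nuisances.

## Synthetic intracellular traces and their analysis

`synth_trace` emulates whole-cell recordings during drifting gratings:
u(t) = u_DC + u_AC·sin(2π·2 Hz·t + jitter) (per-trial phase jitter SD 10°),
noise i.i.d. per 20 ms bin, 3 s trials (6 cycles), 10 kHz sampling; spikes
are an inhomogeneous Poisson process with rate Φ⌊u − u_th⌋₊^κ and a 2 ms
refractory period, each adding a stereotyped waveform (0.3 ms rise, ~0.8 ms
decay, small after-hyperpolarisation, ~60 mV peak).  Poisson spiking keeps
the rate-histogram estimate non-degenerate at low rates.  Ground truth is
stored with the trace and read only by tests.

Spike removal detects upward dV/dt crossings of 10 mV/ms (1 ms merge)
confirmed by a ≥ 15 mV peak over the pre-onset level — necessary because
the binned noise also produces steep but small steps — then subtracts a
least-squares-scaled template per spike and bridges all removal windows
(−0.5 ms to +5 ms) with a single masked linear interpolation, which also
handles bursts with overlapping windows.  Contract (tested): ≥ 99%
detection, ≤ 1% false positives, ≤ 0.5 mV RMS generator error outside
spike windows at default SNR.

Cycle-overlay extraction computes, per trial, the DC level (grand mean),
the AC amplitude (fundamental-Fourier fit of the cycle-averaged waveform
by default; half peak-to-trough of the jitter-aligned grand cycle as a
cross-check — alignment is needed because trial-phase jitter would flatten
a naive average), and the noise SD (across-cycle variance at matched cycle
positions).  The published noise values for the four recorded cells are
printed without units alongside mV quantities; they are treated as mV
standard deviations, consistent with the plotted noise-to-signal range
(≲ 0.55).

FRNL estimation bins 20 ms window means of the generator potential at
1 mV, divides spike counts by occupancy time per bin, and fits a
threshold-linear curve by least squares on a 0.05 mV threshold grid
(occupancy-weighted).  The voltage excursion within a window around its
mean smears the rate-vs-mean-voltage relation and biases a naive fit low
by ~1 mV, so the rectifier is convolved with a Gaussian of the measured
within-window SD before fitting.  Threshold-power-law fits for
κ ∈ {1, 1.25, 1.5, 1.75, 2} are recorded for the consistency display.
Recovery contract (tested on a 3×3 grid of ground truths): u_DC ± 0.5 mV,
u_AC ± 0.8 mV, σ ± 0.4 mV, u_th ± 1 mV with 10 trials at default SNR.

The optimality permutation test counts cells whose (σ/u_AC,
(u_th − u_DC)/u_AC) point falls inside a regime; the null permutes each
parameter vector (u_DC, u_AC, σ, u_th) across cells independently (the
stricter null; permuting only the thresholds is available), and p is the
fraction of shuffles with an inside-count ≥ observed.

## Problem sizes and numerical choices

The full-scale bank (M = 10⁵ training rows, N = 500) is used for the
headline membrane-potential decoding numbers.  Sweeps and regime
computations use reduced repetitions (M_rep = 5, M_rep′ = 10) and, for
regimes, reduced orientation/phase grids — sizes chosen so each analysis
completes in minutes on one core while leaving the measured quantities
within their sampling error; every reduced size is stated at its call
site.  The ideal observer is evaluated on a fixed-size subsample of test
rows (1 200–2 000), giving binomial SEs of ~1%.  Response matrices are
float32 in the large experiments; training is full-batch with a 400
iteration cap and 10⁻⁸ relative-objective stopping tolerance; convergence
failures are flagged in decoder metadata, not silently accepted.

## What the synthetic data does and does not show

The generator reproduces the response statistics the analyses rely on —
sinusoidal modulation, bin-correlated Gaussian noise, threshold-power-law
spiking, stereotyped spike shapes, trial phase jitter.  It does not model
conductance dynamics, spike-shape variability, electrode artefacts,
non-stationary baselines, or temporal correlations beyond 20 ms bins, so
passing recovery tests demonstrates correctness of the pipeline's
estimators under the stated model, not robustness to every failure mode of
real recordings.  Likewise the decoding results concern grating stimuli
and a feed-forward population without extra-classical receptive-field
effects.

## Known limitations and open points

* With the literal default calibration (contrast 0.5 halving the 12 mV
  modulation, σ = 3 mV), asymptotic fixed-phase membrane-potential
  decoding reaches ≈ 82% rather than the published ≈ 87%; the chance-level
  result under phase variability and the −57 mV optimum are reproduced
  exactly.  Folding the stimulus contrast into the calibration (an
  alternative reading of the published parameter table) overshoots to
  ≈ 99%, so the literal reading is kept.
* With the zero-fraction sparseness the scaled prediction correlates with
  actual linear FC at only r ≈ 0.93–0.94: on the rising flank of the sweep
  the linear decoder outperforms that prediction.  The activity-sparseness
  prediction (the default) reaches r ≈ 0.96–0.97 (published: 0.98).
* The fixed-phase decoding level depends on the population draw at the
  ±3-percentage-point level (the random filter phases set how many cells
  are informative at the one reference phase); reported values state their
  seed.
* The exactness of the robust-regime bands is limited by the 2 mV (1/6 in
  normalised units) threshold grid and the Monte-Carlo error of FC at the
  90% cut; membership of points near a band edge can flip between seeds.
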