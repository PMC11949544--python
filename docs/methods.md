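# Methods

## The model

`neuromass` simulates interictal scalp EEG of a focal epilepsy with a
whole-brain network of neural masses and evaluates the result against a
reference recording with clinically motivated similarity metrics.

### Single-region dynamics

Each cortical region is a layered neocortical mass with six
subpopulations: pyramidal cells `PYR`, a collateral-excitation pyramidal
pool `PYR2`, and four GABAergic interneuron classes — `PV` (fast somatic
inhibition), `SST` (slow dendritic inhibition, delivered with slower
apical and faster basal kinetics from a single SST pool), `VIP`
(disinhibition of SST) and `NGFC` (very slow volume inhibition).  Each
subpopulation converts its summed membrane potential v (mV) into a mean
firing rate through the wave-to-pulse sigmoid

    S(v) = 2 e0 / (1 + exp(r (v0 - v))),

with e0 = 2.5 s^-1 (half of the 5 s^-1 maximum rate), r = 0.56 mV^-1 and
v0 = 6 mV.  Every directed connection is an alpha-function synapse

    y'' = (W / tau_w) u - (2 / tau_w) y' - y / tau_w^2,

where u is the presynaptic rate scaled by a dimensionless contact
coefficient, W the PSP gain (mV) and tau_w its kinetic time constant (s);
the closed-form impulse response (W/tau_w) t exp(-t/tau_w) peaks at
t = tau_w with amplitude W/e and is used as the integrator's oracle in the
tests.  The membrane potential of a subpopulation is the signed sum of its
incoming PSPs.  Only the synaptic inputs onto the layer-V pyramidal pool
(the PYR membrane potential) drive the current dipole seen by the scalp.

Default kinetics follow the classical neural-mass literature: EPSP
3.25 mV / 10 ms; fast somatic IPSP at tau = 5 ms with gain-times-tau
matched to the classical fast loop; slow dendritic IPSPs 10 mV at 30 ms
(apical) and 15 ms (basal); VIP IPSP 10 mV / 10 ms; NGFC volume
inhibition slowest at 60 ms.  Contact coefficients are fractions of the
base constant C = 135.  A weak optional PYR->NGFC excitation is enabled in
the default parameter set but is not part of the canonical motif listing,
whose glutamatergic connections are exactly PYR<->PYR2, PYR->PV and
PYR->SST.  All defaults live in `nmm_core`/`presets` and are overridable
through YAML; tests assert regime properties, never exact default values.

The thalamus is one lumped mass: an excitatory thalamocortical pool `TC`
and slow/fast reticular GABAergic pools `RN1`/`RN2`.  Cortical afferents
excite TC at full weight and the reticular pools at weight 0.2, so a step
increase in cortical drive raises the TC equilibrium, while strengthening
reticular gains lowers it.

### Noise and integration

The only stochastic input is a Gaussian white rate drive onto PYR (TC for
the thalamus), mean 90 s^-1 and SD 30 s^-1 specified in a 512 Hz band (the
clinical sampling rate); per-step noise SD is rescaled by sqrt(dt_ref/dt)
so the filtered response does not depend on the integration step.  The
coupled system is advanced by a fixed-step stochastic Heun scheme on the
(y, y') pairs, dt = 1/2048 s by default (dt <= tau_w/10 is enforced).
Local drift terms are re-evaluated at the predictor; the noise, the
delayed long-range inputs and any user-supplied external drives are held
constant across a step.  Non-finite state raises an error naming the step
and region.  The first 2 s of every simulation are discarded before any
analysis.

### Parameter regimes

* `background` — the defaults; a noise-driven stationary fluctuation with
  a 1/f-like spectrum and no narrowband peak above 8 Hz.
* `fcd_spikewave` — the epileptic column of a type-2 focal cortical
  dysplasia: glutamatergic gains x1.65, PV-mediated somatic gain x1.5,
  SST dendritic gains x0.9.  The direction of these changes (excitation
  and somatic inhibition up, dendritic inhibition down — a strongly raised
  excitation-to-dendritic-inhibition ratio) is the biological signature of
  the dysplastic tissue; the magnitudes were calibrated once so the column
  emits 2-3 spike-wave complexes per second (2.5/s at the defaults,
  stable across seeds) and then frozen.  In the spike-triggered average
  the sharp transient leads and the slow wave peaks ~120 ms later.
* `alpha_boost` / `beta_boost` / `delta_boost` — resting-rhythm add-ons.
  Alpha: SST dendritic gains x1.2 with the noise drive raised to
  250 s^-1, giving a ~10 Hz peak (the inhibitory loops only resonate once
  the operating point sits on the steep part of the sigmoid, hence the
  raised drive).  Beta: PV gain x5 with SST->PV x0.2 and SST dendritic
  x0.5 at drive 300 s^-1, letting the fast somatic loop dominate at
  ~21 Hz.  Delta: all PSP time constants doubled (the rate constants
  1/tau halved), moving the column's resonance into the delta band.

## Whole-brain network

The atlas holds 66 cortical regions (Desikan-Killiany labels, both
insulae excluded) plus one thalamus, 67 masses in total.  Long-range
connections are glutamatergic, from each source's PYR (or TC) onto the
destination's PYR, PV, SST, VIP and NGFC (cortex) or TC, RN1, RN2
(thalamus), each target class with a configurable shared weight.  The
coupling term for region i is

    u_i = G * sum_j C_ij * S_j(t - d_ij),

with C the max-normalized structural connectivity, G a single global gain
(default 6, calibrated once so epileptic discharges spread visibly to
connected regions without surviving, on the scalp, the resection of their
source), and d_ij the conduction delay: centroid distance divided by
7.5 m/s, rounded to the nearest integer step (error <= dt/2) and served
from a ring buffer.  Times before t = 0 read the resting-state rate
S(0) (zero-history convention); combined with the 2 s burn-in this
removes the startup transient.  Region i draws its noise from the seed
sequence `region_seed(seed, i)`, so a decoupled network reproduces
isolated columns bit-for-bit — an equality the tests assert.

Structural surgery primitives: `fragment_region` splits a region into
children that each inherit the parent's full connectivity row/column
(child-child weights are zero, like the parent's self-weight), carry
`area` = parent area x surface fraction, and sit along the parent's
anteroposterior tangent axis at fraction-weighted positions (default
spread 20 mm).  `annul_region_connections` zeroes a resected region's row
and column and nothing else.

## Forward model

Regional layer-V drives become scalp potentials through the current
dipole approximation

    phi(r) = 1/(4 sigma pi) * sum_k I_k ||d_k|| cos(theta_k) / R_k^2,

with I_k = eta y_k, eta = 1e-3 S, axial path ||d_k|| = 3 mm,
sigma = 0.33 S/m.  The synthetic head is a single-shell homogeneous
conductor: centroids on a 70 mm cortical shell with radially oriented
(normal-constrained) dipoles, 32 standard 10-20/10-10 electrodes on a
95 mm shell.  The leadfield G (66 regions x 32 electrodes) is evaluated
from that formula directly; `aggregate_leadfield` also supports summing a
dipole-level matrix (e.g. 15000 dipoles) into regional rows, with
excluded (insular) dipoles dropped before aggregation.  The thalamus, a
deep closed-field source, does not project.

Two amplitude conventions are calibrated once and frozen: a global output
gain (5e4) maps model units to microvolts so background scalp EEG sits
near 30 uV peak-to-peak, and each background region's projected drive is
scaled by a synchrony factor 0.3 — scalp amplitude grows with the
synchronously active cortical area, and interictal discharges recruit
their whole region coherently while background activity does not.  A
fragmented child's dipole strength additionally scales with its surface
fraction, which is what makes an oversized epileptic zone project
too-large, too-diffuse discharges.

Montages: recordings are referential (32 channels) or bipolar; the
standard longitudinal ("double banana") montage defines 18 derivations in
five anterior-to-posterior chains, and derivation traces are anode minus
cathode.

## Similarity metrics

**Single-channel index.** Both signals are zero-meaned, the
cross-correlation R(l) = sum_n f[n] g[n+l] is normalized by the product of
the norms, and the index is the signed value at the lag of largest |R|
(ties toward the smallest |lag|).  Identical signals give exactly 1, a
sign-flipped copy -1, a delayed copy 1 at the true lag; the index is
amplitude-scale invariant and lies in [-1, 1].  The unnormalized sum
alone could not honor that stated range, hence the normalization.  The
function applies unchanged to whole windows or to single extracted event
snippets.

**Spike detection.** Per derivation, over a fixed analysis window
(default 40 s): spikes are detected on the 8-40 Hz component, where sharp
transients stand out from slow background and from the slow wave itself —
peaks above k = 4.5 robust SDs (1.4826 x MAD) and a 10 uV floor, narrower
than 120 ms at half prominence, with a 200 ms refractory.  A detected
event must additionally span >= 4 robust SDs peak-to-peak on the 1-40 Hz
signal.  Amplitude extrema are measured on the 1-40 Hz signal in a 600 ms
event window.  Polarity: the first letter is the sign of the spike
extremum; the second the sign of the following slow wave, read from a
100 ms-smoothed segment 80-320 ms after the spike, as a deviation from a
linear local baseline (in rhythmic 2-3/s trains the absolute level is
polluted by the neighbouring complexes), and capped before the next
detected complex.  Sign-flipping a recording maps PP<->NN and PN<->NP
exactly.

**EEG-IES score.**  Feature sets hold, per derivation: event count and
rate, dominant polarity class, mean event peak-to-peak amplitude, and a
presence flag; per EEG: the highest-amplitude derivation, the per-chain
anteroposterior amplitude ordering, and the phase-inversion electrode —
the common electrode of two adjacent derivations whose dominant
polarities are PN above and NP below, the most prominent such pair
(largest summed amplitude) winning, ties broken toward the more anterior
electrode.  Scoring weights: highest-amplitude derivation 1, amplitude
gradient 5 (all chains must match; all-or-nothing), rate within +/-50% of
the reference 1 per derivation, polarity class 1 per derivation, presence
1 per derivation, absence 1 per derivation, phase inversion 5.  The
presence and absence criteria ask the same per-derivation status question
from the two viewpoints and both award when the status agrees; this keeps
the theoretical maximum at 11 + 4 x (number of derivations) and makes an
EEG score 100% against itself.  On derivations where the reference has no
events, the rate and polarity criteria are satisfied exactly when the
simulation is also event-free there.

## Synthetic data

The generators replace clinical inputs entirely and are deterministic per
seed.  Geometry: quasi-uniform (golden-angle) points on the left
upper-lateral shell, ordered anterior-to-posterior and matched to an
anteroposterior ordering of the Desikan-Killiany labels, mirrored to the
right hemisphere — frontal labels land frontally, so an epileptic mass in
the left rostral middle frontal region projects onto Fp1-F3/F3-C3 as the
clinical picture suggests, but the layout is not a real cortical surface.
Connectivity: symmetric exp(-distance/40 mm) decay times a lognormal
factor, thresholded to 30% density (thalamocortical links always kept),
max-normalized.  Reference EEGs: background noise (white, low-passed at
25 Hz, 5 uV SD) plus spike-wave templates — a 70 ms difference-of-Gaussians
spike and a 300 ms half-sine wave, deliberately independent of the neural
mass model so detector validation against the injected ground truth is
not circular — at controlled rate, amplitude and polarity per derivation;
the default configuration mimics a left parasagittal frontal irritative
field with a phase inversion on F3.  Event count is exactly
floor(rate x duration), with whole complexes kept away from the window
edges.

The epileptogenic-zone replay (`replay_fcd_scenario`) is a parameter-
recovery experiment: a reference scalp EEG is simulated with the
epileptic mass in a known region (or one fragment of it); the epileptic
mass is then placed consecutively in every candidate cortical region,
each simulated EEG is scored against the reference with the EEG-IES
index, and placements are ranked (descending score, ties by candidate
order).  With identical seeds the true placement reproduces the reference
exactly and scores 100%, so recovery tests the whole scalp-level pipeline
rather than numerical luck.  The winning region is then fragmented and
each child rescored — the correct sub-fraction scores strictly higher
than the whole region, reproducing the logic by which an oversized zone
is trimmed.  Finally the true zone's leadfield rows are zeroed (in-silico
surgery) and the detector confirms the scalp spikes are gone.

### Problem sizes

Scenario simulations default to 16 s (2 s burn-in + 14 s analysis) at
dt = 1/2048 s with scalp output at 512 Hz; reference-EEG generation uses
the full 40 s window.  These sizes keep a full 66-candidate placement
search to a few minutes on one CPU while leaving ~35 events per active
derivation for the rate and polarity statistics.

## Known limitations

* The synthetic head is spherical with radial dipoles: no realistic
  cortical folding, no boundary-element conductor, no post-surgical
  breach conduction.  Resection is purely a leadfield operation; the
  resected tissue's dynamics continue but no longer project.
* The coupled background occasionally (about one event per several
  hundred derivation-windows) produces a sharp transient that any
  amplitude-based detector tuned for >= 0.9 recall at moderate SNR will
  flag; real background EEG contains such non-epileptic sharp transients
  too.  Raising the threshold to silence them entirely would cost ~35% of
  recall at SNR 5, so sensitivity was kept.
* Passing the recovery experiment on synthetic references shows the
  pipeline is self-consistent and identifiable at these effect sizes; it
  does not demonstrate localization accuracy on real recordings, where
  geometry, conductivity and background dynamics are all richer.
* The EEG-IES score is undefined as a discriminator when the reference
  contains no spikes at all (it degenerates to presence/absence
  agreement), matching its clinical scope: comparing recordings that do
  contain interictal discharges.
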