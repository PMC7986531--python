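# Methods

## Body mechanics

The worm is an inextensible planar elastic rod discretized into N = 48
material points (L = 1 mm, so segments of ~21 µm). Rather than enforcing
inextensibility with a penalty or a per-step constraint solve on positions,
the configuration is parametrized by the head position and the N−1 segment
angles; segment lengths are then constant to machine precision by
construction, and the line tension is the constraint force, recoverable
from the nodal balance when needed. Curvature, muscle drive, and the neural
fields live on the N−2 interior junctions.

Bending energy is quadratic in the angles, E_b = ½ Σ E I₂ (κ − β)² h, with
E = 100 kPa and I₂ = πr⁴/4 on a spindle radius profile (40 µm mid-body,
elliptical taper with a floor at 10% of the maximum so the ends stay
numerically stiff). Free-end (zero force/torque) boundary conditions are
the natural conditions of the energy formulation. Internal viscosity is
neglected.

Drag follows resistive force theory: per unit length
F = −(K_τ v_τ τ̂ + K_ν v_ν ν̂). The dynamics are the overdamped force
balance projected onto the generalized coordinates (principle of virtual
work): R(q) q̇ = −∇E_b, with R = Jᵀ C J the configuration-dependent drag
metric. Time stepping is semi-implicit Euler with dt = 1 ms: the elastic
term (a constant tridiagonal Hessian in the angles) is treated fully
implicitly, the drag metric is frozen at the current configuration, and
each step solves one SPD (N+1)×(N+1) system. Because each step minimizes
E_b(q) + ‖q − qⁿ‖²_R / (2 dt), the scheme is unconditionally stable and
dissipates elastic energy monotonically for β = 0 (verified by test).
Halving dt changes mid-body curvature traces by < 1% in driven runs
(grid-independence test). The model is fully deterministic; runs with the
same configuration are bit-identical.

## Controllers and muscles

CPG mode imposes A(u,t) = sin(2πuL/λ_f − 2πt/T_f) with default T_f = 2 s
(1 s in fast test runs) and λ_f = 0.65 mm, through the normalized sigmoid
β = β₀ tanh(αA)/tanh(α), α = 3 (α < 10⁻⁸ is evaluated by its linear
limit). Frequency is imposed, not emergent — that is the point of the
paradigm comparison.

Proprioceptive mode: the B-type switches at each junction read the mean
signed curvature over the posterior half of the body (Δ = 0.5, window
truncated and renormalized toward the tail, so the tail junction reduces
to its local curvature). Update order within a step: mechanics →
proprioceptive currents → dorsal (DB) switch update → VD = DB derivation →
ventral (VB) update seeing the current-step VD → muscle integration. The
muscle ODE uses the exact exponential integrator, so it is dt-robust and
exact for piecewise-constant activation.

Thresholds absorb the AVB drive. The dorsal switch is symmetric: ON when
−I_κ > θ₀, OFF when −I_κ < −θ₀. The collapse rule pins the ventral ON
threshold at θ₀ − w: VB is intrinsically more excitable, and it is the
VD→VB inhibition (active exactly while DB is on) that holds VB silent
until the dorsal phase ends. The ventral OFF threshold is −θ₀. With these
choices the wild-type pair is exactly a single bistable switch with
transitions at ±θ₀; this was a genuinely open corner of the design (the
collapse rule fixes only the ON side) and the alternative readings —
putting the asymmetry on the ventral OFF threshold, where inhibition acts
as an explicit off-reset — were implemented and rejected because removing
inhibition then wrecks crawling (30–65% frequency drops) rather than
leaving it untouched.

Neuromuscular weights are w_exc = 0.8, w_inh = 0.2. This satisfies the
identity that eliminating muscle inhibition equals the c = 0.8 amplitude
scaling (c = w_exc/(w_exc + w_inh)) while keeping the activation amplitude
at 1 and hence |β| ≤ c β₀ in steady state.

## Calibration and its limits

Free constants not fixed by the model statement: the threshold scale θ₀,
the inhibition strength w, and the drag magnitudes. They were tuned once,
before the perturbation experiments, and frozen: θ₀ = 2 mm⁻¹, w = 1 mm⁻¹,
agar-like drag K_τ = 11.2, K_ν = 448 N·s·m⁻² (anisotropy 40), water-like
K_τ = 28, K_ν = 41.6 N·s·m⁻² (anisotropy 1.5). Two calibration notes:

* The literature point values for the drag coefficients (10⁻³–10⁻¹
  N·s·m⁻²) make this body mechanically instantaneous relative to the
  0.1 s muscle timescale at E = 100 kPa, which erases all load dependence;
  the magnitudes above restore a mechanical timescale comparable to the
  muscle one while keeping the anisotropy ratios.
* Pushing the crawl frequency into the animal's 0.3–0.9 Hz band requires
  loads at which the oscillator sits on its stability boundary, where a
  20% perturbation extinguishes the rhythm outright instead of slowing it.
  Calibration therefore targeted robust relative behavior; the wild type
  runs at 1.20 Hz (agar-like) and 1.21 Hz (water-like, swim band not
  reached), and all perturbation results are reported normalized to the
  matched wild type.

What the calibrated model does and does not reproduce. Reproduced, and
asserted in tests: the reduction ordering combined ≥ hyp1 ≥ hyp2 > 0 in
both environments; exact CPG frequency invariance under every muscle
perturbation; hyp2 speeding up CPG crawling; the reset knockout leaving
crawling untouched (< 3% frequency change) while degrading swimming
(speed −66%, uncoordinated); retrograde wave propagation; water > agar
frequency. Not reproduced at published magnitude: the knockout frequency
reductions come out near half the printed 20–42% values; the swimming
failure under the reset knockout is partial (spatial inhomogeneity
re-seeds the rhythm even though the coactivated state is pointwise
absorbing); and the crawling speed drop under hyp1 exceeds the frequency
drop because the emergent wavelength shortens with frequency in this
implementation, shrinking the per-cycle stride. These three appear as
deliberate test failures in `tests/test_acceptance.py` rather than as
loosened tolerances.

## Measurements

Undulation frequency of a run is the dominant spectral peak of mid-body
curvature after a 2 s transient (Hann window, spectrum zero-padded to
0.01 Hz, peak refined by continuous-frequency sinusoid least squares —
the windowed-FFT maximum alone is biased on records holding few cycles).
Speed is the net centroid displacement per unit time. Runs last 22 s
(agar-like) / 14 s (water-like) simulated so the measurement window holds
well over ten periods; one run takes ~10 s of wall time.

## Kinematics on track tables

Tracks are per-frame midline skeletons (≥ 9 points, µm) at a uniform frame
rate, with a mask for tracking gaps. Design choices where the published
analysis chain is underdetermined: mid-body is the middle skeleton point;
locomotion direction is the sign of mid-body velocity projected on the
head-ward tangent, smoothed over 0.5 s; behavioral windows are 2.5 s with
0.5 s stride; the episode filter's "larger than either wavelength" is read
strictly (path per cycle must exceed the smallest available wavelength;
a `use_max` flag gives the permissive reading).

Posture amplitude and wavelength need care because a worm holds only ~1–2
spatial periods: any straight-line axis (principal axis or head–tail
chord) tilts with the wave phase and distorts the deviation profile. The
axis is therefore the rotation whose deviation profile is best explained
by a single spatial sinusoid; amplitude is half the peak-to-peak deviation
envelope (robust to the envelope offset of non-integer period counts);
wavelengths come from a continuous-frequency least-squares spectrum with
the top two candidates refined jointly, a secondary being reported only
when it carries ≥ 10% of the primary's power. Body length is polyline
arclength, expressed as percent of the prestimulus mean; at a masked
stimulus frame the nearest-frame fallback prefers the poststimulus
neighbor.

The bimodal crawl-frequency fit is a two-component Gaussian mixture by EM
with 10 seeded starts (scikit-learn), components ordered by mean, with
degenerate input flagged rather than fatal and a BIC comparison against
the one-component fit flagging unimodality. The permutation test reshuffles
labels 5000 times for a two-sided p on the mean difference, with a
percentile-bootstrap 95% CI.

## Calcium phase pipeline

ΔF/F per frame is (mean of the brightest 50% of ROI pixels − whole-frame
median) normalized by the trace's own mean over retained frames, so every
retained trace has mean exactly 1 (asserted to 10⁻¹²). Channel phase is
360·x/λ of the nearest point on the sinusoidal path (dorsal apex 90°,
ventral 270°); positions farther than half the channel width are flagged
NaN. Cell frequency is the fraction of cycle traveled per unit time on the
forward-monotone unwrapped phase; exactly 0.6 Hz classifies as low (the
cutoff is read as strict-greater for "high"). The perimotor soma→NMJ
offsets ship as an editable table of placeholder zeros — the published
atlas values are not reprinted here and must be user-supplied. Collation
uses 72 bins of 5°, empty bins marked with n = 0.

## Synthetic data

Generators are pure functions of (spec, seed) and embed their ground truth
in output metadata. The undulator advects a y = A sin(2πx/λ − 2πft)
midline at a signed drift speed, re-solving the axis span each frame so
the arclength stays at the body length; coordinate noise is Gaussian
(default 0; tests use 2 µm, SNR ≥ 40). The shrink generator scales
arclength to the target percentage at the stimulus with exponential
recovery and masks the stimulus frame, mimicking the touch-gap. Frequency
samples draw i.i.d. from the stated two-Gaussian mixture; the mixture SDs
(0.10/0.05 Hz) are generator choices recorded in metadata, since only the
means and proportions are published. Fluorescence movies move a Gaussian
disk along the channel path with a phase-locked intensity profile,
pixel-snapped square ROIs (so the rasterized pixel count cannot flicker
frame-to-frame), and Gaussian photon noise.

What the generators do not emulate: real segmentation failures, head/tail
swaps, self-occlusion during turns, non-Gaussian imaging noise, or
photobleaching. Passing round-trip tests therefore validates the
estimators' numerics, not robustness to those artifacts.

## Known limitations

* The agar-like wild type crawls faster (1.2 Hz) than real animals; only
  normalized comparisons should be read quantitatively.
* The oscillation boundary of the proprioceptive model is sharp; sweeps
  that cross it (large τ, small c, heavy drag) report collapsed points
  rather than graded ones.
* Backward locomotion is exposed as a configuration flag (reversed
  proprioceptive field) but none of the shipped analyses exercise it.
* 2D planar motion only; no body self-contact.
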