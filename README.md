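# wormgait

Neuromechanics of *C. elegans* undulatory locomotion, built to ask what
GABAergic inhibition in the ventral nerve cord is *for*: an integrated model
(continuum viscoelastic body + neural control + muscle dynamics + resistive-
force environments) in which three hypothesized roles of inhibition —
cross-inhibition of opposing body-wall muscles, disinhibition of the
innervated muscles, and the VD→VB inhibitory reset — can be knocked out one
at a time, in crawling-like and swimming-like media. Alongside the model,
the package re-implements the behavioral-kinematics chain used on worm
tracker output (curvature kymograms, undulation frequency, translocation
speed, amplitude/wavelength, shrinking, episode filtering, the bimodal
crawl-frequency mixture fit, permutation tests) and the calcium-imaging
phase pipeline for worms undulating through a sinusoidal microfluidic
channel. All of it runs on simulation output and seeded synthetic data; no
external downloads.

It is aimed at computational neuroscientists and worm-behavior people who
want a small, deterministic, fully-testable version of this model class.

## The model

The body is an inextensible planar viscoelastic rod of length *L* = 1 mm
parametrized by arclength fraction *u* ∈ [0, 1]. Muscles impose a preferred
curvature β(u, t); the environment resists motion with anisotropic
resistive-force-theory drag. At low Reynolds number the force balance is

    F_env − (1/|x_u|) (p τ̂)_u + (1/|x_u|) ( (1/|x_u|) E I₂ (κ − β)_u ν̂ )_u = 0,
    F_env = −(K_τ v_τ τ̂ + K_ν v_ν ν̂),

with zero force and torque at the free ends (equivalently β = κ at
*u* = 0, 1), Young's modulus *E* = 100 kPa, second moment I₂(u) = πr(u)⁴/4,
and line tension *p* enforcing inextensibility. Curvature is signed,
dorsal-positive.

Two controllers produce the neural activation A(u, t):

* **CPG (feedforward)**: A = sin(2πuL/λ_f − 2πt/T_f), muscle response
  β = β₀ tanh(αA)/tanh(α) (wild type α = 3 — a sharp, disinhibition-assisted
  upstroke).
* **Proprioceptive (feedback)**: dorsal and ventral B-type motoneurons are
  binary bistable switches driven by the mean signed curvature over the
  posterior half of the body, I_κ(u) = ⟨κ⟩_[u, u+Δ], with hysteretic
  thresholds; D-type (GABAergic) motoneurons mirror the opposite B-type
  instantaneously, and VD inhibits VB with strength *w*. Muscles integrate
  the activation leakily: τ_m dβ/dt = −β + β₀ A, with τ_m = 0.1 s and
  β₀ = 10 mm⁻¹.

The knockouts: hypothesis 1 scales β by c = 0.8 (no muscle
cross-inhibition); hypothesis 2 slows the muscle (τ → 1.2 τ_m, or drops the
sigmoid under CPG control); hypothesis 3 sets the VD→VB current to zero
(proprioceptive control only). Perturbation strength is capped at 20%.

## Worked example

```python
from wormgait.experiments import default_spec, run_experiment, relative_change
from wormgait.muscle import PerturbationSpec

wt = run_experiment(default_spec("proprioceptive", "agar_like"))
h1 = run_experiment(default_spec("proprioceptive", "agar_like", PerturbationSpec("1", 0.2)))
print(wt.frequency, wt.speed)
print(relative_change(wt, h1))
```

prints (calibrated defaults)

```
1.196178975799482 0.5224515199940762
{'frequency_reduction_pct': 19.530245255969103, 'speed_reduction_pct': 35.77269612973144}
```

i.e. the wild type crawls at ~1.20 Hz and 0.52 mm/s, and removing muscle
cross-inhibition (c = 0.8) slows the emergent rhythm by ~19% — inhibition
is doing frequency work even though no oscillator parameter was touched.
The numbered drivers under `analysis/` run the full stories (wild-type
gaits, the knockout matrix under both control paradigms, muscle-parameter
sweeps, the tracker-style kinematics round trip, calcium phase profiles)
and write their tables under `results/`.

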