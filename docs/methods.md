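# Methods

## The model

`nucsense` simulates how a moving nucleus can read out its position along a
neural progenitor cell (NPC) of the developing zebrafish retina from the
local concentration of the Notch intracellular domain (NICD), and how that
readout can produce a trajectory-dependent probability of neurogenic
differentiation despite the stochasticity of interkinetic nuclear migration
(INM).

The cell is an elongated pseudostratified epithelial cell of length
L = 50 μm with its apical pole at z = 0. NICD is produced at the apical
surface at constant areal rate R, diffuses in the cytoplasm
(D = 2.9 μm²/s), and is degraded everywhere at first-order rate k. With the
cell length as length scale (ξ = z/L), t_d = L²/D ≈ 0.24 h as time scale and
C₀ = R/(kL) as concentration scale, the cytoplasmic balance is

    ∂θc/∂t = ∂²θc/∂ξ² − φ² θc,   −θc′(0) = φ²,   θc′(1) = 0,

with the Thiele modulus φ² = kL²/D the single transport parameter. Without
a nucleus the steady profile is the classical

    θc(ξ) = φ cosh(φ(1−ξ)) / sinh(φ),

with apex/base contrast cosh(φ): φ ≫ 1 gives a steep exponential gradient
(decay length 1/φ), φ ≲ 1 gives an almost flat profile. Because k is not
measured, φ is the free parameter of the analysis (default φ = 10).

Convection by the moving nucleus is neglected: the Peclet numbers vL/D of
the two migration phases are 0.038 (basalward, 8 μm/h) and 0.13 (apicalward,
27 μm/h), both well below 1.

The nucleus — an ellipsoid with semi-axes a = 5 μm (along the cell axis) and
b = 2.5 μm — exchanges NICD with the cytoplasm across its surface with
import and export mass-transfer coefficients K_i = 12 μm/h and K_e = 2 μm/h
(dimensionless α_i = K_iL/D ≈ 0.057, α_e ≈ 0.0096). The nuclear balance is

    dθn/dt = β (α_i θ̄c − α_e θn),     β = (A_n/V_n) L ≈ 51,

where θ̄c is the cytoplasmic concentration averaged over the nuclear
footprint [ξn − a/L, ξn + a/L]. Two consequences anchor the behavior:

* at steady state the net exchange vanishes, so θn = (α_i/α_e) θ̄c ≈ 6 θ̄c
  — the nucleus concentrates NICD sixfold;
* the import/export equilibration time V_n/(A_n K_e) ≈ 0.49 h acts as a
  low-pass filter: positional fluctuations faster than ~half an hour are
  damped in θn, which is what makes concentration sensing robust to the
  jitter of nuclear motion.

## Nuclear motion

The centroid position follows a drift–diffusion SDE (Euler–Maruyama,
default step 10⁻³ t_d ≈ 0.86 s),

    dξn = v_nd dt + sqrt(2 D_n,nd dt) dW,

with one out-and-back episode per cell cycle: drift +8 μm/h until first
passage across a sampled turning position, a pause of sampled duration with
drift zero (the Wiener term, D_n = 0.125 μm²/h, stays on in all phases),
then drift −27 μm/h until first return to the apical resting position
ξ_min = (gap + a)/L = 0.12, where mitosis would occur. The centroid is
confined to [0.12, 0.9] (nucleus fully inside the cell) by a reflecting
clamp; clamp events are counted and reported.

The turning-position and pause-time distributions were measured
experimentally but are not available in tabulated form, so the package
provides parametric stand-ins (uniform / truncated-normal / histogram for
turning; exponential / lognormal / histogram / fixed for pause), with a
CSV hook for digitized empirical histograms. Defaults: turning uniform over
30–90% of cell length (the admissible centroid range; uniform coverage gives
every probability bin statistical power, and the normalization below makes
the probability curve independent of cross-bin weighting), pause exponential
with mean 1 h (the minimal waiting-time model). Both are assumptions, not
measurements, and both matter quantitatively for the φ = 50 scenario (see
Limitations).

## From concentration to fate

For each trajectory the solver produces θn(t). The depletion time τ is the
total time θn spends below a threshold, f × max θc of the steady profile
with the nucleus at its starting position (f = 0.6 by default; an
alternative reference, the apical steady nuclear level, is provided because
nuclear levels are ~6× cytoplasmic ones). Crossings are refined by linear
interpolation within a step; τ accrues over all phases. Trajectories are
binned by turning position (default 10% bins over 30–100% of cell length)
and the differentiation probability per bin is the normalized mean
depletion time

    p_i = ⟨τ⟩_i / max_j ⟨τ⟩_j,

so the deepest-translating bin has p = 1 by construction. Empty bins are
reported as missing, never imputed; if every ⟨τ⟩_i is zero (small φ: θn
never crosses the threshold) the result is flagged degenerate rather than
normalized.

## Numerical scheme

The 3D problem (thin cell, ellipsoidal nucleus, moving boundary) is reduced
to 1D with a well-mixed nuclear compartment. This is a deliberate deviation
from a moving-mesh finite-element treatment of the same physics, and rests
on two scale separations: radial diffusion across the ~1 μm process
equilibrates in ~0.1 s, and intranuclear diffusion in ~35 s, both far faster
than import/export (~0.5 h) — so neither radial nor intranuclear gradients
carry information. The exchange coupling uses the true ellipsoid surface
area and volume, which preserves both the equilibrium ratio α_i/α_e and the
kinetic time scale of the 3D geometry. The cytoplasmic sink/source is
spread over the nuclear footprint with the pointwise driving force
g (α_i θc(ξ) − α_e θn), g = A_n L/(A_c 2a), with A_c = πw²/4 the process
cross-section; at steady state the nucleus then acts as a weak diffusive
shunt (zero net flux, apical-side uptake, basal-side release). Cytoplasmic
volume exclusion by the nucleus is not modeled: the 1D domain is [0, 1]
throughout. Since no cross-sectional area profile of the real cell is
available this adds an O(1)-geometry uncertainty to g, but not to the
steady-state map θn(ξn) (which is independent of g) nor to the nuclear
kinetics (set by β).

Space: cell-centered finite volumes, uniform grid, 250 cells by default
(the apical flux enters the first cell as a source; second-order accurate;
max relative error vs the closed form < 10⁻³ for φ ≤ 10). Time: backward
Euler on the coupled linear system; each step solves a tridiagonal system
bordered by the scalar θn via a Schur complement (two tridiagonal solves).
The scheme is unconditionally stable, positivity-preserving (M-matrix), and
conserves the exchange exactly — the discrete mass budget
(influx − degradation − storage change) closes to round-off, which the
diagnostics report per run. A step-size guard rejects
dt > 0.5/(β max(α_i, α_e)), the accuracy limit of the fastest retained
process; the default solver step is 5×10⁻³ t_d. Trajectories simulated at
the finer native step are coarsened to the solver step by linear
interpolation (never upsampled: that would fabricate fluctuations).

Initial condition: the steady coupled solution with the nucleus at its
apical starting position. This is an assumption (the initialization of the
original 3D computation is not specified); it avoids spurious transients,
and at φ = 50 it matters — see below.

Problem sizes used by the shipped checks: ensembles of 100–600 trajectories
(stratified 100-per-bin for the monotonicity check), grids of 125–250 cells.
These sizes give sampling errors well below the effect sizes being checked;
the full-scale configuration (1500 trajectories, as in the original
analysis) is the `fate` scenario default.

## What the tests do and do not show

The synthetic generator reproduces the *structure* of measured INM
(drift–pause–return, fitted positional diffusivity, one turn per cycle) but
not the measured turning/pause laws. Passing tests therefore validate the
mechanism — gradient formation, import/export damping, monotone increase of
depletion time and probability with turning position — not the quantitative
bar heights of any experimental probability curve, which depend on the
unpublished empirical distributions.

Two quantitative points are worth recording:

* Low-exchange limit. With import/export scaled by 0.01 the nuclear
  relaxation time becomes ~49 h; over a full traversal (~7.3 h) θn still
  relaxes by 1 − e^(−7.3/49) ≈ 13% toward its near-zero basal equilibrium.
  "Nearly constant" at this scaling factor therefore means ~13%, not <5%;
  the corresponding test asserts the stricter figure and is expected to
  fail, documenting the time-scale arithmetic rather than hiding it.
* φ = 50. The steady apical nuclear level (≈ 6 × θ̄c(0.12) ≈ 11) is already
  below the threshold 0.6 × max θc ≈ 28, so τ equals the whole trajectory
  duration and the probability curve is set purely by trajectory duration:
  p_i ≈ [travel(ξ_i) + mean pause] / [travel(0.85) + mean pause]. With the
  default speeds and a 1 h mean pause this first exceeds 0.5 in the 40–50%
  bin. Early differentiation is reproduced qualitatively; the exact bin at
  which p crosses 0.5 is controlled by the pause-time distribution (a ≳3 h
  mean pause moves the crossing into the 30–40% bin), i.e. by exactly the
  empirical ingredient that is unavailable.

## Parameters at a glance

| parameter | symbol | default | units |
|---|---|---|---|
| cell length | L | 50 | μm |
| process width | w | 1 | μm |
| nuclear semi-axes | a, b | 5, 2.5 | μm |
| apical gap | — | 1 | μm |
| NICD diffusivity | D | 2.9 | μm²/s |
| degradation | k | via φ (default φ = 10) | 1/s |
| production | R | 1 (cancels in θ) | arb. |
| import / export | K_i, K_e | 12 / 2 | μm/h |
| drift speeds | v | 8 (out), 27 (back) | μm/h |
| positional diffusivity | D_n | 0.125 | μm²/h |
| threshold fraction | f | 0.6 | — |
| grid / solver step | — | 250 cells, 5×10⁻³ t_d | — |

## Known limitations

* The well-mixed nuclear compartment discards intranuclear gradients by
  construction (consistent with using spatially averaged nuclear
  concentrations, but the spatial profile is lost).
* The effective cytoplasmic cross-section near the cell body is unknown;
  the sink strength g inherits that uncertainty (the steady θn(ξn) map does
  not).
* One turn per cell cycle; no multiple basal excursions, no division
  bookkeeping, no downstream Her4 kinetics — fate is the threshold proxy
  only.
* Boundary behavior of the SDE (reflecting clamp) is an assumption; clamp
  events are rare for the default parameters and are counted.
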