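# Methods

`snarefusion` models the fusion of reconstituted SNARE-bearing small
unilamellar vesicles (SUVs) stage by stage, from diffusive encounter to
full fusion-pore expansion. Each stage is a small, closed-form or
quadrature-based physical model with explicitly stated parameters; a
stochastic assay generator reproduces the bulk fluorescence experiments
those parameters are calibrated against. This note records the models,
their assumptions, the defaults and why, the numerical choices, and
what the synthetic data can and cannot show.

## Collision and encounter (stages i–ii)

Vesicle meetings are Smoluchowski coagulation events. For a probe
vesicle of radius `Rv` in a bath of target vesicles (radius `Rt`,
number density `ρt`):

    ν = 2 (Rt + Rv)² kBT ρt / (3 η Rt Rv)

which is algebraically `4π(Dt + Dv)(Rt + Rv)·ρt` with Stokes–Einstein
diffusion coefficients — the classic diffusion-limited capture rate.
Lipid molarity is converted to vesicle density through a spherical-shell
lipid count, `(4πR_out² + 4πR_in²)/a_lipid`, ≈ 19,800 lipids for a
25 nm / 5 nm / 0.65 nm² vesicle. Under the standard assay conditions
(1 mM total lipid, 9:1 tSUV:vSUV, water at 298.15 K) this gives
≈ 300 collisions per second per vSUV. The companion quantity, the total
collision rate in 100 μL, evaluates to ≈ 9×10¹³ s⁻¹; the published
order-of-magnitude figure for the same conditions is 2×10¹⁴, and the
two cannot be reconciled exactly with any single lipids-per-vesicle
count that also yields 300 s⁻¹. The default geometry targets the
300 s⁻¹ anchor and the total rate is treated as order-of-magnitude
only.

One collision keeps the membranes within SNARE-bridging distance
`d` (8–15 nm; default 15 nm) for `τ = d²/(6 D_SUV)` ≈ 1.9 μs at
`D_SUV = 20 μm²/s`. A SNARE with lateral diffusion `D_p = 5 μm²/s`
sweeps `a_exp = (2D_p/3D_SUV)·d²` ≈ 37.5 nm² during that window —
about 115 lipids counting both leaflets, hence a saturating SNARE
density near one copy per 100 lipids. The per-collision encounter
probability is a hard product of `min(1, n·a_exp/A)` factors per
vesicle, with `A` the per-leaflet-equivalent membrane area; no
partial-coverage correction is attempted because the underlying
mean-square-displacement argument is itself only order-of-magnitude.
Note the downstream kinetic chain (below) uses the rounded 10 μs
per-collision dwell of the published analysis; the 1.9 μs
mean-square-displacement value is computed and reported separately,
and the two are deliberately not reconciled.

## Initiation kinetics and the fusion barrier (stage iii)

SNAREpin nucleation is a single thermally activated step obeying
Kramers' overdamped escape law, `τ = τ0·exp(Ea/kBT)`, with the attempt
time `τ0` between 0.1 and 10 ns for nanometre-scale reactions. Reports
carry this prefactor range through as an interval. The forward chain —
10⁶–10⁷ collisions before fusion × 10 μs dwell × ~10 v-SNAREs per
contact — gives a cumulated one-on-one contact time of 100–1000 s, and
inverting Kramers brackets the initiation barrier at 23–30 kBT. With
the barrier lowered to 8 kBT (pre-structured t-SNARE), the same law
predicts 0.3–30 μs assembly.

The fusion barrier proper (Eb ≈ 25 kBT) is rooted in short-range
hydration/protrusion repulsion `P(d) = P0·e^(−d/λ)` (`P0 ≈ 100 atm`,
`λ ≈ 0.3 nm`). Delivering 25 kBT over ~1 nm is an average force of
~100 pN; at the 100 atm opening pressure this force loads ~10 nm², or
~15 lipids in one leaflet. The total-lipid figure is reported as the
raw 4× product (two leaflets × two membranes ≈ 60); the published
anchor "~100 lipids" is not a clean multiple of 15 and both numbers
are surfaced rather than hidden.

## The N-SNAREpin fusion-time model (stage v)

N simultaneously released SNAREpins (a crude stand-in for the
synaptotagmin-clamped, calcium-synchronised state) act twice:

* travel: overdamped approach at `v = N·Fp/(3πdη)`, so
  `τt = 3πldη/(N·Fp)`;
* waiting: each pin lowers the fusion barrier by `δe`, so
  `τw = τ0·exp((Eb − N·δe)/kBT)`, clamped at `τ0` once `N·δe ≥ Eb`
  (Kramers theory is invalid past barrier disappearance; that regime is
  travel-limited by construction).

`τf = τt + τw` decays exponentially at small N and as 1/N at large N.
Defaults: `Fp = 17 pN` (the optical-tweezer zippering-force scale),
`l = 5 nm`, `d = 50 nm`, `Eb = 25 kBT`, `δe = 6 kBT`, `τ0 = 5 ns`.
This calibration was chosen once to satisfy, jointly, every published
anchor of the model: regime crossover at N = 4 where the fusion time
is a few dozen ns, barrier disappearance at `⌈Eb/δe⌉ = 5` pins,
τw < 100 μs from N = 3, and a single-pin fusion time of ≈ 0.9 s. These
anchors over-determine the four-parameter family; no calibration
satisfies in addition a strict (<1%) travel-time domination at N = 8,
because the clamped `τw = τ0` never falls below 5 ns while
`τt(8) ≈ 17 ns`. Large-N travel domination is therefore exact only for
shorter attempt times, and the threshold counts — not the absolute
times at threshold — are the robust outputs of the model.

## Pore expansion (stage vi)

A nascent pore of radius `r` is bounded by a torus-like rim whose
minor radius is fixed by the intermembrane gap and membrane thickness,
`b = (h + t)/2 = 3.5 nm` at the reference geometry. Its bending energy
is integrated over the meridian with the hoop curvature evaluated at
the tube centre:

    E_rim(r) = s · (κ/2) ∮ (1/b − cosθ/(r+b))² dA,  θ ∈ [−π/2, π/2]

with `dA = 2π(r+b)·b·dθ`. Two numerical facts force this "crude torus"
treatment rather than the exact local-curvature torus: the exact
integrand diverges as `π²κ√(2b/r)` for `r → 0` (a zero-lumen torus is
singular), and its asymptotic rim cost `π²κ/b ≈ 28 kBT/nm` at
`κ = 10 kBT` could not be overcome by three 10 pN pins
(3 × 2.4 kBT/nm), contradicting the expansion threshold the model is
built to express. The dimensionless shape factor `s` absorbs the
crude-geometry ambiguity (quarter- vs half-torus span, monolayer vs
bilayer modulus conventions span roughly s ∈ [0.25, 1]); it is the
model's single calibrated constant, set to 0.3 so that the reference
parameter set (25 nm vesicle, κ = 10 kBT, h = 2 nm, t = 5 nm, 10 pN
per pin) yields an expansion threshold of exactly 3 SNAREpins. The
threshold is insensitive to the exact value (it stays 3 for
s ∈ [0.28, 0.37]) and the n = 2 landscape retains a ≈ 7 kBT barrier at
the default.

As the pore consumes the vesicle, the vesicle's stored curvature
energy (8πκ for the full sphere) is released in proportion to the
consumed cap area, `−4πκ·h_cap/R_v` with the cap bounded by the rim
attachment circle `r + b`. This term turns the bare landscape over at
a finite radius (≈ 17 nm at reference parameters), producing the
single-maximum expansion barrier. Each SNAREpin contributes a constant
radial force, a linear tilt `−N·F·r` (10 pN ≈ 2.4 kBT/nm). E(0) = 0 is
the closed-pore reference.

Numerics: the meridian integral uses adaptive quadrature
(`scipy.integrate.quad`, abs. tol. 1e-10); the landscape grid defaults
to 401 points on r ∈ [0, 20] nm — 20 nm rather than a shorter grid so
the bare landscape's interior maximum is resolved; halving the grid
spacing moves the barrier height by far less than 0.05 kBT. The
barrier is the largest forward climb `max_r [E(r) − min_{r'≤r} E(r')]`;
a barrier below 1 kBT (thermal) counts as vanished, exposed as a flag.
Reseal times are read off the same landscape: Kramers escape over the
backward barrier from a metastable open minimum toward r = 0, with
"immediate reseal" reported when no such minimum exists — the crude
landscape does not by itself produce the sub-nanometre flicker minima
seen in conductance experiments, so reseal analysis usually applies to
externally supplied or modified landscapes.

Transport through an open pore is standard: diffusive efflux
`τ = V·L/(πa²D)` (≈ 1.4 ms for a 1-nm pore on a 25-nm vesicle, which
is why lipid-mixing dyes cannot resolve pore kinetics) and ohmic
conductance with access resistance `g = σπa²/(L + πa/2)`, inverted by
bisection for apparent diameters.

## Synthetic assays and parameter recovery

The generator emulates the bulk lipid-mixing assay at its published
operating point: 300 collisions s⁻¹ per vesicle, one fusion per 10⁶
collisions, ≥1000 labelled vesicles, hour-scale traces. Each labelled
vesicle fuses at most once (the unlabelled partner is in excess), so
first-fusion times are exponential with rate ν·p; an exact
per-collision Bernoulli mode (geometric collision count × gamma
collision times) exists for cross-validation and is
indistinguishable at p ≪ 1. Traces are the empirical fused fraction
scaled by the dequench gain plus additive Gaussian noise; content
release adds per-event partial release `1 − e^(−t_open/τ_efflux)` for
transient pores. No photobleaching, no FRET spectral model, no optics:
noise exists to exercise the estimators, and passing recovery tests
shows identifiability of the rate chain under these idealised
conditions, not robustness to real instrument drift.

Recovery inverts the chain as the published analysis does: a
least-squares fit of `A(1 − e^(−kt))` recovers the fusion rate; the
confidence interval is a seeded parametric bootstrap that redraws the
vesicle ensemble (the dominant error in a bulk trace is the
finite-ensemble sampling of the fused-fraction curve, which is
autocorrelated and invisible to naive residual resampling); the
initiation barrier follows from collisions-per-fusion × dwell ×
SNAREs-per-contact and the Kramers inversion. End-to-end, a known
barrier planted in the generator is recovered within 0.5 kBT.

All stochastic outputs are bit-reproducible under a fixed seed
(`numpy.random.default_rng`).

## Problem sizes

Default problem sizes are desk scale by design: 401-point landscapes,
10-pin curve scans, 1000–40,000-vesicle ensembles, few-hundred-replicate
bootstraps. The Monte-Carlo validation of the Smoluchowski kernel uses
400 walkers in a 15-contact-radius periodic box with the standard
cubic-lattice finite-size correction (factor 1/(1 − 2.837·a/L)).

## Known limitations

* The torus-pore landscape is calibrated, not derived: its shape factor
  encodes a geometry convention that the crude model cannot pin down by
  itself. Absolute barrier heights should be read as scale estimates;
  the pin-count thresholds are the robust predictions.
* No hemifusion/stalk intermediates, no lipid-composition effects, no
  chaperone kinetics (Munc13/Munc18/synaptotagmin), no optimum-N
  (non-monotonic) crowding models — all deliberately out of scope.
* The encounter model ignores hydrodynamic interactions, polydispersity
  and tethered geometries; collision rates in crowded or docked
  configurations will differ.
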