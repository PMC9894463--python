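# Methods

`schoolfeed` couples an individual-based schooling model with a daily
feed-conversion growth update to ask how the spatial footprint of feeding
shapes growth differences among individually identical fish. This note
records the model, its parameters, the numerical choices, and what the
synthetic experiments do and do not show.

## Behavioral model

Each of *n* fish is a point individual with position **x**, velocity **v**,
body mass *W* (g) and total length *TL* (m). Motion follows Newton's
equation with a semi-implicit Euler update at Δt = 0.025 s:

    W a(t+Δt) = F(t),   v(t+Δt) = v(t) + a·Δt,   x(t+Δt) = x(t) + v(t+Δt)·Δt

The swimming force is the sum of six rules, each a *unit-direction* vector
scaled by a fixed weight (so each rule contributes a force of magnitude
exactly its weight, or zero when the interaction is absent):

| rule | weight | direction |
|---|---|---|
| separation | w₁ = 0.6 | away from the nearest in-view individual |
| cohesion | w₂ = 0.4 | toward the centroid of in-view individuals |
| alignment | w₃ = 0.4 | toward the mean heading of in-view individuals |
| boundary | w₄ = 1.0 | away from the nearest in-view wall/bottom/surface point |
| feed | w₅ = 3.0 (feeding) / 0 (standard) | toward the nearest live pellet |
| wander | w₆ = 0.2 | random; (x₁,x₂,x₃) ~ U[−1,1]³, normalized |

Perception is a sphere of radius 2·TL minus a rear blind cone of half-angle
30° about −**v** (undefined, hence absent, at zero speed). Feed is detected
regardless of the field of view. The cube-then-normalize wander direction
is *not* uniform on the sphere (cube corners are over-represented); it is
kept as the model's literal rule, with an isotropic option
(`isotropic_random`).

Speed is capped at |v|ₘₐₓ = Cᵥ·TL with Cᵥ = 1.5 s⁻¹ cruising (standard
mode) and 7.0 s⁻¹ in feeding mode; because the rule forces are large
relative to inertia (mass is converted to kilograms in the Newton step, a
choice exposed as `force_scale`), the dynamics are effectively cap-limited:
the cap, not the force magnitudes, sets the speeds.

A fish is in *feeding mode* while feed is present in the tank and its
intake that day is below the satiation cap Smax = 4% of body mass;
otherwise it swims in standard mode.

## Feed and intake

The tank is a vertical cylinder (radius 1.5 m, depth 1.5 m; z = 0 at the
bottom). Once per day a ration of 1.86% of school biomass is converted to
0.065 g pellets (a 5.0 mm sphere at water density; count = floor(ration /
pellet mass)), scattered uniformly over a square at the surface, and sinks
at 0.025 m/s until it rests on the bottom, where it stays edible until the
1000 s feeding window ends. The three standard squares have sides 1.5 m
(A), 1.0 m (B) and 0.5 m (C), centered on the tank axis.

Intake is contact-based: a pellet whose center is within
`pellet_radius + 0.1·TL` of a feeding-mode fish (a "mouth sphere" of
~1.7 cm for a 14 cm fish) is consumed and removed that step. A fish may
take several pellets in one step; the satiation gate is re-checked as
pellets are processed, so per-day intake can exceed Smax by at most one
pellet mass. Contested pellets go to a uniformly random contacting fish.
Daily intake is *defined* as (pellets eaten) × (pellet mass) and is carried
that way, so intake bookkeeping and daily mass conservation are exact in
floating point.

The mouth-sphere factor is the one deliberately calibrated constant.
With 0.1, day-1 feeding of the 1.5 m square completes in ~2.5 s —
comfortably within the ~30 s reported for this kind of setup, and in the
*scramble* regime where position and speed decide who eats. Shrinking the
factor until completion stretches to ~25-30 s (factor ≈ 0.013) moves
feeding into a consumption-limited regime in which every fish gets a
near-equal share and the between-method variance signal collapses; the
completion-time narrative and the reported magnitude of growth dispersion
are not simultaneously reproducible with this single knob. The default
stays at 0.1, preserving the competition mechanism the tool exists to
study.

## Growth

At day end each fish grows by ΔW = S·FCE with FCE = 1 (no maintenance
cost: mass never decreases, a documented model limitation), and total
length follows the fitted allometry TL = (W/a)^(1/b) with a = 0.0209,
b = 2.843 (length in cm, mass in g; 38.53 g ↔ 14.08 cm). Ration defaults
to a fraction of *current* biomass (selectable to *initial*). Under full
daily consumption and FCE = 1 the school biomass compounds exactly:
B(d) = B(0)·1.0186^d, so mean day-90 mass is bounded by
38.53·1.0186⁹⁰ ≈ 202.4 g. The simulator reaches this ceiling (all feed is
eaten every day), which is the model's exact upper bound on mean growth —
reported mean masses a few percent above it cannot be produced by this
ration rule and are treated as within the stochastic tolerance of the
comparison, not as a target to tune toward.

## Experiment layout

A run is 90 feeding days. Day-1 positions are uniform in the cylinder with
random horizontal headings at cruising speed (so schooling structure forms
quickly); from day 2 each day starts from the previous day's final state.
The daily-randomization variant re-draws positions and headings every day,
removing day-to-day carry-over of privileged positions; with
randomization the inner loop may end early once all feed is gone (`fast`),
since final positions are then irrelevant.

Randomness is organized as one `SeedSequence` per run: child 0 seeds the
initial state and child *d* seeds day *d*. Within a day the stream is
consumed in a fixed order — (variant only) re-randomization, pellet
placement, the pellet tie-break pool (one uniform per pellet, drawn up
front so its size is fixed), then per-chunk wander draws (2000 steps per
chunk). Replicate seeds derive from a master seed via `SeedSequence`
spawn keys, reduced below 2³¹. Identical config and seed reproduce the
ledger byte-for-byte.

## Numerics and implementation

Two engines implement the identical per-step order (modes → perception →
forces → synchronous integration → sinking → consumption): a per-fish
reference in plain NumPy — the readable specification of the model and the
oracle in tests — and a compiled (numba) kernel used for production runs.
Both consume the same pre-drawn random streams. All selection logic
(membership, nearest neighbor/boundary/pellet with fixed tie orders,
consumption, tie-breaks) follows identical rules; the kernel may
reassociate the neighbor centroid/heading sums for vectorization, so
trajectories agree to floating-point tolerance (observed ~1e-15 per step
on micro-scenarios) rather than bit-for-bit. Pellets never move
horizontally, so a per-day cell grid over the feeding square serves both
nearest-pellet search (expanding rings with a conservative bound) and
contact tests.

Degenerate cases: coincident positions fall back to the step's seeded
wander direction; a fish exactly at the neighbor centroid, or already at
the mean heading, feels no cohesion/alignment; boundary candidates tie in
the order wall, bottom, surface. After each step positions are clamped to
the tank interior (radius − 1 mm, z ∈ [1 mm, depth − 1 mm]) with the
outward velocity component zeroed; penetration handling is not otherwise
specified by the model.

## What the synthetic experiments show

The generator's defaults are the study conditions themselves (100 fish of
38.53 g, the three squares, 1.86% ration, 90 days), so the package's
experiments emulate that design, not any particular rearing dataset: no
water flow, no metabolic cost, no mortality, identical initial masses, and
behavioral parameters taken as given rather than fitted to tracked
trajectories. Passing tests therefore demonstrate the *mechanism* — speed
scales with length, so early winners of feeding scrambles compound their
advantage, and narrower feed squares amplify the resulting variance and
right-skew of final mass at essentially unchanged mean — not a calibrated
prediction for a specific farm.

Within a test session the full-scale checks use five master seeds and take
medians; day-1 completion checks use ten. Because the mean is pinned at
the consumption ceiling while narrow squares skew the distribution
rightward (median below mean), a rank test on the three day-90 vectors
tends to detect a location difference here even though the means are
equal; the variance (Bartlett) signal is many orders of magnitude stronger
and is the effect of interest.
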