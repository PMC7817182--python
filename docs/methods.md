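# Methods

## The model

The simulation represents a T cell as a two-dimensional mechanical system
advanced by overdamped Langevin dynamics.  Each timestep assembles forces
on every microtubule (MT) vertex — elastic confinement by the cell
boundary, steric exclusion by the nucleus, minus-end anchor and torsion
springs coupling fibers to the centrosome body, bending forces from the
discrete worm-like-chain energy, and dynein link forces — and moves each
coordinate by `dt/γ · F` plus Gaussian noise of per-axis variance
`2 kT dt/γ`.  Motor agents (KIF21B cappers, synapse dynein) evolve by
discrete stochastic rules in the same timestep.

### Geometry

The cell is a disk of radius R = 7 µm.  A horizontal plane can truncate it
to a fraction of the full height: 0.9 for the polarizing cell (the flat
side is the immunological synapse, placed at the bottom,
`y = R(1 − 2·0.9) = −5.6 µm`), 0.2 for the small cap in which the
centrosome is held during initialization (top of the cell, opposite the
future synapse — the side is a modeling choice; published snapshots show
centrosomes starting distal to the synapse), and 1.0 for the plain circle
used during Phase I.  Plane/circle junctions are smoothed by fillet
circles tangent to both (radius 1 µm by default).  Tangency determines the
fillet center, not its radius: a circle tangent to a line and internally
tangent to a circle forms a one-parameter family, so the fillet radius is
a parameter.  The boundary and the 5-µm nucleus are elastic with
100 pN/µm stiffness; points inside the space (outside the nucleus) feel
nothing, and penetration is penalized linearly toward the closest boundary
point.  Diffusing motors cannot take elastic forces, so they bounce off
the nucleus specularly; if no admissible bounce is found in 1000 attempts
(tight corners), the molecule is placed on the nucleus edge.

### Fibers and centrosome

90 fibers are polylines with 0.5 µm interior segments (terminal segment
0.25–0.75 µm, re-segmented as the contour grows or shrinks) and bending
rigidity κ = 20 pN µm² (the textbook MT value).  The bookkept contour
length is authoritative; constraint projection (Gauss–Seidel sweeps,
tolerance 1% of the segment length, at most 50 sweeps, after which the run
aborts) restores segment lengths after each unconstrained move.  The
centrosome is a rigid disk (radius 0.5 µm) with 90 anchor directions
spaced exactly 2π/90 apart.  Minus ends attach to anchor points by
100 pN/µm springs; a weak torsional spring (0.5 pN µm/rad) biases the
first segment along its anchor direction.  The torsion is deliberately
soft: with a stiff clamp, short fibers become rigid rods rammed head-on
into the nucleus or the wall (the confinement cap leaves the centrosome
within ~1 µm of both), the majority of tips stall under tens of pN, and
the aster cannot develop the curling, gliding morphology seen in T cells.
Forces on anchors and torsion springs react on the body as force and
torque, so dynein pulling and polymerization pushing transmit to the
centrosome.

### Numerics

Explicit Euler at dt = 0.01 s would be unstable for the stiff springs
(100 pN/µm against a vertex drag of 0.125 pN s/µm), so all linear springs
toward known points are integrated semi-implicitly (per-vertex diagonal
implicit update), and bending is integrated implicitly with a cached dense
inverse per vertex count.  A per-step displacement limiter (half a segment
length) lets rare stiff transients — e.g. vertices left outside the new
boundary at the Phase I→II shape change — relax over a few steps instead
of jumping, which keeps the constraint projection well-conditioned; the
shape change therefore pushes stray vertices in elastically, never
teleports them.  Per-vertex drag is `drag_per_length × segment_length`
uniformly, with `drag_per_length = 0.25 pN s/µm²` (an effective
cytoplasmic value); kT = 0.00414 pN µm (300 K).  Halving dt changes a
deterministic 10 s trajectory by < 1% (tested).

### Plus-end dynamics

Growth speed decreases exponentially with the antagonistic load on the
tip (the component of external tip force opposing the growth direction):
`v(f) = v_g exp(−f/f_g)`.  Catastrophe follows one of two variants:

* **non-pausing** — constant rate `k_cat`, swept over 0.02–0.07 s⁻¹;
* **KIF21B-pausing** — force-dependent through the instantaneous speed:
  the mean catastrophe time is linear in v,
  `1/k(v) = 1/k_stall + (1/k_free − 1/k_stall)(v/v_g)`, so `k(0) = 0.3 s⁻¹`
  (stalled) and `k(v_g) = k_free` exactly.

`k_free` comes from inverting exponential survival: 81% of freely growing
tips must survive a 3.3 s observation window, giving
`k_free = −ln(0.81)/3.3 ≈ 0.0639 s⁻¹`.  The calibration module also
provides the barrier variant (`calibrate_linear_relation`): a single tip
grows toward an elastic barrier placed at 0.8 of the distance reachable in
the window, and the zero-force rate is root-found so that survival under
that load history is 81%.  Because a larger characteristic force means
less slowdown at the barrier and hence a lower hazard, the admissible
`k_free` *increases* (roughly linearly) with `f_g`; at `f_g = 4 pN` it is
0.050 s⁻¹.  The cell model uses the zero-load inversion as its default.

Shrinking fibers retract at `v_s` to a 0.1 µm stub and immediately
re-enter growth (forced re-nucleation): the fiber count is conserved and
there is no rescue parameter.  Paused fibers (held by a capper) neither
grow, shrink, nor catastrophe spontaneously.  Initial lengths are
exponential with mean 1 µm (floored at the stub length).

### KIF21B cappers

Free motors diffuse (D = 5 µm²/s), reflect at the cell boundary and
bounce off the nucleus.  Binding is evaluated against the diffusive path
(sampled at quarter-steps), not only the endpoint, because a motor's
r.m.s. step (~0.3 µm) exceeds the 0.1 µm capture radius and endpoint-only
checks let motors tunnel through the capture band.  Bound motors walk
plus-end-directed at 0.77 µm/s (the measured single-molecule speed) as
force-free riders; walking detachment is slow (0.02 s⁻¹ — the motor is
highly processive).  On reaching a growing tip the motor caps it: the
fiber pauses and an exponential timer of mean 8.3 s is drawn fresh (so
the pause is independent of the preceding walk).  On expiry the fiber
switches to shrinkage, the capper and every other motor on that fiber
unbind.  Second arrivals at a paused tip wait there and are released by
the collective unbind; arrivals at a shrinking tip unbind without effect.
At most one motor caps a given fiber.

### Dynein

50 couples sit at fixed anchors spaced uniformly by arclength over the
synapse contour (flat part plus fillets).  An unbound couple binds the
closest fiber point within 0.05 µm at 5 s⁻¹.  A bound hand walks
minus-end-directed with `v = v_max clamp(1 − f_opp/f_stall, 0, 1)`
(v_max = 1 µm/s, f_stall = 4 pN), where `f_opp` is the component of the
anchor-link spring force (stiffness 100 pN/µm) opposing the walk;
unbinding is Kramers-like, `k_off = 0.1 s⁻¹ · exp(|f|/3 pN)`, and a hand
reaching the minus end detaches.  Only sliding is modeled; there is no
end-on capture or depolymerization coupling.

## Parameter choices

The quantitative parameter table of the source study is not available in
the text we work from, so mechanical and kinetic values not fixed by the
narrative (growth and shrinkage speeds, characteristic force, drags,
stiffnesses, motor kinetics) are package defaults chosen once, by matching
the phenomena the study reports rather than by fitting to any test:

* `v_g = 0.3 µm/s` makes the motor-free pausing network dense
  (steady-state mean ≈ 3 µm in the confined cell), as the knockout-like
  snapshots show; with `v_g = 0.1` the mean is ~1.5 µm and Phase II loses
  all dynein engagement in every condition.
* `v_s = 0.05 µm/s` is an effective net shrinkage rate (≈ 3 µm/min),
  absorbing the rescues and shrinkage pauses the model does not represent;
  it sets the network turnover flux low enough that ten cappers make a
  visible dent (see Limitations).
* `f_g = 4 pN` keeps glancing wall contacts from stalling growth, which
  is what lets fibers glide and curl along the boundary.
* Capper kinetics (D, capture radius, binding rate, processivity) are set
  so that the motor duty cycle is dominated by the 8.3 s pause, matching
  the source's own estimate that ten motors can trigger on the order of
  one hundred catastrophes in one hundred seconds.

## What the simulations show — and do not show

The generator *is* the study: there is no external data.  Phase-I runs
reproduce MT-length control (mean length falls monotonically with the
catastrophe rate and with motor number; the 0.02 → 0.07 s⁻¹ sweep spans a
~2.5-fold decrease in this implementation).  Phase-II runs reproduce the
polarization mechanism: with ten motors the centrosome rounds the nucleus
quickly; without motors the long-MT network engages dynein on both sides
of the nucleus and the resulting force balance (low normalized force
imbalance |R−L|/(R+L)) delays or prevents polarization.

Three caveats matter when comparing magnitudes with the source study,
whose quantitative parameter table we do not have.  First, the
capper-induced fold-decrease in mean length has a structural ceiling in
this model class: each cap costs the motor the full 8.3 s pause, so ten
motors supply at most `10/8.3 ≈ 1.2` catastrophes per second, while the
relation `fold = 1 + (cap flux)/(natural catastrophe flux)` ties the
achievable fold to network turnover.  With the calibrated free rate the
natural flux is 1–3 s⁻¹ for any speed pair that keeps Phase II alive, and
honest diffusive search (plus mass-proportional binding, which spends
most walks on shrinking fibers) delivers ~0.3 caps/s: the measured fold
at the defaults is ≈ 1.15, well short of a full 2.  Second, elastic
confinement truncates the long-MT conditions: the constant-catastrophe
sweep ratio measures ≈ 2.5× here (5-seed means 8.6 µm vs 3.5 µm) where an
unconfined network would give 3.5×.  Third, because both Phase-II
conditions engage only a couple of dynein couples per frame at these
lengths, the normalized force-imbalance statistic saturates near 1 in
both, and its upward shift with motor number is not resolved — the
polarization-time contrast carries the mechanism instead.  All three
effects are analyzed, not tuned away, and the corresponding checks in the
test suite report them as failures by design.

## Scaled-down test conditions

The acceptance tests run 5 seeds per Phase-I condition (300 s each, as in
the protocol) and continue 3 of the pausing steady states per condition
into Phase II with a 400 s cap; the published protocol uses 30 repeats and
an 800 s cap.  These sizes keep the default suite around twenty minutes on
one CPU while leaving the trend statistics interpretable.  The
1D length-only Monte Carlo (`simulate_network_1d`) serves as an
independent oracle for the steady-state sawtooth mean
(`v_g/k + min_length`) and for trend checks at negligible cost.

## Known limitations

* Two-dimensional; fibers may cross one another (mimicking the third
  dimension) and only nucleus/boundary sterics apply.
* The nucleus is rigid and immobile; no deformation-mediated effects.
* No MT rescue, no GTP-cap kinetics, no nucleation kinetics (fiber count
  fixed at 90).
* Dynein acts only at the synapse and only by sliding.
* The Phase-II outcome depends on rare long-fiber excursions reaching the
  synapse and on polymerization pushing; both are sensitive to the free
  parameters discussed above.
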