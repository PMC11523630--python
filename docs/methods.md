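# Methods

## The system being modelled

The model describes a plant with the *Arisaema* life history — stage
structure (juvenile, adult) plus sequential hermaphroditism (adults flower
male first, switch to female as they grow, and can revert after costly seed
production) — and its specialist pollinator, a fungus gnat of which only the
males visit flowers. The plant offers no reward: it is attractive because its
floral odour resembles the pheromone of female gnats. Male inflorescences let
a trapped visitor escape through a basal exit hole, so he leaves carrying
pollen; female inflorescences have no exit, so the visit that pollinates is
also the visit that kills. The pollinator is therefore a victim, not a
mutualist, and plant fitness and pollinator mortality are coupled through the
same behavioural event. One plant corresponds to one inflorescence (the
species flower once per season), so abundances are at the flower scale, and
model time is dimensionless.

## Visit behaviour of a male insect

A male gnat searching for mates encounters male plants, female plants and
female insects with per-event probabilities proportional to their
attractiveness-weighted abundances a_M·X_M, a_F·X_F and Y_F (a weight of 1
means indistinguishable from a real female insect; juveniles do not flower
and are invisible). Given a lifetime budget of at most N visit events,
terminated early by the first female-plant visit:

* **Q1** — expected male-plant visits made before dying at a female plant.
  A life that never hits a female plant transfers no pollen and contributes
  zero. Literal form: Q1 = p_F·Σ_{j=0..N−1} Σ_{k=0..j} k·C(j,k)·p_M^k·p_Y^{j−k};
  simplified: Q1 = p_F·p_M·Σ_{j=1..N−1} j·(1−p_F)^{j−1}.
* **Q2** — expected copulations: the same sum with p_M and p_Y exchanged,
  plus the survivor term N·p_Y·(1−p_F)^{N−1} for lives that never hit a
  female plant.
* **P** — probability of ever being trapped. The geometric series is
  implemented as P = Σ_{k=0..N−1} p_F·(1−p_F)^k = 1 − (1−p_F)^N, i.e. one
  minus the probability of surviving all N independent events. (A naive
  exponent convention starting the series at k = 0 with exponent k−1 is
  singular; the implemented reading is the one consistent with the stated
  meaning and is confirmed by the stochastic oracle below.)

Both the literal combinatorial sums and the simplified geometric forms are
implemented; they agree to 1e−12 absolute (binomial coefficients are taken
from exact integer arithmetic before any floating multiplication, so the
double sums are stable over the supported N ≤ ~20 range). When no visit
target exists at all (a_M·X_M + a_F·X_F + Y_F = 0) the probabilities and all
three statistics are defined as 0 rather than 0/0.

An independent check is provided by `visit_oracle.simulate_visit_sequences`,
which simulates individual visit sequences with an explicit seeded generator
and tallies Q1, Q2, P directly. A non-lethal mode (`lethal=False`) covers the
release-after-deceit variant found in most other trap flowers: all N visits
are realized, Q1 counts male-plant visits made while still carrying pollen
(before the first female-plant visit, all of them if none occurs), and Q2
counts every copulation (so Q2 = N·p_Y in expectation). Whether pollen is
replenished at later male-plant visits is a modelling convention here, chosen
to mirror the lethal narrative with death removed.

## Population dynamics

Pollination success of female plants, Φ_X = Y_M·Q1/(A_X + Y_M·Q1), and mating
success of female insects, Φ_Y = Y_M·Q2/(A_Y + Y_M·Q2), saturate in the
male-insect "delivery pressure" (Holling type II; both are defined as 0 at
zero pressure even if the half-saturation coefficient is 0). Juvenile plants
are produced vegetatively by both adult sexes (r_VM, r_VF) and sexually by
pollinated females (r_P·Φ_X), all throttled by the logistic recruitment room
(1 − plant total/K_X). Sex change male→female runs at g_MF; reversal
female→male runs at g_FM·Φ_X — reproduction, not time, drives reversal. Male
insects suffer the extra death rate q·P from being trapped. Setting the
female-plant balance to zero gives the interior-equilibrium identity
X_M/X_F = (g_FM·Φ_X + d_F)/g_MF, used as an independent consistency check on
simulated steady states. A structural consequence worth noting: with
g_MF = g_FM = d_F (as in the calibrated defaults) that identity is 1 + Φ_X,
so the equilibrium plant male ratio cannot exceed 2/3 no matter how strong
pollination is; the simulated default steady state sits at ≈ 0.61.

Without insects the plant persists iff
[g_JM/(g_JM+d_J)]·[r_VM/(g_MF+d_M) + (g_MF/(g_MF+d_M))·(r_VF/d_F)] > 1 —
juvenile-to-male survival times expected lifetime juvenile production.
`persistence_boundary_r` inverts this for the common vegetative rate
r_VM = r_VF; under the default death rates the boundary is flat at
r\* = 0.013 for every g_MF, because (1 + g_MF/d_F)/(g_MF + d_M) is constant
when d_F = d_M.

## Parameters

All rates are per unit model time; capacities and abundances are flower-scale
individuals. Fixed life-history defaults: r_P = 1, K_X = K_Y = 15,
g_JM = 0.05 (net maturation, absorbing juvenile regression), g_FM = 0.01,
d_J = 0.015, d_M = d_F = 0.01 (juveniles die faster; adult survival is
size-saturated), s = 0.5 (balanced gnat birth ratio), f = 2, d_Y = 0.1
(gnats live months, plants decades), A_X = 1, A_Y = 10, q = 0.5, N = 10.
The swept quantities — attractiveness a_M = a_F, vegetative rates
r_VM = r_VF, sex-change rate g_MF — have no single natural value; default
construction uses the calibrated vegetative ("second") scenario with
moderate attractiveness (a = 0.4, r_V = 0.02, g_MF = 0.01) so that the
out-of-the-box model is the calibrated coexistence case. Two presets bracket
the empirical life histories: `first` (r_V = 0, g_MF = 0.005; obligate
pollination, as in most congeners) and `second` (r_V = 0.02, g_MF = 0.01; a
strong cormlet producer).

## Simulation protocol and numerics

The standard run starts from (X_J, X_M, X_F, Y_M, Y_F) = (1, 0, 0, K_Y/2,
K_Y/2) — juveniles colonizing a plant-free insect steady state — and
integrates to t = 50 000 with LSODA (rtol 1e−8, atol 1e−10; the stiff/
non-stiff switching handles both the transient and the long near-equilibrium
tail cheaply). Correctness of the tolerances is checked by halving them and
requiring < 1e−4 relative change in the window means. Output is sampled on a
uniform 2001-point grid from the solver's dense output.

**Extinction clamping.** Whenever total plant (X_J+X_M+X_F) or total insect
(Y_M+Y_F) crosses 0.001 from above, integration halts at the crossing (an
integrator event), the population is zeroed, and the run resumes; each clamp
is recorded in the trajectory. This prevents rebounds from abundances far
below one individual and makes the alternative-stable-state structure
reproducible. The same 0.001 threshold is re-applied to the window means at
classification time, so a population merely hovering below it still counts
as extinct.

**Summaries.** Steady-state abundances are trapezoidal time averages over
the last 10 % of the run (t = 45 000–50 000), accommodating fluctuating
attractors. Sex ratios are ratios of window means (not means of ratios),
which stays stable when one sex is nearly absent; when both sexes' means are
below 1e−12 the ratio is reported as missing rather than 0/0. Outcomes are
the four combinations of plant/insect extant at the threshold.

**Static visit-behaviour curves.** The Q1/Q2/P response curves fix the
composition rather than the dynamics: female insects at K_Y/2 and adult
plants totalling K_X/2 (juveniles excluded — they are not visited), split by
the stated male ratio (0.8 in attractiveness mode, following observed wild
sex ratios; swept in male-ratio mode at a = 0.4). The plant total is not
pinned down by the system itself; K_X/2 mirrors the insect convention, and
the qualitative shapes (Q1 and P increasing and Q2 decreasing in a; Q1
unimodal, Q2 increasing, P decreasing in male ratio) are verified over adult
totals from K_X/4 to K_X. The Q1 argmax uses a 0.01 grid step with ties
broken to the smallest value; at the defaults it falls at 0.67.

**Sweeps.** Regime maps default to linear axes; published-style ranges are
g_MF, r_V ∈ [0, 0.05] and capacities in [1, 30]; resolution is a knob
(21×21 for production maps; the test suite and acceptance checks use 9×9
grids, which already resolve every qualitative regime at desk scale). Axes
named `r_V` or `a` always set both members of the linked pair. When one axis
is g_MF and the other r_V, the analytic persistence frontier is attached to
the map.

## Design choices where the design was open

* Q1 of a life with no female-plant visit counts zero (pollen is never
  delivered); the survivor term appears only in Q2. The Monte-Carlo oracle
  resolves this ambiguity: the alternative accounting disagrees with the
  closed form by O(1).
* Clamping during integration (not only at classification). Either reading
  of "threshold 0.001" is defensible; clamping during the run is the one
  that makes bistability robust to 1e−300-scale abundances.
* Ratio of means rather than mean of ratios, per the "long-term average
  abundance" framing and for numerical stability.
* A single validation pass at parameter construction; all downstream
  operations assume validated inputs.

## What the tests do and do not show

The suite validates the combinatorics against brute-force enumeration and
stochastic simulation, the integrator against analytic invariants (capacity
bounds, the trivial equilibrium, the equilibrium sex-ratio identity, the
insect-free persistence condition) and self-convergence, and the sweep
machinery against the qualitative regime structure (plant extinction without
vegetative reproduction at low attractiveness, co-extinction at high
attractiveness and high sex-change rate, plant-only survival through
cormlets, bistability below the persistence boundary). All of this concerns
the model, not the field system: the equations are deterministic, well-mixed
and unstructured in space, with no environmental or demographic noise, no
seasonality, no pollinator learning or avoidance, and no evolution of
attractiveness. Passing tests say the model is solved correctly, not that
*Arisaema* populations behave like the model.

## Known limitations

* The persistence condition concerns invasion of the trivial equilibrium;
  inside the bistable region long-run fate genuinely depends on initial
  conditions, and the classification from the standard colonization start is
  only one branch.
* Steady-state means over a fixed window would mis-summarize attractors with
  periods comparable to the window; the dynamics here settle to fixed points
  at the explored parameters, and the window average is validated on
  synthetic periodic input, but exotic attractors elsewhere in parameter
  space would warrant a longer window.
* With g_MF = g_FM = d_F equal, the equilibrium plant male ratio is capped
  at 2/3 (see above); calibration targets above that value are unreachable
  in that regime and should be read against the cap.
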