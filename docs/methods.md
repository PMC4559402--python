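# Methods

## The model

`huddlesim` simulates a litter of neonatal rodent pups as circular agents
of radius r in a circular arena of radius 10r.  Each pup carries n
thermometers evenly spaced on its circumference at angular offsets
(k − ½)·2π/n from its heading (k = 1..n); the first n/2 lie on the pup's
left, the rest on its right.  A thermometer is *contacted* when it falls
inside a littermate's body; for equal radii the published angular
criterion (circular distance from the littermate's bearing below the lens
half-angle arccos(d/2r)) is algebraically identical to "thermometer within
distance r of the littermate centre", which is the form the vectorised
code evaluates.  The exposed fraction η_i is the fraction of uncontacted
thermometers.

Each timestep applies five stages synchronously from the start-of-step
state:

1. **Sensing.**  τ_ik = T_a·ε_ik + s·χ_ik (+ optional Gaussian sensor
   noise), where ε is the exposure flag, χ the body temperature of the
   nearest contacting littermate, and s ∈ (0, 1] an optional contact
   scaling.  T_L/T_R are the means of τ over the left/right thermometers.
2. **Motor drives.**  M_L = F(T_R)/(F(T_L)+F(T_R)), M_R = 1 − M_L
   (contralateral wiring).  F is the identity except in the
   homeothermotaxic variant, where F(T) = (1 + exp(−(T_p − T_b)·T/σ))⁻¹
   makes a cold pup (T_b < T_p) heat-seeking and a warm pup heat-avoiding.
3. **Rotation.**  θ ← θ + dt·arctan(v1·(M_R − M_L)).  The sign convention
   deserves a note: headings are counterclockwise-positive (translation
   along (cos θ, sin θ)), and a warmer right side (M_L > M_R) must turn
   the pup *clockwise*, toward the warmth — hence the M_R − M_L ordering.
4. **Translation.**  x ← x + dt·(v2·(cos θ, sin θ) + β·x/|x| + Σ_j
   (r − d_ij/2)·(x−x_j)/d_ij), summing over littermates with d_ij ≤ 2r.
   β = r_arena − |x| − r when the pup breaches the wall, else 0.
   Collisions are a single additive spring, not a constraint solver;
   transient overlaps are expected and are what generates surface
   contact.  Coincident centres take a seeded random push direction.
5. **Thermal update.**  Forward Euler on
   dT_b/dt = −k1·η·(T_b − T_a) − k2·(1−η)·(T_b − T_c) + G.
   T_c is the *mean* of χ over contacted thermometers (a temperature, so
   the exchange term is a relaxation); a fully exposed pup reports
   T_c = T_b so the exchange term is exactly zero.  The endothermic
   variant skips this stage and holds T_b = 37 °C.

Runs start with all pups uniform-random within one pup radius of the
arena centre (a pre-formed macro-huddle), headings uniform, T_b = 30 °C,
followed by 100 temperature-only settle steps (positions frozen) that are
excluded from all metrics.

## Parameters

| name | default | units | notes |
|---|---|---|---|
| r (pup radius) | 1 | length | sets the length unit |
| r_arena | 10 | r | boundary force can be disabled |
| n (thermometers) | 1000 | — | tests use 100–200; η(n=200) agrees with η(n=1000) to <0.01 |
| k1 | 1.0 | 1/time | exposed-surface conductance; the circumference-normalised form 1/(2πr) evaluated at unit circumference |
| k2 | 2.5 | 1/time | contact conductance (2.5·k1) |
| G | 6.32 | °C/time | thermogenesis; G/k1 sets the dispersed offset T_b − T_a |
| v1 | 200 | — | rotation gain (near bang-bang turning) |
| v2 | 0.3 | r/time | constant forward speed |
| T_p | 37 | °C | preferred body temperature |
| σ | 100 | °C² | transfer steepness |
| dt | 0.05 | time | forward-Euler step |
| steps | 8000 | — | recorded steps per run |
| s | 1.0 | — | contact scaling (sensing only); shifts the endothermic critical temperature to s·37 °C |
| noise variance | 0 | °C² | per-thermometer, per-step Gaussian sensor noise |

The k1 = 1 convention is the one under which the closed-form model's
plateau centre T_p − (G/2k1)(1/A_min + 1/A_max) falls at ≈25.3 °C and its
upper breakpoint at ≈30.7 °C, matching the temperature range over which
the collective behaviour is reported to change; evaluating 1/(2πr) at
r = 1 instead would push the whole transition below 0 °C.

## Group-level metrics

- **Huddling**: mean over pups and recorded steps of (1 − η).
- **Pup flow**: mean over pups of the average absolute time derivative of
  η, (1/(n_t−1))·Σ|η(t)−η(t−1)|/dt.  The derivative (per unit time, not
  per step) is the normalisation under which the reported baseline value
  ≈0.013 at T_a = 5 °C is reproduced by the stated dynamics.
- **Subgroups**: connected components of the contact graph with edges at
  d ≤ 2r (touching or overlapping); also the time-averaged largest
  component size.
- **Mean body temperature** over pups and recorded steps.

## The super-organism model

Treating the litter as one body with total exposed area A held optimal
for thermal homeostasis gives the piecewise form A(T_a) = clamp(G/(k1·
(T_p − T_a)), A_min, A_max) and B(T_a) = T_a + G/(k1·A) off the plateau,
T_p on it.  A_min/A_max default to the canonical measured values (0.36,
1.0) and can be recomputed from any sweep as the extreme per-run mean
exposed fractions; the recomputed path is used when comparing against
simulations.  At G = 0 the form degenerates to a step at T_p (A_min
below, A_max above) and is known not to describe the agent simulations,
which disperse at every ambient temperature without thermogenesis; the
code warns in that case.

## Numerical and design choices

- All pups update synchronously from the start-of-step state; the
  contact field is computed once per step.
- Nearest-littermate ties (equidistant centres) resolve to the lowest pup
  index; for equal radii the nearest centre always contains any contacted
  thermometer, so χ is well defined.
- Contact uses the closed disc with a ~1e−12 relative tolerance so the
  degenerate coincident-centre case registers as full overlap.
- Headings are stored unwrapped; nothing depends on wrapping.
- One RNG stream per run (NumPy PCG64) covers initialisation, sensor
  noise and degenerate-case tie-breaks; with noise off a seed fixes the
  trajectory bitwise.
- Sweeps draw per-run integer seeds (< 2³¹) from a master generator, so a
  sweep table reproduces exactly from its base seed.
- A non-finite body temperature or position aborts the run with a
  diagnostic; the usual cause is an oversized dt (the Euler update is
  stable at the default dt = 0.05, where the fastest thermal rate
  k1+k2 = 3.5 gives dt·rate ≪ 1).

## What the simulations do and do not reproduce

With the defaults above the package reproduces: the endothermic phase
transition located at ≈36–37 °C (and at s·37 °C under contact scaling);
deep cold-side huddling of the full model (huddling ≈0.64–0.67 at
T_a = 5 °C, matching 1 − A_min); macro-huddle maintenance by the
ectothermic and homeothermotaxic variants (largest aggregates of 8–12
pups vs transient contacts when heat exchange is removed); full dispersal
above ≈31 °C with T_b − T_a → G/k1; and the analytic plateau geometry.

Three families of reported results are *not* recovered under our reading
of the equations, and are reported as-measured rather than adjusted:

1. **Residual high-temperature contact.**  Noiseless endothermic pups
   above 37 °C disperse completely (≈99.5 % exposure, not ≈80 %): with no
   contact there is no sensor asymmetry, so pups run straight, reach the
   wall and pin there radially — a true fixed point of the stated
   dynamics.
2. **Endothermic micro-huddling.**  Below 37 °C the clamped litter holds
   a single churning blob (largest component ≈6–10 pups) rather than
   fracturing into aggregates of ≤4; the mean aggregate size (≈4.4) is
   close to the reported bound, the largest is not.
3. **Mid-slope thermoregulation and flow.**  The settle phase super-heats
   the densely overlapped initial pile (towards T_a + G/(k1·η̄) with
   η̄ ≈ 0.16), so runs begin with a thermal explosion; at intermediate
   ambient temperatures the litter fragments into frozen micro-groups
   before it can thermoregulate.  This depresses the pup-flow baseline
   (≈0.005 vs ≈0.013), moves the flow peak to ≈10 °C (vs 16 °C) and holds
   slope-region body temperatures at ≈30–34 °C rather than 37 °C.
   Alternative readings (sensor noise on; settle that also relaxes
   overlaps mechanically) shift but do not close these gaps and degrade
   the cold-side results that currently match.

The synthetic protocol mirrors the study conditions exactly (no animal
data enters anywhere); passing tests therefore demonstrate internal
consistency of the implementation and reproduction of the stated
collective phenomena, not fidelity to real litters.

## Problem sizes

Full-scale runs are 12 pups × 1000 thermometers × 8000 recorded steps.
The test suite and parts of the acceptance script use a reduced profile —
3 replicates, 4000 recorded steps, and 200 thermometers for quantities
insensitive to thermometer resolution — with tolerances widened
accordingly; huddling- and flow-critical quantities keep n = 1000 because
η resolution biases them (documented convergence check in the geometry
tests).
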