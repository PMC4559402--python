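# huddlesim

An agent-based simulator of **thermoregulatory huddling** in rodent
litters, for computational ethologists and collective-behaviour
modellers.  Newborn rodent pups keep warm by aggregating; the group shows
two emergent properties — a *phase transition* into huddling as the
ambient temperature falls below a critical value, and a continuous *pup
flow* in which cool peripheral pups displace warm central ones.
`huddlesim` reproduces these from purely local interactions: each pup is
a circular thermotaxic agent (a Braitenberg vehicle) that senses
temperature only at its body surface, exchanges heat only through
contact, and generates heat at a constant rate.

## Model

Pup *i* carries n surface thermometers; the exposed ones read the ambient
temperature T_a, contacted ones the body temperature of the touching
littermate.  The mean readings of the left/right body halves, T_L and
T_R, drive contralateral motors M_L = F(T_R)/(F(T_L)+F(T_R)),
M_R = 1 − M_L, giving rotation dθ/dt = arctan(v1(M_R − M_L)) toward the
side with the stronger contralateral drive, plus constant forward speed
v2, an arena-boundary spring, and pairwise overlap springs.  The body
temperature follows

    dT_b/dt = −k1 η (T_b − T_a) − k2 (1 − η)(T_b − T_c) + G ,

with η the exposed surface fraction, T_c the mean contact temperature,
k1/k2 thermal conductances and G the (brown-adipose-tissue) thermogenesis
rate.  Three variants: **endothermic** (T_b clamped at 37 °C),
**ectothermic** (identity transfer F(T) = T), and **homeothermotaxic**
(F a sigmoid gated by T_p − T_b, so pups seek heat only when colder than
the preferred temperature T_p = 37 °C).

The closed-form *super-organism* companion model treats the litter as one
body that adapts its total exposed area A(T_a) = clamp(G/(k1(T_p − T_a)),
A_min, A_max) to hold its temperature at T_p, predicting a
thermoregulatory plateau of width (G/k1)(1/A_min − 1/A_max) — the
package's central testable prediction: raising G (or lowering k1) widens
the range of ambient temperatures over which huddling regulates body
temperature.

See `docs/methods.md` for the full equations, parameter table, numerical
choices, and a frank account of which published group-level statistics
this implementation does and does not recover.

## Worked example

Simulate a homeothermotaxic litter of 12 pups at T_a = 5 °C (2000 steps,
200 thermometers for speed):

```sh
huddlesim run --variant homeothermotaxic --ta 5 --steps 2000 \
    --thermometers 200 --seed 7 --out demo/
```

prints

```json
{
  "huddling": 0.648880625,
  "mean_body_temperature": 24.884201237722994,
  "pup_flow": 0.04377605469401369,
  "mean_subgroups": 1.0,
  "mean_largest_aggregate": 12.0,
  "max_aggregate_size": 12
}
```

— at this cold ambient the litter holds a single macro-huddle
(`mean_subgroups` 1.0, all 12 pups in one contact component) with about
65 % of the body surface in contact (`huddling` = mean of 1 − η), and
collective heat retention keeps the litter ≈20 °C above ambient.
`demo/` receives the full trajectory (CSV + JSON sidecar), the metric
summary and a reproducibility manifest.  The same run is two lines of
Python:

```python
import huddlesim as hs
cfg = hs.SimConfig(variant="homeothermotaxic", steps=2000, n_thermometers=200)
cfg.thermal.ambient = 5.0
result = hs.run_simulation(cfg, seed=7)
print(result.summary)
```

Other subcommands: `huddlesim sweep` (parameter grids with seeded
replicates), `huddlesim metrics <trajectory.csv>` (recompute group
metrics from a stored run), `huddlesim superorg` (analytic curves),
`huddlesim fixtures` (named deterministic configurations).

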