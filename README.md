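# ciconia

A biologging analysis pipeline for **partial migration** in white storks
(*Ciconia ciconia*): within one breeding population, some adults are
year-round residents while others migrate to Africa for the winter. The
package turns raw GPS/accelerometer tag output into the quantities such a
study runs on — per-burst energetics and behavior, annual migratory
strategies and seasonal phenology, breeding-return dates, and annual
survival estimated jointly with tag failure — and ships a synthetic-data
generator so the whole chain is testable without field data.

It is aimed at movement ecologists working with Movebank-style GPS/ACC
exports and at quantitative ecologists who need a transparent, scriptable
implementation of the multievent capture–recapture survival model.

## What it computes

**ODBA (overall dynamic body acceleration).** For a tri-axial burst
*a<sub>x</sub>, a<sub>y</sub>, a<sub>z</sub>* (in g), the static component
of each axis is removed with a centered 4-s running mean and

> ODBA = mean<sub>t</sub> Σ<sub>axis</sub> | a(t) − smooth(a)(t) |,

a standard proxy for locomotion energy expenditure. A random-forest
classifier over burst features (axis moments, ODBA, dynamic ranges, axis
correlations, heave spectrum) assigns each burst one of four behaviors:
foraging, resting, soaring, flapping.

**Migration phenology and strategy.** Daily roosts are median nocturnal
(22:00–04:00 local solar time) positions. A migration is a run of ≥ 3
consecutive days each moving > 60 km roost-to-roost. Birds are classified
as `local` (always < 50 km from the nest), `regional` (farther, but never
south of the Gibraltar line, 35.9° N), `nw_africa` (south of Gibraltar,
wintering north of the Sahara line, 20° N) or `sub_saharan` (wintering in
the Sahel). Each annual cycle (4 Aug – 3 Aug) is partitioned into autumn /
wintering / spring / breeding, using the detected migration windows for
migrants and fixed calendar dates for residents. Nest occupation is the
first day of the first run of three consecutive days with a fix within
75 m of the nest.

**Survival with tag loss.** Annual resighting data are coded as events
0 (not seen), 1 (active GPS), 2 (alive, ring read, no GPS), 3 (recovered
dead) and modeled as a hidden Markov chain over states Aa (alive, tag
active), Ai (alive, tag inactive), Ra (recently dead, tag active), LD
(long dead), with survival φ, signal-loss probability λ, and
group-specific resighting p<sub>Ai</sub>. Release state, active-tag
detection and dead recovery are certain by design (τ<sub>Aa</sub> = p<sub>Aa</sub> = r = 1).
Models are fitted by maximum likelihood (forward algorithm, logit scale,
multi-start) and compared with QAICc using an externally supplied
overdispersion coefficient ĉ.

## Worked example

```python
from ciconia.synthetic import SimConfig, simulate_track, simulate_encounter_histories
from ciconia.trajectory import (classify_strategy, daily_roosts,
                                detect_migration_windows, partition_seasons)
from ciconia.multievent import MultieventParams, ModelSpec, fit, compare

cfg = SimConfig()
fixes, truth = simulate_track("sub_saharan", 2018, cfg, seed=1)
label = classify_strategy(fixes, truth.nest, cfg.geography)
windows = detect_migration_windows(daily_roosts(fixes), cfg.geography)
print(f"strategy: {label}   (truth: {truth.strategy})")
print(f"autumn migration: {windows.autumn[0]} to {windows.autumn[1]}")

params = MultieventParams(phi=0.91, lam=0.3,
                          p_ai={"resident": 0.63, "migrant": 0.14})
histories, _ = simulate_encounter_histories(params, n=500, occasions=6, seed=11)
null = fit(histories, ModelSpec(name="phi(.)", phi_by="constant", c_hat=2.52, seed=1))
full = fit(histories, ModelSpec(name="phi(strategy)", phi_by="resident_migrant",
                                c_hat=2.52, seed=1))
print(null.estimates.round(3).to_string(index=False))
print(compare([null, full]).round(2).to_string(index=False))
```

prints

```
strategy: sub_saharan   (truth: sub_saharan)
autumn migration: 2018-08-15 to 2018-08-27
     parameter  estimate  se_logit  ci_low  ci_high
      phi[all]     0.922     0.095   0.907    0.934
        lambda     0.301     0.064   0.275    0.328
 p_Ai[migrant]     0.156     0.174   0.116    0.207
p_Ai[resident]     0.622     0.079   0.585    0.657
        model  k   loglik  deviance  c_hat   qaicc  delta_qaicc
       phi(.)  4 -1832.45   3664.90   2.52 1462.41         0.00
phi(strategy)  5 -1831.96   3663.91   2.52 1464.06         1.65
```

The fit recovers the generating values (φ = 0.91, λ = 0.30, resident and
migrant resighting 0.63 / 0.14) within sampling error, and QAICc prefers
the model without a survival–strategy effect on data generated without
one (Δ = 1.65 here).

The same chain is available from a shell via the `ciconia` command:
`simulate → odba → classify → segment → summarize → survival`, with
Movebank-dialect CSV in between (`ciconia --help`).

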