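# coroost

Multiyear co-roosting social-network analysis for bat maternity colonies.

Temperate bat maternity groups are fission–fusion societies: females split
and merge across day roosts daily, disperse to hibernate each fall, and
reassemble each spring. Whether the same pairs keep roosting together year
after year could reflect *persistent social preference* — or merely shared
*roost fidelity*, since two bats that both favour the same box will meet
there without caring about each other. `coroost` implements the full
analytical chain used to separate those explanations from PIT-tag detection
streams at monitored roost boxes, together with an agent-based colony
simulator with known ground truth so every stage can be verified without
field data.

## The analysis

**Day-roost assignment.** A bat's day roost for a date is the roost of its
last antenna detection strictly before that date's sunset. Agreement with
the last detection before the same morning's sunrise quantifies assignment
reliability. Analyses keep adult females with ≥ 10 assigned days between
28 April and a per-year parturition cutoff.

**Association networks.** Under the gambit of the group, bats in the same
roost on the same day associate pairwise. Per dyad and year the Simple
Ratio Index is

    SRI = x / (x + y_AB + y_A + y_B)

with `x` days together, `y_AB` days both seen apart, `y_A`/`y_B` days only
one seen.

**Lagged association rate.** `g(τ)` estimates the probability that a pair
associated on day `t` is associated on day `t + τ`, compared with the null
level (mean number of associates per bat) / (N − 1).

**Roost-fidelity control.** From each bat's roost-use profile `p_i`
(fraction of assigned days per box), the no-social co-roosting probability
is `P_ij = Σ_k p_ik p_jk` — exactly the dyadic co-occurrence that individual
preferences alone would generate.

**Matrix inference.** Mantel tests (node-permutation null) correlate SRI
matrices across year pairs; MRQAP with Dekker's double semi-partialling
regresses the focal year's SRI matrix on the previous year's SRI matrix and
the focal year's co-occurrence matrix. All matrices are standardized, so
coefficients are scaled effect sizes, and their ratio (co-occurrence ÷
previous-year) is the fold difference between fidelity and social memory.

**Individual metrics.** Degree, betweenness centrality and the coefficient
of variation of SRI per known-aged bat, regressed on exact age; and a
paired within- vs among-cohort comparison of association strengths.

## Worked example

```python
import numpy as np
from coroost import (
    assign_day_roosts, qc_sunrise_agreement, yearly_networks,
    align_years, mantel_test, mrqap_dsp, fold_difference,
    roost_use_profiles, cooccurrence_probability, filter_individuals,
)
from coroost.inference import PREV_ASSOCIATION, COOCCURRENCE
from coroost.simulate import ColonyConfig, simulate_colony

colony = simulate_colony(ColonyConfig(n_years=3, seed=11))
day_roosts = assign_day_roosts(colony.detections, colony.sun)
agreement, _ = qc_sunrise_agreement(colony.detections, day_roosts, colony.sun)
print(f"sunrise/sunset agreement: {agreement:.1%}")

networks = yearly_networks(day_roosts, colony.roster, colony.windows)
y1, y2, y3 = sorted(networks)
m1, m2, _ = align_years(networks[y2], networks[y3])
res = mantel_test(m1, m2, n_perm=999, rng=np.random.default_rng(0))
print(f"Mantel R {y2}-{y3}: {res.r:.2f} (p = {res.p_two_tailed:.3f})")

focal, comp, shared = align_years(networks[y3], networks[y2])
filt = filter_individuals(day_roosts, colony.roster, colony.windows[y3])
cooc = cooccurrence_probability(roost_use_profiles(filt, colony.windows[y3]))
fit = mrqap_dsp(focal, {PREV_ASSOCIATION: comp, COOCCURRENCE: cooc.subset(shared)},
                n_perm=999, rng=np.random.default_rng(1))
print(f"previous-year effect: {fit.coefficients[PREV_ASSOCIATION]:.3f} "
      f"(p = {fit.p_two_tailed[PREV_ASSOCIATION]:.3f})")
print(f"co-occurrence effect: {fit.coefficients[COOCCURRENCE]:.3f} "
      f"(p = {fit.p_two_tailed[COOCCURRENCE]:.3f})")
print(f"R^2 = {fit.r_squared:.3f}, fold difference = {fold_difference(fit):.1f}")
```

Output:

```
sunrise/sunset agreement: 97.0%
Mantel R 2016-2017: 0.52 (p = 0.001)
previous-year effect: 0.176 (p = 0.001)
co-occurrence effect: 0.603 (p = 0.001)
R^2 = 0.517, fold difference = 3.4
```

The colony was simulated with persistent dyadic affinity *and* individual
roost preferences. The fit recovers the planted structure: roost fidelity
(co-occurrence, 0.603) explains most of the year-to-year consistency, yet
last year's associations still predict this year's (0.176, p = 0.001) even
after the fidelity control — persistent social preference beyond shared
roost use.

## Command line

```bash
coroost simulate --out sim/ --seed 1      # detections + roster + truth
coroost assign-roosts sim/detections.csv --out sim/day_roosts.csv
coroost run-all config.yaml               # full pipeline from one config
coroost figures config.yaml               # regenerate figure panels
```

Subcommands `networks`, `lar`, `mantel`, `mrqap`, `metrics`, `cohort` run
individual stages on CSV/YAML inputs.

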