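# rapskill

Statistical analysis of **spatial skill in hermit-crab shell fights**.

During a shell fight the attacker repeatedly strikes ("raps") its shell
against the defender's; each rap can leave a countable mark — a point of
impact (POI) — on the defender's shell.  Contest research has long
focused on *vigour* (how often an attacker raps).  This package
implements the complementary question: does it matter *where* the
strikes land?  Spatial skill is split into

- **accuracy** — how close the average strike position is to a target
  (coarse scale: the proportion of POIs inside a target zone of the
  body whorl; fine scale: mean distance to a shell landmark), and
- **precision** — how tightly strikes cluster (the residual spread of
  POI positions).

It is written for behavioural ecologists and biostatisticians who want
to run, extend or stress-test this analysis: every stage works on plain
CSV tables, and a calibrated synthetic-data generator with full ground
truth makes each stage verifiable by simulation.

## What it computes

**Coarse scale.** With per-fight zone proportions `pz1`, `pz2` and
relative weight difference `RWD = 1 − defender weight / attacker weight`,
a binomial GLM (logit link, fitted by IRLS)

```
logit P(eviction) = b0 + b1·pz1 + b2·pz2 + b3·pz1·pz2 + b4·RWD
```

with per-term likelihood-ratio χ² tests, plus tie-corrected Kendall
tau-b correlations between spatial (`pz1`, `pz2`) and temporal
(total raps, mean raps per bout) performance — each run with and
without Tukey-fence outliers.

**Fine scale.** A double-hierarchical Gaussian model (DHGLM) for the
cube-root-scaled distance y_ij of POI j (individual i) to a shell
landmark (A: apex; B: outer lip / body whorl junction):

```
y_ij = β0 + β'x_i + a_i + e_ij,    e_ij ~ N(0, σ_ij²)
log σ_ij = δ0 + γ'x_i + b_i
a_i ~ N(0, σ_a²),   b_i ~ N(0, σ_b²)
```

with fixed effects x_i = (RWD, outcome, vigour) in both submodels.  The
mean submodel is accuracy, the log-SD submodel precision.  Fitting is a
self-contained Metropolis-within-Gibbs sampler (exact Gibbs updates for
the conditionally Gaussian mean-model block, adaptive random-walk
Metropolis elsewhere); inference uses 95% credible intervals, pseudo-P
values (twice the smaller posterior tail mass at zero, floored at 2/N),
split R-hat and effective sample size.  The model is fitted four ways:
distance to A and to B, over the whole shell and restricted to zone-1
POIs.

## Worked example

```
$ python examples/02_coarse_scale_analysis.py
fights analysed: 94 (0 outlier-flagged, removed here)

GLM of eviction, per-term likelihood-ratio tests:
  prop_zone1               chi2(1) =  0.656   p = 0.418
  prop_zone2               chi2(1) =  2.332   p = 0.127
  prop_zone1:prop_zone2    chi2(1) =  3.006   p = 0.083
  rwd                      chi2(1) =  1.403   p = 0.236

Kendall tau-b, spatial vs temporal performance:
  prop_zone1~total_raps              tau = +0.246   p = 0.000
  prop_zone1~mean_raps_per_bout      tau = +0.312   p = 0.000
  prop_zone2~total_raps              tau = -0.221   p = 0.002
  prop_zone2~mean_raps_per_bout      tau = -0.284   p = 0.000
```

The positive zone-1 and negative zone-2 correlations say that attackers
who concentrate strikes on the target zone also rap more vigorously —
skill and vigour travel together.  The fine-scale run on the same
synthetic dataset (`examples/03_fine_scale_dhglm.py`) prints the
Table-style posterior summary; e.g. `mean.vigour  -0.183  [-0.252,
-0.113]  P 0.000` — more vigorous attackers strike closer to landmark B
— and `sd.outcome  -0.223  [-0.386, -0.063]  P 0.007` — evicting
attackers strike more precisely, matching this dataset's generating
values (−0.15 and −0.3).

`examples/01_simulate_dataset.py` generates data and
`examples/04_parameter_recovery.py` runs a small recovery study.  The
same functionality is available from the shell:

```
rapskill simulate --seed 42 --out data/
rapskill analyze --fights data/fights.csv --pois data/pois.csv --out run/
rapskill recover --n-reps 20 --seed 1 --out rec/
```

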