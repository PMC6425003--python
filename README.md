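# fstatkit

**f-statistics, qpAdm-style admixture modeling, and admixture-graph
simulation for low-coverage ancient DNA.**

`fstatkit` reimplements, as a tested Python library, the statistical stack
behind a classic ancient-DNA study design: a temporal transect of
low-coverage pseudo-haploid genomes (hunter-gatherers and early farmers) set
against modern reference panels, analyzed with allele-sharing statistics and
admixture-proportion models. It is aimed at population geneticists who want
the machinery of the ADMIXTOOLS ecosystem — D/f-statistics with block
jackknife, qpWave/qpAdm — in an importable, simulable, unit-tested form.

## What it computes

* **Patterson's D and f2/f3/f4 statistics** from EIGENSTRAT genotype data,
  with per-statistic complete-case site selection and SEs from a weighted
  delete-one-block jackknife (blocks of 0.05 morgans, 5 Mb physical
  fallback). Per-site terms for `D(W, X; Y, Z)` with population frequencies
  *w, x, y, z*:

      num = (w − x)(y − z),   den = (w + x − 2wx)(y + z − 2yz),   D = Σnum / Σden

  `D > 0` means the test population *Y* shares excess alleles with *W*.
* **Individual-permutation tests**: exhaustive leave-one rotation of a small
  cohort against an anchor individual, and random re-splits of two pooled
  cohorts, with the empirical P inclusive of the identity grouping
  (1000 permutations → denominator 1001; P is never 0).
* **qpWave rank tests and qpAdm fits**: the f4 matrix between left
  populations (target first) and right outgroups, its jackknife covariance,
  rank-r alternating-GLS factorization with a chi-square fit test, mixture
  weights from the left null vector, weight SEs by delete-one-block
  re-estimation, and feasibility flags for weights outside [0, 1].
* **Basal Eurasian α**: a two-source fit of a target against a deep African
  proxy plus a non-basal source, with crown-Eurasian outgroups; the proxy's
  weight reads as the basal proportion. A composed prediction
  `α_pred = p · α_source` with delta-method SE links two fits.
* **PCA with least-squares projection** of missing-data samples onto
  components built from complete modern panels (smartpca normalization).
* **A synthetic-data generator**: allele frequencies evolving on an
  admixture graph under Balding–Nichols drift, pseudo-haploid sampling, and
  coverage-driven missingness `P(missing) = exp(−coverage)`, with four
  registered scenarios whose true mixing proportions are set to the
  published estimates they emulate (89.7/10.3, 78.7/21.3, 25.8/62.9/11.3,
  and basal α of 24.8% and 38.5%).

## Worked example

```python
import fstatkit as fk

scen = fk.study_scenario("aaf_two_way", n_snps=100_000, seed=11)
ds = fk.simulate_dataset(scen.graph, scen.config)   # 46 individuals, EIGENSTRAT-able
blocks = fk.assign_blocks(ds)

print(fk.d_statistic(ds, "AAF", "AHG", "CHG", "Mbuti", blocks))

m = scen.models[0]
fit = fk.qpadm_fit(ds, m.target, m.sources, m.outgroups, blocks)
for s, w, se in zip(fit.sources, fit.weights, fit.weight_se):
    print(f"{s}: {w:.3f} +/- {se:.3f}")
print(f"fit p = {fit.p_value:.3f}, feasible = {fit.feasible}")
```

prints (seed 11):

```
<D(AAF, AHG, CHG, Mbuti) = 0.00846909 +/- 0.00461 (Z = 1.84, 93537 SNPs, 572 blocks)>
AHG: 0.924 +/- 0.041
Iran_N: 0.076 +/- 0.041
fit p = 0.621, feasible = True
```

The farmer cohort (AAF) shows a marginal excess of allele sharing with the
Caucasus lineage relative to the hunter-gatherer (Z = 1.8 — the same
marginal-signal regime as the contrasts this emulates), and the two-way
qpAdm fit attributes 92 ± 4% of its ancestry to the local hunter-gatherer
lineage — within 1 SE of the configured truth of 89.7% — with an adequate
model fit (χ² p = 0.62).

The `analysis/` directory holds numbered drivers that walk the full ledger
on simulated cohorts (simulation → QC → D-statistics → permutations → qpAdm
models → basal α and the composed prediction → PCA), writing tables under
`results/`. A `fstatkit` CLI with the same stages is installed as a console
script; `fstatkit run --config cfg.yaml --out results/run` executes a
configured pipeline deterministically (same config + seed → byte-identical
tables).

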