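# embryoquant

Spike-in calibrated **absolute transcript quantification** and
maternal-to-zygotic transition (MZT) analysis for embryo RNA-seq time
courses.

Relative RNA-seq normalisation breaks down in early embryos: the global
poly(A) pool collapses and rebounds within hours, so "fraction of reads" and
"molecules per embryo" tell different stories. When a known amount of
synthetic spike-in RNA (e.g. the 92-species ERCC mix) is added per embryo
before library prep, read counts can be calibrated back to absolute
transcript copies per embryo. This package implements that calibration and
the downstream analyses a developmental time course needs: detection limits,
mRNA mass per embryo, temporal classification of genes (maternal-down /
persistent / transient / zygotic), identification of zygotic-early genes,
intron-signal and gene-architecture corroboration, and TAGteam (CAGGTAG /
CAGGTAB) promoter-motif enrichment. It is aimed at people analysing
long-read or short-read embryo time courses with per-embryo spiking, and it
ships a synthetic-data generator with full ground truth so every stage is
testable without any sequencing data.

## The model

Relative expression is RPG10K (reads per gene per 10,000 aligned reads):

    rho_ij = c_ij / N_j * 1e4

where `N_j` counts all aligned reads in sample `j`, spike-ins included. For
each sample the spike-in species `q` with known abundance `S_q` (molecules
per embryo-equivalent) and observed relative abundance `r_qj` are fitted by
an intercept-only Poisson regression with log link and offset `log S_q`:

    E[r_qj] = exp(beta_j + log S_q)

whose maximum-likelihood intercept has the closed form

    beta_j = log( sum_q r_qj / sum_q S_q ).

`exp(-beta_j)` converts one RPG10K unit into transcripts per embryo:

    m_ij = rho_ij * exp(-beta_j)

The per-sample detection limit is `threshold * exp(-beta_j)` at the RPG10K
sensitivity floor (default 0.01, about two reads at 2 million aligned
reads). Copies convert to mass via the single-stranded RNA molar mass
`MW(L) = 320.5 L + 159` g/mol, and per-embryo masses are compared across
species of different egg sizes by volume scaling (RNA content tracks cell
volume).

## Worked example

```python
from embryoquant import (AbsoluteQuantModel, SimulationConfig,
                         simulate_experiment, volume_scaled_mass)

sim = simulate_experiment(SimulationConfig(seed=1))   # 2000 genes, 92 spikes
res = AbsoluteQuantModel(sim.counts, sim.spikes, sim.models).fit()
print(res.summary())
```

prints

```
Spike-in calibrated absolute quantification
====================================================================
sample      t(h)      beta       scale     limit  detected       total
--------------------------------------------------------------------
t1h          1.0   -8.8554        7012     70.12      1719   5.834e+06
t2h          2.0   -8.8305        6840      68.4      1479   4.107e+06
t3h          3.0   -8.9137        7433     74.33      1614   1.005e+07
t4h          4.0   -8.9059        7375     73.75      1603   9.465e+06
t5h          5.0   -8.8993        7327     73.27      1576   8.981e+06
t6h          6.0   -8.8402        6906     69.06      1686   4.776e+06
--------------------------------------------------------------------
mean detection limit: 71.49 transcripts/embryo   (threshold 0.01 RPG10K)
```

Each row is one hourly sample: `beta` is the fitted conversion factor,
`scale = exp(-beta)` the transcripts per embryo represented by one RPG10K
unit, `limit` the smallest per-embryo abundance distinguishable at the
sensitivity floor, `detected` the number of genes at or above it, and
`total` the summed transcripts per embryo — which shows the 2 h dip and 3 h
rebound of the simulated maternal pool. The estimated scales agree with the
generator's true molecules-per-RPG10K ratios to within 0.1% here.

Volume-scaled mass comparison between embryos of different sizes:

```python
vs = volume_scaled_mass(1.26, source_volume_mm3=0.025, target_volume_mm3=0.268)
print(vs.volume_ratio_3sig, vs.scaled_mass_ng_3sig)   # 10.7 13.5
```

i.e. 1.26 ng of mRNA in a 0.025 mm3 embryo corresponds to 13.5 ng in a
0.268 mm3 embryo (volume ratio 10.7).

A command-line interface mirrors the library:
`embryoquant simulate | quantify | absnorm | classify | zygotic | motif |
report` (see `embryoquant --help`); all outputs are TSV with commented
headers, logs go to stderr.

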