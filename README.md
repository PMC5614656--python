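# splicestat

Stochastic modelling of alternative-splicing isoform usage.

Most eukaryotic genes produce several mature transcript isoforms, and
which isoform dominates matters for cell identity and disease.
`splicestat` implements a stochastic model of this process: treating
intron recognition as a minimization search by the splicing machinery,
the expression levels of a gene's isoforms behave like draws from a
Weibull (type III extreme-value) distribution

    W(x; a, b) = (a/b) (x/b)^(a-1) exp(-(x/b)^a)

with a *universal* shape `a` and a gene-specific scale `b`.  The
remarkable consequence is that the whole frequency spectrum of isoform
usage — how often the top isoform holds 80 % of a gene's output, how the
median frequency `mf(k, M)` of the k-th ranked isoform falls with the
annotated isoform count M, how many isoforms are detectably expressed —
follows from a single number, the shape `a ≈ 0.39`, which is also the
root of the fixed point `1 + 1/a = Γ(1 + 1/a)`.

The package is aimed at transcriptomics analysts who want to

- fit the shape parameter to their own Cufflinks/Cuffdiff or Salmon
  quantifications by Monte-Carlo grid search on the median-frequency
  matrix;
- call *significantly dominant* isoforms with M-specific frequency
  thresholds (the 95th percentile of pooled simulated frequencies);
- detect genes that switch their dominant isoform between conditions;
- benchmark quantification pipelines with simulated paired-end RNA-seq
  whose ground truth follows the model (or a Normal negative control).

## Worked example

```python
from splicestat import weibull_model as wm
from splicestat import monte_carlo as mc
from splicestat.monte_carlo import SimulationConfig

print(f"canonical shape a* = {wm.canonical_shape():.4f}")

cfg = SimulationConfig(a=0.39, reps=100_000, seed=7)
table = mc.dominance_threshold_table([2, 5, 10, 20, 30], 0.05, cfg)
print(table.to_string(index=False))

p, se = mc.probability_rank_exceeds(1, 2, 0.8, cfg)
print(f"P(f(1,2) >= 0.8) = {p:.3f} +/- {se:.3f}")
```

prints

```
canonical shape a* = 0.3903
 M  alpha  threshold
 2   0.05   0.999476
 5   0.05   0.850658
10   0.05   0.529766
20   0.05   0.268193
30   0.05   0.174876
P(f(1,2) >= 0.8) = 0.736 +/- 0.001
```

Read: the fixed-point root is 0.39 at two decimals.  An isoform of a
10-isoform gene is significantly dominant (5 % level) once its frequency
exceeds ~0.53; for a 30-isoform gene ~0.17 suffices.  And for any two
isoforms of the same gene, the dominant one carries at least 80 % of
their joint expression about 74 % of the time — matching the analytic
tail `2/(1 + 4^0.39)` and explaining why one of two antagonistic
isoforms is almost always decisively dominant.

The same analyses run from the shell:

```
splicestat simulate-expression --n-genes 3000 --law weibull:0.39,10 --seed 3 --out run/sim
splicestat profiles --table run/sim/quant.sf --dialect salmon --t2g run/sim/t2g.tsv --out run/prof
splicestat median-matrix --profiles run/prof/profiles.tsv --out run/mat
splicestat fit-shape --matrix run/mat/median_matrix.csv --seed 3 --out run/fit
splicestat thresholds --a 0.39 --m 2,5,10,20,30 --reps 100000 --seed 7 --out run/thr
```

Each subcommand writes a `manifest.json` (parameters, seed, version)
from which the run can be reproduced byte for byte.

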