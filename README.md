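# paradiverge

Analysis of **paralogous gene pairs** under multiple stresses: how does the
divergence of a duplicated gene pair's *expression* relate to the divergence
of its *coding sequence*, and do pairs with different stress-response
patterns sit under different selection pressure?

The package is aimed at plant molecular-evolution and stress-transcriptomics
work where the inputs are codon-aligned paralog CDS pairs, an FPKM-like
expression matrix over a stress × time-course design (four stresses — drought
`Dr`, cold `Cd`, *Botrytis cinerea* infection `Bc`, *Pieris rapae* herbivory
`Pr` — with three time points each), and a per-gene differential-expression
table.

## What it computes

* **Pattern classes.** A pair is **FF** under a condition when both genes are
  differentially expressed (padj < 0.05 and |log2FC| > 1), **FP** when exactly
  one is, **PP** when neither is. Pairs are grouped into seven stress-sharing
  clusters (all four stresses; abiotic `Dr`+`Cd`; biotic `Bc`+`Pr`; one
  specific stress; plus an explicit "other") and, across each stress's three
  time points, labelled **enhancing** (PP→FP→FF), **decreasing** (FF→FP→PP),
  stable or mixed.
* **Sequence divergence.** Per-pair *Ka* (nonsynonymous substitutions per
  nonsynonymous site) and *Ks* (synonymous per synonymous site) by the
  Nei–Gojobori (1986) counting method — fractional site counting, pathway-
  averaged difference counting with stop-codon pathways excluded, and the
  Jukes–Cantor correction d = −¾ ln(1 − 4p/3). Ka/Ks > 1 is read as positive
  selection, < 1 as purifying selection.
* **Expression divergence vs Ks.** The within-pair Pearson correlation *r*
  of log expression is rescaled to r′ = ln(1 + r)/(1 − r) and regressed on
  Ks (OLS); a negative slope means expression divergence grows with sequence
  divergence. A Fisher-transform variant of r′ is selectable.
* **Randomized-pair null.** Whether a class's median Ka/Ks is extreme is
  judged against 10,000 resampled equal-size sets of pairs, with the
  add-one empirical p = (#{null as-or-more extreme} + 1)/(n + 1).
* **Co-expression network.** Soft-thresholded adjacency |r|^10 between DE
  paralogs and transcription factors, pruned at edge weight ≥ 0.3 and node
  max-|r| ≥ 0.5, with TF families ranked by DE-paralog neighbours.
* **Synthetic data.** A first-class simulator provides ground truth for all
  of the above: codon evolution at a chosen ω and target Ks, expression pairs
  coupled as ρ = exp(−λ·Ks), and DE tables with plantable trajectories.

## Worked example

```python
from paradiverge import ParalogDivergenceModel, SimulationConfig

config = SimulationConfig(n_pairs=150, omega=0.5, coupling_lambda=1.0,
                          de_fraction=0.3, enhancing_fraction=0.05,
                          decreasing_fraction=0.05, seed=7)
model = ParalogDivergenceModel.from_simulation(config)
results = model.fit(seed=7, n_reps=1000)
print(results.summary())
```

prints (abridged):

```
pairs analysed: 150

Pattern counts (per stress, analysis time point):
stress  time_index  FF  FP  PP
    Bc           3  17  55  78
    Cd           3  19  57  74
    Dr           3  15  54  81
    Pr           3  20  66  64

r' vs Ks regressions:
  FF: slope=-1.9483  p=4.53e-05  r^2=0.251  n=60
  FP: slope=-1.7236  p=2.53e-09  r^2=0.248  n=127

Permutation tests (median Ka/Ks vs randomized pairs, 1000 reps):
  FF under Cd: observed=0.4068  tail=less  p=0.048
  ...
Ks distribution: modal bin midpoint 0.75, P(Ks > 1) = 0.521 (n=140)
```

Reading the output: with every simulated pair evolved under purifying
selection (ω = 0.5) and expression coupling λ = 1, both pattern classes show
the expected significantly negative r′-vs-Ks slope — pairs that diverged
longer ago in sequence are also less correlated in expression. The
permutation p-values are unremarkable because here FF/FP membership is
independent of ω by construction.

The same pipeline runs from files:

```bash
paradiverge kaks --pairs pairs.fasta --out kaks.tsv
paradiverge run  --config demo.json --seed 1 --out results/
```

`run` writes `kaks.tsv`, `patterns.tsv`, `clusters.tsv`, `trajectories.tsv`,
`regression.json`, `permutation.json`, `network.tsv` and `summary.json`.

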