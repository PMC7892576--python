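# mixclust

Clinical and biological tables routinely mix continuous measurements
(age, ejection fraction, creatinine) with categorical ones (NYHA class,
diabetes status).  Choosing an unsupervised method for such *mixed* data is
not obvious: distance-based algorithms need a dissimilarity that blends the
two variable types, while model-based algorithms need a joint probability
model.  `mixclust` is a simulation benchmark that puts nine ready-to-use
strategies head to head on labelled synthetic mixed data and scores each
recovered partition with the adjusted Rand index (ARI).

It is aimed at applied statisticians and methods researchers who want a
controlled, reproducible way to compare mixed-data clustering algorithms —
or to drop a new algorithm into an existing harness.

## What is implemented

**Simulator.** Each dataset has a known partition into G clusters.
Continuous variables are spherical unit-variance Gaussians whose centres
lie on a randomly oriented line, spaced so that nearest-neighbour clusters
attain a target quantile *separation index*
J ∈ ]−2, +2[ (spacing δ = 2·z₀.₉₇₅·(1+J)/(1−J); J = −0.3, 0, 0.3 encode
low/mild/high relevance).  Categorical variables carry one level per
cluster, then a fraction ν of values (ν = 0.95, 0.85, 0.75 for
low/mild/high relevance) is resampled uniformly over the G levels.
Irrelevant padding variables of either type can be added, and continuous
columns are standardised before clustering.  Seven scenario presets sweep
population size, cluster count, variable counts, relevance proportions and
relevance degrees around the baseline N=300, G=6, 4+4 variables, all mild.

**Nine clustering strategies**, all given the true G:

| name | family | pipeline |
|---|---|---|
| `gower_pam` | distance | Gower dissimilarity (1 − S, Hamming on categoricals) → PAM (BUILD+SWAP on total deviation) |
| `gower_hc` | distance | Gower → Ward ascendant hierarchical clustering (Lance–Williams update, ward.D2 convention) |
| `uet_pam` | distance | unsupervised extra-trees dissimilarity √(1−S) → PAM |
| `uet_hc` | distance | extra-trees dissimilarity → Ward HC |
| `kproto` | distance | k-prototypes: d₂ = Σ(xⱼ−yⱼ)² + γΣδ(xⱼ,yⱼ), means/modes prototypes, auto γ |
| `kamila` | model | KDE of minimal centroid distances (radially corrected) + multinomial log-probabilities |
| `mixmod` | model | diagonal Gaussian × multinomial mixture, EM, single run of ≤200 iterations |
| `lcm` | model | same mixture, multi-start small EM, tolerance-driven stop |
| `lca` | model | tertile-discretise continuous, multinomial mixture EM (1e−10 stop) |

**Evaluation.**  Hubert–Arabie ARI from the contingency table,
(Σᵢⱼ C(nᵢⱼ,2) − E)/(max − E), and a replicated benchmark harness with
per-(scenario, replicate, method) child seed streams, failure capture, and
classical summary statistics.

## Worked example

```python
import numpy as np
import mixclust as mc

spec = mc.ScenarioSpec()                 # N=300, G=6, 4+4 variables, mild relevance
ds = mc.generate_scenario(spec, np.random.default_rng(0))

shared = {}
for name in mc.METHODS:
    part = mc.run_method(name, ds, 6, np.random.default_rng(1), shared)
    print(f"{name:10s} ARI = {mc.adjusted_rand_index(part.labels, ds.true_labels):.3f}")
```

prints (dissimilarity matrices are computed once and shared):

```
gower_pam  ARI = 0.160
gower_hc   ARI = 0.167
uet_pam    ARI = 0.295
uet_hc     ARI = 0.373
kproto     ARI = 0.325
kamila     ARI = 0.397
mixmod     ARI = 0.611
lcm        ARI = 0.898
lca        ARI = 0.399
```

On this mildly relevant baseline draw the mixture-model strategies recover
the hidden 6-cluster structure far better than Gower-based PAM/HC — the
benchmark's central finding once replicated over many datasets.

The same pipeline is available from a shell:

```bash
mixclust simulate --scenario 1 --seed 3 --out data.csv
mixclust dissim --data data.csv --manifest data.manifest.json --method gower --out d.csv
mixclust cluster --method pam --k 6 --dissim d.csv --out labels.csv
mixclust benchmark --scenario 4 --reps 50 --seed 1 --out results.csv
mixclust summarize --results results.csv --out summary.csv --plot boxes.png
```

The `analysis/` scripts run the study end to end: `01_simulate.py` writes
one example dataset per scenario condition and checks generator
calibration, `02_benchmark.py` runs the replicated sweeps, and
`03_summarize.py` writes summary tables and boxplots under `results/`.

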