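# gdrn — diffusion-model reconstruction of functional brain networks

`gdrn` identifies the brain connections and regions whose functional
coupling differs between exposure groups — the motivating setting is a rat
nicotine-addiction study with a saline control, a low-concentration and a
high-concentration nicotine group.  Each subject's regional fMRI time
series are turned into a Pearson functional-connectivity (FC) matrix; a
denoising diffusion probabilistic model (DDPM) is trained per group on the
vectorized matrices; subjects are classified by how well each group's model
reconstructs them; and ranked edge/region difference tables are produced
from the group networks.  It is aimed at researchers who have region-level
time series (or precomputed connectivity matrices) and want a generative,
reconstruction-based alternative to mass-univariate edge statistics.

## Model

For a subject with time series $X \in \mathbb{R}^{T_{\mathrm{scan}} \times n}$
over $n$ atlas regions, the brain network is the Pearson matrix
$R_{ij} = \mathrm{corr}(X_{\cdot i}, X_{\cdot j})$.  Its strictly upper
triangle, after a Fisher z-transform $z = \operatorname{atanh} r$, is the
modelling vector $x_0 \in \mathbb{R}^{n(n-1)/2}$.

The per-group generative model is a standard DDPM with
$\alpha_t = 1-\beta_t$, $\bar\alpha_t = \prod_{s\le t}\alpha_s$:

* forward marginal   $q(x_t \mid x_0) = \mathcal N\!\big(\sqrt{\bar\alpha_t}\,x_0,\ (1-\bar\alpha_t)I\big)$,
  i.e. $x_t = \sqrt{\bar\alpha_t}\,x_0 + \sqrt{1-\bar\alpha_t}\,\epsilon$;
* reverse kernel   $p_\theta(x_{t-1} \mid x_t) = \mathcal N\!\big(\mu_\theta(x_t,t),\ \beta_t I\big)$ with
  $\mu_\theta = \tfrac{1}{\sqrt{\alpha_t}}\big(x_t - \tfrac{\beta_t}{\sqrt{1-\bar\alpha_t}}\,\epsilon_\theta(x_t,t)\big)$;
* training loss   $L = \mathbb E_{t,x_0,\epsilon}\,\lVert \epsilon - \epsilon_\theta(x_t,t)\rVert^2$.

$\epsilon_\theta$ is a small fully connected residual network with a
sinusoidal time embedding, implemented in numpy.  Classification noises a
subject's network forward to an intermediate step $t_{\mathrm{noise}}$,
denoises it back, and assigns the subject to the group whose model yields
the smallest mean squared reconstruction error.  Detection averages each
group's networks on the Fisher-z scale, scores every edge by the absolute
group-mean difference $|A_{ij}-B_{ij}|$, scores each region by the sum of
its incident edge scores, and reports the top 20 edges and top 15 regions
per pairwise comparison (high vs saline, low vs saline, high vs low).

Because the original rat data are not public, the package ships a
first-class synthetic cohort generator: group correlation matrices with a
known set of *planted* differential edges, subject-level jitter and
finite-scan Pearson noise, giving ground truth for recovery benchmarks.

## Worked example

```python
from gdrn import (GROUPS, GroupModelSet, SyntheticSpec, TrainConfig,
                  default_atlas, evaluate_pairwise, generate_cohort,
                  recovery_score, run_comparison, sample, train)

spec = SyntheticSpec(seed=11, n_subjects_per_group=70)   # 40 train + 30 test
_, fc, truth = generate_cohort(spec)

cfg = dict(T=200, epochs=300, batch_size=16)
models = {g: train(fc[g][:40], TrainConfig(**cfg, seed=50 + i))
          for i, g in enumerate(GROUPS)}
sched = TrainConfig(**cfg).make_schedule()

model_set = GroupModelSet(models, sched, t_noise=50, n_repeats=8, seed=23)
rep = evaluate_pairwise(model_set, fc["high"][40:] + fc["saline"][40:],
                        "high_vs_saline")
print(f"high vs saline accuracy: {rep.accuracy:.2f}")

samples = {g: sample(models[g], sched, 64, seed=17 + i)
           for i, g in enumerate(GROUPS)}
top_edges, top_regions = run_comparison(samples["high"], samples["saline"],
                                        default_atlas(10))
print(f"recovered planted edges in top-10: "
      f"{recovery_score(top_edges, truth, 10):.0%}")
print(top_edges.df.head(5))
```

Output:

```
high vs saline accuracy: 1.00
recovered planted edges in top-10: 100%
   i  j     score
0  1  7  0.551664
1  1  5  0.438341
2  0  6  0.333699
3  5  9  0.330667
4  7  8  0.324019
```

All 30 held-out high-nicotine and 30 saline subjects are assigned to the
correct group, all ten planted edges appear in the top-10 ranking computed
from networks *sampled from the trained models*, and the leading edge
scores (absolute group-mean correlation differences) are close to the
planted effect size of 0.4.

The same stages are available from the shell:

```bash
gdrn pipeline --seed 7 --out run/          # synth -> train x3 -> classify -> detect x3
gdrn synth --spec spec.yaml --out cohort/
gdrn train --group saline --data cohort/saline --out model_saline.npz
gdrn sample --ckpt model_saline.npz -n 64 --seed 7 --out samples/
gdrn detect --group-a model_high.npz --group-b model_saline.npz \
            --atlas cohort/atlas.tsv --out detect/
```

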