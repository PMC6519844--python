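# enchained

Growth–fragmentation models of secretory-IgA-enchained bacterial chains:
dominant-eigenvalue analysis, closed-form approximations, exact stochastic
simulation, and maximum-likelihood fitting of chain-length histograms.

## The problem

In the gut lumen, secretory IgA (sIgA) does not kill bacteria — it enchains
them. Because rod-shaped bacteria such as *Salmonella* divide at mid-cell,
daughters that stay cross-linked by sIgA form clonal *linear chains*, bound
pole to pole. The links break over time under flow-induced forces. When an
outermost link breaks, the single bacterium escapes; when an inner link
breaks, the two subchains usually collide laterally and become a complex
cluster that no longer releases anything. Replication (rate *r* per
bacterium) and breaking (rate *α* per link) therefore compete: fast
replicators get trapped in clusters, slow replicators dissolve back into
free bacteria. The quantity of interest is the long-time exponential growth
rate λ of the free bacteria, and the stationary distribution of chain
lengths.

The package is for quantitative microbiologists and modellers who want to
compute λ(r), locate the replication rate that maximises it, compare
stationary chain-length distributions with microscopy-derived histograms,
and estimate the single identifiable shape parameter r/α (or
r_eff/α = log 2 / (ατ) for synchronous division) from data.

## The models

Writing n_i(t) for the mean number of linear chains of length *i* (n_1 =
free bacteria), each variant is a linear system dN/dt = M N on
N = (n_1, n_2, …). For the base model

```
dn_1/dt = −r n_1 + Σ_{i≥2} 2α n_i
dn_i/dt = r(i−1) n_{i−1} − i r n_i − (i−1)α n_i + 2α n_{i+1}    (i ≥ 2)
```

λ is the dominant (Perron) eigenvalue of the truncated operator and the
associated eigenvector P, normalised to Σ p_i = 1, is the stationary
length distribution. Five variants are implemented:

| variant      | extra parameters | what changes |
|--------------|------------------|--------------|
| `base`       | —                | fixed rates r, α; inner breaks always absorbed |
| `escape`     | δ, δ′, δ″, c, c′ | escape on replication; loss of free bacteria/chains |
| `fixed_time` | τ                | synchronous division every τ; per-interval transfer matrix, N = exp(λτ) |
| `q_model`    | q                | inner-break subchains survive independently with probability q |
| `force`      | β                | per-link breaking rate α·exp(β((L/2)²−x²)/2), largest at the chain centre |

Closed forms (geometric stationary distributions, the exact q = 1
solution, the force-model shape, the sIgA-per-bacterium estimate) live in
`enchained.approx`; an exact event-driven simulator of the stochastic
rules in `enchained.simulate` provides an independent check on everything.

## Worked example

```python
import numpy as np
import enchained as en

# growth rate and stationary distribution of the base model at r = alpha
eig = en.solve_eigen(en.ModelParams("base", r=1.0, alpha=1.0))
print(eig.lambda_, eig.distribution[:4])
# 0.4374  [0.5818 0.2281 0.1011 0.0467]

# the replication rate that maximises free-bacteria growth
res = en.argmax_growth_rate("base", en.ModelParams("base"))
print(res.r_star, res.lambda_star)
# 1.093  0.439

# fit the division-to-breaking ratio to a synthetic histogram
p = en.conditional_model_distribution("fixed_time", 4.1, 2, 56, 56)
h = en.sample_histogram(p, 10_000, seed=1, lengths=np.arange(2, 57))
print(en.fit_ratio(h, "fixed_time").summary())
```

```
Chain-length distribution fit
=============================================
variant:            fixed_time
r_eff/alpha:        4.136
95% CI:             [4.049, 4.225]
log-likelihood:     -17023.669
chains used:        10000
length range:       2-24
```

At r = α roughly 58% of objects are free bacteria and the rest are
short chains; growth peaks at r* ≈ 1.09 α — replicating faster than that
*reduces* the growth of free bacteria, because chains are converted to
complex clusters faster than they shed bacteria. The fit recovers the
generating ratio 4.1 well inside its 95% profile-likelihood interval.

The same operations are available from a CLI:

```
enchained argmax --variant base
enchained simulate --variant fixed_time --tau 0.2 --seed 1 --out hist.tsv
enchained fit hist.tsv --variant fixed_time --out fit.json
enchained estimate-siga
```

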