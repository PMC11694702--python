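# phylotherm

Comparative-phylogenetics toolkit for asking how bacterial cold adaptation
evolves within a genus: do cold-adapted species (type strains with minimum
growth temperature ≤ 5 °C) accumulate gradually inside one conserved clade,
or do they pop up sporadically all over the tree?

The package is aimed at microbial comparative genomicists who already have a
rooted species tree (e.g. from single-copy core genes), per-strain growth
temperatures (e.g. from BacDive), and optionally core-protein FASTA files
and a gene-family presence/absence matrix. It provides:

* **Trait-evolution model selection.** Thirteen models of continuous-trait
  evolution for the minimum growth temperature *x* on a phylogeny, compared
  by AIC = 2k − 2 ln L. Gaussian models (Brownian motion with rate σ²,
  Ornstein–Uhlenbeck with pull α, early burst, a linear rate trend, and the
  Pagel λ/κ/δ tree transforms) are scored by REML on phylogenetic
  independent contrasts: each contrast *c* with effective time *T* contributes
  ln N(c; 0, σ²T) on the transformed tree. Lévy jump models — pure
  jump-normal (compound Poisson, ψ(k) = λ(e^{−σ_J²k²/2} − 1)),
  variance-gamma (ψ(k) = −ν⁻¹ ln(1 + σ²νk²/2)), normal-inverse-Gaussian
  (ψ(k) = −δ(√(α²+k²) − α)) and their Brownian mixtures — are scored with
  increment densities obtained by numerically inverting exp(Tψ(k)),
  treating contrasts as independent increments (the standard
  pulsed-evolution approximation).
* **Fritz–Purvis D** for the binary cold/not-cold state, with both null
  ensembles (tip shuffle → D = 1; Brownian threshold → D = 0) simulated and
  seeded, plus a Mantel-style patristic-distance vs |Δt_min| test.
* **Brownian ancestral state reconstruction** (marginal GLS via two-pass
  pruning) and root→clade lineage trends.
* **Arg/(Arg+Lys) proteome composition** — the arginine fraction among
  arginine+lysine residues, a marker that decreases with cold adaptation —
  with nonparametric group comparisons (Kruskal–Wallis / rank-sum,
  Benjamini–Hochberg).
* **Cold-clade detection** (maximal monophyletic all-cold clades) and
  **clade-specific gene-family scoring** from presence/absence matrices.
* **Seeded synthetic-data generators** (Yule trees, traits under all 13
  models, threshold/random binary states, proteomes, presence/absence
  matrices) so the full analysis runs without any external data.

## Worked example

```python
from phylotherm import simulate, TraitEvolution, fit_all, d_statistic, classify_cold

# a 200-tip genus where cold adaptation follows a Brownian liability
tree = simulate.sim_yule(200, birth_rate=1.0, seed=11)
liab = simulate.sim_trait(tree, simulate.EvolModelSpec("BM", {"sigma2": 1.0}), seed=11)
t_min = 9.0 + 6.0 * (liab - liab.mean()) / liab.std()   # degrees C
cold = (t_min <= 5.0).astype(int)

res = TraitEvolution(tree, t_min, family="BM").fit()
print(res.summary())

d = d_statistic(tree, cold, n_perm=1000, n_sim=1000, seed=7)
print(d.summary())
```

prints (abridged):

```
Trait evolution fit: BM
  contrasts: 199
  lnL (REML): -438.5648
  k: 1   AIC: 879.1295
  converged: True (1 restarts, 1 iterations)
  parameters:
          sigma2 = 5.77469

Phylogenetic signal of a binary trait (D statistic)
  tips: 200  state-1 tips: 48
  d_obs = 13.0925
  mean d (tip shuffle, n=1000): 64.4813
  mean d (Brownian threshold, n=1000): 29.3292
  D = -0.4619   (1 = random placement, 0 = Brownian clumping, < 0 = stronger)
  P(random)   = 0.000999
  P(Brownian) = 0.987
  seed = 7
```

The BM fit recovers the liability's diffusion rate on the temperature scale
(≈ 6°²/unit time, since t_min = 9 + 6·standardized liability), and negative
D with P(random) at the 1/1001 floor says the cold state is clumped at
least as strongly as Brownian inheritance predicts — the "conserved cold
clade" regime. Randomly reassigning the same temperatures across tips
pushes D to ≈ 1 (the "sporadic" regime).

Model ranking across families, ancestral states, composition and clade
scans work the same way (`fit_all`, `asr_bm`, `arg_lys_ratios`,
`find_cold_clades`, `clade_specific_families`), or run everything from one
YAML config:

```bash
phylotherm run --config run.yaml
```

Each stage is also its own subcommand (`fit-models`, `asr`, `phylo-d`,
`mantel`, `rk-ratio`, `clade-scan`, `clade-families`, `group-compare`,
`simulate ...`).

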