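# opermorph

Outline-based geometric morphometrics and phylogenetic comparative methods
for studying the evolution of the opercle — the flat bone plate forming the
gill cover of bony fishes — across species flocks such as the Lake
Tanganyika cichlid radiation.

The opercle is one of the few skeletal elements measurable in both extant
and fossil fishes, which makes its outline shape a natural trait for asking
how ecological diversification proceeds: does shape track feeding ecology,
is its evolution concentrated early (an "early burst") or late, and are
distant relatives more similar than neutral evolution predicts
(convergence)?  `opermorph` implements the complete analysis chain for such
a study, end to end, with a synthetic-data generator that produces full
study bundles with known ground truth so every stage is testable without
access to the original specimens.

## What it computes

1. **Morphometrics** — TPS outline I/O; resampling of each closed outline
   to *k* arc-length-equidistant semilandmarks traversed clockwise from a
   homologous dorsal start point; centroid size
   CS = √Σ‖p<sub>i</sub> − p̄‖²; generalized Procrustes analysis
   (translation, unit-CS scaling, rotation, no reflection); PCA of the
   aligned coordinates (shape space) and of coordinates + ln CS (form
   space); broken-stick assessment of PC variance.
2. **Group structure** — canonical variates analysis of species-mean
   shapes by feeding preference (6 levels) and feeding mode (7 levels);
   permutation Procrustes ANOVA with Goodall's
   F = (SS<sub>B</sub>/(g−1)) / (SS<sub>W</sub>/(N−g)).
3. **Phylogenetic regression** — PGLS with Brownian-motion residual
   covariance, β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y, reporting the signed √R²(GLS) as the
   trait correlation.
4. **Macroevolutionary models** — ML fits of BM, Ornstein–Uhlenbeck, white
   noise, early burst (ACDC, positive rate change allowed), Pagel's δ and
   Pagel's λ via transforms of the phylogenetic covariance C; AICc
   comparison with Akaike weights w<sub>i</sub> = e^(−Δᵢ/2)/Σe^(−Δⱼ/2);
   Blomberg's K with permutation P; BM ancestral states; the evolutionary
   rate matrix R̂; multivariate BM simulation.
5. **Convergence** — pairwise distance-contrast analysis: observed
   morphological distances vs distances simulated under BM with R̂,
   counting pairs below the bootstrap lower-95% bound of their simulated
   distance distribution.
6. **Disparity through time** — relative subclade disparity at each node
   time, a 95% BM simulation envelope and the MDI (area between observed
   and simulated-median curves over the first 90% of tree height) with a
   two-sided simulation P.

## Worked example

Generate a synthetic study (20 species, 140 specimens, 60 semilandmarks),
superimpose, ordinate, and fit the six trait-evolution models to PC1:

```python
import numpy as np, pandas as pd, opermorph as om

ds = om.make_dataset(n_species=20, n_specimens=140, k=60, seed=42)
configs = [om.resample_outline(o, k=60, start=0) for o in ds.specimens]
alignment = om.gpa(configs)
means, mean_cs = om.species_mean_shapes(alignment)
space = om.shape_pca(np.stack([m.coords for m in means]).reshape(len(means), -1))
print("PC variance %:", np.round(100 * space.proportions[:3], 1))

pc1 = pd.Series(space.scores[:, 0], index=[m.species_code for m in means])
fits = [om.fit_trait_model(pc1, ds.tree, m)
        for m in ("BM", "OU", "WN", "EB", "delta", "lambda")]
print(om.compare_models(fits).summary())
print(om.blomberg_k(pc1, ds.tree, n_perm=999, seed=1).summary())
print(om.mdi(pc1, ds.tree, n_sims=1000, seed=2).summary())
```

Output:

```
PC variance %: [67.3 20.5  3.3]
 model    LogL      AICc   dAICc  AkaikeWeight
    BM 58.8743 -113.0427  0.0000        0.4178
    OU 59.2560 -111.0121  2.0306        0.1514
    WN 47.8816  -91.0573 21.9854        0.0000
    EB 59.2560 -111.0121  2.0306        0.1514
 delta 59.4070 -111.3139  1.7287        0.1760
lambda 58.8743 -110.2486  2.7940        0.1033
Blomberg's K = 0.8329 (P = 0.001)
MDI = 0.0211 over [0, 0.9] (P = 0.824, 1000 BM simulations)
```

The generator's dominant latent axis evolves by Brownian motion, and the
analysis recovers exactly that: PC1 carries most of the shape variance, BM
wins the AICc comparison (weight 0.42, white noise is rejected by ΔAICc ≈
22), phylogenetic signal is strong (K near 1 with a significant permutation
test), and the disparity-through-time curve stays inside the neutral
envelope (MDI ≈ 0, P ≫ 0.05).

The same workflow is available from the shell:

```bash
opermorph simulate --outdir run --n-species 54 --n-specimens 416 --seed 1
opermorph align --tps run/specimens.tps --outdir run
opermorph ordinate --outdir run
opermorph fitmodels --outdir run --tree run/tree.nwk
opermorph dtt --outdir run --tree run/tree.nwk --seed 1
# or everything at once from a config file:
opermorph run --config run.cfg
```

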