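# gtrlink

Maximum-likelihood estimation of a **linked** general time-reversible (GTR)
amino-acid exchangeability matrix under **profile mixture models**, for
phylogenetics of deep divergences.

Profile mixture models (C10–C60, UDM, and similar) describe heterogeneity
of admissible amino acids across alignment sites: every site class `c` has
its own equilibrium frequency profile `pi_c`, but all classes share one
exchangeability matrix `S`.  In practice that shared matrix is usually
fixed to LG — a matrix estimated under a *single* profile, which makes it
systematically misfit in a mixture setting.  `gtrlink` estimates the shared
matrix itself by maximum likelihood on a fixed tree, alongside mixture
weights, the gamma rate-heterogeneity shape, and branch lengths.

The model: for site pattern `x_p` on tree `T`,

    L(x_p) = Σ_c w_c Σ_k d_k P(x_p | T, S, π_c, r_k),
    q_ij = s_ij π_j (i ≠ j), normalized to unit mean rate,

with `K` equal-probability discretized-gamma rate categories `r_k(α)`.
`S` is symmetric non-negative with the Y/V entry pinned to 1, so 189 free
exchangeabilities; the alignment log-likelihood `ℓ = Σ_p log L(x_p)` is
maximized by block coordinate ascent (analytic-gradient quasi-Newton for
branch lengths and exchangeabilities, EM for weights, bounded search for
α).  A column-wise simulator, SAD (sum of absolute differences between
matrices on a uniform-profile comparison scale), AIC/BIC tables, and
fixed-topology log-likelihood difference reports round out the toolkit.

Audience: molecular evolution researchers fitting site-heterogeneous
substitution models to concatenated protein alignments, and method
developers who need a transparent, tested reference implementation with
exact oracles.

## Worked example

Simulate a 10-taxon alignment under the LG matrix with a 4-class profile
mixture and re-estimate everything from an all-ones start:

```python
import numpy as np
import gtrlink as g

mix = g.ProfileMixture(g.biochemical_profiles(),
                       np.array([0.35, 0.15, 0.25, 0.25]))
rates = g.discretize_gamma(0.67, 4)
tree = g.recovery_study_tree()

sim = g.simulate_alignment(g.SimulationSpec(
    tree, g.lg_matrix(), mix, rates, n_sites=2000, seed=1))

spec = g.MixtureModelSpec(g.lg_matrix(), mix, rates, tree)
fit = g.fit_joint(sim.alignment, spec,
                  g.FitOptions(max_outer_rounds=3))

print(f"loglik   {fit.loglik:.1f}")
print(f"alpha    {fit.alpha_hat:.3f}   (truth 0.67)")
print(f"weights  {np.round(fit.weights_hat, 3)}")
print(f"SAD to truth  {g.sad(fit.S_hat, g.lg_matrix()):.3f}   "
      f"(start {g.sad(g.poisson_matrix(), g.lg_matrix()):.3f})")
```

Output:

```
loglik   -25174.7
alpha    0.736   (truth 0.67)
weights  [0.342 0.152 0.258 0.248]
SAD to truth  0.125   (start 0.506)
```

The fitted matrix lands at SAD 0.125 from the generating LG matrix —
a four-fold improvement over the POISSON starting point at 0.506 — while
the weights land within 0.01 of 0.35/0.15/0.25/0.25 and the gamma shape
within 0.07 of its true value.

The same fits are available from a shell:

```
gtrlink estimate --aln sim.fasta --tree tree.nwk \
    --model GTR+profiles.tsv+G4 --out run1/
gtrlink sad --m1 LG --m2 POISSON        # prints 0.506258
gtrlink simulate --spec spec.json --seed 7 --out sim1/
```

Model strings follow the usual naming: `LG+C60+G4` (fixed LG, profile file
`C60`, gamma with estimated shape), `GTR+C10+F+G4{0.5}` (estimated
exchangeabilities, an added empirical-frequency class, shape fixed at
0.5).  Profile-set names always resolve to files (TSV, one profile per
row, or a NEXUS-style frequency block).

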