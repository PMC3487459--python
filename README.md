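# lfgscape

Does recombination speed up or slow down adaptation when the fitness
landscape is rugged? `lfgscape` is a simulation and screening toolkit for
population geneticists studying that question in bacteria that recombine by
transformation (uptake of free environmental DNA, modeled as single-allele
replacement). It quantifies the effect of recombination on the rate of
adaptation across multilocus fitness landscapes whose mutational paths to
the global peak are obstructed by **low-fitness genotypes (LFGs)** — a
tractable caricature of the pervasive sign epistasis seen in empirical
landscapes.

## Model

Genotypes are binary strings over `L` biallelic loci (`0` deleterious, `1`
beneficial). A genotype with `k` deleterious alleles has Malthusian fitness

```
m(k) = 1 − s · k^ε
```

so the all-`1` genotype is the global peak (`m = 1`), `s` is the selection
coefficient per deleterious allele, and `ε` tunes baseline magnitude
epistasis (`ε = 1` additive; `ε < 1` intermediates below the additive chord,
i.e. positive epistasis; `ε > 1` negative epistasis). A **fitness
topography** is a set of intermediate genotypes overlaid with `m = 0` — the
LFGs that make some mutational trajectories inaccessible.

Two engines share this landscape definition:

* **Deterministic (infinite population):** genotype frequencies `x_i` obey

  ```
  dx_i/dt = μ Σ_{j∈N(i)} x_j − μ L x_i          (mutation, per-locus rate μ)
          + (m_i − m̄) x_i                       (selection)
          + (r/L) Σ_l [x_{flip(i,l)} p_l(a_il) − x_i p_l(1−a_il)]   (transformation)
  ```

  where the free-DNA pool mirrors the population's allele frequencies
  `p_l`, and `r` is the total per-genome uptake rate. Fixation is the
  first time the peak's frequency exceeds 0.99 (event detection on a
  stiff-capable adaptive integrator).

* **Stochastic (finite population):** a Moran-type continuous-time model
  with compartments `n_i`, birth rate `B·e^{m_i}·n_i`, density-dependent
  death `B·(N/N0)·n_i`, per-neighbor mutation `μ·n_i` and transformation
  `(r/L)·n_i·A_l/N`. The core is a hybrid of Gillespie's exact SSA and
  tau-leaping (numba-compiled), exact for small compartments and leaping
  Poisson updates for large ones.

The headline statistic is **T_fix**: the ratio of the (mean) fixation time
of the peak genotype with recombination to that without. `T_fix > 1` means
recombination decelerates adaptation. Deterministically, LFGs make
recombination decelerate adaptation (the more LFGs, the more so); in finite
populations the Fisher–Muller effect usually flips the sign.

## Worked example

```python
from lfgscape import (GenotypeSpace, FitnessTopography, build_landscape,
                      DynamicsParams, t_fix_ratio, stochastic_t_fix)
from lfgscape.stochastic import StochParams

space = GenotypeSpace(4)
topo = FitnessTopography(4, frozenset({0b0011, 0b0101, 0b1001}))
land = build_landscape(space, s=0.05, eps=1.0, topography=topo)

ratio, with_r, without_r = t_fix_ratio(land, DynamicsParams(mu=1e-5, r=0.05))
print(f"deterministic fixation time: r=0.05 -> {with_r.time:.1f}, "
      f"r=0 -> {without_r.time:.1f}, T_fix = {ratio:.3f}")

params = StochParams(N0=10_000, mu=1e-5, r=0.05, n_reps=10, seed=1)
st, arm_r, arm_0 = stochastic_t_fix(land, params)
print(f"stochastic (N0=1e4, 10 reps/arm): mean times "
      f"{arm_r.mean:.0f} / {arm_0.mean:.0f}, T_fix = {st:.3f}")
```

prints

```
deterministic fixation time: r=0.05 -> 301.7, r=0 -> 290.8, T_fix = 1.037
stochastic (N0=1e4, 10 reps/arm): mean times 270 / 460, T_fix = 0.587
```

With three LFGs blocking paths through `0011`, `0101` and `1001`,
recombination slows the infinite population down by ~4% (it breaks apart
multi-mutants faster than it assembles them), but accelerates the finite
population by ~40%: beneficial single mutants arising in different lineages
interfere, and transformation recombines them onto one background.

A command-line interface wraps the screening machinery:

```
lfgscape enumerate -L 4 --max-lfgs 2 --classes
lfgscape screen-det --max-lfgs 4 -o screen.tsv
lfgscape summarize screen.tsv
```

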