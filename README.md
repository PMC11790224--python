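# allochron

Individual-based simulation of **allochronic speciation** — reproductive
isolation arising from divergence in the daily timing of mating — modelled
on the corn and rice strains of the fall armyworm (*Spodoptera
frugiperda*), a nocturnal moth in which the two strains mate at different
hours of the night.

The package is for evolutionary biologists studying how mating-system
mechanics shape the scope for speciation by phenotype matching.  Each moth
carries a heritable circadian timing trait τ ∈ [0, 1] (fraction of night
elapsed).  Its nightly activity profile is

    A(t; τ) = √Beta(t; 1 + aτ, 1 + a(1−τ)),

normalised so ∫ A² dt = 1, and a female–male pair meets Poisson(λ) times
per night with λ = η ∫ A(t; τ♀) A(t; τ♂) dt — assortative mate encounter by
timing overlap.  Encounters are processed chronologically under one of
three mating systems (first-male-precedence *baseline*, *scramble*,
*monogamy*).  Juvenile survival is under habitat-divergent soft selection
between corn (optimum τ* = 0) and rice (τ* = 1) habitats in a K-patch
metapopulation with migration; timing is encoded by L = 20 additive
diploid loci whose expression can evolve **sex-specific regulation**,
resolving the intralocus sexual conflict created by sexual selection for
early male activity.  Premating isolation is measured as the mate-pair
chronotype correlation r<sub>MF</sub> and genetic differentiation as
Hudson's F<sub>ST</sub> at 20 neutral loci between the early and late
chronotype clusters (1-D 2-means).

## Worked example

A scaled-down secondary-contact run: two locally adapted strains (τ ≈ 0.1
and 0.9) resume gene flow at generation 100, with sex-specific expression
of timing genes enabled (`examples/secondary_contact.py` runs this next to
the collapsing shared-expression variant):

```python
import dataclasses
from allochron import get_preset, run

cfg = dataclasses.replace(get_preset("fig2a-mini"), seed=11, generations=300)
t = run(cfg).terminal
print(f"centers ({t.cluster_centers[0]:.2f}, {t.cluster_centers[1]:.2f}), "
      f"rMF={t.r_mf:.2f}, FST={t.f_st:.3f}")
print(f"late cluster: female tau {t.extras['late_mean_tau_f']:.2f}, "
      f"male tau {t.extras['late_mean_tau_m']:.2f}")
```

prints:

```
centers (0.06, 0.67), rMF=0.97, FST=0.047
late cluster: female tau 0.70, male tau 0.44
```

Read: two chronotype clusters persist after 200 generations of contact
(k-means centres 0.06 and 0.67), mating is strongly assortative by timing
(r<sub>MF</sub> = 0.97), neutral differentiation between chronotypes is
accumulating (F<sub>ST</sub> ≈ 0.05), and late-cluster males express
earlier activity (τ ≈ 0.44) than their females (τ ≈ 0.70) — the
male compromise between sexual selection for earliness and overlap with
their own strain's females.  Running the same configuration with
`fig1a-mini` (shared expression) instead collapses the polymorphism.

The same runs are available from a shell:

```bash
allochron run --preset fig2a-mini --seed 11 --out out/
allochron grid --preset fig3-mini --seeds 0,1,2 --out grid.tsv
```

writing a per-census TSV, a terminal-summary JSON, and a config echo.

The scripts in `examples/` each demonstrate one capability: the encounter
kernel, sexual selection under the three mating systems, secondary
contact with and without sex-specific expression, and the (c, m)
parameter grid.

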