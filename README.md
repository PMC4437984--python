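# isoniche

Quantitative toolkit for measuring **intraspecific trophic diversity** from
bivariate stable-isotope data (δ13C, δ15N) and combining it with a
rubric-based **Breeding Vulnerability Index** to rank fish species'
vulnerability to ecosystem perturbation — the workflow used to assess seven
key fishes of Lake Turkana (Kenya) facing reduced inflow from the Omo River.

δ13C (‰ vs VPDB) tracks carbon source (pelagic vs littoral), δ15N (‰ vs
atmospheric air) tracks trophic level, so a population's spread in
(δ13C, δ15N) space proxies its dietary niche breadth. Specialists (small
isotopic niche) are expected to fare worse under perturbation than
generalists, and species that also depend on the flood pulse or on threatened
breeding habitat carry "two strikes".

## What it computes

For each species' point cloud:

- **SEA / SEAc** — the standard ellipse area, `SEA = π·√(λ1·λ2)` with λ the
  eigenvalues of the sample covariance (the bivariate analogue of a standard
  deviation, containing ≈ 40% of normal data), and its small-sample
  correction `SEAc = SEA·(n−1)/(n−2)`; ellipse **eccentricity**
  `√(1 − λ2/λ1)` on raw or community-standardized axes.
- **SEA_B** — the posterior mean niche area under a conjugate
  normal–inverse-Wishart model, plus pairwise Bayesian probabilities
  `P(niche_i < niche_j)` arranged rows-smaller / columns-larger.
- **Ellipse overlap** — percent overlap of SEAc ellipses via exact-area
  polygon clipping, per-species median overlap, and aggregate-niche
  containment (is one species' niche nested in the pooled rest?).
- **Layman metrics** — convex hull area (Hull), mean centroid distance (CD),
  mean nearest-neighbour distance (MNND) and its SD (SDNND), with
  fixed-size bootstrap means (Hull_b, CD_b, …) that remove their sample-size
  dependence.
- **Lipid QC** — the paired bulk/lipid-extracted screen
  (`Δδ13C = ((δ13C_B − δ13C_LE)/δ13C_B)·100`, C:N < 3.5 rule, one-sided
  slope test) deciding whether uncorrected δ13C may be used.
- **Baseline partition** — size-corrected residual variance attributed to
  site, year and their interaction, the strict `> 5` unique-sites rule, and
  the unique-sites-vs-niche-size regression.
- **BVI** — flood-pulse factor (0–2) + breeding-habitat factor (0–2, with
  weighted sub-population splits), combined with SEAc into a composite
  vulnerability ranking.

A synthetic-data module (`isoniche.simulate`) generates communities with
known means, covariances, site/year baseline offsets, body-size trends and
lipid effects, so the whole pipeline is testable without field data.

## Worked example

```python
from isoniche import (bvi, community_ellipses, generate_community, group_by_species,
                      probability_matrix, rank_species, read_traits, sample_posterior,
                      turkana_like_specs)

df = generate_community(turkana_like_specs(), seed=1)   # 635 synthetic fish, 7 species
datasets = group_by_species(df)
ells = community_ellipses(datasets)

posts = [sample_posterior(d, draws=10_000, seed=10 + i) for i, d in enumerate(datasets)]
m = probability_matrix(posts)
print(m.loc["Alestes baremose", "Lates niloticus"])     # 1.0

scores = [bvi(t) for t in read_traits()]                # packaged Turkana trait table
seac = {d.species: ells[d.species].seac_ for d in datasets}
for r in rank_species(scores, seac):
    print(f"{r.species:22s} BVI={r.bvi.total:3.1f} SEAc={r.seac:5.2f} "
          f"composite={r.composite:.2f} -> {r.klass}")
```

```
Alestes baremose       BVI=4.0 SEAc= 7.59 composite=1.90 -> loser
Labeo horie            BVI=3.0 SEAc=10.49 composite=1.51 -> loser
Tilapia zillii         BVI=2.0 SEAc= 5.65 composite=1.50 -> loser
Hydrocynus forskalli   BVI=1.5 SEAc= 7.92 composite=1.26 -> loser
Synodontis schall      BVI=1.0 SEAc=11.64 composite=0.95 -> winner
Oreochromis niloticus  BVI=2.0 SEAc=16.64 composite=0.95 -> winner
Lates niloticus        BVI=0.0 SEAc=25.49 composite=0.00 -> winner
```

The probability 1.0 says every paired posterior draw had the zooplanktivore's
niche smaller than the top predator's. The composite is BVI/4 plus one minus
the min–max-scaled SEAc, so a score above 1.0 means a species is exposed on
both axes — the four "losers" here are exactly the flood-pulse- and
habitat-dependent specialists.

The same stages are available as a CLI
(`isoniche simulate|niche|bayes-compare|overlap|layman|lipid-qc|baseline|bvi|report`,
with global `--seed`, `--config`, `--out-dir`), each writing CSV tables and a
run log.

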