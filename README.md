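# protcomm

Soil protistan community ecology for amplicon surveys: diversity,
phylogenetic null-model community assembly, trophic trait composition,
a composite fruit-quality index, and environmental-driver analysis —
built for the common orchard design of three cultivation modes
(greenhouse, hilly-converted, paddy-converted farmland) sampled at two
crop growth stages (flowering, fruiting).

## Who this is for

Microbial ecologists working from an 18S ASV table (samples × amplicon
sequence variants), a PR2-style taxonomy, a rooted phylogeny of the
ASVs, and per-sample soil chemistry / fruit quality tables. The package
starts *after* denoising: it applies the standard table preparation
(exclusion of fungal/metazoan/land-plant ASVs, singleton removal,
rarefaction), and carries the analysis through to ecological
interpretation. A seeded synthetic-data generator reproduces the whole
design so every stage is testable without sequencing data.

## The core model

For every pair of communities the assembly analysis computes the
between-community mean nearest taxon distance

  betaMNTD(A, B) = ½ [ Σᵢ∈A fᵢ minⱼ∈B d(i, j) + Σⱼ∈B fⱼ minᵢ∈A d(j, i) ],

with f the relative abundances and d the patristic distance, and
standardizes it against a null distribution from shuffling tip labels
across the whole phylogeny:

  betaNTI = (betaMNTD_obs − mean_null) / sd_null.

betaNTI > +2 indicates heterogeneous selection, betaNTI < −2 homogeneous
selection. For the remaining (phylogenetically stochastic) pairs the
abundance-based Raup–Crick metric RC ∈ [−1, 1] — observed Bray–Curtis
against null assemblages preserving each sample's richness and total
count — separates dispersal limitation (RC > +0.95), homogenizing
dispersal (RC < −0.95) and drift (|RC| ≤ 0.95). Per-group fractions of
the five processes are reported over within-group sample pairs.

Around that core: Chao1 / Shannon / Pielou / Faith PD alpha diversity,
Bray–Curtis PCoA and PERMANOVA, Tukey HSD group contrasts, trophic
groups (consumer / phototrophic / parasitic) from taxonomic
affiliation, a production index (mean of per-parameter z-scores of the
twelve fruit-quality measurements), redundancy analysis on Hellinger-
transformed abundances, and a random-forest driver ranking with
out-of-bag permutation importance.

## Worked example

```python
from protcomm import CommunityAssembly, prepare
from protcomm.simulate import scenario, simulate_dataset

ds = prepare(simulate_dataset(scenario("selection", seed=1)), seed=5)
res = CommunityAssembly(ds).fit(n_null=199, seed=0, groupby="cell")
print(res.summary())
```

```
Community assembly null-model analysis
  samples: 36   pairs: 630   null replicates: 199
  mean betaNTI: +5.954   selection fraction: 0.809

  Process fractions over defined within-group pairs:
                      n_pairs  n_undefined  heterogeneous_selection  ...   drift
  greenhouse/flowering       15           10                   1.0000  ...  0.0000
  greenhouse/fruiting        15            0                   0.0667  ...  0.3333
  hilly/flowering            15            3                   0.6667  ...  0.1667
  hilly/fruiting             15            1                   0.9286  ...  0.0000
  ...
```

Under the simulated nitrogen gradient, 81% of defined sample pairs are
classified as selection-driven (|betaNTI| > 2), and heterogeneous
selection dominates most within-farmland fractions — the signature of
environmental filtering along a gradient. The same design run through
the `neutral` scenario yields a mean betaNTI near 0 and a
drift-dominated partition.

The same pipeline runs from the shell:

```sh
protcomm simulate --scenario selection --ntaxa 40 --per-cell 6 --seed 1 --out data/
protcomm assembly --dataset data/ --nnull 999 --seed 0 --out results/
protcomm run --config pipeline.yaml --out results/   # all stages + manifest
```

## Layout

- `protcomm.io` — TSV/newick reading and writing, taxon exclusion,
  singleton removal, seeded rarefaction
- `protcomm.diversity` — alpha indices, Bray–Curtis, PCoA, PERMANOVA,
  Tukey HSD, within-group dispersion
- `protcomm.assembly` — patristic distances, betaMNTD/betaNTI,
  RCbray, process partitioning; `CommunityAssembly` model object
- `protcomm.traits` — trophic group assignment and composition
- `protcomm.quality` — production index and its regressions
- `protcomm.drivers` — RDA and random-forest driver ranking
- `protcomm.simulate` — the scenario generator
- `protcomm.pipeline` / `protcomm.cli` — orchestration and CLI

See `docs/methods.md` for the models, parameter choices, and known
limitations.
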