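# subcomm

Biogeography and community-assembly analysis of **abundant, intermediate and
rare microbial sub-communities**, built for soil fungal (ITS) surveys that
compare site groups under contrasting land management (e.g. tilled vs
untilled soils).

Soil fungal communities are dominated by a few abundant taxa and a long tail
of rare ones, and these sub-communities respond differently to disturbance:
abundance-class partitioning followed by per-class diversity, niche-breadth,
spatial and null-model analyses is the standard way to ask *which ecological
processes assemble each sub-community, and how management changes them*.
`subcomm` implements that entire workflow as a reusable, tested library with
a CLI, plus a synthetic-survey generator so every stage can be validated
against controllable ground truth.

## What it computes

Given an OTU count table (taxa × samples, TSV), a rooted phylogeny with
branch lengths (Newick) and sample metadata (group, coordinates, soil
chemistry; TSV):

- **Partitioning** — abundant (mean relative abundance > 0.1 %), rare
  (< 0.01 %) and intermediate taxa, classified within each treatment group.
- **Alpha diversity** — per-sample Chao1
  (S<sub>obs</sub> + F₁(F₁−1)/(2(F₂+1))) and Shannon (−Σ pᵢ ln pᵢ), compared
  between groups with the Wilcoxon rank-sum test.
- **Beta diversity** — Bray–Curtis dissimilarity, principal-coordinates
  ordination, one-way PERMANOVA (9999 permutations), ANOSIM, and
  betadisper-style multivariate homogeneity of dispersions, all implemented
  from their definitions with permutation p-values of the form
  (1 + b)/(1 + m).
- **Niche breadth** — Levins' B<sub>j</sub> = 1/Σᵢ P²ᵢⱼ per taxon, with
  generalists (B > 3) and specialists (B < 1.5).
- **Spatial structure** — great-circle distances, log–log distance–decay
  regression of community similarity (the slope is the decay exponent), and
  Mantel tests against geographic and environmental distances.
- **Assembly processes** — abundance-weighted βMNTD, βNTI against a
  tip-shuffling phylogenetic null, RC<sub>bray</sub> against a
  richness/abundance-preserving Raup–Crick null, and the five-way process
  classification (variable selection βNTI > 2, homogeneous selection
  βNTI < −2, dispersal limitation RC > 0.95, homogenizing dispersal
  RC < −0.95, undominated otherwise), with deterministic vs stochastic
  fractions per group and class.

The synthetic generator (`subcomm.simulate`) produces surveys with a Yule
phylogeny, Brownian (phylogenetically conserved) niche optima, a spatially
autocorrelated environmental gradient, lognormal species-pool abundances,
optional dispersal kernels and ecological drift, and an environmental-
homogenization ("tilled") regime — the data-generating assumptions under
which the analyses above are interpretable.

## Worked example

```python
from subcomm.pipeline import RunConfig, run_pipeline

config = RunConfig(
    simulation={"preset": "homogenized", "n_taxa": 150,
                "n_sites_per_group": {"tilled": 19, "untilled": 25},
                "read_depth": 20_000},
    n_perm_permanova=9999, n_perm=999, n_null=199,
    seed=1, out_dir="example_out")
report = run_pipeline(config)

anosim = {r["class"]: r for r in report["beta_tests"]
          if r["statistic_name"] == "anosim_R"}
for cls in ("abundant", "intermediate", "rare"):
    r = anosim[cls]
    print(f"{cls:12s} ANOSIM R = {r['statistic']:.3f}  p = {r['p_value']:.4f}")
for key, val in sorted(report["dispersion_means"].items()):
    print(f"dispersion  {key:22s} mean distance to centroid = {val:.3f}")
for row in report["process_fractions"]:
    print(f"{row['group']:9s} {row['class']:12s} stochastic = "
          f"{100 * row['stochastic']:.1f}%  (n = {row['n_pairs']} pairs)")
```

prints

```text
abundant     ANOSIM R = 0.082  p = 0.0280
intermediate ANOSIM R = 0.090  p = 0.0280
rare         ANOSIM R = 0.084  p = 0.0330
dispersion  abundant/tilled        mean distance to centroid = 0.461
dispersion  abundant/untilled      mean distance to centroid = 0.586
dispersion  intermediate/tilled    mean distance to centroid = 0.492
dispersion  intermediate/untilled  mean distance to centroid = 0.591
dispersion  rare/tilled            mean distance to centroid = 0.573
dispersion  rare/untilled          mean distance to centroid = 0.608
tilled    abundant     stochastic = 93.6%  (n = 171 pairs)
tilled    intermediate stochastic = 85.4%  (n = 171 pairs)
tilled    rare         stochastic = 75.4%  (n = 171 pairs)
untilled  abundant     stochastic = 59.0%  (n = 300 pairs)
untilled  intermediate stochastic = 56.3%  (n = 300 pairs)
untilled  rare         stochastic = 66.3%  (n = 276 pairs)
```

Reading the output: all three sub-communities differ in composition between
groups (ANOSIM R > 0, p < 0.05); every sub-community is more homogeneous in
the tilled group (smaller mean distance to its group centroid); and assembly
is more stochastic in the homogenized tilled group, with abundant taxa the
most stochastic class — the signature the homogenization regime is designed
to produce. All per-stage tables (partition labels, alpha indices,
ordinations, decay fits, per-pair βNTI/RC values…) are written as TSV files
under `out_dir`, together with `run_report.json`.

The same pipeline is available from the shell:

```bash
subcomm simulate --preset homogenized --seed 1 --out data/
subcomm run --config run.yaml          # full pipeline from one YAML
subcomm assembly --table data/otu_table.tsv --tree data/tree.nwk \
    --meta data/metadata.tsv --n-null 999 --seed 7 --out assembly_out/
```

## Layout

- `src/subcomm/` — `io`, `simulate`, `partition`, `alpha`, `beta`, `niche`,
  `spatial`, `assembly`, `pipeline`, `cli`
- `tests/` — unit, property and acceptance tests (pytest + hypothesis)
- `docs/methods.md` — models, assumptions, numerical choices and limitations
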