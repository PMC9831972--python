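# reefpop

Demographic inference and landscape genetics for reef-associated
meta-populations — the analysis toolkit behind questions like: *did this
wide-ranging reef species expand from a geographic origin, how connected are
its populations, and what demographic history explains the site-frequency
spectra observed at each sampling site?*

The package covers, end to end and on plain-text inputs:

* **Diversity statistics from the folded SFS** — θ<sub>π</sub> (mean pairwise
  difference per site), θ<sub>w</sub> (Watterson's estimator) and Tajima's
  *D*, with a simulation-based two-tailed significance test for *D* under a
  constant-size coalescent matched to the observed θ<sub>π</sub>.
* **An event-driven structured-coalescent simulator** for three demographic
  scenarios: panmictic size change (**NS**: *N*<sub>mod</sub> →
  *N*<sub>anc</sub> at *T*<sub>c</sub>), a finite island model (**FIM**) and
  a two-dimensional stepping-stone model (**SST**), both on a 10×10 deme
  grid with per-deme size *N*, migration *Nm*, and a merger into one
  ancestral pool of size *N*<sub>anc</sub> at *T*<sub>col</sub> generations.
  The simulator uses exact event-aggregation shortcuts (geometric /
  negative-binomial compression of migration steps) and is calibrated
  against msprime in the test suite.
* **ABC with random forests** — reference tables of
  (model, parameters, summaries), LDA-augmented summary statistics,
  random-forest model choice with out-of-bag error and confusion
  diagnostics, and quantile-regression-forest posteriors (median and 95%
  interval) for *Nm*, *T*<sub>col</sub>, *N*<sub>anc</sub>, …
* **Landscape least-cost analysis** — habitat rasters coded
  {land, open sea, seamount, reef} with permeabilities fixed to 0 (land) and
  1 (sea) and reef/seamount permeabilities fitted in [1, 100] by maximizing
  the correlation between least-cost distances and linearized genetic
  distances *F*<sub>ST</sub>/(1−*F*<sub>ST</sub>); plus a range-expansion
  **origin map**: the Pearson correlation between per-site θ<sub>π</sub> and
  the least-cost distance from every candidate marine cell (most negative
  cell = inferred origin of the expansion).
* **Population structure** — Hudson's nucleotide
  *F*<sub>ST</sub> = 1 − *H*<sub>w</sub>/*H*<sub>b</sub> with permutation
  significance, Mantel tests, and isolation-by-distance regressions.
* **Synthetic data generators** for every input (archipelago rasters with
  planted diversity decay and planted isolation by distance), so the whole
  pipeline is testable without any sequencing data.

## Worked example

```python
import numpy as np
from reefpop import DemographicModel, SampleSpec, simulate_sfs, diversity_stats
from reefpop.abcrf import (PriorSpec, SimConfig, build_reference_table,
                           append_lda_axes, rf_model_select, summarize_sfs)

# one "observed" dataset: 10 diploids from the central deme of a
# stepping-stone world, 500 RAD-like loci of 100 bp
truth = DemographicModel(kind="SST", N=1000, m=0.01, T_col=2e5, N_anc=20_000)
obs = simulate_sfs(truth, SampleSpec(deme=(4, 4), n_dip=10), n_loci=500, rng=1)
print(diversity_stats(obs, nsim=1000, rng=2))

table = build_reference_table(["NS", "FIM", "SST"], PriorSpec(), 300,
                              SimConfig(n_dip=10, n_loci=500), rng=3)
table, obs_vec = append_lda_axes(table, summarize_sfs(obs))
post = rf_model_select(table, obs_vec, n_trees=500, rng=4)
print(post.selected, post.votes)
```

prints (exact numbers depend only on the seeds):

```
DiversityStats(theta_pi=0.005116210526315789, theta_w=0.005203313034210158,
               tajimas_d=-0.07010582222297247, p_value=0.9470529470529471)
NS {'FIM': 0.054, 'NS': 0.856, 'SST': 0.09}
```

θ<sub>π</sub> ≈ θ<sub>w</sub> ≈ 0.005 per site is the diversity of an
effective population of ~65,000 at the default mutation rate 1.93×10⁻⁸, and
Tajima's *D* ≈ −0.07 (p ≈ 0.95) shows no departure from the constant-size
null: at *Nm* = 10 the hundred-deme lattice behaves like one large panmictic
population, which is also why the model-choice forest votes for the
unstructured scenario here — the three-way classification is only
informative away from this overlap region (see `docs/methods.md`).

A complete demo dataset plus pipeline config can be generated and run with

```bash
reefpop make-fixtures demo --seed 1
cd demo && reefpop run config.yaml
```

which writes per-site diversity tables, the fitted permeabilities, the
origin map (ESRI ASCII grid), per-site ABC reports and the
*F*<sub>ST</sub>/Mantel isolation-by-distance analysis under `results/`,
with a manifest of seeds and stage timings. Individual steps are available
as subcommands (`sfs-stats`, `simulate`, `abc-table`, `abc-select`,
`abc-estimate`, `lc-dist`, `perm-fit`, `origin-map`, `fst`, `mantel`,
`ibd`).

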