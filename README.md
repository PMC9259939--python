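# ishquant

Single-cell quantification of multiplex fluorescent in situ hybridization
(RNAscope-style) images, for neuroscientists measuring how a target
transcript is distributed across neuronal populations.

In single-molecule ISH, each target transcript appears as one
diffraction-limited fluorescent punctum ("dot"). Given a DAPI channel plus
1–3 transcript channels, the pipeline:

1. **segments nuclei** from DAPI (Gaussian smoothing → Otsu threshold →
   hole filling → optional distance-transform watershed split);
2. **expands each nucleus into a cell mask of exactly twice its area** — an
   area budget, grown ring by ring and halted at the budget or at
   neighbouring cells, not a fixed dilation radius;
3. **detects dots** per transcript channel as local maxima of the
   scale-normalised Laplacian-of-Gaussian response, with sub-pixel
   localisation, and assigns each dot to the cell mask containing its
   centroid;
4. **scores each cell**: the expression score is the ratio of dot count to
   mask area (reported both as dots/px² and as dots per 100 µm²);
5. **types each cell** from marker channels (e.g. *Slc17a7* → glutamatergic,
   *Gad1* → GABAergic, *Chat* → cholinergic; ≥ 3 marker dots by default) and
   calls target positivity (≥ 1 dot by default);
6. **summarises populations**: percent positive per section, summarised as
   mean ± SEM across sections; relative-frequency histograms of the
   expression score (bin width 1); and a two-sided **Wilcoxon rank-sum
   (Mann–Whitney U)** comparison between populations — exact by full
   enumeration of the C(n₁+n₂, n₁) rank assignments for small samples,
   tie-corrected continuity-corrected normal approximation otherwise.

Because raw micrographs of this kind are rarely shared, the package bundles
a **synthetic-field simulator** with full ground truth (cell positions,
types, per-cell counts, dot positions): nuclei at configurable density,
per-cell transcript counts from negative-binomial or Poisson models per
cell type, Gaussian puncta, background, noise and optional channel
bleed-through. Every pipeline stage is validated against this ground truth.

## Worked example

Quantify the default simulated study — two cortical populations
(glutamatergic *Gprc5b* counts NB(mean 3, dispersion 2); GABAergic NB(8, 2)),
one animal, 4 sections × 3 images, 50 cells per image:

```python
from ishquant import RunConfig, StudyConfig
from ishquant.pipeline import run_pipeline

res = run_pipeline(RunConfig(study=StudyConfig(), make_plots=False), seed=7)
s = res.summary
print(f"cells quantified: {res.manifest['n_cells']} across {res.manifest['n_images']} images")
for pop in ("glutamatergic", "GABAergic"):
    p, pp = s.populations[pop], s.populations[pop].percent_positive
    print(f"{pop}: n={p.n_cells}, Gprc5b+ {pp.mean:.2f}% +/- {pp.sem:.2f}% "
          f"(mean +/- SEM over {pp.n_sections} sections), "
          f"median score {p.median_score:.2f} dots/100um^2")
print(s.rank_sum)
```

prints (numbers from this exact run):

```
cells quantified: 600 across 12 images
glutamatergic: n=307, Gprc5b+ 84.88% +/- 1.80% (mean +/- SEM over 4 sections), median score 2.88 dots/100um^2
GABAergic:     n=282, Gprc5b+ 96.41% +/- 0.49% (mean +/- SEM over 4 sections), median score 6.38 dots/100um^2
RankSum(U=19880.5, n1=307, n2=282, p=7.434e-30, normal_approx)
```

The generating model implies 84.0% / 96.0% positive cells in closed form
(P(count ≥ 1) under each negative binomial), so the pipeline recovers the
percent positive to within ~1 point and the direction and significance of
the population difference. `res.cell_table` holds the per-cell table
(animal/section/image ids, areas, per-channel counts, densities, scores,
type label, positivity flags) and the run manifest records the full
configuration plus the sensitivity of percent positive to the positivity
threshold (min_dots ∈ {1, 2, 3}).

The same run from a shell:

```bash
ishquant quantify --config run.yaml --seed 7 --out out/
ishquant compare --cell-table out/cell_table.csv --pop-a glutamatergic --pop-b GABAergic
ishquant simulate --config study.yaml --seed 7 --out sim/   # images + ground truth
ishquant report --summary out/summary.json --out plots/
```

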