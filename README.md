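# histoquant

Quantitative post-mortem histology for small-cohort neurodegeneration
studies. The package implements, as a tested and reusable pipeline, the
image- and statistics-side of a typical primate substantia-nigra workup:

- **Puncta quantification** — detection of lysosome/autophagosome marker
  puncta (e.g. LAMP2, LC3) inside a labelled neuron, and their number and
  area over the whole cell, a perinuclear band and the remaining cytosol.
  Cells are screened with a cytoplasm:nucleus area-ratio criterion
  (default 2:1) before analysis; punctum-to-nucleus distances use the mean
  radius of an ellipse fitted to the nuclear region.
- **Stereology** — total neuron number by the optical fractionator,
  `N̂ = ΣQ⁻ / (ssf · asf · tsf)`, with unbiased counting frames
  (inclusion on top/right edges, exclusion on left/bottom) laid on a
  systematic uniform random grid. The default design uses 100 × 80 µm
  frames spaced 600 × 400 µm on a 1-in-12 section series.
- **Densitometry** — mean-grey optical density, thresholded stained-surface
  ratio of chromogen (DAB) sections, percent-of-control normalisation, and
  ROI averaging of elemental (ppm) concentration maps such as synchrotron
  X-ray fluorescence output.
- **Estimation statistics** — unpaired Student t-tests, bootstrapped mean
  differences with confidence intervals (the numerical content of
  Gardner–Altman plots), and control-referenced z-score profiles
  `z = (x − mean_ctrl) / sd_ctrl` across many endpoints.
- **Synthetic data** — a generator for every input above with known ground
  truth: neuron images with catalogued puncta, 3-D neuron fields sliced
  into serial sections, stained images with an exact surface fraction,
  elemental maps, and two-group measurement tables. The generators are the
  oracle the pipeline is validated against.

## Worked example

```python
import histoquant as hq

# 1. simulate one labelled neuron and quantify its puncta
params = hq.CellImageParams(n_perinuclear=10, n_cytosolic=5, seed=42)
image, truth = hq.generate_cell_image(params)
cells, puncta, excluded = hq.run_puncta_pipeline({"cell42": image})
print(cells[["cell_id", "qc_ratio", "n_whole", "n_peri", "n_cyto"]]
      .to_string(index=False))

# 2. stereology: 12 000 neurons, 1-in-12 sections, 100x80 µm frames
series, _ = hq.generate_neuron_field(n_neurons=12000, seed=42)
estimate = hq.run_stereology(series, seed=42)
print(f"counted {estimate.sum_Q} cells -> N_hat = {estimate.n_hat:.0f}")

# 3. estimation statistics on a two-group table (true effect −30)
table, _ = hq.generate_group_table(effect=-30.0, seed=42)
ctrl = table.loc[table.group == "control", "value"].to_numpy()
test = table.loc[table.group == "test", "value"].to_numpy()
comp = hq.bootstrap_mean_diff(ctrl, test, seed=42)
print(f"mean difference {comp.mean_diff:.1f} "
      f"[{comp.ci_low:.1f}, {comp.ci_high:.1f}] "
      f"(t={comp.t:.2f}, p={comp.p:.4f})")
```

prints

```
cell_id  qc_ratio  n_whole  n_peri  n_cyto
 cell42  7.987277       15      10       5
counted 27 cells -> N_hat = 9720
mean difference -29.1 [-39.6, -18.8] (t=-5.69, p=0.0005)
```

The quantified cell recovers all 15 catalogued puncta with the correct
perinuclear/cytosolic split. The single-field fractionator estimate (9720
from 27 counted cells × the design multiplier 360) scatters around the true
12 000 with the expected ~17% CV of one field; averaging over many fields is
unbiased (see the acceptance script). The bootstrap interval comfortably
covers the true effect of −30.

A CLI mirrors the library: `histoquant sim …`, `histoquant quantify …`,
`histoquant stereo …`, `histoquant densito …`, `histoquant stats …`
(run each with `--help`).

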