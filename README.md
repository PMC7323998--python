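# crestrack

Quantitative tracing of the two cranial neural-crest (NC) waves that
build the anterior segment of the zebrafish eye. During 11–31 hpf a
first wave (1°NC, formed laterally at 12–14 hpf) envelops the proximal
hemisphere of the optic cup while a second wave (2°NC, formed
mediodorsally at 16–17 hpf) clusters at the dorsal eye rim and then
migrates over the rim into the distal (lens-facing) hemisphere, where
the cornea and iridocorneal structures later form. `crestrack` is for
developmental biologists and image-analysis researchers who want a
fully synthetic, ground-truth-controlled version of that experiment:
every analysis stage of the live-imaging study — nucleus detection,
division-aware tracking, backward/forward fate propagation, lineage
homogeneity, migration-angle statistics, photoconversion-based wave
classification, penetrance tabulation — runs against a simulator whose
cell programs are known exactly, so recovery of the biology can be
measured instead of assumed.

The core objects:

* a **two-wave agent simulator** on the embryo frame (eye sphere of
  radius R, proximodistal axis u = (lens − centre)/R): guidance drift +
  jitter + nuclear exclusion, Poisson divisions, promoter-gated
  photoconvertible reporter pools (dG/dt = k·a(t) − k_d·G), and
  genotype switches for the guidance defects of *pax6* mutants;
* a **light-sheet renderer / LoG detector** on anisotropic voxels
  (0.4 × 0.4 × 2.0 μm; PSF FWHM 1.5 μm lateral, 6.6 μm axial);
* a **division-aware linker** (optimal assignment with birth/death
  costs, gap closing, midpoint-scored daughter attachment) producing a
  lineage forest;
* **fate statistics**: destination labels (proximal iff (p−c)·u < 0
  inside the eye shell), lineage homogeneity (fraction of lineages
  whose terminals occupy a single compartment), penetrance "x% (a/n)";
* **circular statistics**: stride-sampled planar migration angles,
  10° rose histograms, the circular median (argmin of summed
  wrap-around distance), and the Wallraff rank test of angular
  dispersion with an exact small-sample path;
* **Welch's two-sample t test** from "mean ± SD (n)" group summaries.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
from crestrack import SimulationConfig, build_embryo_model, simulate_populations
from crestrack.lineage import LineageForest
from crestrack import fate
from crestrack.reporters import GroupSummary, welch_t_test

cfg = SimulationConfig(dt_s=240.0, seed=0)       # 300 frames, 11-31 hpf
model = build_embryo_model(cfg)
truth = simulate_populations(model, cfg)
forest = LineageForest.from_truth(truth)
labels = fate.classify_destination(forest, model, t_eval_hpf=30.0)
report = fate.lineage_homogeneity(forest, labels)
print(f"cells: {len(truth)}, divisions: {truth.n_divisions()}")
print(f"lineages: {report.n_lineages}, homogeneous: {report.percent_homogeneous}%, "
      f"mixed: {report.percent_mixed}%")
r = welch_t_test(GroupSummary(28.6, 3.6, 25), GroupSummary(12.8, 6.7, 28))
print(f"Welch: t = {r.statistic:.2f}, df = {r.df:.1f}, p = {r.p_value:.2g}")
```

prints

```
cells: 168, divisions: 62
lineages: 44, homogeneous: 91%, mixed: 9%
Welch: t = 10.85, df = 42.3, p = 8.5e-14
```

The simulated embryo carries 44 founder lineages grown to 168 cell
records; with the default 9% mixed-destination program, 91% of lineages
settle homogeneously in one compartment — the same arithmetic the
lineage-homogeneity report applies to real track tables. The Welch line
reproduces a published endothelial-cell comparison from its printed
group summaries (control 28.6 ± 3.6, n = 25 vs knockdown 12.8 ± 6.7,
n = 28).

A command-line pipeline wraps the same stages
(`crestrack simulate | render | detect | track | fate | angles |
report`), reading a JSON run config and writing track CSVs, Newick
lineage trees, TIFF stacks, rose-diagram JSON and a combined report:

```sh
crestrack simulate --seed 1 --out out/
crestrack fate   --tracks out/sim0_tracks.csv --out out/
crestrack angles --tracks out/sim0_tracks.csv --out out/
crestrack report --out out/
```

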