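# Methods

`crestrack` reconstructs, at desk scale, the quantitative live-imaging
analysis by which two cranial neural-crest (NC) waves colonizing the
zebrafish eye can be distinguished: a synthetic 4D embryo generator, a
light-sheet-like renderer and nucleus detector, division-aware tracking,
backward/forward fate propagation with proximodistal destination
statistics, circular migration-angle statistics, and
photoconversion-based expression classification. This note records the
model, its assumptions, the parameters that matter, and the choices made
where the design was genuinely open.

## Embryo geometry

The embryo frame is right-handed with `axis_ap = +x` (anterior),
`axis_ml = +y` (towards the tracked eye) and `axis_dv = +z` (dorsal), in
micrometres. The eye is a static sphere (default radius R = 40 μm,
centre 70 μm lateral of the midline); the lens sits at its lateral pole,
so the proximodistal unit vector is `u = (lens − centre)/R`. "Proximal"
and "distal" are the hemispheres on either side of the equatorial plane
through the eye centre perpendicular to `u`. A cell is *inside the eye
shell* when `| ‖p − c‖ − R | ≤ shell_um` (default 6 μm); inside the
shell it is *distal* if `(p − c)·u > margin_um` (default 0), otherwise
*proximal*, with the exact-equator tie broken to proximal; outside the
shell it is *periocular*. The anatomy does not grow or deform — a
deliberate simplification (see Limitations).

## Two-wave simulator

The generator's defaults are the study conditions:

| parameter | default | unit | why |
|---|---|---|---|
| `t_start/t_end` | 11 / 31 | hpf | continuous recording window |
| `dt_s` | 20.4 | s | stride 10 = 3 min 24 s, the angle-sampling interval |
| `delamination_window_1nc` | 12–14 | hpf | early wave forms laterally |
| `delamination_window_2nc` | 16–17 | hpf | late wave forms mediodorsally |
| `cluster_window` | 18–22 | hpf | periocular cluster phase |
| `entry_window` | 22–28 | hpf | cluster dissolves, cells enter the distal eye |
| `n_1nc` / `n_2nc` | 30 / 14 | founders | gives ≈160 cell records over the window |
| `n_entering_2nc` | 25 | cells | centre of the 20–30 entering-cell range |
| `division_rate_per_h` | 0.05 | 1/h | free parameter (no published rate) |
| `speed_um_per_min` | 1NC 0.3, 2NC 1.5 | μm/min | free parameters; slow epithelial crawl vs fast mesenchymal migration |
| `noise_sigma_um` | 0.25 | μm/√min | diffusive jitter amplitude, consistent across frame intervals |
| `mixing_fraction` | 0.09 | — | per-lineage probability of a mixed-destination program |
| `wnt_wave2_fraction` | 0.5 | — | fraction of the late wave with sustained Wnt activity |
| `silencing_1nc/2nc` | 16 / 20 | hpf | hard promoter-off switches |
| `green_halflife_h` | 12 | h | reporter persists to ~48 hpf |

Cell speeds and the division rate are free parameters flagged as such:
the source observations describe behaviour, not kinetics.

**Motion.** Velocity per frame = population/phase-specific guidance
drift + isotropic Gaussian jitter + short-range nuclear exclusion
(soft pairwise repulsion within 8 μm, one nucleus diameter). The early
wave migrates to the proximal eye surface, crawls towards the equator
(direction `ap + 0.8·u` tangentialized, speed decaying towards the
equator), and *anchors* — contact inhibition — either at the equatorial
band or on touching an already-anchored neighbour at 8.5 μm (just
outside the exclusion zone, so the frozen monolayer does not oscillate).
A reflecting boundary 1 μm proximal of the equator guarantees that
proximally-programmed cells never cross (the basis of the wildtype
schedule invariant). The late wave migrates to a mean-reverting cluster
point near the dorsal eye rim, stays outside the eye shell until
cluster dissolution, and the first `n_entering_2nc` cells then cross
the dorsal rim and settle at mutually spaced (≥8 μm) points on the
distal cap, routed tangentially around the sphere rather than through
the eye volume. Dividing cells pause briefly (mitotic rounding):
daughters appear one frame after the parent's last frame, displaced
±3.5 μm, and do not translocate for their first two frames.

**Genotype modes.** `pax6b_null`: the late-wave cluster never dissolves
(cells stay periocular). `pax6_double_null`: additionally the early
wave crosses the equator deep into the distal half. Wildtype genotype
comparisons for defect calls are run with `mixing_fraction = 0`: the
defect criterion counts *any* early-wave cell in the distal eye as
abnormal, and the rare programmed stray branches below would otherwise
dominate that count.

**Mixed lineages.** With probability `mixing_fraction` a lineage is
programmed mixed-destination: at its first division after destination
assignment, one daughter becomes a single, non-dividing stray branch
re-routed to the opposite compartment. A mixed program is unobservable
without at least two branches, so a mixed-flagged lineage that would
never divide is forced to divide once at a seeded random time well
before the end of the window; divergence is also disallowed too close
to the end for the stray to reach its compartment. The one-stray-branch
convention keeps the expected number of off-compartment cells small
(a few per embryo, matching the order of the published stray rate) and
makes the programmed fraction identifiable from terminal labels.

**Reporter pools.** Promoter activity a(t) is 1 from birth until the
population's silencing time. Green pool: `dG/dt = k_syn·a − k_deg·G`;
red pool: `dR/dt = −k_deg·R`; photoconversion at t_c moves the whole
green pool to red instantaneously in every cell alive at t_c. Daughters
inherit the parent's pool concentrations. Conversion at 17 hpf followed
by a G/(G+R) > 0.1 classification at any later time separates the
silenced early wave from the still-transcribing late wave exactly,
because the switches are hard — real data would blur this boundary.
The Wnt-reporter intensity is a deterministic two-wave profile: a
transient Gaussian wave in all NC cells (peak 14 hpf) plus a sustained
wave (peak 21 hpf) in the Wnt-positive subset of the late wave.

## Rendering and detection

Each cell contributes a separable anisotropic Gaussian blob
(σ = FWHM/2.355; FWHM 1.5 μm lateral, 6.6 μm axial) scaled by its
channel pool on 0.4 × 0.4 × 2.0 μm voxels, plus Poisson shot noise and
Gaussian read noise over a flat background. Detection filters with a
Laplacian-of-Gaussian whose per-axis σ is specified in physical μm and
converted per axis to voxels (anisotropy is never silently ignored;
a missing voxel-size config is an error). Candidate maxima must exceed
robust (median + k·1.4826·MAD, k = 5) thresholds on **both** the LoG
response and the raw intensity — either alone admits rare noise spikes
— and are refined by intensity-weighted centre of mass in a 3-voxel
neighbourhood. On noiseless frames localization error is below half a
voxel per axis; at study-like density (~600 nuclei per field, peak
≈10× background) detection F1 exceeds 0.95.

## Tracking

Frame-to-frame linking is an optimal assignment on a Jaqaman-style
augmented cost matrix: squared distance within a hard gate (default
10 μm at the 4-min frame interval), with a birth/death alternative cost
of (0.6·gate)² so that a genuinely new detection (a daughter) stays
unmatched instead of triggering a chain of identity swaps. Track ends
are re-joined to later starts across ≤2 skipped frames (cost penalized
per skipped frame, join only if cheaper than gate²); this runs before
division attachment so that a healed break is never misread as a
division. Remaining track starts are attached as second children of an
adjacent continuing predecessor within 1.5× the gate, scored by
midpoint consistency — the two daughters of a symmetric division
straddle the parent — and accepted below 0.35× the daughter gate. Ties
resolve to the lowest detection id. Assignment optimality is verified
against brute-force enumeration for ≤7 points per frame. Chains are
contracted into lineage segments (gap-closed frames linearly
interpolated); a node with two successors is a division.

Evaluation matches reconstructed positions to true cells per frame by
greedy nearest neighbour within 2 μm, scores edges against the true
associations, and reports division recall (reconstructed division at
the same frame mapping onto the true parent), track purity, and a
destination-misassignment rate (terminals whose tree root maps to a
different true founder lineage — the error mode that would propagate a
selection to the wrong origin). False divisions caused by mid-movie
founder delaminations near existing tracks inflate that last diagnostic
(~0.5 on default scenes) without affecting edge F1, division recall or
purity; it is reported, not optimized.

## Fate statistics

Selections are region predicates evaluated at a reference time;
backward propagation returns the unique ancestor path, forward
propagation all descendants, clipped to the window. Destination labels
are assigned to terminals at t_eval = 30 hpf; a terminal born after
t_eval inherits the position of its ancestor alive at t_eval, and a
terminal dead before t_eval is unlabelled. A lineage is homogeneous
when its labelled terminals occupy one compartment of the
proximal/distal dichotomy; periocular and unlabelled terminals do not
enter the dichotomy, and lineages without any in-dichotomy terminal are
excluded and counted separately. Percentages round half away from zero
(39% = 9/23). The migration-defect call for a genotype is: affected iff
fewer than `min_2nc_distal` (default 1) late-wave terminals are distal
or more than `max_1nc_distal` (default 0) early-wave terminals are
distal; an empty forest is affected, flagged.

Mixing-fraction recovery is measured by pooling lineages across five
simulated embryos at default size (≥200 lineages), mirroring pooling
of lineages across specimens; a single embryo densified to 200+
founders would overcrowd the 40 μm eye surface.

## Circular statistics

Displacement angles are sampled every `stride_frames` (default 10 =
3 min 24 s at dt 20.4 s), projected onto the anteroposterior–
mediolateral plane. Convention (stated prominently because medians
depend on it): 0° = anterior, angles increase towards the tracked eye's
distal side, range [0, 360). Steps shorter than 0.5 μm in the plane are
dropped to suppress stationary-cell noise. The circular median is the
data angle minimizing the summed wrap-around distance, ties to the
smallest angle. The Wallraff test replaces each angle by its circular
distance to its own group's median and compares groups by a two-sided
Mann–Whitney test on midranks: exact enumeration of all rank splits for
n_A + n_B ≤ 12, tie-corrected normal approximation otherwise. Reported
p-values are stored exactly; the "< 2.2e-16" floor is applied only in
formatted output.

The angle groups are the *pure waves*: terminals of lineages
homogeneous for a compartment (the group labels are per-wave, so stray
branches of mixed lineages are excluded — their inbound journeys would
otherwise dominate the sparse proximal sample). The default angle
window starts at 15 hpf, covering the migration era of both waves, and
under wildtype defaults the distal group's median direction (~105–115°)
robustly exceeds the proximal group's (~25–45°), reproducing the
directional contrast between the waves. Sampling only after 22 hpf is
available via `angle_window_start_hpf`; in this simulator that window
yields a noise-dominated proximal sample because the settled monolayer
is motionless once anchored (static anatomy; see Limitations). The
Wallraff test is mildly conservative (attained level ≈0.045 at 200
angles per group under a von Mises null) because each group's median is
estimated from the same data.

## Welch's t test

`t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b)` with Welch–Satterthwaite
degrees of freedom and a two-sided p from the t distribution; SDs are
sample SDs (n−1), the convention required to reproduce printed t/df
values from printed "mean ± SD (n)" summaries. From the published
endothelial-cell summaries (28.6 ± 3.6, n = 25 vs 12.8 ± 6.7, n = 28)
this yields t = 10.85, df = 42.31 — within the rounding of the inputs
of the printed t = 10.7, df = 42.1.

## Problem sizes

Default simulations use 44 founders (≈160 cell records). Tracking
fidelity is evaluated on the 300-frame grid (dt = 240 s over 11–31
hpf); angle statistics use the native 20.4 s grid (3530 frames).
Recovery experiments pool five embryos; null calibration uses 2000
replicates of 200 angles per group. The full pipeline rerun
(`scripts/acceptance.py`) completes in well under a minute.

## Known limitations

* The anatomy is static: no eye growth, lens morphogenesis or tissue
  deformation. Consequently the settled proximal monolayer is
  motionless, whereas real proximal cells keep creeping with the
  growing eye; migration-angle contrasts are therefore measured over
  the migration era rather than only after 22 hpf.
* Promoter switches and photoconversion are instantaneous and perfect;
  expression classification on the synthetic data is error-free, so
  passing it demonstrates the plumbing, not robustness to biological
  blur.
* The detector and linker are validated only against this generator's
  ground truth; they stand in for an interactive analysis framework
  whose algorithms are not reproduced here.
* Divisions are a homogeneous Poisson process with symmetric daughters;
  no apoptosis, no cell-cycle structure.
* The destination-misassignment diagnostic is inflated by false
  division attachments at founder-delamination sites and is reported
  as-is.
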