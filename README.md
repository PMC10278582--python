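# cortexdiff

Orientation-resolved diffusion-MRI profiling of cortical gray matter.

## The problem

The cortex contains two interleaved axon systems — *radial* fibers that
enter and exit the cortex, and *tangential* fibers that run parallel to
the pial surface — so most gray-matter voxels hold crossing fiber
populations.  A single diffusion tensor (DTI) averages over them and
dilutes exactly the microstructural signal one needs to detect subtle
cortical malformations (e.g. focal cortical dysplasia, a common cause
of drug-resistant epilepsy).  `cortexdiff` implements an analysis chain
that keeps the populations apart:

1. **Multi-tensor fitting.**  The multi-shell signal is modeled as a
   mixture of non-exchanging Gaussian compartments,
   `S(b,g) = S0 · Σᵢ fᵢ · exp(−b gᵀ Dᵢ g)`, with up to three axially
   symmetric tensors per voxel (each with its own λ∥, λ⊥, orientation
   and signal fraction).  Orientation seeding uses a two-resolution
   discrete search over subdivided-icosahedron axis grids (321 / 1,281
   axes); tensors whose principal axes lie within 20° are merged; the
   number of compartments kept is decided by a nested F-test (α=0.05).
2. **Laplacian cortical coordinates.**  A harmonic potential ψ solved
   between the pial (ψ=0) and gray/white (ψ=1) boundaries yields
   streamline "grid-lines" (50 per slice, 88 µm integration steps,
   resampled to 10 equidistant vertices) — a depth coordinate that is
   comparable across subjects regardless of cortical thickness.
3. **Parallel / perpendicular labeling.**  At every grid vertex, the
   fitted tensors are scored by |e₁ · t| against the local grid-line
   tangent; the highest becomes the *parallel* fixel (radial system),
   the lowest the *perpendicular* fixel (tangential system), giving
   FA_par / FA_perp / MD_par / MD_perp sheets of shape 50 × 10.
4. **Permutation statistics.**  Point-wise two-sided permutation tests
   (difference of group means, add-one p estimator) with cluster-wise
   inference from the empirical null of the maximum cluster size
   (cluster-forming p < 0.05, 4-connectivity), plus Cohen's *d* maps.

Because no real data ship with the package, a first-class synthetic
module generates cortical-ribbon phantoms with the emulated acquisition
(90 directions × b = 670/1,270/2,010 s/mm² + 15 b0, 0.175 mm in-plane),
Rician noise, between-subject variability, and injectable focal
lesions.  A structure-tensor module (15 µm Gaussian window; orientation,
energy, coherency maps) covers the histology arm of the same workflow.

## Worked example

The `analysis/` scripts run the whole study end to end on the phantom
(at 0.35 mm analysis scale so each script finishes in minutes):

```bash
python analysis/01_simulate_phantom.py   # 19 control vs 18 lesioned subjects
python analysis/02_fit_tensors.py
python analysis/03_build_grid.py
python analysis/04_depth_profiles.py
python analysis/05_group_statistics.py
python analysis/06_histology_structure.py
```

`04_depth_profiles.py` prints, for one subject (depth-averaged values):

```
 depth_index    FA    MD  FA_par  FA_perp
           0 0.404 0.001   0.794    0.603
           5 0.400 0.001   0.787    0.631
           9 0.403 0.001   0.799    0.606
```

DTI FA sits near 0.40 — the crossing blurs both populations — while
FA_par ≈ 0.80 and FA_perp ≈ 0.60 recover the generative anisotropy of
the radial and tangential populations separately.  `05_group_statistics.py`
then runs the full 37-subject group comparison and prints:

```
FA_par: 10 cluster(s); min p_cluster = 0.000999; significant points cover 95% of the lesion block
FA_perp: 9 cluster(s); min p_cluster = 0.05594; significant points cover 0% of the lesion block
```

The injected lesion (radial λ∥ × 0.7 in a 10-line × 4-depth block) is
recovered as a familywise-significant FA_par cluster covering the
block, while the untouched tangential population (FA_perp) shows no
significant cluster.

The same stages are exposed as a CLI over files
(`cortexdiff simulate | fit-dti | fit-mt | grid | sample | label |
stats | histo`; see `cortexdiff --help`).

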