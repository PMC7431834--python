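# mitodyn

Quantification of mitochondrial morphology and dynamics in *Drosophila*
ovarian germline stem cells (GSCs), built as a tested, reusable pipeline
that can be exercised end-to-end on synthetic data with known ground truth.

Aging GSCs accumulate small ("fragmented") mitochondria. Asking whether
that reflects excess fission or deficient fusion requires four pieces of
quantification machinery, all implemented here:

1. **3D segmentation and size classification** — bleach-corrected intensity
   stacks are segmented by *hysteresis thresholding* (voxels ≥ a low
   threshold kept only when connected to a voxel ≥ a high threshold),
   labeled as connected components, and measured in μm³. An object with
   volume `V < 0.05 μm³` is *fragmented*; *mitochondrial content* is
   `100 · Σ V_i / V_cell` (%).
2. **Overlap tracking and event detection** — objects in adjacent time
   points sharing ≥ 1 voxel are linked; all linked objects share a track id.
   An object at *t* with out-degree ≥ 2 is a **fission**; in-degree ≥ 2 at
   *t + 1* is a **fusion**. Events are counted in three windows of time
   points (1–4, 4–7, 7–10) with at most one event per track per window, so
   each track carries ≤ 3 counted events; tracks are typed as balanced
   (fissions = fusions ≥ 1), fission-dominant, fusion-dominant, or
   quiescent. The per-frame fragmented count series `F_k` gives
   `Δ_k = F_{k+1} − F_k` (positive = net fission) and an OLS trendline; the
   fission preference index is `(F − f)/(F + f)`.
3. **TEM-style 2D morphometry** — profile area and W/H (minimal-width
   enclosing rectangle, rotation-robust), with the three-class scheme
   anchored at a young reference sample's means (defaults A\* = 0.11 μm²,
   R\* = 2.34): elongated (area > A\*, ratio > R\*), medium (area > A\*,
   ratio ≤ R\*), fragmented (area ≤ A\*). Populations are compared by
   Pearson chi-squared.
4. **Clonal-mosaic statistics** — for germaria carrying marker-negative and
   marker-positive GSC lineages, the *relative division rate*
   `r = (prog⁻/GSC⁻) / (prog⁺/GSC⁺)`, maintenance (% germaria retaining ≥ 1
   marked GSC), and partial- vs full-clone composition.

Every stage has a ground-truthed synthetic counterpart in
`mitodyn.synthetic`: 4D ellipsoid scenes with a scheduled or stochastic
fission/fusion program rendered with photobleaching, blur and shot noise;
2D (area, W/H) section populations; and mosaic germaria with configurable
division rates and weekly loss hazards.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a scene of
50 mitochondria over 10 frames with 5 scheduled fissions and 3 scheduled
fusions, rendered with bleaching, blur and shot noise:

```sh
python analysis/01_simulate_scene.py
python analysis/02_segment_track.py
python analysis/03_dynamics_stats.py
```

prints

```
segmented objects per frame: [50, 50, 51, 50, 51, 52, 53, 52, 52, 52]
detected 8 events (5 fissions, 3 fusions)
recovery vs ground truth: {"n_true": 8, "n_detected": 8, "n_correct": 8, "precision": 1.0, "recall": 1.0}
counted events (capped, 3 windows): 5 fissions, 3 fusions
proportional difference (F-f)/(F+f): +0.250
track classes: {'balanced': 0, 'fission_dominant': 5, 'fusion_dominant': 3, 'quiescent': 39}
fragmented counts: [0, 0, 2, 2, 3, 3, 5, 5, 6, 6]
```

Segmentation recovers the true object count at every frame, the tracker
finds all 8 scheduled events and nothing else, and the fission surplus
shows up both in the positive preference index (+0.25) and in the rising
fragmented-count series (fission products fall below the 0.05 μm³ cut).
`analysis/04_tem_morphology.py` and `analysis/05_clonal_mosaic.py` run the
2D morphometry comparison and the clonal statistics the same way; a mock
mosaic with identical lineages gives a relative division rate of
1.025 ± 0.008 (n = 500 germaria).

The same stages are exposed as a CLI (`mitodyn simulate|segment|track|
stats|tem|clonal|run`) for use on real data laid out in the documented
file formats.

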