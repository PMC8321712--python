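# petloop

Dynamic ¹⁸F-FDG PET analysis of the emotional-control loop — the bilateral
prefrontal cortex, striatum, hippocampus and thalamus — as studied in
generalized anxiety disorder (GAD).  The package implements the full
analysis chain as a tested, reusable library:

* **phantom** — synthetic 4D dynamic-PET volumes, ROI label maps, cohorts of
  time-activity parameters drawn from published group summaries, and 2D
  color scenes with ground-truth masks (no patient data is needed anywhere);
* **tac** — per-frame SUVmax extraction, cerebellar standardization
  `SUVmax(standardized) = SUVmax(ROI) / SUVmax(ipsilateral cerebellum)`,
  and the three endpoint metrics of an 11-frame curve sampled every 15 min
  over 0–150 min:

  ```
  peak           = max_t SUVmax(t)
  pre-peak rate  = (peak − SUVmax(0))   / t_peak          [SUV/min]
  post-peak rate = (peak − SUVmax(150)) / (150 − t_peak)  [SUV/min]
  ```

* **saliency** — context-aware saliency maps from LAB block dissimilarity
  `D(p_i, p_j) = d_color / (1 + c·d_position)`,
  `S_i = 1 − exp(−(1/K) Σ_k D(p_i, q_k))` over the K most similar blocks,
  multiscale averaging and a focus-distance context correction;
* **segmentation** — GrabCut: per-class 5-component color GMMs, the Gibbs
  energy `E = U + V` with a contrast-adaptive boundary term
  `V = γ Σ_{(m,n)∈C, a_m≠a_n} exp(−β‖z_m−z_n‖²)`, solved by exact
  Boykov–Kolmogorov min-cut and iterated to convergence;
* **fusion** — a simplified PET/MRI fusion stage: linear
  intensity-hue-saturation transform plus a shift-invariant à-trous
  multiscale merge (PET low band, max-absolute detail bands);
* **stats** — pooled two-sample t-tests from group summaries
  (`df = n₁ + n₂ − 2`), the 8 ROI × 3 metric comparison tables, qualitative
  dynamics labels (slow-in / fast-out / decreased …), and TAC figures;
* **pipeline** — a seeded end-to-end run from cohort simulation to tables,
  with a thin `petloop` command-line wrapper.

## Worked example

```sh
python examples/cohort_comparison.py
```

simulates 20 subjects per group from the published summaries and compares
them (output abbreviated):

```
Peak SUVmax (cerebellum-normalized), simulated n=20/group:
        roi  side  healthy_mean  gad_mean  t_abs     p  significant
 prefrontal  left         2.418     1.915   8.64 0.000         True
   striatum right         2.028     1.983   0.62 0.540        False
hippocampus  left         1.635     1.208   8.84 0.000         True
   thalamus  left         1.748     2.164   8.50 0.000         True

Dynamics labels (GAD relative to healthy):
        roi  side in_label out_label total_label
 prefrontal  left  slow-in  fast-out   decreased
hippocampus right     none      none        none
   thalamus  left  fast-in  fast-out   increased
```

Per cell, `t_abs` is the pooled two-sample |t| for healthy vs GAD and
`significant` flags p < 0.05; the labels condense each ROI's three cells
into its uptake/washout pattern — e.g. the left prefrontal cortex fills
slower, washes out faster and peaks lower in GAD, while the right
hippocampus shows no change.  The other examples (`phantom_tac.py`,
`saliency_map.py`, `grabcut_demo.py`, `fusion_demo.py`,
`full_pipeline.py`) each exercise one capability the same way.

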