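# cardiorqa

Recurrence-based characterisation of arrhythmic activation patterns in
simulated cardiac tissue.

Catheter-ablation planning hinges on telling *where* and *how* an atrial
arrhythmia is sustained: by a spatially pinned ("mother") rotor, by a
meandering spiral wave, or by self-sustained fibrillatory wavelets.
`cardiorqa` implements a complete in-silico pipeline for studying whether
short (1 s) single-site membrane-potential traces, analysed with recurrence
quantification analysis (RQA) and summarised spatially, can make those
distinctions:

1. **Simulate** 2-D cardiac tissue with the monodomain equation,
   `du/dt = D ∇²u − J_ion + J_stim`, where the ionic term is the
   three-current Fenton–Karma model (fast inward, slow inward, slow outward;
   recovery gates v and w).  Scar/fibrosis is modelled as probabilistically
   damaged, non-conductive nodes inside two concentric circles with a
   linearly decaying border zone.
2. **Embed** each site's 1000-sample trace (1000 Hz) by Takens delay
   coordinates — the lag from the first zero crossing of the
   autocorrelation, the dimension from Cao's E1 statistic.
3. **Quantify recurrences**: the recurrence plot
   `R_ij = θ(ε − ‖x_i − x_j‖)` with ε set to 3% of the trace range, and from
   it REC, DET, RATIO, L_max, L_mean, DIV, ENTR, LAM, V_max, V_mean, the two
   leading eigenvalues of the plot, plus approximate/sample entropy and
   spectral organization indices OI₁, OI₂.
4. **Summarise spatially**: per-metric tissue maps, 3×3 smoothing, and
   Moran's I spatial autocorrelation under binary Moore-neighbourhood
   weights.
5. **Detect and classify**: spatially pinned rotors via the joint thresholds
   `L_max ≥ 800 ∧ L_mean > 15` on the metric maps, and per-simulation
   feature vectors (spatial mean + Moran's I of each metric) that separate
   four arrhythmia classes — anchored rotor, meandering rotor, fibrillation,
   and fibrillation coexisting with an anchored rotor.

## Worked example

```python
from cardiorqa.sim import scenario2_config, run_scenario, extract_traces
from cardiorqa.spatial import compute_metric_maps
from cardiorqa.detect import detect_stable_rotors, extract_feature_vector

# curated atrium-sized (4x4 cm) fixture: a rotor pinned beside a small scar
# while wavebreak floods the distal tissue
cfg = scenario2_config("fibrillation_with_anchored_rotor", seed=4)
rec = run_scenario(cfg)                      # 1-s analysis window, 1000 Hz
traces = extract_traces(rec, stride_per_axis=5)   # 1 mm site grid
maps = compute_metric_maps(traces, measures=("DET", "Lmax", "Lmean"))

feats = extract_feature_vector(maps, metrics=("DET",))
print(f"mean DET   = {feats['DET_mean']:.4f}")
print(f"Moran's I  = {feats['DET_moran']:.3f}")

rotors = detect_stable_rotors(maps["Lmax"], maps["Lmean"])
r, c = rotors.centroids[0]
print(f"{rotors.n_components} pinned rotor at site ({r:.0f}, {c:.0f})")
```

Output:

```
mean DET   = 0.9962
Moran's I  = 0.330
1 pinned rotor at site (24, 34)
```

Mean DET near 1 says the per-site dynamics are overwhelmingly predictable
even during fibrillation (diffusion is the only "non-deterministic" input a
single site sees); the intermediate Moran's I reflects contiguous regular
regions around the pinned rotor embedded in chaotic surroundings; and the
joint L_max/L_mean detector flags exactly one connected component, whose
centroid sits at the rotor core (within ~1 mm of the mean position of the
independently tracked phase singularity).

The same pipeline is scriptable from the shell:

```bash
cardiorqa run --out-dir out --seed 4          # simulate → maps → features
cardiorqa study-resolution --recording out/recording.h5 \
    --strides 2,6,20 --out resolution.csv     # 0.4 / 1.2 / 4 mm site spacing
```

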