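# axonmap

Mapping axonal arbors of single neurons from high-density microelectrode
array (HD-MEA) recordings.

Cultured neurons on a CMOS HD-MEA (thousands of electrodes at ~18 μm pitch)
produce tiny extracellular signatures wherever their axons pass an
electrode.  Averaging the voltage around many spikes of one neuron (the
spike-triggered average, STA) suppresses uncorrelated noise by 1/√n and
reveals the neuron's **electrical footprint**: per-electrode waveforms with
negative-peak amplitude V_n and delay τ_n relative to the trigger.  `axonmap`
implements the full workflow for electrophysiologists who want arbor maps at
scale — whole-array activity scanning, switch-matrix configuration planning,
spike sorting and STA assembly, axon segmentation, and quantitative
evaluation — together with a seeded simulator that provides ground truth.

## The segmentation statistic

An action potential sweeping along an axon reaches neighboring electrodes at
nearly the same time, while background electrodes peak anywhere in the
averaging window **T**.  Over each 7-electrode hexagonal neighborhood the
sample standard deviation of delays, s_τ, therefore separates into two
modes:

* axonal patches:   s̄_axon = r / (c·√3)  ≈ 30 μs  (pitch r = 18 μm,
  conduction velocity c = 0.3–0.44 m/s)
* background:       s̄_random = T / √12  ≈ 2.3 ms  (T = 8 ms)

A threshold s_min placed automatically in the valley of the s_τ density,
combined with a causality gate (peaks must follow the axon-initial-segment
peak), yields the axonal electrode set — **method II**.  The classical
**method I** selects electrodes with V_n > 5·s_n.  Both are compared by
Hausdorff distance to ground truth and by ROC/AUC from two-component score
mixtures (two normals for log V_n/s_n; beta + truncated exponential for
s_τ/(T/2)).

## Worked example

```python
import numpy as np
from axonmap import (SimConfig, build_hex_layout, grow_arbor, render_footprint,
                     segment_method_I, segment_method_II, compare_methods)

layout = build_hex_layout(40, 40, pitch=18.0)          # 1,600 electrodes
sim = SimConfig(seed=3)                                # 5 uV noise, c = 0.35 m/s
rng = np.random.default_rng(3)

arbor = grow_arbor(sim, rng, soma=layout.positions.max(axis=0) / 2)
fp = render_footprint(arbor, layout, sim, n_spikes=14, rng=rng, neuron=0)

seg1 = segment_method_I(fp, k=5.0)
seg2 = segment_method_II(fp, layout, rng=rng)
print(f"method I  (V_n > 5 s_n):      {seg1.n_electrodes} electrodes")
print(f"method II (s_tau < {seg2.params['s_min_ms']:.2f} ms): "
      f"{seg2.n_electrodes} electrodes")

report = compare_methods([fp], layout, rng=np.random.default_rng(0))
print(report[["auc_I", "auc_II", "tpr_I", "tpr_II", "s_min_ms"]]
      .round(3).to_string(index=False))
```

prints

```
method I  (V_n > 5 s_n):      156 electrodes
method II (s_tau < 0.70 ms): 125 electrodes
 auc_I  auc_II  tpr_I  tpr_II  s_min_ms
 0.874   0.998  0.596   0.947     0.697
```

The automatic valley threshold lands at 0.70 ms, between the axonal
(~0.03 ms) and background (~2.3 ms) modes.  Method II separates axon from
background almost perfectly (AUC 0.998) and recovers 95% of the axonal
mixture mass at its operating point, whereas the fixed 5·s_n amplitude
threshold leaves ~40% of the (mostly small) axonal signals undetected —
method I's 156 electrodes include false positives far from the arbor, which
the delay statistic rejects by construction.

A closed-loop run from raw simulated traces (activity scan → fixed-electrode
selection → configuration batches → sorting → STA → segmentation →
evaluation):

```sh
axonmap all --out run/ --seed 1 --neurons 3
axonmap plan --electrodes 11011 --amplifiers 126 --fixed 62
```

The `plan` command prints the switch-matrix arithmetic for the standard
11,011-electrode / 126-amplifier chip: 172 configurations, 2.76
configurations per neuron, optimal fixed-electrode count 63 (≈ half the
amplifiers).

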