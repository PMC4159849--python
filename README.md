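# tmdimer

Interface analysis of transmembrane α-helix dimers in coarse-grained
(CG) simulations.

Single-pass membrane proteins such as glycophorin A (GpA) dimerise
through their transmembrane helices, and the packing interface —
classically the GxxxG motif with a right-handed crossing angle of about
−40° — is sensitive to the lipid environment. Self-assembly CG-MD
studies of such dimers produce thousands of frames that visit many
distinct interfaces. `tmdimer` provides the analysis chain for that kind
of data, for computational structural biologists who need to turn raw
two-helix trajectories into interface statistics:

* **Contact maps and interface similarity.** A frame's interface is the
  boolean matrix `C(i,j) = 1` iff residue *i* of helix A and residue *j*
  of helix B are closer than 6 Å (0.6 nm). Similarity to a reference
  interface (e.g. the NMR dimer, PDB 1AFO, which has c(NMR) = 21
  contacts in its 72–96 transmembrane segment) is
  `s = c(TT) / c(NMR)`, the fraction of reference contacts reproduced.
  A dimer counts as stable when ≥ 19 contacts persist for 100 ns.
* **Interface clustering.** Contact maps are compared with the dice
  dissimilarity `d = (c_TF + c_FT) / (2 c_TT + c_TF + c_FT)` and grouped
  by average-linkage (UPGMA) clustering cut at 0.5, giving discrete
  interface clusters whose per-condition frequencies are the headline
  observable.
* **Dimer geometry.** Helix axes, tilt angles, and the signed crossing
  angle Ω (negative = right-handed), plus helix-length distributions
  |BB_i − BB_(i+12)| and top-view density projections.
* **Interface kinetics.** Retention times (dwell durations per cluster)
  and a pruned directed transition network: per cluster only the three
  most frequent outgoing transitions are kept, and transitions observed
  once are discarded as unreproduced.
* **Sampling statistics.** Pearson correlation r between
  cluster-frequency vectors of subsamples of size n (drawn without
  replacement, 1000 permutations), fitted with a double exponential
  `r(n) = a(1 − e^(−bn)) + c(1 − e^(−dn))` whose saturation value
  `lim = a + c` quantifies sampling completeness.
* **Helix-topology augmentation.** Elastic-network-style backbone bonds
  (i→i+3/i+4/i+5 at 0.49/0.61/0.82 nm) appended to GROMACS ITP files,
  with a force-constant screening driver over {None, 500, 1000, 5000,
  10000} kJ·mol⁻¹·nm⁻².
* **Synthetic generator.** A Markov interface model plants discrete
  interface states (helix rotations, crossing angle, separation) with
  exponential dwell times and Gaussian bead noise, so the whole chain is
  testable end to end without running MD.

## Worked example

Generate an ensemble of 300 synthetic self-assembly outcomes for a
"thin-membrane-like" condition, cluster the interfaces, and check
sampling completeness:

```python
import numpy as np
from tmdimer import (
    MarkovInterfaceModel, ConditionSpec, sample_condition_assemblies,
    cluster_interfaces, cluster_frequencies, compute_contact_map,
    crossing_angle, subsampled_correlation, fit_double_exponential,
)
from tmdimer.synthetic import render_assembly_frames

model = MarkovInterfaceModel(seed=0)
thin = ConditionSpec("thin", {"parallel-sym": 0.15, "parallel-rot": 0.15,
                              "right-handed-asym": 0.40, "nmr-like": 0.30})
labels = sample_condition_assemblies(thin, 300, seed=0)
frames = render_assembly_frames(model, labels, seed=1)
maps = [compute_contact_map(f) for f in frames]
clustering = cluster_interfaces(maps)
print(cluster_frequencies(clustering, ["thin"] * len(maps), min_count=3))

angles = [crossing_angle(f) for f, c in zip(frames, clustering.labels) if c == 1]
print(f"cluster 1 crossing angle: {np.mean(angles):.2f} +/- {np.std(angles):.2f} deg")

pool = list(clustering.labels[clustering.labels != -1])
curve = subsampled_correlation(pool, n_values=[5, 10, 20, 30, 50, 75, 100, 130],
                               n_permutations=1000, seed=0, mode="auto")
fit = fit_double_exponential(curve)
print(f"autocorrelation r at n=130: {curve.mean_r[-1]:.3f}; "
      f"fitted limit a+c = {fit.limit:.2f}")
```

Output:

```
condition  thin
cluster
1           101
2            84
3            45
4            31
cluster 1 crossing angle: -32.78 +/- 5.64 deg
autocorrelation r at n=130: 0.919; fitted limit a+c = 0.93
```

The four planted interface states are recovered as four clusters
(ordered by frequency; 39 of the 300 noisy frames fell below the
19-contact stability filter and are excluded). Cluster 1 is the planted
right-handed interface at −32°, measured with the expected spread under
0.05 nm bead noise. The autocorrelation saturates near its fitted limit
of 0.93: two disjoint subsamples of ~130 runs already agree on the
cluster-frequency distribution, i.e. 300 runs sample this (synthetic)
interface space nearly completely.

The same analysis is available from the shell:

```bash
tmdimer run-all --config config.yaml --seed 1 --out results/
```

which writes cluster assignments, per-condition frequency tables,
contact-frequency maps (CSV + PNG), crossing-angle summaries, retention
times, the pruned transition network (CSV + GraphML), correlation
curves with their double-exponential fits, and a manifest with the
seed and config hash. Subcommands (`simulate`, `contacts`, `cluster`,
`geometry`, `kinetics`, `correlate`, `topology`, `noe`) expose the
individual stages.

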