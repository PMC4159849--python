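# Methods

This note documents the models, conventions and numerical choices
behind `tmdimer`, and what the synthetic-data tests do and do not show
about real simulation data.

## Coordinate and mapping conventions

All internal coordinates are nanometres; PDB input (ångström) is
converted on read and back-converted on write. Residue numbering is the
author numbering of the source structure, 1-based, and survives
truncation — the glycophorin A transmembrane 25mer keeps its 72–96
numbering so contact maps stay comparable across constructs.

Backbone beads are placed either at the centre of mass of the backbone
atoms N, CA, C, O with standard atomic masses, hydrogens ignored
(`COM`, the MARTINI 2.x convention) or at the Cα position (`CA`, the
convention of CG parameterisations that define the helix through the Cα
trace). Side-chain beads are optional and use the standard MARTINI
heavy-atom groups (one to four beads per residue; none for Gly/Ala).
For NMR ensembles, model 1 is the default and any model can be
selected; the analysis functions take the model index as a parameter so
sensitivity to the ensemble member can be checked directly.

## Contact maps and the stable-dimer rule

A residue pair (i, j) across the two helices is in contact when its
inter-residue distance is strictly below the cutoff (default 0.6 nm;
"shorter than" is read as a strict inequality, so a pair at exactly the
cutoff is not a contact). The inter-residue distance defaults to the
minimum over all bead pairs of the two residues (`min_bead`), because
side-chain beads carry the GxxxG packing signal; a backbone-only mode
(`BB_only`) exists for sensitivity analysis, and the reference-count
check tries both since the convention behind the published count is not
derivable from the number alone. With an orthorhombic box present,
distances use the minimum-image convention per component.

The stable-dimer criterion (≥ 19 contacts for ≥ 100 ns) is evaluated
per stored frame over contiguous runs: a window qualifies only if
*every* frame in it meets the contact threshold and its time extent
reaches the span. This is the strictest reading; a window-average rule
would classify marginal encounters as stable.

## Interface clustering

Contact maps are flattened to boolean vectors, compared with the dice
dissimilarity (undefined and rejected for two empty maps), and
clustered with average linkage (UPGMA) via `scipy.cluster.hierarchy`.
Flat clusters are cut at cophenetic distance ≤ 0.5 — inclusive, the
semantics of `fcluster(criterion="distance")`. Maps below the
19-contact filter are excluded from clustering and labelled
`UNASSIGNED` (−1); frequency tables count only assigned maps.

Cluster ids are not arbitrary: they are assigned by decreasing global
cluster size, ties broken by first occurrence, so "cluster 1" is always
the most frequent interface of the pooled data. Published cluster
numberings from other runs are artifacts of those runs; correspondence
can only be established by inspecting contact-frequency maps.

## Dimer geometry

**Helix axis.** The axis is fitted from the turn vectors: second
differences `p[i+1] − 2p[i] + p[i−1]` of an ideal helix are purely
radial, so the axis is the normal of their span (smallest right
singular vector). This is exact on ideal helices; a plain PCA of the
bead cloud is biased by about a degree on a 25-bead helix because the
finite helix is phase-asymmetric, which is why PCA is used only as the
fallback for (near-)straight traces, where it is exact. Axes are
oriented N→C.

**Crossing angle.** With axes a_A, a_B and w the closest-approach
vector from helix A to helix B, the signed crossing angle has magnitude
`arccos(a_A · a_B)` and the sign of `(a_A × a_B) · w`. The convention
makes canonical right-handed GxxxG dimers negative (NMR GpA ≈ −40°) and
is chirality-consistent: mirror-reflecting a frame flips the sign,
which is enforced by a property test. Near-parallel axes (cross product
below 1e−8) return 0 with a `parallel` flag instead of an error; if the
axes intersect exactly, the centroid difference substitutes for w.

**Tilt.** Unsigned tilt is the angle between axis and membrane normal
folded to [0°, 90°]. A signed mode projects the N→C direction and takes
the sign of the in-plane x component — a reporting convention that is
only meaningful within one consistent frame.

**Helix length.** Lengths are |BB_i − BB_(i+12)| for *all* valid i
(pooling over start residues and chains), spanning roughly three
helical turns. Histograms use 0.01 nm bins over [1.4, 2.4] nm.
Distribution differences are the L1 distance Σ|p − q| on shared bins
(maximum 2 for disjoint supports) with an optional scale factor.
Published screening-score tables on other data use an unspecified
scale, so only rankings — not absolute values — are comparable across
implementations.

## Interface kinetics

Retention times are contiguous same-label runs times the frame
interval; unassigned frames break runs by default (an optional bridging
mode absorbs gaps between identical labels, keeping total time
conserved). Dwell sums plus unassigned time always equal the
trajectory duration.

The transition network collapses each trajectory's label sequence to
its subsequence of node-set visits with consecutive duplicates merged:
excursions through clusters outside the node set are invisible
("indirect" transitions), and a round trip A→x→A collapses to a
self-visit and is dropped — the natural consequence of the collapse
rule for a case the pruning rules do not address. Counts are pooled
across trajectories before filtering. An edge is kept when its count is
≥ 2 (singletons are not reproduced) and it ranks among the 3 most
frequent outgoing edges of its source; ties are broken towards the
smaller target id. All observed edges stay in the graph with a `kept`
flag so the pruning is auditable.

## Sampling statistics

Frequency vectors are taken over the fixed global cluster space (every
cluster ever observed, zeros included) so that vectors from different
subsamples and conditions are commensurable. Pearson's r is computed on
these vectors; zero-variance vectors make r undefined and are rejected
— a degenerate single-cluster pool is reported as NaN with an
invalid-permutation count, never silently as 1.

Subsampling draws without replacement: autocorrelation splits one
permuted pool into two disjoint size-n halves (for the largest n this
is exactly the first-half/second-half split); cross-condition mode
draws one size-n subsample from each pool independently. Default 1000
permutations; fully seeded and bit-reproducible.

The double exponential `r(n) = a(1 − e^(−bn)) + c(1 − e^(−dn))` is
fitted by `scipy.optimize.curve_fit` with non-negative parameters and
amplitudes bounded by 1 (a correlation coefficient cannot exceed 1;
without the bound, a nearly flat curve can be fitted equally well by an
unbounded amplitude with a vanishing rate, making the extrapolated
limit meaningless). Weighted fits use 1/sd per point, with zero sds
replaced by the smallest positive sd; an unweighted mode exists for
noiseless curves. A deterministic multistart (fixed grid plus seeded
perturbations) guards against local minima, and the result is reported
fast-term-first (b ≥ d), resolving the a↔c symmetry of the model. The
saturation value is `limit = a + c`; it is an extrapolation and is only
meaningful when the measured curve approaches saturation within the
sampled n range.

## Helix-topology augmentation

ITP handling is line-preserving and append-only: the input file is kept
verbatim and harmonic bonds (function type 1) between backbone beads i
and i+3/i+4/i+5 are appended to the `[ bonds ]` section, each tagged
with a comment so augmentation is reversible (`strip_elastic_bonds`)
and collisions with existing bonds raise an error. Default equilibrium
lengths are 0.49, 0.61 and 0.82 nm — averages over known dimerising
transmembrane-helix structures, taken as configuration constants rather
than recomputed, since the underlying structure set is not
reconstructable. The force-constant screen consumes helix-length
distributions from a provider callable (external simulation output or a
synthetic surrogate) and never runs MD itself; provider failures are
recorded per grid point and the screen continues.

## NOE validation

Structures are scored against maximal inter-atomic distance bounds on
atomistic coordinates (the CG→atomistic backmapping that produces them
is an input boundary, not part of the package). Ambiguous selectors
(wildcards) resolve to the minimum distance over matching atom pairs,
the standard treatment of unassigned protons; fulfillment is distance ≤
bound, monotone in the bound by construction. Constraint tables are CSV
(`res_a, atom_a, res_b, atom_b, d_max_nm, source`); the shipped
examples are synthetic schema fixtures, not experimental constraint
lists, which are not redistributable here.

## The synthetic generator

The generator emulates the *statistical* structure of dimer
self-assembly data: a small set of discrete interface states (helix
rotations φ_A, φ_B, signed crossing angle, inter-axis separation), a
continuous-time Markov jump process with exponential dwell times
(memoryless kinetics — the simplest structure consistent with observed
retention-time summaries), isotropic Gaussian bead noise, and
per-condition state-frequency vectors standing in for lipid-dependent
interface preferences. Jumps are resolved at the frame interval;
sub-interval excursions are not represented.

Defaults, chosen once as the study conditions: four states (two
near-parallel interfaces on distinct helix faces, one right-handed
interface at −32°, one NMR-like interface at −40°), inter-axis
separations of 0.65 nm (parallel) and 0.60 nm (crossed) corresponding
to close CG helix packing — these keep every planted dimer above the
19-contact threshold on backbone-only helices, with crossed interfaces
packing tighter as GxxxG-like interfaces do; noise σ = 0.05 nm, which
makes contact maps fluctuate (within-state dice ≤ ~0.4) without
destroying separability (between-state dice ≥ ~0.65, comfortably across
the 0.5 clustering cutoff); mean dwell 100 ns; 300 assembly runs per
condition and 150-scale subsamples for the correlation analysis.

What passing tests show: the analysis chain is internally consistent —
clustering recovers planted partitions exactly, measured crossing
angles equal planted ones to 1e−6° on noiseless frames, dwell and
transition statistics match the generating process within sampling
error, and the fitting machinery recovers known parameters to 1e−4.
What they do not show: anything about force-field realism. The
generator has no energetics, no membrane, no correlated fluctuations,
no intermediate/transition structures between states, and its planted
states are far better separated than the 83-cluster inventory of a real
self-assembly data set. Quantities that depend on real trajectories
(empirical cluster frequencies per lipid, absolute screening scores,
retention times of specific clusters) are outside what this package can
reproduce by construction.

## Problem sizes and determinism

The shipped tests and the acceptance script run desk-scale problems:
ensembles of 30–300 assemblies, long trajectories of 2–20 µs at 50 ns
frame spacing, 10⁵ ns label sequences for dwell statistics, 25–1000
permutations per correlation point. These sizes put every stochastic
check well inside its 3-standard-error band while keeping the full
suite in the tens of seconds. Every stochastic component takes an
explicit seed; the pipeline derives per-stage seeds from one master
seed via `numpy.random.SeedSequence`, and identical seeds reproduce
CSV outputs byte for byte.

## Known limitations

* The experimental reference structure (PDB 1AFO) is not shipped;
  reference-dependent computations require the file locally or network
  access.
* GRO files carry no chain field; the package encodes chain B by a
  resid offset of 1000 in its own trajectory exports, a convention the
  reader inverts. External GRO data should be loaded through MDAnalysis
  directly and converted via the documented containers.
* The transition network is count-based, matching the published
  procedure; it is not a Markov state model and implies no rate or
  lag-time analysis.
* Contact maps treat residues as the contact unit; hydrogen-bond-level
  detail (e.g. the threonine hydroxyl in the GpA interface) is not
  representable in a bead model.
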