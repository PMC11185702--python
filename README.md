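# neckcompare

Comparative connectomics of the neurons that bridge the insect brain and
ventral nerve cord (VNC) through the neck connective: descending neurons
(DNs), ascending neurons (ANs) and sensory ascending neurons (SAs).

When the same nervous system is reconstructed twice — the two hemispheres of
one animal, or a female and a male electron-microscopy volume — the central
analytical problems are: which neuron on one side corresponds to which on
the other; which anatomical compartment and axon tract each neuron occupies;
how strongly cell types connect once raw synapse counts are normalized; how
far each neuron sits from the sensory periphery; and which cell types are
present in only one sex or change shape between the sexes. `neckcompare`
implements this pipeline as a reusable, tested library, together with a
synthetic connectome generator that plants ground truth for every stage so
the whole analysis can be validated end to end.

## What the package computes

**Morphological similarity (NBLAST).** Neurons are skeleton trees (SWC),
resampled and reduced to *dotprops* — points $x_i$ with unit tangents $u_i$.
For a query/target pair, each query point finds its nearest target point and
contributes

$$s_i = |u_i \cdot v_{j(i)}|\; e^{-d_{ij}/\sigma}, \qquad \sigma = 3\,\mu m,$$

summed and normalized by the query self-score, so a neuron scores exactly 1
against itself; the reported score is the mean of the two directions. An
empirical score matrix (distance × dot-product bins) can replace the
parametric kernel.

**Matching.** Right-side neurons are reflected onto the left — about the
midline plane, or through a fitted mirroring registration when the dataset's
space is warped — and the optimal one-to-one assignment maximizing total
NBLAST score pairs the sides. Across datasets, skeletons pass through a
thin-plate-spline transform fitted to landmark pairs, and types are matched
by mutual best score combining morphology with the cosine similarity of
their connectivity to shared partners
($0.7\,\mathrm{morph} + 0.3\,\mathrm{conn}$ by default). Accepted matches
are binned into confidence 1–5; confidence > 3 counts as high.

**Annotation.** A brain neuropil is assigned when it holds ≥ 80% of a
neuron's synapses, a dual label when the top two jointly reach 80% with each
≥ 5%, otherwise *multi*. In the VNC the rule is strict (> 80%), with grouped
labels *ut* (upper tectulum) and *xl* (leg neuropils), *xn* otherwise, and
*XA* for neurons with no cord synapses. Longitudinal tracts are assigned by
simplifying each neuron to its longest neurite from the cord entry point,
NBLAST-clustering, and labelling clusters by the nearest reference tract
centerline.

**Connectivity.** Adjacency matrices count presynapses; analysis converts
them to percent input of the receiving neuron and averages by type. Circuits
are extracted around seed neurons with the two-stage thresholds
weight > 10 ∧ percent output > 0.5%, then augmented with motor/sensory
partners at weight > 5; display pruning at 1% or 2% input follows. Effective
connectivity is the sum over directed paths of products of input fractions
(powers of the fraction matrix). Information-flow ranking spreads from
sensory seed sets — a neuron is visited once a fraction θ = 0.3 of its input
comes from visited neurons (or with probability min(1, f/θ) per iteration in
stochastic mode) — and type-averaged rank vectors are Ward-clustered and cut
(default height 5).

**Dimorphism.** Types compared across the female and male datasets are
classified by fixed precedence: reconstruction problems and known exclusions
(neuropeptidergic, histaminergic, abdominal issues) first; then *sex
specific* (confidently paired left-right but absent from the other sex),
*sexually dimorphic* (matched across sexes but divergent in shape while
consistent across hemispheres), *biological variation* (member-count
differences only), else *matched*. Synapse-density maps use 5 μm voxel
grids; new types are named systematically, numbering down from 999, with an
"f" suffix marking female instances of matched types in comparative tables.

## Worked example

```python
import neckcompare as nc
from neckcompare import pipeline as pl

# generate a small paired female/male connectome with planted ground truth
sc = nc.generate_connectome(nc.smoke_config(seed=11))

# left-right pairing within the female dataset
lr = pl.run_lr_pairing(sc, "F")
print("left-right pairs recovered:",
      pl.evaluate_lr_pairing(sc, "F", lr)["recovery_rate"])

# cross-dataset (female -> male) type matching
cross = pl.run_cross_matching(sc)
ev = pl.evaluate_cross_matching(sc, cross)
print("cross-dataset matches recovered:", ev["recovery_rate"])
print("fraction at confidence > 3:", ev["high_confidence_fraction"])

# information-flow rank by planted layer (stochastic mode, 100 runs)
print(pl.rank_depth_profile(sc, mode="stochastic", n_runs=100, rng_seed=0))
```

Output:

```
left-right pairs recovered: 1.0
cross-dataset matches recovered: 1.0
fraction at confidence > 3: 1.0
   layer      rank
0      1  1.033000
1      2  1.988616
2      3  2.685333
```

All 20 planted left-right pairs and all 20 cross-dataset correspondences are
recovered at high confidence, and the mean traversal distance from the
sensory seeds increases with the planted circuit depth (ANs ≈ 1 hop,
DNs ≈ 2, motor neurons ≈ 3).

A command-line interface mirrors the library
(`neckcompare simulate | validate | nblast | match-lr | match-xd | neuropil |
rank | cluster | density`).

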