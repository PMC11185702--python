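# Methods

This note records the models and procedures `neckcompare` implements, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic study conditions do and do not
establish about real data.

## Skeletons and geometry

Neurons are rooted trees of 3-D nodes (SWC dialect: 7 whitespace-separated
columns, `#` comments, root parent −1). Coordinates are held in nanometres;
the SWC unit scale is a read-time parameter (default 1 nm/unit) so unit
errors fail loudly rather than silently. Validation enforces a single root,
resolvable parents, acyclicity, reachability and finite coordinates; any
negative parent other than −1 is rejected as corruption rather than
tolerated.

*Resampling* subdivides every parent–child edge longer than the target
spacing into equal sub-edges. Original nodes — hence all branch and end
points — are preserved exactly, and total cable length is invariant by
construction; a scheme that re-interpolates along segments would cut
corners on bent neurites and lose both properties.

*Dotprops* place one point per resampled node; the tangent is the first
principal direction of the k nearest points (k = 5, spacing 1 μm by
default — common practice in fly connectomics; both configurable), stored
in its lexicographically larger orientation so signs are deterministic.
The colinearity measure α rescales the leading variance fraction from
[1/3, 1] to [0, 1]. A single-point skeleton receives the degenerate
fallback tangent (1, 0, 0) with α = 0.

*Longest neurite from an entry point*: the entry snaps to the nearest
skeleton node (the anatomical entry is a plane crossing; snapping is the
discrete realization), and the maximal-cable-length path from that node to
a terminal is returned, ties broken by smaller leaf node id.

*Landmark registration* is an exact-interpolation thin-plate spline in 3-D
with the biharmonic kernel φ(r) = r and an affine part, solved as one
dense linear system (regularization 0). Fitting requires ≥ 4 non-coplanar
source landmarks. The same machinery serves two roles: the cross-dataset
bridge (one TPS step fitted to landmark pairs, 2110 pairs at full scale)
and within-dataset mirroring registrations for spaces whose midline is not
an axis-aligned plane.

## NBLAST

Query points find nearest target points (k-d tree; ties by smaller index);
each pair contributes `|u·v| · exp(−d/σ)` with σ = 3 μm and distances in
μm. Raw scores are normalized by the query self-score (exactly n for the
parametric kernel, so self-comparison is exactly 1), and pair scores are
the mean of the two directions. The parametric kernel is the default
because it is self-contained and analytically testable; empirical score
matrices (distance × |dot| bins, open top bins) can be loaded from CSV.
α-weighting of the dot product is available but off by default — published
variants differ, so the choice is an explicit flag rather than a hidden
convention.

## Matching

Within a dataset, right-side neurons are reflected onto the left (plane
reflection, or a fitted mirroring transform when supplied) and the
left–right pairing is the optimal one-to-one assignment (Hungarian
algorithm) on mean NBLAST scores; pairs below τ_pair = 0.3 are reported
unmatched. The manual matching the pipeline formalizes was a judgment
process; optimal assignment is its deterministic counterpart, and all ties
are broken lexicographically by neuron id.

Across datasets, units are types/groups: a group's morphology score
against another group is the mean over members of the best member-wise
score, combined with the cosine similarity of partner-weight vectors over
a supplied partner correspondence as
`combined = 0.7·morph + 0.3·cosine` (weights renormalize onto morphology
when no cosine is available). Mutual-best pairs with combined ≥ τ_match =
0.4 are matched; above threshold but not mutual-best is ambiguous.
Confidence bins the combined score at cuts (0.2, 0.4, 0.6, 0.8) into 1–5
with > 3 high. The cuts realize a 1–5 scale that was assigned manually at
source; they are defaults, not calibrated claims, and are recorded in
outputs.

## Neuropil and tract annotation

Brain rule: single label at ≥ 80% of a neuron's synapses; ordered dual
label when the top two neuropils by count jointly reach 80% with each
≥ 5%; otherwise *multi*. Only the top-2 pair is tested — the one
order-free deterministic reading. The brain threshold is inclusive (≥)
and the VNC threshold strict (>), following the respective rule wordings
literally; both are configuration constants. VNC abbreviations map NTct,
WTct, HTct, IntTct, LTct, LegNpT1–3, mVAC, Ov, ANm to nt, wt, ht, it, lt,
fl, ml, hl, mv, ov, ad (the source abbreviation list prints "hl" twice;
this resolution — haltere tectulum "ht", hind leg "hl" — is inferred from
usage). DNs are evaluated on presynapse counts, ANs on postsynapse counts;
zero-synapse neurons are *XA*; groups whose members disagree are re-scored
on element-wise mean counts.

Tracts: longest-neurite dotprops, all-by-all NBLAST, average-linkage
clustering on 1 − mean score cut at 0.75, clusters labelled by the
reference centerline with minimal mean point distance, *none* beyond
τ_tract = 20 μm. Reference tracts are centerline point sets rather than
meshes: mesh overlay was a manual step, centerline distance is the
automatable proxy.

## Connectivity analysis

Adjacency weights are presynapse counts. Input fractions divide each
column by its sum; autapses are kept in the adjacency but excluded from
the fraction denominators so a neuron cannot inflate its own input.
Circuit extraction: stage 1 keeps seed partners with weight > 10 and
> 0.5% of the presynaptic neuron's total output (evaluated per neuron, in
both directions around the seeds); stage 2 adds MN/SN/SA partners above
weight 5 — these classes are systematically under-reconstructed and
sensory neurons connect as populations; edges are then annotated with
(optionally type-averaged) input percent and pruned below the display
threshold (1% and 2% are the conventional display cuts). Extraction is
monotone: raising any threshold never adds a node or edge.

Effective connectivity is defined here as the sum over directed paths of
products of input fractions, i.e. entries of powers of the fraction
matrix, cumulated over 1..max_hops — the quantity is named but not defined
at source; this definition is stated explicitly as the package's.

Information flow: seeds start visited at distance 0; at iteration t an
unvisited neuron with visited-input fraction f ≥ θ (deterministic) or with
probability min(1, f/θ) (stochastic) is visited at distance t; θ = 0.3,
max_iter = 12 (the observed rank range runs 1–12; whether that reflects an
iteration cap is not stated — 12 is a default, not a claim). Stochastic
distances average first-visit iterations over seeded replicates and are
reproducible for a fixed seed. Type averaging ignores unreached members;
clustering imputes unreached to max_iter + 1, uses Ward linkage on
Euclidean distances (the source names no linkage; cut heights are only
meaningful relative to a linkage, so both are recorded in output
metadata), and cuts at height 5 by default.

## Dimorphism classification

Per-type evidence (left-right pairing, cross-dataset status and morphology
score, member counts, exclusion flags) passes through a fixed precedence:
reconstruction_issue (not well reconstructed, or abdominal-ganglion
issues) > excluded (neuropeptidergic, histaminergic AHNs) > unpaired >
sex_specific (no cross-dataset match) > sexually_dimorphic (matched with
cross morphology score < τ_shape = 0.55 while left-right consistency
≥ τ_lr = 0.7) > biological_variation (member-count mismatch only — count
differences are explicitly not dimorphism) > matched. The two thresholds
quantify a judgment that was qualitative at source; they are reported with
every classification. Ambiguous cross matches carry no dimorphism evidence
and default to matched.

Synapse-density grids tile space into cubic voxels (default 5 μm, roughly
isotropic) with the origin at the filtered data minimum (stored in the
header so grids are comparable); boundary points fall to the higher-index
voxel by the floor convention. Counts are conserved exactly under
filtering and refinement. New systematic names number down from 999 within
a context (target neuropil for DNs, hemilineage for ANs), skipping
collisions; the female "f" marker is appended to the type name.

## Synthetic study conditions

The generator emulates the statistical structure of paired-sex EM
connectomes at desk scale: type templates grown by a seeded branching
random walk (lognormal segment lengths, mean 4 μm, σ_log = 0.35; branch
probability 0.12; direction jitter 0.35; ≤ 60 nodes) inside axis-aligned
neuropil compartments laid out on a grid (80 μm boxes, 11 VNC
compartments); left/right instances related by mirror reflection plus
0.4 μm Gaussian node jitter; the male dataset additionally passes through
a planted affine (4° rotation, 1.05 scale, (20, 10, 5) μm translation)
plus a smooth sinusoidal warp (3 μm amplitude, 250 μm period). Landmark
tables sample a noisy 6³ grid through the true transform; per-dataset
mirror landmark tables supply the mirroring registrations (in the warped
male space the midline is not a plane — as in real volumes, where
mirroring is itself a registration). Connectivity is a layered type-level
weight matrix W (sensory modalities → ANs → DNs → motor types, with
direct sensory→DN drive capped below the spreading threshold so planted
layer depth is identifiable); realized counts are Poisson draws around W
per member pair — the minimal noise model, since the analysis surface
only needs controllable signal/noise. Synapse sites sit on the AN
dendrite when the target is an AN and on the presynaptic arbour
otherwise, so each matchable neuron's rule-relevant synapses lie in its
home compartment and the planted neuropil label is well defined.
Sex-specific types are instantiated in one dataset only; dimorphic types
have the subtree closest to half their arbor scaled 1.6× about its root
in the male dataset — chosen once so the morphological divergence is
comparable to, but distinguishable from, cross-dataset noise.

Two presets define the standard fixtures: *smoke* (20 types, no planted
specials) and *recovery* (60 types, 3 female-specific + 2 male-specific +
5 dimorphic). Generation is deterministic per seed.

What the generator does **not** emulate: reconstruction artifacts and
proofreading error, mesh-based compartments, population types with
variable member counts, neurotransmitter identity, inhibition,
biophysically realistic arbors, or realistic synapse-count distributions
(overdispersion beyond Poisson). Passing the recovery criteria therefore
shows the pipeline is correct and well calibrated under its stated noise
model — not that real cross-sex matching at EM scale achieves these rates;
the headline biological numbers from full connectomes are out of scope by
design.

## Problem sizes and numerical conventions

The test suite and acceptance script run at the scales the properties are
stated for: 10,000 random count vectors for the neuropil rule oracles;
exhaustive permutation oracles up to 8 neurons per side; brute-force path
enumeration on graphs ≤ 10 nodes, ≤ 4 hops (agreement to 1e−12);
100-replicate stochastic ranking; the 60-type recovery connectome for
matching and dimorphism recovery (~270 neurons per dataset, ~80k synapse
rows across both). Exactness tolerances: NBLAST closed forms and
self-scores to 1e−12; TPS landmark interpolation to numerical conditioning
(nm-scale residuals on 300 μm volumes); assignment optimality gap 0 to
1e−9. All randomness flows through seeded `numpy` generators; iteration
orders are fixed and ties broken lexicographically throughout, so every
result is reproducible bit-for-bit given a seed.

## Known limitations

- The confidence cuts, matching weights and dimorphism thresholds are
  declared defaults standing in for manual judgments; they are not
  calibrated against annotator decisions.
- Only a single TPS step bridges datasets; real inter-template bridges are
  sequences of registrations that a single TPS only approximates.
- Tract assignment labels clusters by centerline distance; neurites that
  genuinely switch bundles mid-course are labelled by their dominant
  cluster.
- The brain dual-neuropil rule tests only the top-2 compartments by count;
  other 80%-reaching pairs are deliberately not considered.
- Stochastic information-flow ranks depend on θ and the iteration cap;
  cross-study comparability requires matching both.
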