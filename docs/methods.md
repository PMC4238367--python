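# Methods

`meaprior` estimates the functional connectivity of a cultured neuronal
network recorded on a high-density micro-electrode array (HD-MEA; by
default a 64 × 64 lattice of square electrodes at 42 μm pitch), using a
structural connectivity prior computed from a fluorescence image of the
same culture. This note documents the model, the parameter choices, the
synthetic benchmark, and the known limitations.

## Structural prior

**Directional features.** The image is tiled into one patch per
electrode (patch boundaries are the rounded positions of the ideal float
lattice after an optional registration offset and pixel scale, so patches
tile the active area without overlap). In each patch, line segments
approximating neurites are detected with a Canny edge map followed by the
probabilistic Hough transform. Each segment endpoint contributes one Von
Mises component: the mean direction μ is the endpoint's bearing on the
circle circumscribing the patch (counterclockwise from the +x image
axis), and the concentration is

    κ = kappa_scale / (d + ε),   capped at κ_max,

where d is the endpoint's distance to the patch boundary in pixels —
endpoints far from the boundary exit the patch at an uncertain angle and
get a diffuse component. Mixture weights are the segments' Hough votes,
normalized over the 2n endpoints of the patch's n segments. Since the
probabilistic Hough transform returns endpoints but no accumulator count,
a segment's vote is the number of edge pixels within one pixel of the
rasterized segment, which coincides with the accumulator count for clean
lines. Defaults: `kappa_scale = 10 px`, `ε = 1 px`, `κ_max = 1e4`
(numerical cap; an endpoint exactly on the boundary otherwise produces an
unbounded concentration), Canny σ = 1 px, Hough threshold 5 votes,
minimum length 8 px, maximum gap 3 px. The Hough parameters were tuned
on the synthetic renderer and are recorded in every output's metadata.

The mixture is discretized by integrating its density over eight 45°
sectors centered on the neighbor bearings (E = 0°, NE = 45°, …, ordered
E, NE, N, NW, W, SW, S, SE). Sector masses use the exact Von Mises CDF;
a patch with no detected segment yields the all-zero histogram. The
discretization is tested against adaptive quadrature of the mixture
density to 1e-6.

**Heat kernel.** The 8-connected lattice adjacency is
`A(x, y) = f_x[x→y] + f_y[y→x]` (symmetrized sum of the two directed
histogram entries). With the graph Laplacian `L = D − A`, the heat kernel

    h_t = exp(−t L) = Σ_i exp(−λ_i t) φ_i φ_iᵀ

is computed by dense eigendecomposition for up to 4096 nodes and by the
scaled-and-squared matrix exponential beyond that; the two routes agree
to 1e-8 and both are row-stochastic by construction (`L·1 = 0`).
Diffusion time defaults to `t = 25`, the published operating point for
the 64 × 64 lattice: larger t explores more of the graph (the number of
node pairs receiving heat above any fixed ε is non-decreasing in t) at
the cost of mixing neighboring feature contributions.

**Normalization.** The heat map is restricted to *seed* electrodes —
those with at least one neuron in their recording area, from a
user-supplied neuron map or the simple intensity blob detector — and
divided by its maximum. Because the diagonal self-heat term always
dominates, the default divides by the maximum *off-diagonal* seed-pair
entry so that actual candidate links span (0, 1]; normalization by the
full-matrix maximum is available as `normalize_mode = "full"`. The
normalized map's diagonal is zeroed.

**SC graph and structural distance.** Seed pairs with normalized heat
≥ `sc_threshold` (default 0.05) form the SC edge set; each edge carries
the euclidean distance between electrode centers in μm (pitch for axial
neighbors, pitch·√2 for diagonal ones, and longer for non-adjacent
pairs). The structural distance d_xy is the shortest-path length over
this weighted graph (Dijkstra), under the assumption that minimal paths
are statistically the most probable anatomical routes. Distances are
normalized by the maximum finite off-diagonal value; unreachable pairs
are flagged and assigned the maximum normalized distance 1. The default
threshold was chosen on the synthetic benchmark as the largest value at
which the SC graph still recovers ≥ 90% of the ground-truth neurite
edges on a noise-free rendering (higher thresholds trade recall away
quickly because heat spreads along multi-patch neurites).

## Functional graph

For every unordered pair of active electrodes (both with ≥ 1 spike) the
cross-correlogram is computed in Δτ = 0.5 ms bins over a ±50 ms window:
bin k counts spike pairs with time difference in
[kΔτ − Δτ/2, kΔτ + Δτ/2), normalized by √(N_x·N_y). The window
comfortably exceeds the largest physiologically meaningful latency
(array diagonal / 400 mm/s ≈ 9.5 ms). The peak statistics are the
maximum value C_P, its lag C_τ (ties broken toward the smallest |lag|,
then the positive lag, favoring the proximate causal reading), and the
raw count C_O at the peak bin; the identity
C_O = C_P·T·√(MFR_x·MFR_y) links the raw and normalized scales and is
asserted in the tests.

**Velocity filter.** A link is physiologically implausible when
|C_τ| < d/v_max with v_max = 400 mm/s, the upper bound on propagation
velocity for in-vitro preparations: no signal can cover the straight-line
inter-electrode distance faster. Coincident electrodes (d = 0) are never
discarded by this filter.

**Dithering null.** Significance is assessed against surrogate data:
every spike of both trains of a sampled pair is jittered by an i.i.d.
uniform offset in ±5 ms (clipped to the recording interval, which avoids
artificial edge coincidences; spike counts and rates are preserved and
ISI distributions approximately so), and the correlogram peak is
recorded; this is repeated 100 times per pair over a seeded random
sample of min(500, all) active pairs. C_s is the empirical 95th
percentile (p = 0.05) of the pooled null peaks — one global threshold
per recording. On independent Poisson pairs the fraction of links
exceeding C_s stays within the nominal 5% plus sampling noise.

## Structural refinement

Links incident to electrodes with no neuron are pruned first (spurious
activity from noise or dendritic pickup). The surviving velocity-filtered
links are then reweighted:

    W(x, y) = C̃_P(x, y)^(1 + d_xy)

with C̃_P the peak normalized by the maximum over the links entering
refinement (the post-pruning, velocity-filtered population) and d_xy the
normalized structural distance. The exponent form is the reading
consistent with W ∈ [0, 1] and with the intended penalty behavior: for
fixed d > 0 the relative attenuation W/C̃_P increases with C̃_P, so weak
correlations are penalized harder by distance while strong functional
evidence survives even over long paths — the opposite of a negative
exponential weighting C_P·e^(−d), which attenuates strong links the
most in absolute terms. Functionally linked pairs with no structural
path keep their link but carry the maximum penalty d = 1 plus a flag.

The final threshold W_s is the 95th percentile of the identically
processed null: each null peak is normalized by the same maximum
(clipped to 1 if it exceeds it, so the domain of the reweighting law is
respected) and reweighted with the structural distance of its own
sampled pair. A link is retained iff W ≥ W_s.

A caveat worth stating: the retained count is *usually* but not
*necessarily* smaller than the C_s-thresholded count. W_s penalizes the
null sample by the null pairs' own distances, so a link population with
systematically shorter structural distances than the random null sample
can pass at more than the nominal rate. On the synthetic benchmark this
tendency holds for most but not all seeds; it is a property of the data,
not an invariant of the construction.

## Link classification

Each labeled (retained/discarded) link is described by C_P, C_O, C_τ,
the correlogram entropy C_H = −Σ C_n(τ)·log₂ C_n(τ) with
C_n = C/ΣC (0 bits for a single occupied bin, log₂K for K equal bins;
broad, unreliable correlograms score high), and the two mean firing
rates. A linear SVM (C = 1, features standardized per training fold)
under stratified, seeded 10-fold cross-validation scores every non-empty
combination of the five feature groups {C_P}, {C_O}, {C_τ}, {C_H},
{MFR_x, MFR_y} — 31 subsets, reported as a ranking. The analytic noise
level ACC_η = 100·max(class counts)/total is the accuracy of the
constant majority classifier and marks the plateau of uninformative
subsets. On the synthetic benchmark the retained class shows lower
median C_H and |C_τ|, i.e., sharper and more physiological correlograms.

## Synthetic benchmark

The generator emulates the validation regime of sparse cultures: neurons
on distinct electrodes (one per electrode), joined to neighbors within
3 pitches by curved polylines (midpoint perpendicular noise, so path
length ≥ straight-line distance) with connection probability 0.3; half
of the neurites carry a directed coupling. The image renderer draws
anti-aliased bright-on-dark neurites with soma blobs, a Gaussian PSF
(σ = 1 px) and additive Gaussian noise (σ = 0.05 by default) at 16 px
per electrode. Spike trains are homogeneous background Poisson processes
at 1 Hz (matching the order of the reported culture firing rates);
each source spike elicits a target spike with probability 0.5 at delay

    delay = 1 ms synaptic latency + path length / 200 mm/s  (± 0.5 ms jitter),

propagating for up to three synaptic hops. The synaptic latency term
matters: without it, short-range couplings peak at zero lag and would be
discarded by the velocity filter, which no real monosynaptic connection
would be. All delays respect the 400 mm/s bound by construction. A
further 10% of electrodes spike at the background rate without holding a
neuron, reproducing the spurious no-neuron activity that the pruning
stage exists to remove. Everything is reproducible from a single seed.

What the generator does **not** emulate: bursting and rate
nonstationarity (backgrounds are homogeneous Poisson, which keeps the
null analyzable), inhibitory links (the correlogram approach only
detects excitatory coupling), optical artifacts beyond blur and additive
noise, and multi-neuron electrodes. Passing the end-to-end tests
therefore demonstrates correctness of the estimators under these
idealized conditions, not performance on bursty biological recordings.

The benchmark's headline check runs the full pipeline on ten seeded
16 × 16 cultures (100 neurons, 300 s — sizes chosen to keep a complete
multi-seed study comfortably within a single-core test run while leaving
every stage non-trivial): the structurally refined graph must beat the
C_s-only graph in precision against the ground-truth couplings with
recall within 15%. Typical values are ~21% vs ~22% precision at 100%
recall — modest, because most false positives are *short-range*
polysynaptic correlations that are genuinely topology-coherent and thus
deliberately spared by the prior.

## Numerical and degenerate-input conventions

- Eigenvalues of the Laplacian are clipped at 0 before exponentiation;
  the heat matrix is explicitly symmetrized (machine-precision cleanup).
- An all-zero correlogram yields C_P = 0 with an undefined-lag flag;
  such links never survive filtering. Correlogram entropy is undefined
  (an error) for all-zero input.
- With a single link entering refinement both C̃_P and d_norm normalize
  to 1 (degenerate maximum).
- A silent electrode never enters the functional graph; an empty seed
  set or an electrode missing from the neuron map is an error, not a
  silent skip.
- Jittered spikes are clipped to [0, t_r], not wrapped.
- Percentages in the accounting report are rounded to one decimal.
- All randomness flows from explicit seeds (patch-level Hough RNGs are
  spawned from the pipeline seed); rerunning a pipeline with the same
  inputs and seed produces byte-identical output bundles.
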