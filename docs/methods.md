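# Methods

## The statistical model

Two-color single-molecule localization microscopy (SMLM) yields, per color
channel, a table of fitted fluorophore positions. Because one fluorophore
blinks and is detected many times, every localization map is clustered at
the scale of the localization error even when the underlying biomolecules
are completely spatially random (CSR). Classical univariate cluster
statistics therefore cannot distinguish biomolecular nanoclustering from
overcounting.

The test implemented here sidesteps the blinking problem by working on
*cross-channel* correlations only. Let `cdf(r)` be the empirical
cumulative distribution of distances from each localization of the query
channel (red) to its nearest neighbor in the reference channel (blue).
Under the null hypothesis that the two channels are independent, this
distribution is unchanged when the query channel is translated by an
arbitrary vector with periodic wrap-around at the region of interest (a
toroidal shift): the shift destroys any cross-channel correlation while
preserving each channel's internal structure, including all blinking
artifacts. Each of N random shift vectors, drawn uniformly over the ROI
rectangle, therefore produces one exact draw from the null distribution of
the summary statistic

    g = ∫₀^{r_max} cdf(r) dr = r_max − mean_i( min(r_i, r_max) ),

and ranking `g_data` within the union of the N control values (descending
for the clustering alternative; ascending for repulsion) gives the exact
one-sided Monte-Carlo p-value `p = rank / (N+1)`, supported on the grid
{1/(N+1), …, 1}. With the default N = 99 the resolution is 0.01, and the
rejection rule `p ≤ α` has false-positive rate exactly α whenever α is a
grid multiple.

Statistic variants: the mean distance to the k nearest cross-channel
neighbors (k = 3, 5, 10) and the per-point cross-type Ripley statistic
`L_cross(r*) = sqrt(K̂_i/π)` with
`K̂_i = (area/n_ref) · #{reference points within r* of query point i}`,
without edge correction (edge effects are shared identically by data and
controls, so they cancel in the ranking). Since clustering produces
*large* L values and hence a *small* integral of `cdf(L)`, the L_cross
ranking direction is reversed relative to the distance statistics.

Key conventions:

- `r_max = "auto"` uses the maximum statistic value over the data *and*
  all control collections, so every cdf reaches 1 inside the integration
  window and the test has no free parameter. A finite user-supplied
  `r_max` (of order localization error + expected cluster size) can be
  set when prior knowledge exists.
- Rank ties are resolved to the worst rank (conservative, favors the
  null); exact ties are measure-zero with continuous coordinates.
- The query channel is the one that is shifted. Only cross-correlations
  enter the statistic, so swapping the roles changes nothing about the
  null law.
- The degenerate shift v = (0,0) has probability zero and is not
  excluded.

## The simulator

`clasta.simulate` generates synthetic two-color experiments stage by
stage, emulating how a real localization map arises:

1. **Molecule patterns** in a 10 × 10 µm² ROI at 75 molecules/µm² by
   default: CSR monomers; n-mers (n = 1–4, all protomers exactly at the
   n-mer position; a configurable nonzero spacing is deliberately not
   offered since label linkage error is absorbed by the localization
   error); circular domains (radius 20–150 nm, 3–25 domains/µm²) or
   80 × 400 nm² rectangles, with a chosen fraction of molecules
   Poisson-allocated to domains and the rest rejection-sampled outside
   all domains. Domains may overlap and may straddle the ROI edge.
2. **Labeling**: each molecule independently carries no label (prob.
   1 − efficiency), a red label (efficiency × ratio) or a blue label —
   never both. Presets: *ideal* = 100% efficiency, *realistic* = 40%.
3. **Blinking**: each label yields m ≥ 1 detections. Detection-count
   distributions are pluggable (log-normal rounded up, geometric, fixed,
   or an empirical table). The bundled SNAP-tag-like defaults are
   log-normal with (µ = 1.1, σ = 0.9) for the red channel (≈ 5.5 mean
   detections) and (µ = 0.9, σ = 0.8) for blue (≈ 4): heavy-tailed counts
   of a few detections per label, with the far-red dye re-activating more
   often, as is typical for SNAP-tag dye pairs. Frames are i.i.d. uniform
   over the 10,000-frame movie by default; a geometric on/off burst model
   is available (only drift is frame-sensitive, so the default is the
   simpler law).
4. **Localization error**: isotropic Gaussian with σ = 30 nm (typical
   SMLM precision), identical for both channels.
5. **Unspecific signal** (*realistic* preset): 5 unspecifically bound
   labels/µm² per channel blinking like the channel's specific labels,
   plus false-positive background of 1 (red) and 2 (blue) signals/µm²
   with a short geometric blink (mean 2 detections) standing in for
   background measured in unlabeled cells.
6. **Drift and chromatic aberration**: linear stage drift `x → x + d·t`
   applied identically to both channels (alternating-laser acquisition);
   residual chromatic aberration as the linear radial field
   `(x', y') = β·(x − x₀, y − y₀)`, β up to 0.06, center (2.5, 2.5) µm,
   red channel only.

Records pushed outside the ROI by stages 4–6 are kept, not wrapped or
clipped (wrapping would create artificial correlations); the analysis
crops to an analysis ROI, as one would crop a real dataset.

**Border handling in validation runs.** Because molecules exist only
inside the simulated field, localization blur carries records *out*
across the field border with nothing blurring in, so both channels are
depleted in the same ~3σ border band. That shared band is genuine
cross-channel structure: it survives in the observed pair but not in the
toroidally shifted controls, and analyzing the full field therefore
inflates the false-positive rate (measured here: ≈0.09 instead of 0.05
at α = 0.05, with mean null p ≈ 0.45 instead of 0.505). A real cell
extends beyond any sensible ROI, so real data has no such band — which
is why the method's usage guidance is to place the ROI centrally, away
from cell edges. The power harness follows the same principle: it crops
the analysis to the simulated field inset by `analysis_margin` (default
100 nm, a little over 3 localization-error sigmas; ~2% of the field
marginal area). With the inset, the measured null calibration is exact
within binomial error. The margin is exposed on `estimate_sensitivity`,
`run_grid` and `clasta power --margin`; setting it to 0 reproduces the
full-field behavior.

What the simulator does **not** emulate: camera noise and PSF rendering
(positions are drawn directly), 3D sample topography, spatially varying
labeling or detection efficiency, and the true empirical SNAP blinking
histograms (not publicly tabulated; the log-normal stand-ins match their
qualitative shape). Passing tests therefore validate the statistical
machinery under realistic artifact models, not any particular dye's
exact blinking law — which is precisely the property the test claims:
its null calibration is independent of the blinking distribution.

## Power analysis

`estimate_sensitivity` runs the simulate → crop → test pipeline over
replicate seeds and reports sensitivity = (# replicates with p ≤ α)/n.
On a truly random scenario this is the false-positive rate and must equal
α. Sub-seeds are spawned from the master seed by replicate index
(`SeedSequence.spawn`), so every (seed, scenario, replicate) triple maps
to one deterministic p-value regardless of execution order; grid cells
are keyed the same way by cell index.

Default replicate counts follow the validation study design (100
replicates per condition, N = 99 controls); both are flags. The bundled
validation runs use 400 null replicates for calibration/uniformity
checks, 100 for the drift scenario, 20 for the strongly clustered
scenario, and a reduced molecule density (10/µm², 24 replicates) for the
oligomer-order monotonicity check — at 75/µm² all oligomer orders
saturate at sensitivity 1 and an ordering check would be vacuous.

## Numerical choices

- Neighbor queries and disc counts use a k-d tree built once per test on
  the reference channel; only the query channel moves under shifts.
- The cdf integral is evaluated in closed form (exact for a step
  function), not by quadrature.
- Distances use the plain Euclidean metric even for shifted controls:
  the torus wraps *points*, not the metric, mirroring how shifted real
  data would be analyzed.
- ROI membership is half-open [min, max) so the toroidal wrap is a
  bijection; the pre-shift containment check accepts the closed
  rectangle because data read without an explicit ROI carries its exact
  bounding box.
- Degenerate input where every statistic value is exactly zero (e.g.
  identical coordinate duplicates only) falls back to r_max = 1 nm to
  keep the integral defined; real data never hits this.

## Known limitations

- The p-value granularity is 1/(N+1); N = 99 cannot resolve p below
  0.01. Increase `--n-controls` for smaller significance levels.
- The test detects *cross-channel* association only; univariate
  clustering confined to one channel is invisible to it by design.
- A single global toroidal shift assumes approximate stationarity of
  each channel across the ROI; strong large-scale density gradients
  (cell edges, vesicular structures) can inflate either error rate, so
  the ROI should be a central, structure-free region of the cell.
- No multiple-testing correction across cells or images is applied;
  aggregating per-cell p-values is left to the user.
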