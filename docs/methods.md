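# Methods

## The model

`irca` treats one ramanome — an n × F matrix of n single-cell Raman spectra
on a shared F-point wavenumber grid — as a sample from a heterogeneous
population in which each cell occupies its own point along one or more
metabolic processes. Feature intensities are proxies for metabolite pool
sizes. For every unordered pair of features the package computes the sample
Pearson correlation across cells, with a two-sided P-value from the
t-transform t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom (|ρ| = 1 maps to
P = 0). Pairs involving a zero-variance feature yield NaN and are excluded
from every network but flagged, not dropped silently.

Interpretation is by thresholding. A *significant* link (P < α, default
0.05) marks a candidate metabolic interaction; a *strong negative*
correlation (ρ ≤ ρ₀, default −0.6, and P < α) marks a candidate conversion:
across cells, one pool grows at the other's expense. The thresholded graph
(IRCN) uses as nodes only features incident to at least one kept edge; the
full feature count is retained separately because the `ave_PCC` statistic
divides the summed kept-edge correlations by C(F, 2), the number of all
possible feature pairs. The pair denominator is deliberate: it makes
`ave_PCC` a density-weighted conversion strength that is comparable across
networks of different sizes, and it reproduces the magnitudes this statistic
is conventionally reported at; a node denominator remains available via
`network_stats(..., ave_pcc_denominator="nodes")`. P-values are raw by
design — the ρ ≤ −0.6 ∧ P < 0.05 contract is a joint screen, not an
inference procedure; a Benjamini–Hochberg option is not applied by default.

Network summaries are `num_node`, `num_edge`, `num_module` (connected
components), `size_largest_module`, `density` (E / C(N, 2) over incident
nodes), `ave_degree` (2E/N) and `ave_PCC`. Degree rankings break ties by
ascending wavenumber so all outputs are deterministic.

For a time series of ramanomes on one feature set, the Δρ map records, per
pair, max_t ρ_t − min_t ρ_t together with the attaining time indices. Pairs
whose correlation flips sign across the course (e.g. joint degradation early,
conversion late) surface as hot spots. NaN time points are skipped; a pair
with fewer than two valid time points gets NaN.

## Standardization

Ramanomes from different batches may differ in spectral range and
resolution, so before any cross-cell or cross-ramanome comparison each
spectrum is (i) cropped to the analysis window (default the 600–1800 cm⁻¹
fingerprint region; widen to 600–3050 cm⁻¹ when the C–D/C–H bands are
needed), (ii) linearly resampled to a 1 cm⁻¹ grid, and (iii) divided by its
trapezoidal area. Order is fixed as crop → resample → normalize and the
procedure is idempotent. Area normalization removes per-cell multiplicative
acquisition factors (laser coupling, focus); Pearson correlation then removes
any remaining per-feature affine differences. One consequence worth knowing:
normalization imposes compositional closure — dividing by total area couples
all features through the denominator — which *strengthens* negative
correlations between dominant anticorrelated pools (measured on synthetic
data: a planted −0.79 amplitude correlation is observed at ≈ −0.86 after
normalization). This bias is inherent to area-normalized intensity data, not
an artifact of this implementation.

Optional per-spectrum corrections precede standardization: subtraction of
the mean of background spectra taken around the cell, and iterative
polynomial baseline removal (fit a degree-d polynomial, clamp the working
signal to the fit from above, repeat until the fit moves less than a
tolerance; default degree 7, tolerance 1e-6, 100 iterations with a warning
on non-convergence). The clamp-above iteration carries the method's known
small downward bias away from peaks; peak-band quantities are unaffected
(band-restricted recovery error of an injected Gaussian peak is ~0.1 %).

## Phenotypes

Named peaks resolve to the nearest grid point within ±1 cm⁻¹ (an error
otherwise — a fingerprint-only spectrum cannot silently answer for
2851 cm⁻¹). Band areas integrate trapezoidally, the same rule used for
normalization. Composite phenotypes: DU = I(1658)/I(1441) (unsaturated C=C
over saturated C–H₂, a lipid-unsaturation index); CD ratio =
A(2040–2300) / [A(2040–2300) + A(2800–3050)], the deuterium fraction of the
C–D + C–H stretch region, a proxy for heavy-water metabolic incorporation,
bounded in [0, 1] for non-negative spectra. Both are invariant under global
scaling of a spectrum. The heterogeneity index of a feature is its sample
(n−1) relative standard deviation across cells; constant features give 0
exactly, zero-mean features NaN with a warning.

PLSR content models map full spectra to metabolite contents. Fitting is
NIPALS partial least squares with mean centering and no variance scaling
(delegated to scikit-learn's `PLSRegression`, verified in the test suite
against an independent hand-written NIPALS iteration); prediction is the
linear map y = (x − x̄)·b + ȳ. The component count defaults to the
leave-one-out cross-validation minimizer of PRESS, since training sets here
are small (tens of population means). Composite phenotypes can be appended
to the feature matrix and correlated as ordinary network nodes.

## The synthetic-data generator

No public single-cell Raman dataset accompanies this problem domain at the
scale needed, so validation uses an emulator whose ground truth is the
*planted* structure, not biology. Each of eight biomolecular components
(protein, carbohydrate/starch, saturated and unsaturated lipid, nucleic
acid, PS and PI membrane lipids, C–D label) is a unit-area sum of Gaussian
bands at its characteristic marker wavenumbers (default FWHM 8 cm⁻¹, a
typical Raman linewidth; the C–D hump is 120 cm⁻¹ wide). A cell's spectrum
is a non-negative mixture: per-cell component amplitudes are lognormal —
a latent Gaussian vector with a planted correlation matrix, exponentiated
and scaled to the component means (Gaussian copula) — so amplitudes are
positive, log-amplitude correlations equal the planted matrix exactly, and
knockouts (zero mean) are exactly zero. Defaults, fixed once: log-amplitude
sigma 0.25 (≈ 25 % cell-to-cell RSD, the order observed for single-cell
metabolite contents), additive Gaussian noise with sd 5 % of the mean
spectrum's maximum, and a per-cell multiplicative lognormal factor
(sd 0.1) that area normalization is expected to remove — included
deliberately to exercise that rationale: with it, raw-peak correlations are
destroyed (planted −0.8 observed at ≈ −0.5) while standardized spectra
recover them.

Trajectory presets schedule means and planted correlations over a
nitrogen-starvation course in hours: `pst` (protein degrades into starch
through day 1 — strong protein–carbohydrate negative correlation — then
starch converts into TAG late, with membrane lipids feeding TAG in
parallel), `starchless` (the carbohydrate component knocked out, removing
all starch structure), `complemented` (identical to `pst`, the
genetic-complementation control), `membrane_to_tag`, and `d2o_labeling`
(C–D band anticorrelated with TAG at intermediate times only). Late-phase
anchors derive their correlation matrices from a single latent
*progression axis*: component loadings λ give ρ(a,b) = λₐλᵦ, which is
positive semidefinite by construction and encodes the premise that cells in
one snapshot sit at different stages of the same conversion process. The
loadings are chosen to reproduce the headline pair values (starch–TAG −0.8,
membrane–TAG −0.6, protein–saturated-lipid ≈ −0.5). States between anchors
interpolate linearly per pair; a convex combination of PSD correlation
matrices is PSD, so every interpolated state is valid. One master seed
spawns per-(replicate, time point) child seeds, so any single ramanome is
reproducible in isolation.

What the generator does *not* emulate: realistic band shapes beyond
Gaussians, pigment fluorescence backgrounds, photobleaching, cosmic rays,
instrument wavenumber jitter, or real amplitude-distribution shapes
(lognormal is a declared modeling choice). Passing tests therefore
demonstrate correctness of the pipeline and recoverability of planted
structure under controlled heterogeneity and noise — not performance on any
particular instrument's data.

## Signatures and clustering

Three signatures summarize a ramanome: MP, the mean standardized spectrum
(which integrates to 1, since the mean of unit-area spectra is unit-area);
MI, the F × F matrix of significant correlations with non-significant
entries zeroed; MC, keeping only strong negative correlations. MC nonzeros
are by construction a subset of MI nonzeros with identical values.
Ramanomes are compared by Euclidean distance — between MP vectors, or
between the strict upper triangles of MI/MC (each symmetric entry counted
once). Clustering is Ward's method on those raw Euclidean distances (the
"ward.D2"-style criterion) cut into k flat clusters, k = 6 by default;
PCA projections fix each component's sign by making its largest-magnitude
loading positive, so coordinates are deterministic.

A caveat established quantitatively during development: thresholded
signatures are *mass-unstable* at realistic sampling depth. With 60 cells
the empirical correlation of a planted ρ = −0.8 pair has sd ≈ 0.05, and the
number of grid-position pairs exceeding the −0.6 cutoff amplifies that
swing several-fold, because entire Gaussian band tails cross the threshold
together (observed late-state MC edge counts range over ~150–750 across
replicate draws). When all conversion mechanisms share one progression axis
— which the PSD constraint forces whenever one pool correlates strongly
with several others — these swings are coherent across the matrix and do
not average out. Euclidean distances between sparse thresholded matrices
then scale with the *difference* in edge mass within a state but only with
the *square root of summed mass* between states, so replicate scatter can
rival between-state separation. In practice MC-based clustering separates
states reliably when their edge masses differ by large factors (as between
a near-empty early network and a dense late one); closely matched states
with overlapping mass ranges may not reach high agreement with the planted
partition at n = 60 (the dedicated clustering test documents the measured
agreement). MI and MP, being dense/unthresholded, do not share this
instability.

## Sampling depth

How many cells are enough? For increasing depth d, the package subsamples d
cells without replacement (a depth is a set of distinct cells; subsample
indices are sorted so full-depth draws are bit-identical) and tracks a
cumulative trait: cumPCC, the correlation between two chosen peaks (default
938/2855 cm⁻¹, the starch/TAG pair), or cumAveDegree, the average degree of
the strong-negative network, reporting mean and sd over permutations. At
d = n every subsample is the full population and the sd is exactly 0. The
gain at depth d is |T(d) − T(d−1)| / |T(d−1)|, evaluated on consecutive
integer depths to honor the one-more-cell definition. The minimal sampling
depth is the smallest d from which the gain stays at or below 1 % for all
larger evaluated depths (the sustained rule guards against noise-induced
early stops; a first-crossing variant is available). Test and acceptance
runs use 1,000 permutations per depth — a scaled-down but
estimator-consistent version of the analysis; the defaults are exposed for
larger runs. Signed correlations (not |ρ|) are averaged, so the curve's
limit is the full-population ρ itself.

## Numerical choices and edge cases

- Exact collinearity: |ρ| within 1e-14 of 1 snaps to ±1 with P = 0.
- Constant features: flagged, NaN pairs, never edges; excluded from the
  `ave_PCC` numerator but not its denominator.
- Resampling is linear interpolation only, extrapolation refused; the
  standardization window is cropped with a one-native-step pad so window
  endpoints remain interpolable on non-integer native grids.
- Wide-matrix CSVs round-trip float64 bitwise (17 significant digits out,
  `float_precision="round_trip"` in).
- Cluster counts, module orderings and degree rankings are fully
  deterministic (size-descending with smallest-wavenumber tie-break).
- Problem sizes in the test suite (60-cell ramanomes, 100-seed recovery
  loops, 10-seed clustering, 1,000 permutations per depth) were chosen as
  the smallest at which the estimators are stable, and are stated in each
  test.
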