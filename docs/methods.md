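# Methods

## Scope and model of the data

The package analyses per-sample event-level cytometry matrices (cells ×
channels, raw fluorescence intensities, one acquisition-time channel) from a
small two-group cohort design: control lymphoid tissue versus lymphoma
biopsies, ~4–5 samples per group, 20–30 markers per panel. Its working
model is the standard one for cytometry clustering: on the logicle
(display) scale, each biological population is approximately Gaussian per
marker, and a sample is a mixture of populations whose mixing proportions
depend on the disease group.

## Logicle transformation

The logicle scale is the Parks–Roeder–Moore biexponential: linear around
zero over a width of *w* decades and logarithmic at high intensity, over
*m* total decades with *a* additional negative decades and top of scale
*t*. The inverse (display → intensity) is evaluated exactly as
B(y) = α·e^{by} − γ·e^{−dy} + φ with b = (m + a)·ln 10 and d the root of
2(ln d − ln b) + w'(b + d) = 0, w' = w/(m + a); the constants are fixed by
B(1) = t and B(w' + a/(m+a)) = 0 (GatingML convention: output scaled to
[0, 1], top of scale ↦ 1, intensity 0 ↦ w' with a = 0). The forward
transform solves B(y) = x by vectorised safeguarded Newton iteration with
automatic bracketing, tolerance 1e-8 relative; the round-trip identity is
property-tested to 1e-6. Defaults are w = 0.5, t = 10 000, m = 2, a = 0.

## Acquisition QC

Clogs and similar anomalies appear as time-localised shifts of channel
means. The filter cuts the time-sorted events into consecutive segments of
200 events, z-scores each segment's per-channel mean against all segments,
scores a segment by the summed |z| over monitored channels, and removes
segments scoring above median + c·MAD (MAD scaled by 1.4826; default
c = 5). This is deliberately a single-statistic segment filter, not the
multi-statistic procedure of dedicated QC packages: the intent (drop
anomalous flow windows, keep clean data intact) is what is tested. On
clean synthetic samples it removes ≤ 2% of events; on injected clog
windows (10% of the run, large shift) it removes ≥ 90% of window events —
both checked in the acceptance suite. The filter is idempotent on its own
output up to the re-estimated threshold.

## Metaclustering

Clustering follows the SOM-then-metacluster design: an online
self-organising map (default 10×10 grid, Euclidean distance, Gaussian
neighbourhood, radius decaying linearly from the 0.67 quantile of node-grid
distances to 0, learning rate 0.05 → 0.01, 10 epochs, seeded and
deterministic) quantises cells into 100 nodes; nodes are then grouped by
consensus clustering — average-linkage trees on 100 bootstrap resamples of
the nodes, each cut at k, co-clustering frequencies collected into a
consensus matrix, final average-linkage cut at k on 1 − consensus. The
elbow rule computes the within-metacluster sum of squares of the codebook
over a k-range and returns the k maximising the discrete second difference;
the curve is always returned, and a pipeline-level override is provided
because granularity choices are ultimately judgement calls. Featureless
curves fall back to the smallest k with a warning. Cell assignment is
best-matching-unit with ties to the lowest node index, verified against an
exhaustive-search oracle.

Scaling before the SOM defaults to natural-log + per-marker z-scaling of
the transformed intensities (disable with `scale_before_som=False`); the
alternative — clustering on the unscaled logicle values — changes only
relative marker weights.

## Annotation and auto-gating

MEM enrichment per marker is |median_pop − median_ref| + IQR_ref/IQR_pop − 1
floored at zero, signed by the median difference, rescaled so the largest
magnitude is 10; the reference is all cells outside the population, and
zero IQRs are floored at 1e-9. Auto-gates are axis-aligned: greedy
coordinate ascent over per-marker percentile grids (99 candidates),
applying at each step the single bound change that maximally increases
F1 = 2TP/(2TP + FP + FN), stopping below a 1e-4 improvement or at 20
bounds. Marker importance is the F1 drop when a marker's bounds are removed
without re-fitting — cheaper and deterministic; re-fitting after removal
would measure redundancy-adjusted importance instead and can be done by
calling `fit_gate` on the reduced marker set.

## Signed distance correlation

For two across-sample vectors x, y (n samples), the sample distance
correlation is computed from double-centered pairwise absolute-difference
matrices (row mean, column mean, grand mean); dCor = dCov/√(dVar_x·dVar_y),
zero when either distance variance vanishes. Above 3 000 points the same
statistic is accumulated in row blocks to bound memory; the two paths agree
to 1e-12. The sign is taken from the Pearson correlation of the same pair;
a Pearson that is zero to numerical precision (|r| ≤ 1e-12) defaults the
sign to +1 with an explicit `zero_sign` flag, since the sign rule is
undefined there.

Significance is by permutation of one argument: for n ≤ 7 all n!
permutations are enumerated (p = #{dcor ≥ observed}/n!, identity included,
so p ≥ 1/n! and the null p is valid at every achievable level); for larger
n a Monte-Carlo test with p = (1 + #{≥})/(1 + n_perm), default
n_perm = 9 999. Both are distribution-free and honest at the n = 4–5 of a
typical cohort; the method used is recorded per row. Type-I error at
α = 0.05 is verified to sit in the 95% binomial band over 1 000 null
replicates.

### Screens

The ligand–receptor screen takes per-sample × population × marker median
intensities (raw scale by default; populations below a cell-count floor
yield missing entries, never zeros), restricts to a group when configured
(the disease group, avoiding between-group composition confounding),
log-transforms and z-normalises each MFI vector across samples, and tests
every catalogued axis in both orientations between the populations of
interest and the TME populations. Rows with raw p < α form the reported
screen; the full table, with BH-adjusted p-values as a separate column, is
always kept. BH families are per screen (LR screen; frequency screen). The
frequency screen applies the same machinery to per-sample population
frequencies, excluding self-pairs. Ties in the ranking are broken by
larger dcor.

The shipped ligand–receptor catalogue holds the canonical axes derivable
from a T-cell checkpoint/costimulation panel against a TME ligand panel
(PD1–PDL1/PDL2, CTLA4/CD28–CD80/CD86, ICOS–ICOSL, OX40–OX40L,
CD137–CD137L, BTLA–HVEM, TIGIT–PVR, TIM3–GAL9, FAS–FASL, CD40L–CD40,
LAG3–HLA-DR) and is user-replaceable; marker spellings are canonicalised
through an alias table at load.

## Group statistics

Mann–Whitney is exact (full enumeration of label assignments,
p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1, ties handled by the enumeration)
for combined n ≤ 12 and normal-approximate with tie correction above;
the exact branch is verified against an independent enumeration oracle for
all splits with combined n ≤ 8. Kruskal–Wallis uses the tie-corrected H;
Dunn's pairwise z uses pooled mid-ranks with the t³ − t tie term and BH
adjustment across the pairwise family. Per-population comparisons are BH
adjusted across populations within a comparison family, and both
mean ± sem and median/IQR summaries are emitted, since conventions differ.
PCA of frequency tables centres and unit-scales each population and uses
the SVD; missing values are refused rather than imputed, constant
populations are dropped with a warning.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with known ground truth per cell:

- Cells i.i.d. Gaussian per metacluster on the transformed scale, mapped
  to raw intensities through the exact inverse logicle. Default cohort:
  4 control LN + 5 DLBCL samples, 3 000 cells each, 26 markers, six
  populations including two rare DLBCL-enriched follicular CD8 clusters
  (CXCR5+PD1+, differing in HLA-DR/ICOS) and a lymphoma-B-like receiver
  population carrying ligand markers. High/mid/low marker means are
  0.70/0.45/0.25 display units with sd 0.05.
- Ligand–receptor coupling: a per-sample latent factor u ~ N(0, 1) shifts
  the sender's ligand by β·u and the receiver's receptor by β·u (linear) or
  β·(u² − 1) (quadratic — centred so the linear correlation is zero by
  construction); independent per-sample noise (sd 0.02) on each side.
  Default β = 0.15 for the linear ICOS→ICOSL coupling.
- Artefacts: doublets as channel-wise sums of two random cells (default
  2%), dead cells as a high viability-channel shift (3%), clog windows as
  raw-intensity offsets inside a time interval.
- Determinism: equal seeds give bit-identical cohorts.

What the generator does **not** emulate: spectral spillover/unmixing
residuals, autofluorescence, non-Gaussian (skewed or multimodal)
within-population marker distributions, batch effects between acquisition
days, and cell-cell correlations within a sample. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data complications.

Power-sensitive properties (permutation calibration, quadratic-coupling
detection) are tested at 20–40 samples because 4–5 samples per group
cannot separate power from noise; the study-sized design is exercised by
the end-to-end test, whose assertions (enrichment flagged, coupled pair
ranked first) are achievable at that n.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to keep the statistical
properties measurable: 3-blob SOM recovery at 6 000 cells, end-to-end
cohorts at 3 000 cells/sample downsampled to 1 500, QC at 10 000 cells,
large-sample dcor at n = 10 000 (block-accumulated), calibration at 1 000
replicates × 199 permutations. Tolerances: dcor oracle agreement 1e-12;
logicle round trip 1e-6 relative; dcor vs the analytic bivariate-normal
value 0.02 at n = 10 000. Degenerate inputs are handled explicitly:
constant vectors give dcor 0; zero parent counts give flagged NaN
frequencies; all-samples-excluded halts with an error; empty gates are
returned when the target is the whole dataset.

## Known limitations

- The QC filter assumes anomalies are localised in time and large relative
  to segment-mean noise; slow drifts spanning most of a run are not
  detected.
- The elbow rule on consensus WSS curves is a guide, not an authority; the
  pipeline reports it and accepts an override.
- Marker importance without re-fitting underestimates the importance of
  markers with redundant partners in the gate (both can score ≈ 0).
- The LR screen is correlational: orientation of an axis is taken from the
  catalogue, and no causal directionality is implied.
- With 4–5 samples per group, exact-permutation p-values have coarse
  granularity (multiples of 1/120 at n = 5); BH-adjusted values across
  tens of rows rarely clear 0.05, which is why the screening rule follows
  raw p with the adjusted column reported alongside.
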