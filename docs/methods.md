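# Methods

This note records the models implemented in `ppiscreen`, the defaults that
matter, the numerical choices made where the underlying procedure left room,
and what the synthetic benchmarks do and do not demonstrate.

## Activity labeling

HTS percent-inhibition values are thresholded at 50%: a compound is active
iff inhibition is *strictly* greater than the threshold. The strictness
matters only for compounds exactly at the boundary but is part of the
contract (`label_by_inhibition`), and the threshold is configurable.

## Descriptor preparation

Descriptors arrive as a compound × descriptor numeric table from any
calculator (Mold2-style tables are the motivating case; reimplementing a
descriptor calculator is out of scope). Two preparation steps:

- **Min–max normalization to [0, 1]**, chosen over z-scoring because every
  downstream distance computation (fuzzy c-means, k-NN members, the
  applicability domain) is Euclidean and benefits from commensurate column
  ranges. Constant columns map to exactly 0 and are flagged. The per-column
  training min/max are retained and replayed verbatim on query compounds,
  whose transformed values may legitimately leave [0, 1] — the
  applicability domain depends on that extrapolation being visible.
- **Low-variance filtering** with default cutoff 1e−8. The variance is
  measured on the raw descriptor scale (recovered through the stored
  normalization span): min–max normalization stretches any non-constant
  column to the full unit interval, so a near-constant descriptor would
  otherwise look as variable as an informative one. The cutoff is a
  pragmatic "effectively constant" bound, not a tuned hyperparameter.

## Cluster-stratified splitting

Fuzzy c-means (fuzziness m = 2, tolerance 1e−6 on the max centroid shift,
random membership initialization under a fixed seed) softly clusters the
prepared matrix into 5 clusters; each compound is then assigned to its
maximum-membership cluster and split 80:20 within the cluster (training
size rounded half up). This gives a held-out set that covers the same
regions of descriptor space as the training set. Degenerate geometry is
handled explicitly: a point coinciding with a centroid receives membership
1 there, and an empty hard cluster is skipped with a warning. The FCM
objective is recorded per iteration and is non-increasing; the test suite
asserts this on every fitted model it builds.

## Consensus classifier

Three member pipelines, each a feature selector feeding a classifier:

1. gain-ratio ranking (top 30) → k-NN, k = 3, Euclidean;
2. CFS best-first subset search → nearest neighbor (k = 1);
3. information-gain ranking (top 30) → random forest, 100 trees, √p
   features per split, unlimited depth, seeded.

The consensus label is the majority of the three votes; with three binary
voters a tie is impossible (asserted, not special-cased). k = 3 for the
k-NN member distinguishes it from the dedicated 1-NN member; both ks, the
ranker cutoff and forest size are constructor parameters.

Entropy-based scores operate on discretized columns: Fayyad–Irani MDL
binary splitting per column, falling back to 10 equal-frequency bins when
MDL accepts no cut (so uninformative continuous columns still contribute a
defined, near-zero score rather than a degenerate one). Gain ratio is
defined as 0 when the feature entropy vanishes. The pairing of one ranker
per member follows the original modeling setup, with one repair: a
single-attribute evaluator cannot drive a best-first *subset* search, so
the third member uses info-gain ranking with the same top-n cutoff.

CFS maximizes `M_S = k·r̄_cf / √(k + k(k−1)·r̄_ff)` over subsets, with
symmetric uncertainty as the correlation measure for both feature–class and
feature–feature terms. The search is forward best-first with a patience of
5 consecutive non-improving expansions (the Weka convention); evaluated
subsets are cached and the open list is a merit-ordered heap with
insertion-order tie-breaking for determinism. On ≤ 8-feature synthetic
problems the search provably returns the exhaustive-enumeration optimum
(tested); on larger problems it is a heuristic, as in every CFS
implementation.

Validation metrics are the standard screening ratios from the 2 × 2
confusion matrix with active as the positive class. A metric whose
denominator is zero is reported as undefined (`None`), never as 0.
Displayed values round half away from zero to 3 decimals.

## Applicability domain

For each training compound the Euclidean distance to its nearest training
neighbor (self excluded) is computed; the threshold is `mean + Z·sd` of
those distances with Z = 0.5 by default. The standard deviation is the
population sd — the distances are the full population of training
nearest-neighbor distances, not a sample from it; either convention would
be defensible and the choice is recorded here. A query is Unreliable iff
its nearest-training-neighbor distance strictly exceeds the threshold; a
distance exactly at the threshold is Reliable. Distances are computed in
the same prepared descriptor space the classifiers use.

## Screening filters

Fingerprints are RDKit hashed path (topological) fingerprints, 2048 bits,
maximum path length 7 — a reasonable default where the original scheme is
unknown; published similarity values are therefore not reproducible in
principle and are treated as annotations, not targets. Tanimoto similarity
is `c/(a+b−c)` on the bit vectors, defined as 1 for two empty
fingerprints. The PAINS screen uses the union of the A, B and C pattern
families as shipped with RDKit. Catalog versions differ in pattern scope;
notably RDKit's `azo_A` SMARTS also matches hydrazones, so a compound
list annotated with a different PAINS implementation can disagree on such
scaffolds. The packaged 30-candidate table stores its structure strings as
printed — including typographic en-dashes — and the readers normalize dash
variants and `InChI =` spacing on ingestion.

## MM–PBSA bookkeeping

The summary works on per-frame component tables (complex, protein,
inhibitor; E_vdW, E_elec, G_PB in kcal/mol, SASA in Å²). Per frame, each
Δ-component is complex − protein − inhibitor; the nonpolar term applies
γ·SASA + β per species *before* differencing, so one β offset survives in
ΔG_NP (γ·ΔSASA − β). Defaults γ = 0.005420 kcal·mol⁻¹·Å⁻²,
β = −1.008000 kcal·mol⁻¹.

Derived rows are summed per frame and then averaged, so the means satisfy
ΔE_MM = ΔE_elec + ΔE_vdW, ΔG_solv = ΔG_PB + ΔG_NP, ΔH = ΔE_MM + ΔG_solv
and ΔG_elec(tot) = ΔE_elec + ΔG_PB exactly, before any display rounding
(2 decimals, half away from zero). SEMs are sd/√n over frames.

The entropy term enters as a *given* −TΔS in kcal/mol (positive =
unfavorable), so ΔG = ΔH + entropy_term; computing normal-mode entropies is
out of scope. The ΔG standard error combines the ΔH and entropy SEMs in
quadrature by default; an `entropy_only` mode reproduces summaries whose
printed ΔG error equals the entropy error alone (published tables of this
kind typically do the latter).

One published six-complex table that the test suite cross-checks contains a
typesetting inconsistency: the T23–RANKL column prints ΔG_solv = 24.20
although its own ΔG_PB + ΔG_NP = 21.17, with all downstream rows following
the printed 24.20 (and a further 0.01 rounding drift in two columns'
ΔE_MM row). The tests assert the inconsistency rather than papering over
it, and validate that column's downstream arithmetic from the printed
ΔG_solv onward only.

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.5 Å AND
donor–hydrogen–acceptor angle ≥ 120° (both configurable). Comparisons carry
a 1e−9 guard so geometries exactly at a cutoff stay on the inclusive side
despite floating-point round-off. Detection is invariant under rigid
motions (tested by randomized rotation + translation). Contact analysis
reports the mean ± sd (population, so a single frame has sd 0) of the
per-frame minimum distance from an atom group to a target atom.

## Binding-assay fits

The titration model is the single-site quadratic ("tight-binding")
isotherm, appropriate because the protein concentration (0.5–0.75 μM) is
not negligible against the fitted K_d (μM range), so free ≠ total ligand.
The discriminant equals (P₀ − L + K_d)² + 4·L·K_d ≥ 0, so the model is
real and bounded by ΔF_max for all physical inputs. Fitting is
trust-region-reflective least squares with positivity bounds,
initialization K_d = median(L), ΔF_max = max(ΔF). Replicates are fitted
independently and reported as mean ± SEM across replicates. Noiseless
recovery is exact to well under 1%; with 1% multiplicative noise and 3
replicates, K_d is recovered within 10% across K_d ∈ [1, 20] μM at the
assay protein concentrations (tested).

Scatchard analysis regresses bound/free on bound with bound =
ΔF/ΔF_max·P₀; points with non-positive bound or free are excluded with a
warning (the L = 0 point carries no ratio information). Slope = −1/K_d and
the x-intercept over P₀ estimates the site stoichiometry n; noiseless
one-site data give n = 1.00.

Dose–response data use a 4-parameter logistic
`y = bottom + (top − bottom)/(1 + (x/EC50)^hill)` (EC50 bounded positive),
reported as IC50 or LC50 according to the assay direction. Constant
responses are rejected; data whose Spearman correlation with concentration
is weak draw a non-monotonicity warning but are still fitted.

## Synthetic data

`make_classification_set` emulates a labeled HTS descriptor matrix:
Gaussian cluster centers (sd 2 per column) with unit within-cluster noise,
an exact `round(balance·n)` actives shifted by the separation on each
informative column, redundant columns as informative + N(0, 0.1), and
independent label flips at the noise rate. The standing benchmark is n =
600, p = 120, 10 informative + 10 redundant, 5 clusters, 46% actives,
separation 3 (a strongly planted signal — the benchmark tests the pipeline
machinery, not the classifiers' limits), 10% label noise, seed 42. The
sizes are desk-scale stand-ins for the original few-thousand-compound set
and keep the full suite and the acceptance script in seconds.

What the generators do *not* emulate: real descriptor distributions
(heavy-tailed, discrete and correlated in ways Gaussians are not),
structure–descriptor consistency (structures and descriptor rows are
generated independently), activity cliffs, or assay-specific artifacts.
Passing the synthetic end-to-end benchmark therefore demonstrates that the
machinery is correct and deterministic, not that the modeling choices would
reach any particular accuracy on real HTS chemistry. With 10% label noise
the observed-label accuracy ceiling is about 0.90; the benchmark's
consensus reaches ≈ 0.85, and published metrics on the real set are
reproduced from their confusion matrices, not by retraining (the original
descriptors and software stack are not redistributable).

Energy-frame and titration generators draw i.i.d. Gaussian values around
requested means; `energy_frames_for_deltas` plants requested Δ-component
means by putting the delta and all variance on the complex over fixed
protein/inhibitor baselines, inverting the nonpolar term through
ΔSASA = (ΔG_NP + β)/γ. All generators are bit-reproducible under a fixed
seed and always emit their ground truth.

## Known limitations

- The consensus model supports exactly the published three-member, binary,
  single-split design; no cross-validation, calibration or multi-class.
- CFS is exact only where enumeration is feasible; best-first is a
  heuristic beyond that.
- The applicability domain is the nearest-neighbor-distance variant only
  (no leverage or density domains).
- Fingerprint scheme and PAINS catalog version are configurable but
  annotations from other implementations may not match pattern-for-pattern.
- MM–PBSA inputs must be precomputed per-frame components; no PB solver,
  MD engine or entropy computation is included.
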