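# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `stemdis`, in the order the pipeline runs.

## Synthetic data: what it emulates, and what it does not

The generators emulate the study design the pipeline targets — a
reporter-enriched cancer stem-like line versus its parental line, three
biological replicates each — with planted ground truth:

* **Counts.** Genes × samples negative-binomial counts with variance
  µ + φµ² (dispersion φ, default 0.1 — a typical bulk RNA-seq value for
  cell-line replicates). Per-gene base means are log-normal
  (median 100, σ = 1 in log space); per-sample library sizes are log-normal
  and clipped to ±20% of a common target depth so CPM normalization is
  exercised non-trivially. Planted genes multiply (or divide) the case-group
  mean by the configured fold, default 16 so that the ≥10-fold network gate
  is reachable. A fold of exactly 1 plants nothing.
* **Protein cohorts.** Each residue is drawn from the designated
  composition set with probability 0.9 (order-promoting W,C,F,I,Y,V,L,N for
  "ordered" proteins, disorder-promoting A,R,G,Q,S,P,E,K for "disordered"),
  and uniformly from all twenty residues otherwise. This makes the planted
  label recoverable by any composition-sensitive scorer without being a
  copy of the internal scorer's formula.
* **Networks.** A round-robin planted partition; within-community edges
  appear with p_intra = 0.6, cross-community edges with p_inter = 0.02.
  Edge confidences are Gaussian (σ = 0.02, clipped to [0,1]) around a
  "true" mean (default 0.95) for within-community edges and a "false" mean
  for cross-community edges. The API default for the false mean is 0.5,
  emulating a full STRING-like export in which the >0.9 filter removes the
  noise; the pipeline's simulate block instead uses 0.92, emulating an
  export already restricted to high confidence, so the end-to-end
  clustering faces a connected graph and must separate communities by
  topology. Hub nodes are wired to six within-community partners so the
  degree > 5 rule must fire.
* **Catalogs and signatures.** Catalogs take a gene universe, draw modules
  uniformly without replacement, and copy a configured fraction of entries
  verbatim under new names (the redundancy that set-identity deduplication
  removes). Signature genes are concordant with their expected direction
  independently with the configured probability; a Bernoulli rather than an
  exact count, so that repeated seeds at probability ½ calibrate the
  concordance test's size.

All randomness in a generator flows from one integer seed through
`numpy.random.SeedSequence(seed).spawn()`, one child stream per independent
role; equal seeds give byte-identical output files.

What the generators do **not** model: batch effects, sample quality
gradients, gene–gene correlation, length/GC biases, realistic network
degree distributions, or biologically coherent module membership. Passing
the planted-recovery tests therefore demonstrates that the implementation
computes what it claims on data satisfying its assumptions — not that the
statistical procedures are powerful or calibrated on real tumor data.

## Differential expression

Counts are normalized to `log2((c + 0.5) / (libsize + 1) · 1e6)`
(pseudocount 0.5). Per gene, a two-sided Welch (unequal-variance) t-test
compares case and control log-CPM values; log2FC is the difference of group
means on that scale. Benjamini–Hochberg is applied over all tested genes
and labels are `up`/`down` when q < α (default 0.05) with the matching
sign. Genes with zero variance in both groups receive p = 1 by convention,
even when the group means differ — a deterministic degenerate rule, not an
inference. The ≥10-fold gate keeps labeled genes with |log2FC| ≥ log2(10)
on the CPM scale, up- and down-regulated lists separate.

Two properties of this deliberately simple test are worth knowing:

* **Power ceiling at n = 3.** With three replicates per group the variance
  estimate has ~2 effective degrees of freedom. At dispersion 0.1 the
  log2-scale residual sd is ≈ 0.45, and an idealized Gaussian simulation
  shows BH-FDR recovery of 16-fold effects saturating near 82%; chance
  small-variance null genes can outrank genuine 16-fold genes, which also
  inflates the realized false-discovery proportion above the nominal FDR.
  Moderated-variance methods (limma-style empirical Bayes) exist precisely
  to fix this and are intentionally out of scope here. The planted-recovery
  tests therefore enforce a floor of 0.70, frozen from a ten-seed
  calibration run (mean 0.755, min 0.715).
* **Conservatism under the null.** On log-NB data the two-sided Welch test
  at n = 3 rejects at ≈ 0.034 for α = 0.05 (stable across count strata) —
  it over-controls the type-I error rather than matching the nominal level.
* **Composition bias.** Planting 16-fold up-genes inflates the case library
  total, so CPM normalization compresses up-gene fold changes (≈ 0.8 log2
  at the default design) and stretches down-gene ones. The mean |log2FC|
  over both directions still recovers the planted 4.0.

## Network analysis

Edges are kept iff confidence **strictly** exceeds the floor (default 0.9);
duplicate and reversed edges merge keeping the maximum confidence;
self-loops are dropped; nodes outside the queried gene set are ignored.
Largest-component ties break toward the component containing the
lexicographically smallest node. Hubs are nodes with degree **strictly**
greater than `min_links` (default 5). Clustering embeds nodes with the k
smallest nontrivial eigenvectors of the confidence-weighted symmetric
normalized Laplacian (dense `scipy.linalg.eigh`; adequate at the few-hundred
node scale this pipeline produces) followed by k-means with 10 restarts and
a fixed seed. Disconnected inputs are clustered per component, with k
apportioned by component size (largest remainder, floor 1); requesting fewer
clusters than components is an error rather than a silent merge.

## Module enrichment

Catalog entries with set-identical gene membership are united
(names joined with `|`, first description kept) before scoring — the
operation is idempotent and order-insensitive. A module's score is the mean
log2FC of its member genes found in the DE table; modules mapping fewer
than `min_genes` (default 5) are skipped with a logged reason. The null is
competitive: means of size-matched gene sets drawn without replacement from
the DE table, n_perm times (default 10 000 for final analyses, smaller in
the pipeline demo); the two-sided p is `(1 + #{|null| ≥ |obs|}) / (n_perm+1)`,
bounded below by 1/(n_perm+1). Null draws are shared across modules of
equal size, which makes p-values of same-size modules positively dependent —
acceptable for a screening statistic and documented here. BH is applied
across the modules of the catalog being tested.

## Signature concordance

Evaluable genes are signature genes present in the DE table; by default
only significantly labeled genes count (`include_ns=False`), avoiding
scoring noise genes, with a flag to count every mapped gene by the sign of
its log2FC. The p-value is the exact binomial upper tail at success
probability ½ (via `scipy.stats.binom.sf`, verified against exact rational
summation to 1e−12 up to n = 600). Zero evaluable genes raise an error
rather than returning p = 1. The test scores *direction concordance*, the
minimal faithful reading of a binomial comparison of a signed signature
with a signed profile; bare-overlap (hypergeometric) testing is a different
question and deliberately not implemented.

## Disorder metrics and classification

* Hydropathy: Kyte–Doolittle, min–max scaled so I → 1 and R → 0; mean over
  residues gives H ∈ [0,1].
* Charge: K,R = +1, D,E = −1, histidine and termini 0 (neutral-pH
  convention); R = |net| / length.
* CH boundary: R = a·H − b with a = 2.785, b = 1.151 (the standard
  charge–hydropathy discriminant), configurable. Positive distance =
  extended-disorder side.
* Internal scorer: FoldIndex-style windowed statistic, window 51 (odd,
  ≥ 5), truncated — never padded — at the ends; FI = a·H_w − |R_w| − b and
  score = clamp(0.5 − FI, 0, 1). It is a composition-based stand-in with
  the right qualitative behavior, not a trained predictor; per-residue
  tracks from external predictors can be read in its place, and the
  profile source is recorded on every profile.
* Sanitization: ambiguity codes (B, Z, X, J) and rare residues (U, O) are
  dropped with a warning; CH statistics are undefined for them.
* PPIDR counts residues **strictly** above 0.5, ×100. Flexibility classes
  take inclusive-lower boundaries (0.25 belongs to highly-flexible, 0.15
  to flexible) so counts always sum to the length.
* Protein bins: highly ordered (PPIDR < 10% or MDS < 0.25), moderately
  disordered (10% ≤ PPIDR < 30% or 0.25 ≤ MDS < 0.5), highly disordered
  (PPIDR ≥ 30% or MDS ≥ 0.5); lower edges inclusive.
* CDF: CDF(t) = fraction of residues scoring ≤ t, compared at boundary
  points (threshold, fraction); signed distance is the mean of
  CDF(t) − fraction, positive on the ordered side. The default boundary —
  seven thresholds evenly spaced on [0.2, 0.8] with fractions rising
  linearly 0.6 → 0.9 — is a configurable convention: published CH-CDF
  analyses each use the boundary of their chosen predictor, and no single
  table is canonical. Cohort-level arithmetic never depends on this
  default.
* Quadrants: Y = CH distance, X = CDF distance (ordered-positive);
  Y ≤ 0 ∧ X > 0 → Q1, Y ≤ 0 ∧ X ≤ 0 → Q2, Y > 0 ∧ X ≤ 0 → Q3,
  Y > 0 ∧ X > 0 → Q4. Zero coordinates resolve to the ordered side of each
  axis — a deterministic tie rule, vanishingly rare on real data.
* Cohort reports tally quadrants and bins (all four quadrant counts are
  reported, including Q4), derive the high-disorder percentage
  100·(|Q2|+|Q3|)/n, the moderately-or-highly-disordered percentages at
  PPIDR ≥ 10 and MDS ≥ 0.25, the stringent PPIDR ≥ 50% count, and the
  top-10 PPIDR range (maximum and 10th-largest). Reported percentages are
  rounded half-up to one decimal. Note one rounding quirk inherited from
  the literature this mirrors: 66/175 = 37.714 reports as 37.7 here,
  while the corresponding published figure prints 37.8.

## Pipeline and reproducibility

Stages exchange plain files under the run directory; the merged report
embeds the tool version, the effective configuration, its SHA-256 hash,
and checksums of any external inputs. Stage randomness derives from the
single config seed with fixed per-stage offsets. A failing stage aborts
with the stage named. The simulate-mode network stage analyzes up- and
down-regulated gene lists separately and reports a direction as skipped
when its ≥10-fold list is too small to host the planted communities
(7 genes per community minimum).

## Problem sizes

Default analyses run at desk scale, chosen as representative of the
method's regime rather than of any particular dataset: 2 000 genes with
100 + 100 planted at 16-fold in a 3 + 3 design; 60-node networks with
three planted communities; 40-module catalogs; 30-gene signatures; 100-
protein cohorts of 80–300 residues; 10 000 permutations for final module
calls and 1 000 null datasets for the type-I calibration.

## Known limitations

* The Welch-on-log-CPM test is a fully specified but low-powered stand-in
  for moderated-variance DE at n = 3 (see above); its realized FDP exceeds
  the nominal FDR under chance small-variance genes.
* The internal disorder scorer is composition-based; it will not reproduce
  trained-predictor scores on real proteins, only the coarse
  ordered/disordered separation its inputs encode.
* Dense eigendecomposition limits clustering to networks of a few thousand
  nodes.
* Module permutation p-values share null draws within a size class.
* The synthetic generators' simplifications listed above bound what the
  green test suite demonstrates about real data.
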