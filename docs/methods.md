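# Methods

## The signal model

Semiconductor sequencers (Ion Torrent / Ion Proton) read DNA one nucleotide
reagent at a time; a homopolymer run of length *L* is incorporated in a
single flow whose voltage is ideally *L* times the single-incorporation
baseline.  The measured voltage *V* is noisy, and the noise structure depends
on three things: the homopolymer length, the nucleotide (C runs read slightly
hot), and the position of the run within the read (signal droops toward the
3' end).  flowcall models the class-conditional signal as a Gaussian per
(nucleotide *N*, zone *Z*, length *L*) cell:

    V | N, Z, L  ~  Normal(mu_NZL, sigma_NZL)

where a *zone* is a uniform position bin (Torrent profile: four 75-bp zones
over 300-bp reads; Proton profile: five 50-bp zones over 250-bp reads;
positions past the last boundary clamp to the last zone).  Signal width grows
with length — in the default table sigma rises from 0.14 at L=2 to 0.38 at
L=6 — which is exactly why naive thresholding degrades for long runs.

## Calling rules

A flow is a **candidate** homopolymer when its voltage strictly exceeds 1.5
incorporation units; single-base and empty flows fall below this cut, so the
candidate length range starts at 2 (default range [2, 6]).

Three callers share the model:

* **nearest-mean** (baseline): argmin_L |V − mu_NZL|, ties to the smaller
  length.  Ignores both class widths and the length prior.
* **bayes**: MAP of the posterior
  P(L|N,Z,V) ∝ phi(V; mu_NZL, sigma_NZL) · P(L), normalized over the length
  range at fixed (N, Z).  P(L) is the empirical length frequency from
  training data.  Computed in log space with logsumexp, so voltages far
  outside the model (0 or 10 units) still return a normalized, finite
  posterior.
* **integrated**: blends the posterior with the reference genome.  Because
  two genomes differ at only ~1% of sites, the reference homopolymer length
  is right 99% of the time and is worth weighting in:

      S(L) = W · ln P(L|N,Z,V) + (1−W) · Pen(L | ref)

  Pen is 0 when L matches the reference run (same nucleotide), −1 for a
  substitution (same length, different nucleotide), −2 for an
  insertion/deletion (any length difference).  The call is argmax_L S(L);
  ties break by larger posterior, then smaller length (undercalls being the
  conservative, better-understood failure mode).  The natural log is used;
  the posterior is floored at 1e−300 inside the log so the penalty term
  stays relevant when the posterior underflows.

W is chosen by 5-fold cross-validated grid search (default grid 0 to 1 in
steps of 0.02, matching the granularity at which optimized weights are
usually reported) minimizing held-out identification error; ties go to the
smaller W, i.e. toward trusting the reference.  Folds are a seeded shuffle
of candidates.  On default-table synthetic data with 1% variants the CV
lands around W ≈ 0.28.

## Fitting and imputation

`fit_priors` uses the sample mean and the n−1 standard deviation per cell,
fitting only cells with ≥ 2 observations.  Sparse cells are imputed: the
mean is L times a per-base slope (least squares through the origin) fitted
across the populated cells of the same (nucleotide, zone); the standard
deviation is copied from the nearest populated cell by length.  A
(nucleotide, zone) with no populated cells borrows the nearest zone of the
same nucleotide, then any nucleotide.  Imputed cells are flagged in the
serialized JSON.

The shipped default table (`flowcall/data/default_priors.json`, labeled as
reconstructed from printed values) anchors: A/Z1 means 1.85, 2.78, 3.68,
4.64, 5.57 with stdevs interpolated linearly 0.14→0.38; C/Z1/L4 at
3.74 ± 0.30; G,T/Z1/L4 at 3.68 ± 0.24; A/L4 zone means 3.68, 3.57, 3.54,
3.57 (zone anchors take the Z1 stdev 0.26, which is not separately
published).  All remaining cells come from the imputation rule.

## Synthetic data

The simulator stands in for a matched pair of real datasets (a semiconductor
run plus a high-accuracy orthogonal gold standard of the same individual):

* **reference**: a chain of homopolymer runs with i.i.d. lengths from a
  configurable spectrum (default: 90% single bases, 10% runs of length 2–6
  with geometric decay, ratio 0.5 — the published per-length spectrum is
  figure-only, so this is a knob, not a claim), nucleotides drawn with mild
  A/T enrichment (0.3/0.2/0.2/0.3) and forced to differ between adjacent
  runs.
* **variants**: each homopolymer locus (run ≥ 2) independently mutates with
  probability `variant_rate` (default 0.01, the rough human-vs-reference
  divergence); a variant is a ±1-base length indel
  (`indel_variant_fraction`, default 1.0) or a run-nucleotide substitution.
* **flowgrams**: reads tile the sample genome as consecutive windows of
  whole runs (default 300 bp); each run emits one flow with voltage drawn
  from its (N, Z, L) Gaussian, truncated at zero by resampling.  Emission
  cells outside the calling range are imputed on the fly; length 1 anchors
  at mean 1.0 with width 0.14 (single incorporations are at least as tight
  as the tightest fitted homopolymer cell).
* `sample_candidates` is a homopolymer-level shortcut that draws labeled
  candidates directly (no genome assembly) for training and benchmarking.

Deliberately **not** modeled: flow order and phasing (carry-forward/droop),
polyclonal wells, chip-position effects, quality scores, alignment noise in
the reference anchoring, and real gold-standard errors.  Passing tests
therefore demonstrate correctness of the inference machinery under the
stated signal model, not performance on real chips.

## Evaluation

An identification error is per homopolymer: called length ≠ true length.
Reports stratify by (nucleotide, zone) with percentages at 3 decimals, in a
fixed column order (No, Nt, Pos, Count, per-method error %, Weight) so diffs
are stable.  `weight_sweep_report` gives the descriptive in-sample
error-vs-W curve next to the CV-selected W, making any optimistic bias of
in-sample selection visible.  `correct_reads` rewrites each called run to
its called length, leaving non-candidate bases untouched.

On fixed-seed default-table data with 1% variants (100,000 candidates) the
callers order as integrated < bayes < nearest-mean, and integrated ≤
reference-only — the qualitative ranking the integrated model is built to
achieve.  Typical numbers from that configuration: ~0.4% (integrated),
~5.0% (bayes), ~5.4% (nearest-mean), ~0.7% (reference-only).

## Numerical and design choices

* Strict inequality at the 1.5-unit candidate threshold.
* n−1 denominator for all standard deviations.
* Posterior normalization asserted to 1e−9; log-space throughout.
* Degenerate fitted cells (constant voltage) get sigma = 1e−6 rather than 0.
* Voltages serialize at 6 decimals — far below the narrowest class width
  (0.14), so no calling-relevant information is lost; all writers use fixed
  ordering and formatting, making fixed-seed pipelines byte-reproducible.
* Read positions are 1-based in every file format.
* Test and acceptance problem sizes (50,000 draws per recovered cell,
  20,000 candidates for weight-grid checks, 100,000 for orderings) are
  chosen so Monte-Carlo error is well inside the asserted tolerances.

## Known limitations

The per-homopolymer abstraction cannot represent errors that create or
destroy runs (e.g. a mid-run substitution splitting one run into three), and
the reference length is assumed supplied by upstream anchoring — alignment
itself is out of scope.  Real flow data exhibit heavier tails and
inter-cell correlation than independent Gaussians; error rates here are
accordingly more optimistic than published real-data figures, and only the
orderings between callers are expected to transfer.
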