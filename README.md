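# flowcall

Homopolymer length calling for semiconductor sequencing (Ion Torrent / Ion
Proton) from raw flow voltages.

Semiconductor sequencers read a homopolymer run of length *L* as one voltage
pulse of roughly *L* incorporation units, and mis-measuring that pulse is
their dominant error mode — indels at homopolymers that derail local
alignment and variant calling downstream.  flowcall is for people building
or studying flow-space error correction: it models the measured voltage *V*
of a run of nucleotide *N* at read-position zone *Z* as class-conditional
Gaussians `V | N,Z,L ~ Normal(μ_NZL, σ_NZL)`, and calls lengths three ways:

* **nearest-mean** — baseline: `argmin_L |V − μ_NZL|`;
* **bayes** — MAP of `P(L|N,Z,V) ∝ φ(V; μ_NZL, σ_NZL) · P(L)`;
* **integrated** — blends the posterior with the reference genome, which
  matches the sample at ~99% of loci:

  `S(L) = W·ln P(L|N,Z,V) + (1−W)·Pen(L|ref)`,  `L* = argmax_L S(L)`

  with `Pen` = 0 for a perfect match, −1 for a substitution, −2 for an
  insertion/deletion, and the weight `W` picked by 5-fold cross-validated
  grid search on labeled data.

The package also ships a synthetic-data generator (reference genome with a
controlled homopolymer spectrum, ~1% injected variants, Gaussian flow
voltages, ground-truth labels), a prior-fitting routine with sparse-cell
imputation, an evaluation harness producing per-(nucleotide, zone) error
tables, and read correction.  See `docs/methods.md` for the full model.

## Worked example

```python
import flowcall as fc
from flowcall.priors import FlowCandidate

priors = fc.default_priors()          # built-in Torrent-profile table
cand = FlowCandidate(read_id="r1", flow_index=0, nucleotide="A",
                     read_position=12, voltage=4.30, ref_length=4)

fc.posterior(cand, priors)
# {2: 0.0, 3: 0.0, 4: 0.2009, 5: 0.7969, 6: 0.0022}
fc.bayes_call(cand, priors).called_length
# 5
res = fc.call_integrated(cand, priors, config=fc.IntegratedConfig(weight=0.28))
res.called_length, {L: round(s, 4) for L, s in res.scores.items()}
# (4, {2: -43.4068, 3: -8.9122, 4: -0.4494, 5: -1.5036, 6: -3.1515})
```

A 4.30-unit pulse from an A run early in the read sits between the 4-mer
(μ=3.68) and 5-mer (μ=4.64) classes; the posterior alone leans to length 5
(0.797), but the reference homopolymer is 4 bases, and at W=0.28 the
−2 indel penalty on every non-reference length pulls the integrated score's
maximum to L=4 (score −0.449 vs −1.504).  Since genuine variants are rare,
this trade wins on balance:

```python
train = fc.sample_candidates(20_000, priors, variant_rate=0.01, seed=7)
best, curve = fc.optimize_weight(train, priors, seed=3)
# best == 0.28, held-out error 0.34% at the optimum
```

On 100,000 synthetic candidates with 1% variants the error rates come out
~0.4% (integrated) < ~5.0% (bayes) < ~5.4% (nearest-mean), with
reference-only at ~0.7%.

## Command line

```
flowcall --seed 11 simulate --out-dir run/
flowcall fit-priors --flowgram run/flowgram.tsv --truth run/ground_truth.tsv --out run/priors.json
flowcall optimize-weight --flowgram run/flowgram.tsv --truth run/ground_truth.tsv --out run/sweep.tsv
flowcall call --flowgram run/flowgram.tsv --truth run/ground_truth.tsv \
        --method integrated --weight 0.28 --out run/calls.tsv
flowcall evaluate --calls run/calls.tsv --truth run/ground_truth.tsv --out run/eval.tsv
flowcall correct-reads --reads run/reads.fasta --calls run/calls.tsv --out run/corrected.fasta
```

All formats are plain text: flowgram TSV (the stand-in for binary SFF),
priors JSON, FASTA, and TSV reports; every writer is deterministic, so a
fixed seed reproduces every artifact byte-for-byte.

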