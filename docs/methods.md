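# Methods

## Problem

CTCF-CTCF chromatin loops co-bound with cohesin (RAD21) form insulated
neighborhoods, regulatory units that constrain enhancer-promoter contacts.
Somatic mutations at the CTCF binding sites (CBS) anchoring these loops can
abolish CTCF binding, dissolve the neighborhood, and de-repress the genes
inside — a recognized route to proto-oncogene activation. `ctcfkit`
implements the full computational chain: a sequence-based classifier of CTCF
binding, a variant scorer comparing reference and alternate alleles, an
insulated-neighborhood caller, and the downstream enrichment and
expression-intersection statistics.

## The binding classifier

**Input encoding.** A candidate site is a 100-bp window centered on a
ChIP-seq peak summit. The window is decomposed into overlapping k-mers
(k = 4, stride 1) and each k-mer replaced by its embedding vector, giving a
97 x 100 matrix per strand; the reverse-complement strand is encoded the
same way. Embeddings come from a skip-gram model (vector dimension 100)
trained on the genome being analyzed: k-mers are the tokens, the context is
a +/-5-token window, and the output softmax runs over the full 4^k
vocabulary, which is small enough (256 at k = 4) that no sampling
approximation is needed. k-mers containing N map to the zero vector, which
preserves the shape law (rows = L - k + 1) over masked sequence. Embedding
rows are frozen during classifier training so the encoder and the classifier
are independently testable.

**Architecture.** Both strand matrices pass through a shared stack of three
1-D convolutions (channels 64/64/32, kernels 8/4/4, each followed by ReLU
and max-pooling 2). Weight sharing across strands forces motif detectors to
be strand-reusable and halves the parameter count. The two pooled feature
sequences are concatenated along the sequence axis and read by one
bidirectional GRU (hidden size 64 per direction); the concatenated final
states feed a dense ReLU layer (64 units, dropout 0.2) and a sigmoid output
giving P(bound). Exact strand symmetry of the output is not architecturally
enforced — the GRU reads the concatenated sequence in a fixed order — so
|P(s) - P(revcomp(s))| is reported, not asserted.

**Training.** Binary cross-entropy, Adam (learning rate 1e-3, batch 64),
at most 12 epochs with early stopping once validation AUROC fails to improve
for more than 3 consecutive epochs; the best-validation parameters are
restored. All randomness (initialization, shuffling, dropout) derives from
one seed, and inference disables dropout, so training is reproducible and
prediction deterministic. The network and its backpropagation are
implemented directly in NumPy (float32, im2col convolutions, explicit BPTT
through the GRU); analytic gradients are verified against finite
differences in the test suite. Hyperparameters are package defaults exposed
in `ModelConfig`; they were sized for CPU-scale training on the synthetic
study (about 4,000 windows, a couple of minutes on one core).

**Evaluation.** AUROC with midrank tie handling (the Mann-Whitney
formulation); the test suite checks it against an O(n^2) concordant-pair
count.

## Sample construction

Positives are 100-bp summit-centered windows ([summit - 50, summit + 50));
when a narrowPeak record carries no summit (column 10 = -1) the peak
midpoint is used. Windows running off a chromosome end or containing >= 10%
N are dropped with a logged count. Each negative is drawn for one specific
positive by seeded rejection sampling of same-length windows until the
candidate matches the positive's GC content within +/-0.02 and its
soft-masked (lowercase) repeat fraction within +/-0.05, contains < 10% N and
overlaps no positive window; a positive with no match after 1,000 draws is
skipped. Matching per pair rather than per distribution makes the guarantee
checkable sample by sample, which the tests do by recomputing both
statistics from the emitted files. The tolerances are package choices —
tight enough that composition alone cannot separate the classes, loose
enough that matching succeeds for ~94% of positives on the 0.41-GC toy
genome.

## Variant scoring

For a variant inside a site's summit window, the scorer predicts binding on
the reference window (p_ref) and on the window carrying the alternate allele
(p_alt). The disruption call is `p_ref >= tau AND p_alt < tau` with
tau = 0.5 by default; delta = p_alt - p_ref ranks severity. SNVs substitute
in place. Indels are length-normalized deterministically around the original
summit: deletions are refilled from the right genomic flank, insertions
trimmed symmetrically (floor(extra/2) bases off the left). VCF alleles are
minimalized on read (shared prefix then suffix stripped), so a pure deletion
has an empty alternate allele and a pure insertion an empty reference
allele; fixture VCFs contain only SNVs, matching the simple-somatic-mutation
setting.

## Neighborhood calling and statistics

A loop (BEDPE) qualifies as an insulated neighborhood iff both anchors
overlap (>= 1 bp, half-open intervals) at least one CTCF peak and at least
one RAD21 peak, and at least one gene lies in the loop span. Containment
defaults to the whole gene body inside [left anchor start, right anchor
end]; a `tss` mode (5' end only) is available since the field uses both
conventions. When several peaks overlap an anchor, the evidence peak is the
one with the largest overlap, ties broken by higher signal then leftmost
start. A neighborhood is *mutated* when a variant falls inside an anchor's
CTCF evidence peak (a variant inside the anchor but outside the peak does
not count), and *disrupted* when any such variant is called disruptive by
the classifier; variants in the peak but outside the summit window are
flagged not-applicable and cannot drive the call.

Proto-oncogene enrichment uses the one-sided upper-tail hypergeometric test
P(X >= x) with N = all annotated genes, K = oncogenes in the universe,
n = neighborhood genes, x = the overlap — exact, no multiple-testing
correction since a single test is reported. The gene universe is the whole
supplied annotation. The differential-expression step is an intersection of
the disrupted-neighborhood gene set with three externally produced DE lists
(case-insensitive symbol match); producing those lists is out of scope.

## The synthetic study

The generator emulates the data shapes the pipeline consumes, with known
ground truth:

- **Motif.** A 19-position PWM shaped like the CTCF core: three central
  columns at consensus probability 0.97, six further core columns at 0.85,
  and weakly informative flanks (max 0.40). The seed permutes consensus
  bases, not the information profile.
- **Genome.** I.i.d. background at a stated GC (0.41 for domain A — roughly
  the human genome-wide value; 0.52 for domain B) with lowercase repeat
  stretches (mean 300 bp) at 10% density.
- **Sites.** PWM-sampled motif instances (random strand) planted on a jittered
  300-bp grid so site windows never overlap; each gets a 200-bp peak whose
  summit marks the motif center. The `small` preset plants 2,000 sites on a
  1.2-Mb genome.
- **Loops/genes.** Scenario blocks instantiate every qualification case:
  fully qualifying, missing RAD21 at one anchor, anchors without CTCF peaks
  (placed in a reserved site-free region), and spans without genes; decoy
  and universe genes live on a loop-free chromosome.
- **Variants.** Core ablations substitute the least-favored base at a
  maximal-information PWM column (strand-aware, reference base read from the
  genome); background SNVs sit 20-45 bp from the motif center, still inside
  the summit window. The free pool (200 + 200 in `small`) uses sites not
  serving as loop anchors. Sites anchoring loops carry consensus-strength
  motif instances — like the strong constitutive motifs at real CTCF
  anchors — so their reference windows are confidently bound, and each
  disruption-designated neighborhood receives a deletion of the full motif
  at its left anchor. The deletion, not a 1-bp ablation, defines the
  expected disrupted set because PWM-sampled training positives contain
  degenerate core bases: a motif damaged at a single position legitimately
  remains inside the learned positive class, so whether one SNV crosses tau
  is a matter of per-run calibration, whereas removing the motif is
  unambiguous. Single-SNV sensitivity is still measured, and reported
  separately, by the variant-direction check.
- **Expression lists.** Three DE lists each contain the designated survivor
  genes plus decoys drawn from outside the mutated/disrupted sets, so the
  three-way intersection with disrupted-neighborhood genes recovers exactly
  the survivors; the oncogene list overlaps the mutated-neighborhood genes
  strongly enough that the hypergeometric test is significant, with the
  attained p-value recomputed, never assumed.

Every fixture is byte-deterministic per seed and ships a truth record that a
self-audit re-derives from the emitted files alone.

**What the synthetic study does not show.** Real CTCF ChIP-seq peaks have
heterogeneous widths, motif multiplicity and cofactor context; real genomes
have non-i.i.d. composition (CpG islands, isochores) and structured repeats;
real somatic mutation burdens are orders of magnitude sparser and
signature-biased. Passing the synthetic study demonstrates that the
machinery is correct and that the model learns planted sequence signal under
composition-matched nulls — not that the specific AUROC values transfer to
real consortium ChIP-seq, ChIA-PET or tumor mutation data.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; GTF and VCF convert at the
  I/O boundary. Overlap means >= 1 shared base; abutting intervals do not
  overlap.
- GC of an all-N window is defined as 0; N fraction >= 10% disqualifies a
  window as either class.
- The hypergeometric tail is computed in log space (via `scipy`'s survival
  function) and clamped to (0, 1]; exactness to 1e-9 against integer
  enumeration is asserted for all N <= 40.
- Model bundles store a probe-batch checksum; loading re-predicts the probe
  and refuses bundles that do not reproduce to 1e-6.
- Ties in evidence-peak selection and all sort orders are broken
  deterministically so outputs are stable across runs.

## Known limitations

- The embedding uses a single fixed k (default 4); multi-length k-mer
  vocabularies are not implemented.
- One variant is scored at a time; compound haplotypes within one window are
  not composed.
- Strand-symmetry of predictions is approximate (see Architecture).
- The neighborhood caller takes loops as given; it does not infer loops from
  contact data.
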