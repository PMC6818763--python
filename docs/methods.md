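# Methods

## The analysis model

RNAi knockdown of a repressor de-represses its targets, so the set of
transcripts up-regulated more than two-fold in a knockdown fat-body
transcriptome (relative to an *iLuc* control) is treated as that
factor's repression target set. The pipeline's four stages operate on
these up-sets and on the 5-kb 5′-upstream regions of the genes they
contain. Differential expression is a pure fold-change rule on FPKM —
no count model, dispersion estimate or replicate-aware test is used,
because the underlying design has one library per treatment per
biological replicate; replicate agreement is instead assessed by set
intersection (the consensus of the per-replicate up-sets).

### Differential calling

* FPKM[t, s] = counts[t, s] / ((length_t/10³)·(library_size_s/10⁶)).
* Per replicate and per knockdown/control pair, the universe is the
  top-N transcripts (default N = 10,000) ranked by
  FPKM(treatment)+FPKM(control); ties break by transcript ID through a
  stable sort, so the subset is platform-independent.
* A transcript is "up" iff log2((FPKM_t + c)/(FPKM_ctl + c)) > 1
  **strictly**; an exact two-fold ratio is not called. The pseudocount
  c (default 0.01 FPKM, configurable) makes zero-control transcripts
  well defined. Down-calls are implemented symmetrically.

### KBS probe scan

The seed is the 30-mer silkworm Kr-h1 binding-site core; a one-base
sliding window yields L−k+1 probes (23 for k = 8), numbered KBS1… by
1-based window start. Scanning is exact string matching of the probe
and its reverse complement over each record; overlapping occurrences
all count; a window matching both strands (possible only for
palindromic probes) counts once; windows containing N never match but
remain in the window count.

The null model for "expected by random chance" is i.i.d. bases with
frequencies estimated from the scanned promoter set itself (uniform
and user-supplied backgrounds are available):
E[hits] = Σᵢ (Lᵢ−k+1)·[p(forward)+p(revcomp)], with the revcomp term
dropped for palindromes. Significance is the upper-tail Poisson
probability P(X ≥ observed); an exact binomial (success probability
E/n_windows) and an empirical dinucleotide-preserving shuffle null
(Altschul–Erickson walk on the transition multigraph, p = (1+r)/(m+1)
over m shuffles) are provided for robustness. No multiple-testing
correction is applied to the per-probe presentation; a Bonferroni
column is emitted alongside. Hit counts of different probes are not
de-duplicated against each other — adjacent 8-mers of one 30-mer
necessarily co-occur, and each probe is reported independently, with a
per-gene presence count emitted for the occurrences-vs-genes
ambiguity.

### Co-occurrence geometry

Coordinates are 0-based half-open within the upstream record; the last
base abuts the TSS, so "downstream" = larger coordinate and a hit's
TSS distance is L − end. Per gene with at least one KBS (default
pattern: the EMSA-validated 9-mer TCTATTTAG; the significant probe set
can be supplied instead) and one HBS (CACGTG), the pair minimising
|Δstart| is kept; ties prefer the pair closest to the TSS, then the
smaller KBS start. Distance is start-to-start (an edge-gap variant
would differ by the pattern-length offset; start-to-start was chosen
for symmetry since the measurement convention is otherwise
unspecified). Cohort fractions use strict thresholds (< 1000, < 300
bp); orientation fractions are computed over non-coincident pairs.
Note that reverse-complementing records maps start s to L−end, which
preserves nearest-pair distances only for equal-length patterns and
swaps the orientation labels; the corresponding test uses equal-length
patterns for this reason.

### Enrichment

Hypergeometric upper tail P(X ≥ k) with X ~ HG(N, K, n), where n and N
count only annotation-mapped genes; the background defaults to the
abundance-filtered universe rather than the whole transcriptome (the
original background is unstated; this choice conditions on
detectability). Significance is raw p < 0.01 as presented; a BH column
is included. Each transcript carries at most one category label.

## The synthetic-data generator

The generator emulates the statistical structure the analyses consume,
not the sequencing process: no reads, alignments or fragment counts
are simulated.

* **Expression**: baseline FPKM is log-normal (log10 mean 0.5, sigma
  0.6 — heavy-tailed abundance so that a top-10,000 selection is
  meaningful; the exact law is not load-bearing). The control column
  is the baseline; treatment columns multiply planted transcripts by
  2^log2fc (default 2, i.e. four-fold, comfortably above the two-fold
  threshold) and all treatment cells by unit-mean log-normal noise
  with coefficient of variation `noise_cv`. The noise model is a
  stand-in: the design offers no replicate-level dispersion to
  estimate. Planted baselines can be floored (bundles use 50 FPKM) so
  the abundance filter provably retains every planted transcript.
* **Overlap structure** is planted by explicit Venn-region partition
  (three-way region sizes are inputs), so intersection counts are
  exact by construction. Replicate Kr-h1 sets share a fixed consensus
  core plus disjoint per-replicate extras with a controlled Met
  overlap.
* **Promoters** are i.i.d. background with motifs written over the
  sequence at planned (gene, motif, strand, start) positions; minus
  strand plants are written as the reverse complement. Later plants
  overwrite earlier ones and truth records only sites whose final
  content survived. Study-scale bundles use a poly-C background so
  that observed counts equal planted counts exactly; since overlapping
  8-mers of one seed share 7 bases, each plant is padded with
  brute-force-verified flanking bases that produce no spurious probe
  window. Null-model calibration uses realistic uniform backgrounds
  instead.
* **Annotation**: exact mode assigns stated per-category counts within
  the target set and cycles all other genes round-robin through the
  alphabet (deterministic significance outcome); ratio mode draws
  categories with the planted category boosted by ratio/C for
  calibration experiments.

Passing on this synthetic data shows the pipeline computes the stated
quantities correctly on inputs with exactly the planted structure; it
does not validate the biological modelling choices (fold-change
thresholding, the i.i.d. null, start-to-start distances) against real
sequencing noise, alignment artefacts or promoter base composition.

## Numerical and engineering choices

* Problem sizes: the bundled study-scale run uses 12,000 transcripts ×
  4 treatments × 3 replicates, 212 + 130 five-kb promoters, and a
  10,000-transcript enrichment background; it completes in seconds.
  The small bundle (600 transcripts, tens of promoters) drives the
  test suite.
* All randomness flows through numpy Generators seeded from a single
  integer (independent spawned streams per generator), so every output
  is byte-reproducible; re-running any stage from its on-disk inputs
  reproduces its outputs (the run manifest records input checksums and
  stage counts).
* Poisson/hypergeometric tails come from scipy's log-space survival
  functions; p-values can underflow to 0 at astronomical excesses
  (observed ≫ expected), which is reported as computed.
* Degenerate inputs: empty promoter sets yield empty hit lists; an
  all-zero hit table flags no argmax; an empty pair cohort reports
  n = 0 with fractions flagged undefined; an unmapped target set warns
  and returns an empty enrichment table.
* The published external up-sets (e.g. a previously published *iMet*
  list) can be supplied as plain ID lists and override the computed
  set for that treatment, keeping prior-study derivations out of this
  pipeline.
* The supplementary tables of the original study are spreadsheet
  downloads; the repository instead validates every published quantity
  on the planted study-scale bundle, whose generator defaults encode
  those set sizes and fractions. Loader hooks (`external_up_sets`,
  plain-TSV expression tables) accept the real files when available.
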