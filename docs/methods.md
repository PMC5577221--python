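# Methods

## Model

`codoncontext` treats synonymous-codon choice as a supervised, context-
conditional classification problem. The object of inference is the
conditional distribution P(codon | peptide window) for the middle residue of
a short window, estimated in two stages:

1. a non-parametric stage — the codon-selection index (CSI), a lookup table
   from observed peptide windows to empirical middle-codon distributions —
   which is exact where the corpus has seen the window, and
2. a parametric smoothing stage — per-amino-acid random forests over
   similarity-pooled features — which generalizes to windows the corpus has
   not seen, by pooling records whose BLOSUM62 matched percent to the query
   exceeds a cutoff *c*.

The underlying assumptions: codon choice depends on a bounded local context
(at most ±3 residues; windows larger than 7 are not considered because the
peptide space outgrows any corpus); peptide similarity under BLOSUM62 is a
good proxy for context equivalence; and context effects are stable enough
across a corpus's genes to be learned from merged counts.

### CSI construction

Proteins are decomposed into all overlapping windows of *w* ∈ {3, 5, 7}
residues (windows never span genes; terminal stop codons are excluded).
Records merged over identical peptides store the occurrence count, the
middle-codon frequency distribution, and a per-position scalar: the mean,
over occurrences, of the corpus-wide within-amino-acid relative frequency of
the codon observed at that position. The per-position scalar reading (rather
than a full per-position codon distribution) keeps the feature vector a
fixed length 6 + *w* regardless of the flanking amino acids' degeneracy;
occurrence-level counts would be needed to reconstruct the alternative
reading, and the serialized format is versioned so it could be extended.

### Matched-percent search

For query *q* and record peptide *r* of equal length with identical middle
residue: *s* = Σᵢ B62(qᵢ, rᵢ), *m* = Σᵢ B62(qᵢ, qᵢ), *p* = *s*/*m*. BLOSUM62
diagonal dominance (every off-diagonal entry strictly below both diagonal
entries, verified exhaustively in the test suite) guarantees *p* = 1 iff
*q* = *r*. The threshold is inclusive (*p* ≥ *c*): a strict inequality would
make *c* = 1 select nothing, while the exact-match record is precisely what
*c* = 1 is meant to isolate. The feature vector is the mean of matched
records' (middle distribution padded to 6 slots in alphabetical codon order,
per-position averages), weighted by *s*; an unweighted mean is available
(`weighted=False`) since the two conventions differ only when matches have
unequal scores, and at *c* ≥ 0.8 all weights are strictly positive.

Search is a linear scan restricted to the middle-residue bucket, vectorized
over the bucket's integer-encoded peptide matrix; correctness against a
scalar exhaustive scan is asserted in the tests, including the float
comparison path (both sides compare on p = s/m in double precision).

### Classifiers and cascade

One multi-class random forest per degenerate amino acid (18 under the
standard code), labels being the synonymous codons themselves rather than a
binary high/low class: designed genes need codon-level output (the binary
view is recoverable through the frequency classes). 1000 trees by default;
all other forest hyperparameters are library defaults, recorded with the
model. Class order is alphabetical. Evaluation is stratified 10-fold
cross-validation with pooled out-of-fold predictions; AUC is macro-averaged
one-vs-rest (undefined for single-class sets, reported as absent); the
baseline predicts every row's high-frequency codon. Training rows come from
a corpus held out of the index — features for in-index genes would contain
their own labels.

The cascade orders the (w, c) grid as (7, 1.0) … (7, 0.8), (5, 1.0) …
(5, 0.8): longer windows and stricter cutoffs carry more context signal and
get priority; each residue is predicted by exactly one level, the first
whose search yields a match.

### Design rules

Positions 1–2 take the least frequent synonymous codon (positions encoding
single-codon amino acids, Met/Trp, are forced); the last two positions take
the modal codon; interior positions go through the cascade. A w = 7 level is
skipped for positions nearer the ends than three residues, so such positions
fall through to w = 5 automatically; positions 3 and L−2 reachable by no
window use the fallback. The fallback policy is configurable: `high`
(default, matching the all-high control), `low`, or `sample` (inverse-
frequency). The designed CDS is validated by re-translation before it is
returned; the stop codon defaults to TAA.

## Synthetic corpora

The generator emulates the one property the method exploits — codon choice
conditioned on a bounded peptide context — with everything else i.i.d.:
proteins are drawn residue-wise from a composition (Met start, TAA stop), and
each residue's codon comes from the first matching context rule with
probability λ (the rule's determinism), else from the genome-wide marginal.
Rules map 2k-character context patterns (k left neighbours then k right,
`*` wildcard) to codon distributions. Gene substreams are derived from the
corpus seed by counter, so corpora are byte-reproducible and order-
independent.

Defaults, chosen once as a realistic desk-scale stand-in for a multi-genome
corpus: 200 genes of 50–150 residues, uniform composition over a reduced
8-letter alphabet (A, E, G, K, L, R, S, V — spanning degeneracies 2, 4 and
6), and a geometric (1, ½, ¼, …) marginal over each amino acid's
alphabetically ordered codons so every amino acid has a unique modal codon.
The reduced alphabet is essential, not cosmetic: with 20 letters the 5-mer
space holds 3.2 × 10⁶ peptides and a desk-scale corpus would almost never
contain an exact window match, leaving the c = 1 pipeline stage untestable.

What the generator does *not* emulate — GC skew, codon-pair bias, operon
structure, gene-family redundancy, expression-level stratification — bounds
what passing tests show: they demonstrate that the pipeline recovers a
context rule that exists and is representable within its window, and that it
reports chance-level performance when none exists, not that real genomes
satisfy those conditions.

## Numerical and procedural choices

- Frequencies are normalized within each amino acid's synonymous set;
  normalized entropy uses log base 2 over the set size and is defined as 0
  for single-codon amino acids. Frequency-class ties break alphabetically.
- The per-record mean entropy at large *w* is biased downward when records
  have few occurrences (a 2-codon amino acid observed once has entropy 0);
  this is a property of the estimator shared by any corpus-based window
  analysis, and the entropy-trend tests therefore compare window sizes on
  corpora whose peptide spaces are densely populated, aggregating only over
  amino acids observed at every window size (Met never appears mid-window in
  synthetic corpora, having only the forced start position).
- Codon-usage distance uses the 59-dimensional within-amino-acid relative
  frequency vector (degenerate amino acids only), since usage *patterns* are
  compared after normalization; a raw 61-dimensional codon-fraction variant
  is available (`kind="fraction"`). Bootstrap replicates sample genes without
  replacement when the genome is large enough, with replacement otherwise;
  consensus-tree construction is delegated to external PHYLIP-compatible
  tools via the exported square matrices.
- RCBS uses the gene's own positional base composition as background:
  d(x,y,z) = (f(x,y,z) − f₁(x)f₂(y)f₃(z)) / (f₁(x)f₂(y)f₃(z)), and RCBS is
  the geometric mean of (1 + d) over the gene's codons minus 1, computed in
  log space.
- CSI files are versioned TSV with 6-decimal floats; round trips reproduce
  counts exactly and floats to 1e-6. Reading frames are validated strictly:
  length divisible by 3, no ambiguous bases, no internal stops; rejects are
  logged, never imputed.
- Genetic code: standard table 1 by default, table 11 selectable; the two
  agree on translating complete bacterial CDS bodies.

## Problem sizes

The test suite and the acceptance script run the pipeline at sizes chosen to
populate the reduced-alphabet peptide spaces densely: rule-recovery corpora
of ~10⁵ index residues with ≥ 5000 governed training windows; null-control
training sets truncated at 10⁴ rows (cross-validated with 200 trees — the
null properties do not depend on forest size, while the default classifier
keeps 1000 trees); entropy profiles over ~10⁵ windows; matcher-oracle
comparisons on ≥ 1000-record indexes with 100 queries at five cutoffs.

## Known limitations

- Exact-match coverage, and hence cascade depth actually exercised, depends
  on corpus size relative to the peptide space; for real genomes the w = 7
  index is expected to cover far less than w = 5, which is why the cascade
  falls through rather than failing.
- Single-class training sets produce constant classifiers (flagged, AUC
  absent); amino acids with no matched windows at a level are simply absent
  from that level and the cascade skips them.
- The designer does not avoid restriction sites, tune mRNA secondary
  structure, or model codon-pair bias; its output is a raw CDS.
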