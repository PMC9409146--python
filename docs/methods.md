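# Methods

This note documents the models, rules and numerical choices behind
cryptoseek, what the synthetic generators do and do not emulate, and the
known limitations of the approach.

## ORF model

A candidate cryptoprotein ORF starts at an AUG, ends at the first in-frame
canonical stop codon (UAA, UGA, UAG), and must be **strictly longer than
`min_codons` codons** (default 50; the stop codon is not counted, so the
default keeps products of ≥ 51 residues). Scanning covers the three
sense-strand frames only: inputs are transcripts, which are already
stranded, so reverse-frame scanning would manufacture sequences with no
biological reading. ORFs running off the 3' end without a stop are
discarded — a product whose C-terminus depends on unobserved sequence is
not a usable database entry. Coordinates are 0-based half-open on the
transcript as given.

Two start conventions are implemented because "all ORFs" is ambiguous:

* default (`all_starts=False`): one ORF per (frame, stop), anchored at the
  5'-most in-frame AUG after the previous stop — the convention of
  standard ORF callers; nested entries sharing a stop differ only by an
  N-terminal truncation and are redundant for database search;
* `all_starts=True`: every qualifying AUG, for users who want the literal
  enumeration.

Codons containing N translate to `X` even when the ambiguity is
synonymous, and ambiguous products are dropped by default: a residue that
cannot be stated exactly cannot be matched against a spectrum-derived
peptide.

For transcripts annotated `protein_coding`, the single largest enumerated
ORF is removed before the length filter (ties: 5'-most start, then lowest
frame). In practice this is the annotated CDS product; removing it leaves
alternate frames, uORFs and 3' ORFs — the non-canonical candidates.
Identical amino-acid products from different transcripts merge into one
entry carrying the full (transcript, biotype) provenance list; the first
source is the coordinate representative.

## Homology purge

The purge implements "no detectable homology to the canonical proteome"
at three fidelity/cost points.

**Exact mode (default).** An entry is removed when any of its fully
tryptic peptides (cleavage after K/R except before P, zero missed
cleavages) of length ≥ `kmer_len` (default 8) occurs verbatim in any
canonical protein, with isoleucine folded onto leucine by default (I and L
are isobaric and indistinguishable by conventional MS/MS). This is the
criterion that matters operationally: an entry whose observable peptides
all exist canonically can never be confidently identified as
non-canonical. Eight residues is the shortest peptide routinely accepted
as an identification, so `kmer_len < 5` is rejected outright. The purge is
audited post hoc: a scan of every kept entry's peptides against the
proteome must find zero matches.

**Align mode.** Local alignment of each entry against each canonical
protein (BLOSUM62, affine gaps 11/1) with a Karlin–Altschul E-value,
E = K·m·n·exp(−λS), using the standard gapped BLOSUM62 parameters
(λ = 0.267, K = 0.041) and a configurable search-space size n. Entries at
E ≤ 0.01 are removed. This emulates a BLASTP screen without an external
aligner and is quadratic in database size, so it is intended for fidelity
checks rather than routine use. The E-value *direction* deserves a note:
a small E-value indicates a significant alignment, i.e. homology, and
homologous candidates are the ones discarded.

**Import mode.** A 12-column BLAST tabular file from any external aligner
is applied directly: entries with a hit at E ≤ threshold are removed with
the best row as evidence; entries absent from the file are kept. This is
the route for purging against large references (e.g. nr), which are out
of scope to bundle.

## Two-pass assignment and quantification

Pass one marks every PSM whose peptide occurs (I/L folded) as a substring
of any canonical protein as `canonical`; these are never reconsidered.
Pass two takes the remaining PSMs with peptide q-value strictly below
`fdr_max` (default 0.10) and maps the peptide against cryptoDB entries by
substring occurrence. Only uniquely mapping peptides are assigned;
multi-mapping PSMs are dropped and counted, never split or double-counted
(after sequence-level deduplication in the build, a shared peptide is
genuinely ambiguous). The five-way partition — canonical, crypto,
FDR-dropped, ambiguous, unmatched — conserves the input count exactly and
is checked on every run.

The package deliberately does not rescore spectra: upstream search engines
produce the PSM tables, and the contribution here is the database logic
and downstream statistics.

Abundance is spectral counting: cell (i, s) of the quantification matrix
is the number of crypto-assigned PSMs of entry i in sample s. A row is
retained when, within at least one cohort, total PSM ≥ 5 and the entry is
detected in ≥ 2 samples; selection is per cohort because each cohort is a
separate experiment with its own feature list.

## Cohort statistics

The statistical unit is the **pool** (pooled plasma samples), and the
default exposure coding is **binary detection** (count > 0) per pool.
Spectral counts from pooled immuno-enriched material are zero-inflated and
semi-quantitative; presence/absence is the robust signal, and reported
odds ratios in this setting are detection contrasts. Abundance coding
(log1p counts) is available as an option. Pool sizes are carried for
reporting but not used as weights — no principled weighting exists without
individual-level data.

* **Newly diagnosed screen**: fc = mean(case counts) / mean(control
  counts); a hit is `case_exclusive` (all control cells zero, ≥ 1 positive
  case cell) or fc strictly greater than 2. An optional pseudocount
  produces finite fold-changes for zero means without changing the
  exclusivity flags.
* **Pre-diagnostic screen** (matched pools): conditional logistic
  regression of case status on detection within matching strata. The
  binary-exposure conditional likelihood is maximized by Newton iteration
  on its exact form: within a stratum of size n with m cases and k exposed
  members, the denominator is a sum over C(n, m) case sets that collapses
  to a noncentral-hypergeometric sum with weights C(k, j)·C(n−k, m−j), so
  the score and information are the mean and variance of the tilted count
  j. For 1:1 strata this reduces to the discordant-pair ratio n₁₀/n₀₁.
  Continuous exposures fall back to statsmodels' ConditionalLogit.
  Unmatched designs use ordinary logistic regression (statsmodels), whose
  MLE for a single binary predictor equals ad/bc.
* **Inference**: Wald one-sided p in the elevated direction (OR > 1) and
  Wald 95% CIs. Under separation (a zero cell; all-discordant-one-way
  strata) the Haldane–Anscombe 0.5 correction is applied and the row is
  flagged `separation_corrected`; degenerate exposures (detected
  everywhere or nowhere) are flagged `not_estimable` with NaN estimates
  rather than raising.
* **Wilcoxon rank-sum** (two-sided) accompanies every row: when combined
  n ≤ 20 the exact null distribution of the mid-rank sum is built by
  dynamic programming over the tie-adjusted rank multiset (half-unit ranks
  doubled to integers), and p = P(|W − E W| ≥ |w_obs − E W|); larger
  cohorts use the tie-corrected normal approximation.

Hit thresholds (fc > 2, OR ≥ 2, α = 0.05 one-sided) are configurable; no
multiplicity correction is applied in the screens, which are explicitly
discovery-oriented.

## Synthetic data generators

The fixtures module generates every input format the pipeline reads, with
ground truth, from a single integer seed (`numpy.random.default_rng`;
outputs are byte-identical across runs and hash seeds).

* **Transcriptomes**: uniform-random background sequence; planted ORFs are
  random proteins back-translated with random synonymous codons, placed
  behind an immediately adjacent in-frame upstream stop so the 5'-most-AUG
  convention recovers them at their recorded coordinates. Planted proteins
  are regenerated until they contain a tryptic peptide of ≥ 8 residues, so
  the purge and the assignment can both "see" them.
* **Proteomes**: random proteins (200–400 aa). Decoy homologs for
  `should_survive_purge=False` plantings are created by appending one long
  tryptic peptide of the planting to a random protein (appending, so a
  later decoy cannot split an earlier one). Survivor plantings are
  verified to share no folded 8-mer with the proteome.
* **Cohorts**: per (cryptoprotein, pool) spectral counts are negative
  binomial — the standard overdispersed model for counts — with mean 8 and
  dispersion 5 by default, a realistic depth for an enriched pooled
  profile in which a detected protein yields a handful of spectra per
  run. Planted effects set the case/control mean ratio (`fold_change`),
  structural control zeros (`case_exclusive`), a detection-probability
  contrast with a given odds ratio (`odds_ratio`, zero-truncated counts
  when detected), or nothing (`null`). Contaminant PSMs exercise every
  filter: a 5% fraction with q-values above the FDR threshold, 10% with
  canonical-substring peptides, 2% matching nothing. Pool sizes default to
  the screening ranges (3 patients per newly diagnosed case pool, 4–14 per
  pre-diagnostic case pool, 8–30 per control pool).

What the generators do **not** emulate: real peptide detectability
(ionization, length/charge biases), shared peptides between paralogous
cryptoproteins, correlated protein abundances, batch effects, or any
biology linking biotype to expression. Passing tests therefore demonstrate
the correctness of the database logic, filters and estimators under the
stated statistical model — not discovery performance on real plasma data.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at sizes chosen to characterize behavior well: 1,000 random transcripts
(≤ 2 kb) for enumeration-oracle equivalence, 500 candidates / 200 proteins
/ 100 planted decoys for purge soundness, and 50 replicated cohorts of 200
cryptoproteins across 10 case / 6 control pools for end-to-end recovery.
Full-transcriptome database builds (tens of millions of nucleotides) use
the same code path via `cryptoseek build-db` and scale linearly; the
enumerated count is sensitive to the `all_starts` convention, so both are
exposed.

## Known limitations

* With only 6 matched 1:1 strata — the realistic pre-diagnostic design —
  Wald inference on (corrected) conditional estimates reaches one-sided
  p < 0.05 only at complete 6:0 discordance, so per-study power for the
  OR screen is low even for strong effects, although the OR estimator
  itself is approximately unbiased (median estimate ≈ 4 for planted
  OR = 4). An exact conditional (sign-test) p-value would be more
  powerful at these sizes; it is not the default because the package
  standardizes on Wald inference across both regression screens.
* Exact-mode purging is a peptide-level screen, not an evolutionary
  homology search; distant homologs sharing no exact tryptic ≥ 8-mer
  survive it (by design — they remain MS-distinguishable).
* Peptide-to-entry mapping trusts the upstream engine's peptide calls;
  site-localized modifications, semi-tryptic peptides and missed
  cleavages are outside the current matching rules.
* The quantification is spectral counting; no intensity-based or
  length-normalized abundance (NSAF, iBAQ) is implemented.
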