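# cryptoseek

Discovery of **cryptoproteins** — proteins translated from reading frames
and transcripts outside the canonical annotation (alternate ORFs,
pseudogenes, retained introns, lncRNAs, UTRs) — from standard proteomics
identifications, with case/control scoring for cancer-association screens
such as immunoglobulin-bound plasma profiling.

Non-canonical translation is a recognized source of tumor neoantigens, and
autoantibodies against such products are candidate early-detection markers
in lung cancer. Searching spectra directly against a naive six-frame
database drowns the signal in false positives, so the approach implemented
here is database-side: enumerate candidate non-canonical ORFs, aggressively
purge anything a mass spectrometer could confuse with the canonical
proteome, and only then assign peptide identifications.

## Pipeline

1. **ORF enumeration** (`orf_enumerator`). Each transcript is scanned on
   the three sense frames for ORFs that start at AUG, end at a canonical
   stop (UAA/UGA/UAG), and exceed 50 codons. For transcripts annotated
   `protein_coding`, the single largest enumerated ORF — the annotated
   product — is excluded, leaving only non-canonical candidates. Identical
   products are merged with full provenance.
2. **Homology purge** (`homology_purge`). A candidate is removed if any of
   its fully tryptic peptides of length ≥ 8 occurs in the canonical
   proteome (I/L folded — isobaric residues are indistinguishable by MS).
   A local-alignment mode (BLOSUM62, Karlin–Altschul E ≤ 0.01) and an
   import mode for external BLASTP tabular output are also provided.
   The survivors form the cryptoprotein database ("cryptoDB").
3. **Two-pass assignment** (`twopass_assign`). PSMs matching the canonical
   proteome are filtered out first; the remainder are mapped to the
   cryptoDB under a peptide FDR < 10%, with multi-mapping peptides dropped.
   Abundance is spectral counting; cryptoproteins are retained with
   summed PSM ≥ 5 and detection in ≥ 2 samples per cohort.
4. **Cohort statistics** (`cohort_stats`). Newly diagnosed cohorts:
   case-exclusivity and fold-change (> 2) on pool means. Matched
   pre-diagnostic cohorts: odds ratios on binary detection via logistic or
   conditional-logistic regression (hit: OR ≥ 2, one-sided p < 0.05), plus
   two-sided Wilcoxon rank-sum p-values (exact with mid-ranks for ≤ 20
   pools).
5. **Synthetic fixtures** (`synthetic_fixtures`). Seeded generators for
   transcriptomes with planted ORFs, proteomes with planted homolog
   decoys, and pooled case/control PSM cohorts with known effects — every
   pipeline stage is testable without downloads.

For a 2×2 detection table (a = detected cases, b = detected controls,
c / d undetected), the logistic maximum-likelihood odds ratio is the
cross-product ratio *ad/bc*; for 1:1 matched strata the
conditional-logistic MLE is the discordant-pair ratio n₁₀/n₀₁. Both
identities are enforced in the test suite to 1e-6, and zero cells fall
back to the Haldane–Anscombe 0.5 correction with an explicit flag.

## Worked example

```python
import cryptoseek as cs

# synthetic study: 36 planted ORFs (6 with canonical homologs), 60-protein proteome
specs = [cs.PlantedOrfSpec(f"p{i:02d}", should_survive_purge=(i >= 6)) for i in range(36)]
transcripts, proteome, truth = cs.simulate_transcriptome(10, planted_orf_specs=specs, seed=11, n_proteins=60)

db = cs.build_orf_database(transcripts)          # enumerate candidates
kept, report = cs.purge(db, proteome)            # remove canonical homologs
print(len(db), "candidates ->", len(kept), "cryptoDB entries,", len(report), "purged")

design = cs.make_design(10, 6, seed=11)          # 10 case pools, 6 control pools
effects = {e.orf_id: ("null", 1.0) for e in kept}
for e, kind in zip(kept[:16], ["case_exclusive"] * 8 + ["fold_change"] * 8):
    effects[e.orf_id] = (kind, 4.0 if kind == "fold_change" else 1.0)
psms, _ = cs.simulate_psm_cohort(kept, design, effects, seed=11, proteome=proteome)

cs.partition_canonical(psms, proteome)           # pass 1: canonical filter
assigned, pep2orf, summary = cs.assign_and_filter(psms, kept)
print(f"canonical={summary.canonical} crypto={summary.crypto} fdr_dropped={summary.dropped_fdr}")

qm, _ = cs.quantify_and_select(assigned, pep2orf, design)
hits = cs.classify_hits(cs.fold_change_table(qm, design))
print(len(hits), "cancer-associated cryptoproteins")
```

Output:

```
37 candidates -> 31 cryptoDB entries, 6 purged
canonical=576 crypto=5760 fdr_dropped=288
16 cancer-associated cryptoproteins
```

37 enumerated candidates shrink to 31 after the purge removes the 6
planted homologs; of ~6.6k simulated PSMs, 576 matched the canonical
proteome and were filtered in pass one, 288 failed the FDR threshold, and
5760 were assigned to cryptoDB entries. The hit table recovers exactly the
16 planted case-exclusive and fold-change-4 cryptoproteins.

The same stages are available from the shell:

```bash
cryptoseek simulate --seed 11 --outdir demo/
cryptoseek build-db --transcripts demo/transcripts.fa --dialect gencode --out demo/db.fa
cryptoseek purge --db demo/db.fa --proteome demo/proteome.fa --out demo/cryptodb.fa
cryptoseek assign --psms demo/psms.tsv --db demo/cryptodb.fa --proteome demo/proteome.fa --out demo/assigned.tsv
cryptoseek quantify --psms demo/assigned.tsv --db demo/cryptodb.fa --design demo/design.tsv --out demo/matrix.tsv
cryptoseek stats --matrix demo/matrix.tsv --design demo/design.tsv --out demo/stats.tsv
```

## Documentation

See `docs/methods.md` for the statistical model, generator assumptions,
numerical choices and known limitations.
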