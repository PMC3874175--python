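# intronreg

A gene-centered toolkit for studying how transcription factors (TFs) use
**first introns** as regulatory elements in compact genomes, designed
around the *C. elegans* / *C. briggsae* comparison.  It is aimed at
regulatory genomicists who want to run — or stress-test on synthetic data
with known ground truth — the full analysis chain from genome annotation
to network statistics:

1. **Gene classification and fragment extraction** (`intronreg.genome`).
   Genes are decomposed into a promoter (start codon to ≤ 2 kb upstream,
   truncated at the nearest neighboring gene boundary), numbered coding
   exons and introns; numbering follows the gene's transcriptional 5′→3′
   direction, so "intron 1" is the intron nearest the ATG on either
   strand.  *Conventional genes* — no 5′-UTR intron, a unique first
   coding exon, not downstream within an operon — are the analysis
   universe, because only for them is the first intron the intron nearest
   the transcription start.
2. **Cross-species intron length conservation** (`intronreg.orthology`).
   Orthologous exons are paired by translated local alignment (3 × 3
   reading frames, BLOSUM62, reciprocal best hit); genes with identical
   exon–intron structure are compared intron-by-intron with the
   length-conservation ratio *r* = max(ℓ_A, ℓ_B)/min(ℓ_A, ℓ_B) ≥ 1,
   excluding introns ≤ 500 bp in both species, with a two-sided
   Mann–Whitney U test of first vs other introns.
3. **Energy-matrix motif scanning** (`intronreg.motifscan`).  A PWM is
   converted to per-position binding energies ε_i(b) = ln(max_b′ f_i(b′)
   / f_i(b)); a window scores E = Σ ε_i(s_i) and its occupancy is
   1/(1 + e^{E−μ}).  Sites are called at occupancy ≥ 0.09
   (E ≤ ln(1/0.09 − 1) ≈ 2.31 kT).  A TF predicted in both species'
   orthologous fragments is a *conserved predicted interaction*.
4. **ChIP peak assignment** (`intronreg.chip`).  Peak midpoints are
   assigned to every containing fragment; per region class the number of
   *distinct* TFs is summarized, with length–binding correlations and the
   per-gene promoter∕intron overlap fraction O/I.
5. **PDI network statistics** (`intronreg.pdi`).  Protein–DNA interaction
   (PDI) edges (TF, gene, region) give per-gene TF sets; pairwise Jaccard
   similarity (promoter-only, intron-only, or pooled) is tested for
   association with co-expression (Fisher exact on a 2 × 3 binning),
   plus genome projection through intron-length bins and hypergeometric
   gene-family enrichment with Benjamini–Hochberg correction.
6. **In-degree modeling** (`intronreg.degree`).  Per-region TF counts are
   fit with an exponential (λ̂ = n/Σx); the per-gene promoter + intron sum
   is compared against the hypo-exponential
   f(x) = λ₁λ₂/(λ₂−λ₁)·(e^{−λ₁x} − e^{−λ₂x}) it predicts, vs a directly
   fitted single exponential (log-likelihood and KS distance).
7. **Synthetic two-species generator** (`intronreg.simulate`).  Emits
   FASTA/GFF3/BED/TSV inputs with planted ground truth for every stage,
   fully deterministic under a single seed.

## Worked example

```sh
python examples/06_in_degree_models.py
```

prints

```
promoter rate from screen totals: lambda_P = 0.145 (mean 6.89 interactions per promoter)
fitted rates: lambda_P = 0.147, lambda_I = 0.311
predicted combined mean: 10.02; observed: 10.02
log-likelihood  hypo-exponential: -6392.6  single exponential: -6609.4
KS distance     hypo-exponential: 0.0585  single exponential: 0.1792
hypo-exponential preferred: True
```

The first line is the worked example from a promoter screen's printed
totals (827 interactions over 120 promoters → λ_P = 0.145; 1/λ is the
mean in-degree).  The rest fits 2000 simulated genes: the per-gene sum of
promoter and first-intron in-degrees is better described by the
hypo-exponential predicted from the two per-region fits than by a single
exponential — promoter and first-intron interactions behave as
independent exponential components of a gene's regulatory input.

The other scripts in `examples/` each demonstrate one capability
(classification, length conservation, motif scanning, ChIP assignment,
similarity vs co-expression) on a small synthetic input and print what
the numbers mean.  `intronreg run-all --simulate --seed 7 --outdir out/`
runs every stage end-to-end from the command line and writes per-stage
TSV/JSON reports plus a `summary.json` echoing every threshold used.

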