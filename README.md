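# ernet

Co-expression network analysis of transcribed transcriptional regulatory
elements (tTREs) from strand-specific capped nascent-RNA 5′-end signal
(PRO-cap/GRO-cap style data).

Enhancers and promoters initiate unstable bidirectional transcripts whose
5′ ends mark transcription start sites at single-base resolution. Across a
cohort of individuals, the covariation of this nascent signal between
regulatory elements traces a co-expression network: correlation decays
with genomic distance, is shaped by the transcription factors bound
between or at the elements, parallels chromatin contact frequency, and —
at the shortest range — depends on the relative orientation of the
transcribing polymerases. `ernet` implements that whole analysis as a
tested library plus CLI, together with a synthetic-cohort generator that
plants every one of those structures with known ground truth.

## What it computes

- **tTRE calling** — strand-specific local maxima of the merged 5′ track
  in a 300-bp window, deduplicated within 150 bp, paired into divergent
  elements (minus-strand TSS 50–250 bp upstream of a plus-strand TSS),
  quantified per library as reads-per-million (RPM).
- **Variably expressed elements** — per element, a one-sided Wilcoxon
  rank-sum test of between-individual vs between-replicate absolute
  log₂ deviations; Storey's π₀ from the uniform tail of the p-value
  distribution; q-value selection at FDR < 0.2.
- **Distance-dependent co-expression** — Pearson *r* for all
  intrachromosomal pairs of variable elements within 5 Mb; decay curves
  as per-distance-bin order statistics (upper 5th percentile, median) in
  equal-count bins of 1000 pairs; an empirical Gaussian null (mean 0,
  fitted sd) from interchromosomal or >1 Mb pairs; a genotype-independence
  filter removing pairs whose in-element SNPs are correlated in the
  cohort; element-to-mRNA correlation with signed distances.
- **TF dependency (ΔAUC)** — pairs split by the number of TF binding
  sites between them (intersection: ≥2 vs ≤1) or on them (occupancy);
  ΔAUC = AUC(no/low-TF curve) − AUC(with-TF curve) over 0–200 kb;
  significance z = (ΔAUC − bg_mean(n)) / bg_sd(n) against a null of
  uniformly re-placed sites evaluated on a grid of site counts and
  interpolated in log(count); Ward clustering of TFs on signed
  significance.
- **Chromatin-contact integration** — per-pair contact frequency at the
  declared bin resolution, linear-scale subtraction of the
  distance-matched non-TRE background, contact decay curves and contact
  ΔAUC through the same machinery, and a cross-modality comparison with
  robust outlier flagging.
- **Strand orientation** — for adjacent element pairs (250 bp–10 kb),
  sense / convergent / divergent strand correlations, k-nearest-neighbour
  local-regression distance trends, and a Welch t-test of convergent vs
  divergent correlation in a short-range window; adjacent vs interleaved
  comparison.

## Worked example

Generate a small synthetic cohort (75 libraries = 67 individuals with 8
replicate pairs), call elements from its rendered tracks, and run the
variability and co-expression stages:

```sh
ernet simulate --preset small --seed 1 --out-dir cohort/
ernet variability --ttres cohort/ttres.tsv --design cohort/design.tsv \
    --out var.tsv
ernet coexpr --ttres cohort/ttres.tsv --design cohort/design.tsv \
    --pairs-per-bin 200 --out pairs.tsv
```

which prints, for seed 1:

```
wrote small cohort (200 tTREs) to cohort/
pi0 = 0.620; 98/200 variable at FDR < 0.2
1561 pairs, null sd 0.1266, median r first/last bin 0.162/0.013
```

Read: the cohort planted 40% variably expressed elements, and the
uniform-tail estimate π₀ = 0.62 of true nulls recovers that (upper bound
1 − 0.62 = 38% variable; 98 elements pass FDR < 0.2). The
spurious-correlation null sd 0.127 is close to the independent-pair
prediction 1/√66 ≈ 0.123, and the binned median correlation falls from
0.16 in the nearest 200-pair bin to ≈ 0 at 5 Mb — the planted
exponential distance decay.

The same stages run from Python; see the module docstrings in
`src/ernet/` for the library surface.

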