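# dualseed

Dual-seed targetome analysis of canonical miRNAs versus their 5′-isomiRs.

## The problem

5′-isomiRs are mature miRNA variants produced by imprecise Drosha/Dicer
cleavage: trimming *k* nucleotides from the 5′ end re-registers the seed
region (nucleotides 2–7 for a "6mer" seed, 2–8 for "7mer-m8"), so a +k
isomiR is usually expected to regulate a different set of mRNAs than its
canonical form. For some miRNAs, however, the canonical 6mer site and the
shifted 7mer-m8 site co-occur in the same transcripts — sometimes as one
contiguous (k+7)-nt "extended" match — so canonical and isomiR targetomes
overlap instead of diverging. `dualseed` quantifies that overlap for
transcriptome-scale data. It is aimed at small-RNA/transcriptomics analysts
who have mature miRNA sequences, a transcriptome (FASTA + GTF), and paired
miRNA/mRNA count matrices.

## What it computes

* **Seed geometry** (`dualseed.isomir`): isomiR notation (`name|+k|+nX`),
  shifted sequences, 6mer/7mer-m8 seeds, mRNA-sense DNA site motifs
  (reverse complements), and extended dual-seed motifs of length k+7.
* **Site scanning** (`dualseed.scan`): transcript loading from FASTA + GTF
  (3′-UTR placed from stop-codon/CDS features), exact overlapping motif
  scans, extendability flags, per-gene target sets
  (targetome = genes with ≥ 1 site).
* **Normalization** (`dualseed.expression`): median-of-ratios size factors
  `s_j = median_i c_ij / (∏_k c_ik)^{1/n}`, FPKM and RPM with
  `log2(1 + x)`, the 99% cumulative-abundance filter, and an expression
  threshold on median `log2(1 + FPKM)`.
* **Anticorrelation screen** (`dualseed.association`): per-gene Spearman ρ
  against the focal miRNA, Benjamini–Hochberg adjustment, Mann–Whitney
  comparison of ρ between genes with and without the canonical seed.
* **Overlap & enrichment** (`dualseed.overlap`): Jaccard index
  J = |A∩B| / |A∪B| of canonical vs isomiR targetomes, percentile ranks,
  6mer→extended-site extension ratios, Fisher exact enrichment
  (sample odds ratio ad/bc).
* **Synthetic studies** (`dualseed.simulate`): transcriptomes with planted
  canonical-only / isomiR-only / dual sites at controlled rates and
  negative-binomial count matrices with planted repression
  `mean = μ_i0 · L_j · exp(−β_i z̃_j)`, plus a background-corrected
  estimator that recovers the planted Jaccard from observed target sets.

## Worked example

The canonical hsa-miR-93-5p sequence is `CAAAGUGCUGUUCGUGCAGGUAG`; its +4
isomiR starts at nucleotide 5. Seed sites in an mRNA fragment of the miR-93
shRNA stem:

```python
from dualseed import IsomiR, MatureMiRNA, make_extended_motif, scan_sites

mir93 = MatureMiRNA("hsa-miR-93-5p", "CAAAGUGCUGUUCGUGCAGGUAG")
print(IsomiR(mir93).seed_motif("6mer").site_seq)            # CACTTT
print(IsomiR(mir93, shift5=4).seed_motif("7mer-m8").site_seq)  # AACAGCA
ext = make_extended_motif(mir93, 4)
print(ext.site_seq, ext.length)                             # AACAGCACTTT 11

fragment = "CTACCTGCACGAACAGCACTTTGTT"
print(scan_sites(fragment, "CACTTT"))       # [17]
print(scan_sites(fragment, "AACAGCA"))      # [12]
print(scan_sites(fragment, ext))            # [12]
```

The canonical 6mer site at position 17 lies inside the 11-nt extended site
starting at 12, i.e. this fragment is a dual-seed target of both the
canonical miRNA and its +4 isomiR.

A full run on synthetic data, from the shell:

```bash
dualseed simulate --seed 1 --outdir data/
dualseed run --config config.yaml   # paths to the data/ files, see docs/methods.md
```

This writes the association table (per-gene ρ, adjusted p, seed flags), the
per-miRNA Jaccard tables for the +3 and +4 isomiRs, the extension-ratio
table, the enrichment report and a reproducibility manifest. On the default
synthetic study (2,000 genes, planted dual-site rate 0.3 out of 0.5 total
planting), the focal miRNA ranks first in the +4 Jaccard table (observed
J ≈ 0.51 including background hits; background-corrected estimate ≈ 0.59
against the planted 0.6), its planted targets are strongly enriched among
anticorrelated genes, and the seed/no-seed Mann–Whitney comparison is
overwhelmingly significant.

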