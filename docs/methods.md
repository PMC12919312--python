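# Methods

## Seed model

A mature miRNA is an RNA string (≥ 16 nt). A 5′-isomiR is defined by a 5′
shift `k ≥ 0` (nucleotides trimmed from the 5′ end) and an optional
non-templated 3′ addition; its sequence is the parent sequence minus the
first `k` nucleotides plus the 3′ suffix. Negative shifts (5′ extensions)
are rejected rather than ignored: deriving them would require genomic
context that a mature-miRNA FASTA does not carry. Seeds are positional —
nucleotides 2–7 (6mer) or 2–8 (7mer-m8) of the mature sequence — so the
seed of a +k isomiR equals parent nucleotides (2+k)…(7+k or 8+k), and 3′
additions never change any seed. The string actually searched in mRNA is
the seed's reverse complement transliterated to DNA ("site motif").

An *extended site* for shift `k` is the reverse complement of canonical
nucleotides 2…(k+8): a contiguous (k+7)-nt mRNA match whose last 6 nt are
the canonical 6mer site and whose first 7 nt are the +k isomiR's 7mer-m8
site (11 nt for k = 4). A canonical 6mer site is *extendable* when the
window ending at its last base matches the extended site.

Matching happens in DNA space on the stored sense-strand spliced sequence;
input is uppercased and any window containing a non-ACGT character is a
non-match. Internal coordinates are 0-based half-open; emitted positions
are 1-based closed (GTF convention).

## Transcripts and regions

Transcripts are loaded from a FASTA plus a GENCODE-style GTF. Both FASTA
dialects are auto-detected: genomic contigs (spliced sequence assembled
from exons, reverse-complemented on the minus strand) or spliced transcript
sequences keyed by transcript id. The 3′-UTR starts immediately after the
stop codon (mapped through the exon structure); when only CDS features are
present the stop codon is assumed to occupy the next three spliced bases.
Version suffixes (".N") on ids are stripped by default.

Gene-level target calls use one representative transcript per gene, by
default the longest spliced isoform (ties broken by smallest transcript
id); `longest_utr3` and `all_union` (a gene is a target if any isoform has
a site) are available. The scanned region defaults to the full mRNA, with
`utr3` as an option — enrichment holds in both, and the union/restriction
relationship (`utr3` targets ⊆ `full_mrna` targets) is property-tested.

## Normalization

mRNA counts: median-of-ratios size factors (reference genes = rows positive
in all samples; geometric means computed in log space), then
FPKM = normalized × 10⁹ / (length × column total) with union-exon gene
lengths from the GTF, then log2(1 + FPKM). miRNA counts: the same size
factors, then RPM (no length normalization), then log2(1 + RPM).
Scale tags make each transition explicit; applying a step twice or
filtering on the wrong scale is an error.

The abundance filter ranks rows by median expression (descending; ties by
row id) and keeps the minimal prefix reaching 99% of the cumulative median
sum, with ties at the cut kept together. Medians are taken on the *linear*
(FPKM/RPM) scale: a cumulative share of total expression is only additive
there. The expressed/not-expressed call for a gene list uses median
log2(1 + FPKM) ≥ 1.0 (closed bound).

## Statistics

* **Spearman**: average-rank ρ (tie correction implicit in
  Pearson-of-ranks); two-sided p from the t approximation for n ≥ 10 and
  exact enumeration over rank permutations below that. Samples are paired
  by shared id, never by column position; constant vectors are flagged and
  excluded from the multiple-testing family.
* **BH adjustment** is the step-up procedure (delegated to statsmodels and
  verified against a hand step-up oracle in the tests). The family is all
  genes that survive the abundance filter and have defined ρ. A gene is
  significantly anticorrelated when ρ < 0 and adjusted p < α (default 0.05).
* **Mann–Whitney** (seed vs no-seed ρ distributions): exact null when both
  groups have n ≤ 8 and no ties, tie-corrected normal approximation
  otherwise; the reported direction is by mean rank.
* **Fisher enrichment**: 2×2 tables over an explicit gene universe; the
  sample odds ratio ad/bc is reported (the conventional default; +inf is
  flagged when bc = 0), with the two-sided point-probability exact p.
* **Jaccard** |A∩B|/|A∪B| is NaN (flagged, written as NA) when both target
  sets are empty; extension ratios are reported at both site level
  (extendable sites / all 6mer sites) and gene level (genes with ≥ 1
  extendable site / genes with ≥ 1 canonical site), since both granularities
  are meaningful summaries of the same annotation.

## Synthetic-data generator

The generator emulates the statistical structure of a tumor-cohort study:

* **Transcriptome** — single-exon genes on individual contigs, i.i.d.
  uniform-GC (default 0.5) sequence, lognormal lengths (median 1,500 nt,
  log-sd 0.4, minimum 300), last third annotated as 3′-UTR. Per gene, one
  planting class is drawn: canonical-6mer-only (0.1), isomiR-7mer-m8-only
  (0.1), dual extended site (0.3), or none; the site string is written into
  the 3′-UTR at a uniform position. Truth labels come from *re-scanning*
  the emitted sequences, so chance background hits are labeled truthfully.
* **Expression** — per sample, focal-miRNA log2 abundance ~ N(10, 1) and a
  lognormal library factor (log-sd 0.2); mRNA counts are negative binomial
  (dispersion 0.1) with mean μ_i0 · L_j · exp(−β_i z̃_j), where z̃ is the
  standardized focal log-abundance and β_i = 1 for every planted target.
  Multiplicative repression is the simplest monotone model producing
  negative rank correlation — the only property the analysis consumes; no
  biophysical realism is claimed. Focal isomiR rows are 2% of the canonical
  row plus counting noise (tumor-like trace expression). A small block of
  normal-tissue samples exercises sample-type selection.
* **Downregulated-gene list** — all planted targets share one β, so the
  emulated experimental hit list is a seeded random sample (default 54) of
  the genes with a planted isomiR site.
* Default cohort size is 100 primary-tumor samples with 2,000 genes and a
  20-miRNA panel — large enough for stable rank correlations and Jaccard
  estimates while keeping simulation-heavy tests fast.

**Background correction.** Observed target sets mix planted sites with
chance hits; with per-gene background probabilities
b(L, m) = 1 − (1 − 4⁻ᵐ)^(L−m+1), the moment equations
P(O₆) = p₆ + (1−p₆)b₆ etc. are solved for the marginal planted rates and
the joint rate, giving a background-corrected Jaccard
p_both/(p₆+p₇−p_both). On the default settings this recovers the planted
0.3/0.5 = 0.6 within ±0.05.

What passing tests do *not* show: real 3′-UTRs are not uniform-GC i.i.d.
sequence (composition, conservation and repeat structure change background
hit rates), miRNA regulation is weaker and confounded in real cohorts than
a β = 1 planted effect, and one planted site per gene ignores site
multiplicity and cooperativity. Results on synthetic data validate the
machinery, not biological effect sizes. Note also that when half the
transcriptome is repressed, normalization is compositional and unplanted
genes drift toward positive correlation; the analysis relies on the
*contrast* between planted and background genes, which is preserved.

## Design choices

* The Jaccard/enrichment gene universe is the abundance-filtered expressed
  set; seed flags in the per-gene report table are sequence properties and
  are computed on all annotated transcripts, not only the expressed set.
* Seeds of shifted isoforms are derived purely positionally from the
  canonical sequence; non-templated first-nucleotide variants are not
  modeled.
* Stage subcommands of the CLI (`normalize`, `associate`, `overlap`,
  `enrich`) recompute their deterministic upstream stages in memory instead
  of defining an intermediate-file protocol; `run` writes everything, plus
  a manifest (config SHA-256, seed, package and library versions).
* Output TSVs are UTF-8, tab-delimited, `NA` for undefined values; exit
  codes are 0 (success), 2 (validation), 3 (stage failure).

## Limitations

* No site-context scoring (AU content, position), no conservation, no
  8mer/7mer-A1 or centered site classes, no G:U wobble.
* No differential expression, batch correction, or read-level isomiR
  quantification; count matrices are consumed as given.
* The generator produces single-exon, plus-strand genes; multi-exon and
  minus-strand handling is exercised by dedicated fixtures instead.
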