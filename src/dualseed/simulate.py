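"""Synthetic study generator.

Produces fully synthetic versions of every input the analysis consumes: a
transcriptome (per-gene contigs with a GENCODE-style GTF defining exon, CDS
and stop-codon features), a mature-miRNA FASTA with an isomiR label table,
paired mRNA and miRNA/isomiR count matrices with a sample sheet, and a
"downregulated genes" list emulating an isomiR-overexpression experiment.

The generative model keeps exactly the statistical structure the analysis
relies on and nothing more:

* transcripts are i.i.d. uniform-GC background sequence; for the focal
  miRNA each gene is independently assigned a planting class -- canonical
  6mer site only, isomiR 7mer-m8 site only, both (one contiguous extended
  site), or none -- and the corresponding site string is written into the
  3'-UTR at a uniform position. Background motif collisions are expected
  and truth labels are taken from a *re-scan* of the emitted sequences, so
  the ground truth is honest by construction.
* per-sample focal-miRNA abundance is lognormal (normal on the log2 scale);
  mRNA counts are negative binomial with mean
  ``mu_i0 * L_j * exp(-beta_i * z~_j)`` where ``z~`` is the standardized
  focal log-abundance, ``L_j`` a lognormal library-size factor, and
  ``beta_i > 0`` only for genes with a planted site. Repression is
  multiplicative on the mean: the simplest monotone model that yields
  negative rank correlation, which is all the analysis uses.
* focal isomiR rows are small fixed fractions of the canonical row
  (tumor-like: a few percent) plus counting noise.

All randomness flows from ``SimulationConfig.seed`` through spawned
child generators; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .isomir import IsomiR, MatureMiRNA, make_extended_motif
from .scan import annotate_extendable, scan_sites

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "SimTranscript",
    "StudyBundle",
    "simulate_transcriptome",
    "simulate_expression",
    "simulate_study",
    "background_site_probability",
    "background_corrected_overlap",
]

#: printed canonical hsa-miR-93-5p sequence, used as the default focal miRNA
MIR93_5P = "CAAAGUGCUGUUCGUGCAGGUAG"

PRIMARY_TUMOR = "primary tumor"
NORMAL_TISSUE = "solid tissue normal"

CLASS_NONE, CLASS_CAN, CLASS_ISO, CLASS_BOTH = "none", "can_only", "iso_only", "both"


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a mid-size tumor cohort.

    Rates ``p_can_only``/``p_iso_only``/``p_both`` are per-gene planting
    probabilities for the focal miRNA; ``beta`` is the repression
    coefficient shared by all planted targets. Lengths are in nucleotides,
    abundances on the log2 scale.
    """

    seed: int = 0
    # transcriptome
    n_genes: int = 2000
    length_log_mean: float = math.log(1500.0)
    length_log_sd: float = 0.4
    min_length: int = 300
    utr3_fraction: float = 1.0 / 3.0
    gc_content: float = 0.5
    # focal miRNA and panel
    focal_name: str = "hsa-miR-93-5p"
    focal_sequence: str = MIR93_5P
    isomir_shifts: tuple[int, ...] = (3, 4)
    planting_shift: int = 4
    n_mirnas: int = 20
    mirna_length: int = 22
    # planting
    p_can_only: float = 0.1
    p_iso_only: float = 0.1
    p_both: float = 0.3
    # expression
    n_samples: int = 100
    n_normal_samples: int = 10
    beta: float = 1.0
    n_downregulated: int = 54
    mirna_log2_mean: float = 10.0
    mirna_log2_sd: float = 1.0
    panel_log2_mean: float = 8.0
    panel_log2_sd: float = 2.0
    isomir_fraction: float = 0.02
    mrna_mu_log_mean: float = math.log(300.0)
    mrna_mu_log_sd: float = 1.0
    dispersion: float = 0.1
    library_log_sd: float = 0.2

    def validate(self) -> None:
        rates = (self.p_can_only, self.p_iso_only, self.p_both)
        if any(r < 0 for r in rates) or sum(rates) > 1:
            raise SimulationError(f"planting rates {rates} must be >= 0 and sum to <= 1")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be positive")
        if not (0 < self.gc_content < 1):
            raise SimulationError("gc_content must be in (0, 1)")
        if not (0 < self.utr3_fraction < 1):
            raise SimulationError("utr3_fraction must be in (0, 1)")
        if self.planting_shift not in self.isomir_shifts:
            raise SimulationError(
                f"planting shift {self.planting_shift} not among isomiR shifts {self.isomir_shifts}"
            )
        if self.n_genes < 1 or self.n_samples < 5 or self.n_mirnas < 1:
            raise SimulationError("need n_genes >= 1, n_samples >= 5, n_mirnas >= 1")

    @property
    def p_none(self) -> float:
        return 1.0 - self.p_can_only - self.p_iso_only - self.p_both


@dataclass(frozen=True)
class SimTranscript:
    """One synthetic single-exon gene on its own contig."""

    gene_id: str
    transcript_id: str
    contig_id: str
    sequence: str
    utr3_start: int  # 0-based offset; UTR = [utr3_start, len)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGU")), size=length))


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[SimTranscript], pd.DataFrame]:
    """Generate transcripts with planted focal-miRNA sites plus honest truth labels.

    Returns the transcripts and a ground-truth frame with the planting
    class per gene and re-scanned site indicators (which therefore include
    background motif collisions).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)

    focal = MatureMiRNA(config.focal_name, config.focal_sequence)
    motif_can = IsomiR(focal).seed_motif("6mer")
    motif_iso = IsomiR(focal, shift5=config.planting_shift).seed_motif("7mer-m8")
    motif_ext = make_extended_motif(focal, config.planting_shift)
    inserts = {
        CLASS_CAN: motif_can.site_seq,
        CLASS_ISO: motif_iso.site_seq,
        CLASS_BOTH: motif_ext.site_seq,
    }

    lengths = np.maximum(
        config.min_length,
        np.round(rng.lognormal(config.length_log_mean, config.length_log_sd, config.n_genes)),
    ).astype(int)
    classes = rng.choice(
        [CLASS_NONE, CLASS_CAN, CLASS_ISO, CLASS_BOTH],
        size=config.n_genes,
        p=[config.p_none, config.p_can_only, config.p_iso_only, config.p_both],
    )

    width = len(str(config.n_genes))
    transcripts: list[SimTranscript] = []
    rows: list[dict] = []
    for i in range(config.n_genes):
        length = int(lengths[i])
        utr_len = max(30, int(round(length * config.utr3_fraction)))
        utr_start = length - utr_len
        seq = _random_dna(rng, length, config.gc_content)
        insert_pos = -1
        if classes[i] != CLASS_NONE:
            site = inserts[classes[i]]
            lo, hi = utr_start, length - len(site)
            if hi < lo:  # resample a workable length rather than fail
                length = lo + len(site)
                seq = _random_dna(rng, length, config.gc_content)
                hi = lo
            pos = int(rng.integers(lo, hi + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
            insert_pos = pos + 1  # 1-based
        tag = str(i + 1).zfill(width)
        tx = SimTranscript(
            gene_id=f"SYNG{tag}",
            transcript_id=f"SYNT{tag}",
            contig_id=f"chrS{tag}",
            sequence=seq,
            utr3_start=utr_start,
        )
        transcripts.append(tx)

        utr = seq[utr_start:]
        starts_can_full = scan_sites(seq, motif_can)
        ext_flags = annotate_extendable(starts_can_full, seq, motif_ext)
        rows.append(
            {
                "gene_id": tx.gene_id,
                "transcript_id": tx.transcript_id,
                "length": length,
                "utr3_length": length - utr_start,
                "planted_class": classes[i],
                "insert_pos": insert_pos,
                "has_can_full": bool(starts_can_full),
                "has_iso_full": bool(scan_sites(seq, motif_iso)),
                "has_can_utr3": bool(scan_sites(utr, motif_can)),
                "has_iso_utr3": bool(scan_sites(utr, motif_iso)),
                "has_extendable_full": bool(any(ext_flags)),
            }
        )

    truth = pd.DataFrame(rows).set_index("gene_id")
    return transcripts, truth


def write_transcriptome(
    transcripts: Sequence[SimTranscript], fasta_path: str | Path, gtf_path: str | Path
) -> None:
    """Write per-gene contigs and the matching GTF (exon, CDS, stop_codon)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.contig_id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gtf_path, "w") as gtf:
        gtf.write("##description: synthetic transcriptome\n")
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_id}";'
            )
            cds_end = t.utr3_start  # stop codon occupies the last 3 CDS-frame bases
            rows = [
                ("exon", 1, t.length),
                ("CDS", 1, cds_end - 3),
                ("stop_codon", cds_end - 2, cds_end),
            ]
            for ftype, start, end in rows:
                gtf.write(
                    f"{t.contig_id}\tsynthetic\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )


def simulate_mirna_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, MatureMiRNA]:
    """The focal miRNA plus random mature miRNAs, all with distinct seeds."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    panel: dict[str, MatureMiRNA] = {}
    focal = MatureMiRNA(config.focal_name, config.focal_sequence)
    panel[focal.name] = focal
    seen_seeds = {focal.sequence[1:8]}
    i = 0
    while len(panel) < config.n_mirnas:
        i += 1
        seq = _random_rna(rng, config.mirna_length)
        if seq[1:8] in seen_seeds:
            continue
        seen_seeds.add(seq[1:8])
        name = f"syn-miR-{i:03d}-5p"
        panel[name] = MatureMiRNA(name, seq)
    return panel


def simulate_expression(
    config: SimulationConfig,
    ground_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    panel: Mapping[str, MatureMiRNA] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired mRNA and miRNA/isomiR count matrices plus a sample sheet.

    Primary-tumor samples carry the planted repression signal; a small
    block of normal-tissue samples is appended so that sample-type
    selection is exercised downstream.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    panel = panel or simulate_mirna_panel(config, np.random.default_rng(config.seed))

    n_total = config.n_samples + config.n_normal_samples
    sample_ids = [f"SAMPLE{j + 1:04d}" for j in range(n_total)]
    sample_types = [PRIMARY_TUMOR] * config.n_samples + [NORMAL_TISSUE] * config.n_normal_samples
    sheet = pd.DataFrame({"sample_id": sample_ids, "sample_type": sample_types})

    size = 1.0 / config.dispersion

    def nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-8)
        return rng.negative_binomial(size, size / (size + mean))

    # focal miRNA abundance drives repression
    z_log2 = rng.normal(config.mirna_log2_mean, config.mirna_log2_sd, n_total)
    z_std = (z_log2 - z_log2.mean()) / z_log2.std()
    library = np.exp(rng.normal(0.0, config.library_log_sd, n_total))

    genes = ground_truth.index.to_numpy()
    beta = np.where(ground_truth["planted_class"].to_numpy() != CLASS_NONE, config.beta, 0.0)
    mu0 = rng.lognormal(config.mrna_mu_log_mean, config.mrna_mu_log_sd, len(genes))
    mean_mrna = mu0[:, None] * library[None, :] * np.exp(-beta[:, None] * z_std[None, :])
    mrna = pd.DataFrame(nb(mean_mrna), index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    # miRNA matrix: panel rows + focal isomiR rows
    labels: list[str] = []
    means: list[np.ndarray] = []
    focal_mean = (2.0**z_log2) * library
    for name in panel:
        if name == config.focal_name:
            labels.append(name)
            means.append(focal_mean)
        else:
            base = 2.0 ** rng.normal(config.panel_log2_mean, config.panel_log2_sd)
            labels.append(name)
            means.append(base * library)
    for shift in config.isomir_shifts:
        labels.append(f"{config.focal_name}|+{shift}")
        means.append(config.isomir_fraction * focal_mean)
    mirna = pd.DataFrame(
        nb(np.vstack(means)), index=pd.Index(labels, name="mirna"), columns=sample_ids
    )
    return mrna, mirna, sheet


def select_downregulated(
    config: SimulationConfig, ground_truth: pd.DataFrame, rng: np.random.Generator | None = None
) -> list[str]:
    """Emulated isomiR-overexpression hit list: a sample of planted isomiR targets.

    All planted targets share the same repression coefficient, so the list
    is a seeded random draw from the genes with a planted isomiR site.
    """
    rng = rng or np.random.default_rng(config.seed)
    pool = ground_truth.index[
        ground_truth["planted_class"].isin([CLASS_ISO, CLASS_BOTH])
    ].to_numpy()
    k = min(config.n_downregulated, len(pool))
    chosen = rng.choice(pool, size=k, replace=False)
    return sorted(chosen)


@dataclass(frozen=True)
class StudyBundle:
    """Paths of a written synthetic study plus its in-memory ground truth."""

    config: SimulationConfig
    transcript_fasta: Path
    gtf: Path
    mature_fasta: Path
    isomir_table: Path
    mrna_counts: Path
    mirna_counts: Path
    sample_sheet: Path
    downregulated_list: Path
    ground_truth_path: Path
    ground_truth: pd.DataFrame


def simulate_study(config: SimulationConfig, outdir: str | Path) -> StudyBundle:
    """Generate and write the full input bundle for one synthetic study."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_tx, rng_panel, rng_expr, rng_pick = _rng_children(config.seed, 4)

    transcripts, truth = simulate_transcriptome(config, rng_tx)
    panel = simulate_mirna_panel(config, rng_panel)
    mrna, mirna, sheet = simulate_expression(config, truth, rng_expr, panel)
    downreg = select_downregulated(config, truth, rng_pick)
    truth = truth.assign(
        beta=np.where(truth["planted_class"] != CLASS_NONE, config.beta, 0.0),
        in_downregulated_list=truth.index.isin(downreg),
    )

    paths = {
        "transcript_fasta": outdir / "transcripts.fa",
        "gtf": outdir / "annotation.gtf",
        "mature_fasta": outdir / "mature_mirnas.fa",
        "isomir_table": outdir / "isomirs.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "downregulated_list": outdir / "downregulated_genes.tsv",
        "ground_truth_path": outdir / "ground_truth.tsv",
    }

    write_transcriptome(transcripts, paths["transcript_fasta"], paths["gtf"])
    SeqIO.write(
        [SeqRecord(Seq(m.sequence), id=m.name, description="") for m in panel.values()],
        str(paths["mature_fasta"]),
        "fasta",
    )
    with open(paths["isomir_table"], "w") as fh:
        fh.write("label\n")
        for name in panel:
            for shift in config.isomir_shifts:
                fh.write(f"{name}|+{shift}\n")
    mrna.to_csv(paths["mrna_counts"], sep="\t")
    mirna.to_csv(paths["mirna_counts"], sep="\t")
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    with open(paths["downregulated_list"], "w") as fh:
        fh.write("gene_id\n")
        fh.writelines(f"{g}\n" for g in downreg)
    truth.to_csv(paths["ground_truth_path"], sep="\t")

    return StudyBundle(config=config, ground_truth=truth, **paths)


def background_site_probability(length: int, motif_length: int) -> float:
    """P(>= 1 chance hit of a fixed motif) in uniform i.i.d. sequence of given length."""
    windows = max(0, length - motif_length + 1)
    return 1.0 - (1.0 - 0.25**motif_length) ** windows


def background_corrected_overlap(
    observed_6mer: set[str],
    observed_7mer: set[str],
    region_lengths: Mapping[str, int],
    motif_lengths: tuple[int, int] = (6, 7),
) -> dict[str, float]:
    """Method-of-moments estimate of planted site rates and their Jaccard index.

    Observed target sets mix planted sites with chance background hits whose
    per-gene probabilities follow from the scanned region lengths. Solving
    the moment equations for the marginal planted rates ``p6``/``p7`` and
    the joint rate ``p_both`` yields a background-corrected Jaccard
    ``p_both / (p6 + p7 - p_both)``.
    """
    genes = list(region_lengths)
    if not genes:
        raise SimulationError("empty gene universe")
    b6 = np.array([background_site_probability(region_lengths[g], motif_lengths[0]) for g in genes])
    b7 = np.array([background_site_probability(region_lengths[g], motif_lengths[1]) for g in genes])
    o6 = np.array([g in observed_6mer for g in genes], dtype=float)
    o7 = np.array([g in observed_7mer for g in genes], dtype=float)
    n = len(genes)

    p6 = (o6.sum() - b6.sum()) / (n - b6.sum())
    p7 = (o7.sum() - b7.sum()) / (n - b7.sum())
    n67 = float((o6 * o7).sum())
    # P(O6 & O7) = pb + (p6-pb) b7 + (p7-pb) b6 + (1-p6-p7+pb) b6 b7, linear in pb
    baseline = (p6 * b7 * (1 - b6) + p7 * b6 * (1 - b7) + b6 * b7).sum()
    slope = ((1 - b6) * (1 - b7)).sum()
    p_both = (n67 - baseline) / slope

    p6 = float(np.clip(p6, 0.0, 1.0))
    p7 = float(np.clip(p7, 0.0, 1.0))
    p_both = float(np.clip(p_both, 0.0, min(p6, p7) if min(p6, p7) > 0 else 0.0))
    union = p6 + p7 - p_both
    return {
        "p6": p6,
        "p7": p7,
        "p_both": p_both,
        "jaccard": p_both / union if union > 0 else math.nan,
    }
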