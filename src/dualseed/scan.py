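"""Transcript models, seed-site scanning and per-gene target sets.

Transcripts are held as sense-strand spliced sequences (minus-strand genes
already reverse-complemented) with an optional 3'-UTR sub-interval. All
internal coordinates are 0-based half-open; emitted site positions are
1-based closed, matching GTF conventions.

Scanning is exact substring matching in DNA space. Site motifs contain only
A/C/G/T, so any window containing an ambiguity code (N etc.) is a non-match
by construction, and motifs are only ever searched on the stored sense
strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .isomir import ExtendedMotif, SeedMotif

__all__ = [
    "ScanError",
    "TranscriptRecord",
    "SeedSite",
    "TargetSet",
    "ExtensionStats",
    "REGIONS",
    "POLICIES",
    "load_transcripts",
    "gene_exon_lengths",
    "select_representative",
    "region_sequence",
    "scan_sites",
    "annotate_extendable",
    "build_target_set",
    "collect_sites",
    "extension_stats",
]

logger = logging.getLogger(__name__)

REGIONS = ("utr3", "full_mrna")
POLICIES = ("longest_spliced", "longest_utr3", "all_union")


class ScanError(ValueError):
    """Invalid scanning input (annotation, region or gene universe)."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One spliced transcript with an optional 3'-UTR interval.

    ``utr3_interval`` is a 0-based half-open range within
    ``spliced_sequence``; ``None`` for non-coding or UTR-less transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    spliced_sequence: str
    utr3_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.utr3_interval is not None:
            s, e = self.utr3_interval
            if not (0 <= s <= e <= len(self.spliced_sequence)):
                raise ScanError(
                    f"{self.transcript_id}: UTR interval {self.utr3_interval} outside "
                    f"[0, {len(self.spliced_sequence)})"
                )

    @property
    def utr3_length(self) -> int:
        if self.utr3_interval is None:
            return 0
        return self.utr3_interval[1] - self.utr3_interval[0]


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    transcript_id: str
    motif_id: str
    start: int  # 1-based within the scanned region
    region: str
    extendable: bool | None = None  # only meaningful for canonical 6mer sites


@dataclass(frozen=True)
class TargetSet:
    """Genes with >= 1 site of a motif in a region: the motif's targetome."""

    mirna_label: str
    seed_type: str
    region: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def _strip_version(identifier: str, strip: bool) -> str:
    if strip and "." in identifier:
        head, _, tail = identifier.rpartition(".")
        if tail.isdigit():
            return head
    return identifier


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.rstrip("\n").count("\t") != 8:
                raise ScanError(f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields")


def _open_gtf(path: str | Path) -> gffutils.FeatureDB:
    _validate_gtf_lines(path)
    try:
        return gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise ScanError(f"failed to parse GTF {path}: {exc}") from exc


def _attr(feature: gffutils.Feature, key: str, default: str = "") -> str:
    values = feature.attributes.get(key, [])
    return values[0] if values else default


def _spliced_offset(exons: Sequence[gffutils.Feature], strand: str, pos: int) -> int:
    """Map a 1-based genomic position to a 0-based spliced-transcript offset."""
    ordered = sorted(exons, key=lambda f: f.start, reverse=(strand == "-"))
    cum = 0
    for ex in ordered:
        if ex.start <= pos <= ex.end:
            return cum + (pos - ex.start if strand != "-" else ex.end - pos)
        cum += ex.end - ex.start + 1
    raise ScanError(f"position {pos} not covered by exons of the transcript")


def _utr3_interval(
    exons: Sequence[gffutils.Feature],
    stops: Sequence[gffutils.Feature],
    cds: Sequence[gffutils.Feature],
    strand: str,
    spliced_length: int,
) -> tuple[int, int] | None:
    """3'-UTR = spliced positions strictly 3' of the stop codon."""
    if stops:
        boundary = max(f.end for f in stops) if strand != "-" else min(f.start for f in stops)
        start = _spliced_offset(exons, strand, boundary) + 1
    elif cds:
        boundary = max(f.end for f in cds) if strand != "-" else min(f.start for f in cds)
        # GENCODE CDS excludes the stop codon; skip its 3 nt as well
        start = _spliced_offset(exons, strand, boundary) + 1 + 3
    else:
        return None
    if start >= spliced_length:
        return None
    return (start, spliced_length)


def load_transcripts(
    fasta: str | Path, annotation: str | Path, strip_versions: bool = True
) -> list[TranscriptRecord]:
    """Build :class:`TranscriptRecord`s from a FASTA plus a GENCODE-style GTF.

    Two FASTA dialects are accepted and auto-detected per transcript:

    * genomic contigs (FASTA ids match GTF seqnames) -- the spliced sequence
      is assembled by concatenating exon slices, reverse-complemented for
      minus-strand transcripts;
    * spliced transcript sequences (FASTA ids match GTF ``transcript_id``
      attributes) -- taken verbatim, with the exon structure used only to
      place the 3'-UTR boundary.

    Transcripts whose sequence cannot be resolved are skipped with a warning.
    """
    sequences = {
        _strip_version(rec.id, strip_versions): str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta), "fasta")
    }
    if not sequences:
        raise ScanError(f"no records in FASTA {fasta}")

    db = _open_gtf(annotation)
    exons: dict[str, list[gffutils.Feature]] = {}
    stops: dict[str, list[gffutils.Feature]] = {}
    cds: dict[str, list[gffutils.Feature]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene_id, gene_name, seqid, strand)
    for ftype, bucket in (("exon", exons), ("stop_codon", stops), ("CDS", cds)):
        for feature in db.features_of_type(ftype):
            tid = _attr(feature, "transcript_id")
            if not tid:
                raise ScanError(f"{annotation}: {ftype} feature without transcript_id")
            bucket.setdefault(tid, []).append(feature)
            meta.setdefault(
                tid,
                (
                    _attr(feature, "gene_id", tid),
                    _attr(feature, "gene_name", _attr(feature, "gene_id", tid)),
                    feature.seqid,
                    feature.strand,
                ),
            )

    records: list[TranscriptRecord] = []
    for tid, tx_exons in exons.items():
        gene_id, gene_name, seqid, strand = meta[tid]
        tid_key = _strip_version(tid, strip_versions)
        tx_exons = sorted(tx_exons, key=lambda f: f.start)
        if tid_key in sequences:
            spliced = sequences[tid_key]
        elif _strip_version(seqid, strip_versions) in sequences:
            contig = sequences[_strip_version(seqid, strip_versions)]
            parts = [contig[f.start - 1 : f.end] for f in tx_exons]
            spliced = "".join(parts)
            if strand == "-":
                spliced = str(Seq(spliced).reverse_complement())
        else:
            warnings.warn(
                f"transcript {tid}: neither transcript id nor contig {seqid} found in FASTA; skipped",
                stacklevel=2,
            )
            continue
        utr3 = _utr3_interval(
            tx_exons, stops.get(tid, ()), cds.get(tid, ()), strand, len(spliced)
        )
        records.append(
            TranscriptRecord(
                transcript_id=_strip_version(tid, strip_versions),
                gene_id=_strip_version(gene_id, strip_versions),
                gene_name=gene_name,
                spliced_sequence=spliced,
                utr3_interval=utr3,
            )
        )
    if not records:
        raise ScanError("no transcript could be matched between FASTA and GTF")
    return records


def gene_exon_lengths(annotation: str | Path, strip_versions: bool = True) -> pd.Series:
    """Union-exon length per gene in bp (the FPKM gene-length convention)."""
    db = _open_gtf(annotation)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for feature in db.features_of_type("exon"):
        gid = _strip_version(_attr(feature, "gene_id"), strip_versions)
        intervals.setdefault(gid, []).append((feature.start, feature.end))
    lengths: dict[str, int] = {}
    for gid, ivals in intervals.items():
        ivals.sort()
        total = 0
        cur_start, cur_end = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_end + 1:
                cur_end = max(cur_end, e)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = s, e
        total += cur_end - cur_start + 1
        lengths[gid] = total
    return pd.Series(lengths, name="length_bp").sort_index()


def select_representative(
    records: Iterable[TranscriptRecord], policy: str = "longest_spliced"
) -> dict[str, tuple[TranscriptRecord, ...]]:
    """Pick the transcripts representing each gene.

    ``longest_spliced`` / ``longest_utr3`` keep a single deterministic
    transcript per gene (length, ties by lexicographically smallest
    transcript id); ``all_union`` keeps every transcript, so a gene counts
    as a target if any isoform carries a site.
    """
    if policy not in POLICIES:
        raise ScanError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    out: dict[str, tuple[TranscriptRecord, ...]] = {}
    for gene, recs in by_gene.items():
        if policy == "all_union":
            out[gene] = tuple(sorted(recs, key=lambda r: r.transcript_id))
        else:
            key = (
                (lambda r: (-len(r.spliced_sequence), r.transcript_id))
                if policy == "longest_spliced"
                else (lambda r: (-r.utr3_length, r.transcript_id))
            )
            out[gene] = (sorted(recs, key=key)[0],)
    return out


def region_sequence(record: TranscriptRecord, region: str) -> str:
    if region == "full_mrna":
        return record.spliced_sequence
    if region == "utr3":
        if record.utr3_interval is None:
            return ""
        s, e = record.utr3_interval
        return record.spliced_sequence[s:e]
    raise ScanError(f"unknown region {region!r}; expected one of {REGIONS}")


def scan_sites(sequence: str, motif: SeedMotif | ExtendedMotif | str) -> list[int]:
    """All (possibly overlapping) exact occurrences of a site motif.

    Returns ascending 1-based start positions within ``sequence``.
    """
    site = motif if isinstance(motif, str) else motif.site_seq
    if not site:
        raise ScanError("empty motif")
    seq = sequence.upper()
    starts: list[int] = []
    i = seq.find(site)
    while i != -1:
        starts.append(i + 1)
        i = seq.find(site, i + 1)
    return starts


def annotate_extendable(
    starts: Sequence[int], sequence: str, extended: ExtendedMotif
) -> list[bool]:
    """Flag which canonical 6mer sites sit at the 3' end of an extended site.

    A 6mer site at 1-based start ``p`` is extendable iff the window ending
    at the site's last base and spanning ``extended.length`` nt matches the
    extended site string (so the 6mer occupies its last 6 positions). Sites
    too close to the sequence 5' boundary are non-extendable by definition.
    """
    seq = sequence.upper()
    lead = extended.length - 6
    flags = []
    for p in starts:
        i = p - 1  # 0-based start of the 6mer
        flags.append(i >= lead and seq[i - lead : i + 6] == extended.site_seq)
    return flags


def build_target_set(
    label: str,
    motif: SeedMotif | ExtendedMotif,
    representatives: Mapping[str, Sequence[TranscriptRecord]],
    region: str = "full_mrna",
) -> TargetSet:
    """Genes whose representative transcript(s) carry >= 1 site of ``motif``."""
    if not representatives:
        raise ScanError("empty gene universe")
    genes = frozenset(
        gene
        for gene, recs in representatives.items()
        if any(scan_sites(region_sequence(rec, region), motif) for rec in recs)
    )
    seed_type = getattr(motif, "seed_type", f"extended+{getattr(motif, 'shift5', '?')}")
    return TargetSet(mirna_label=label, seed_type=seed_type, region=region, genes=genes)


def collect_sites(
    motifs: Sequence[SeedMotif | ExtendedMotif],
    representatives: Mapping[str, Sequence[TranscriptRecord]],
    region: str = "full_mrna",
    extended_by_motif: Mapping[str, ExtendedMotif] | None = None,
) -> list[SeedSite]:
    """Enumerate every site of every motif; optionally flag extendable 6mers.

    ``extended_by_motif`` maps a 6mer motif's ``motif_id`` to the extended
    motif used for the extendability annotation.
    """
    extended_by_motif = extended_by_motif or {}
    sites: list[SeedSite] = []
    for gene in sorted(representatives):
        for rec in representatives[gene]:
            seq = region_sequence(rec, region)
            for motif in motifs:
                starts = scan_sites(seq, motif)
                if not starts:
                    continue
                mid = motif.motif_id
                if mid in extended_by_motif:
                    flags = annotate_extendable(starts, seq, extended_by_motif[mid])
                else:
                    flags = [None] * len(starts)
                sites.extend(
                    SeedSite(gene, rec.transcript_id, mid, p, region, f)
                    for p, f in zip(starts, flags)
                )
    return sites


@dataclass(frozen=True)
class ExtensionStats:
    """Site- and gene-level extendability of canonical 6mer sites."""

    n_sites: int
    n_extendable_sites: int
    n_genes_with_site: int
    n_genes_with_extendable: int

    @property
    def site_ratio(self) -> float:
        return self.n_extendable_sites / self.n_sites if self.n_sites else float("nan")

    @property
    def gene_ratio(self) -> float:
        return (
            self.n_genes_with_extendable / self.n_genes_with_site
            if self.n_genes_with_site
            else float("nan")
        )


def extension_stats(
    motif6: SeedMotif,
    extended: ExtendedMotif,
    representatives: Mapping[str, Sequence[TranscriptRecord]],
    region: str = "full_mrna",
) -> ExtensionStats:
    """How many canonical 6mer sites extend into the isomiR-compatible site."""
    n_sites = n_ext = n_genes = n_genes_ext = 0
    for recs in representatives.values():
        gene_sites = gene_ext = 0
        for rec in recs:
            seq = region_sequence(rec, region)
            starts = scan_sites(seq, motif6)
            flags = annotate_extendable(starts, seq, extended)
            gene_sites += len(starts)
            gene_ext += sum(flags)
        n_sites += gene_sites
        n_ext += gene_ext
        n_genes += bool(gene_sites)
        n_genes_ext += bool(gene_ext)
    return ExtensionStats(n_sites, n_ext, n_genes, n_genes_ext)


def sites_to_frame(sites: Sequence[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "transcript_id": s.transcript_id,
                "motif_id": s.motif_id,
                "region": s.region,
                "start": s.start,
                "extendable": s.extendable,
            }
            for s in sites
        ],
        columns=["gene_id", "transcript_id", "motif_id", "region", "start", "extendable"],
    )
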