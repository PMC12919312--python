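"""Mature miRNAs, 5'-isomiRs and the seed/site motifs they define.

A 5'-isomiR is a mature miRNA variant whose 5' end is shifted by ``shift5``
nucleotides relative to the canonical form (positive shift = nucleotides
trimmed from the 5' end), optionally carrying non-templated 3' additions.
Because the seed region is positional (nucleotides 2-7 for a "6mer" seed,
2-8 for "7mer-m8", counted from the 5' end), a 5' shift re-registers the
seed and can redirect targeting.

miRNA sequences are stored in the RNA alphabet (A/C/G/U). Target-site
motifs -- the strings actually searched for in mRNA sequences -- are the
reverse complements of the seeds, transliterated to the DNA alphabet, since
transcript sequences come from DNA-space references.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IsomirError",
    "MatureMiRNA",
    "IsomiR",
    "SeedMotif",
    "ExtendedMotif",
    "SEED_TYPES",
    "parse_isomir_notation",
    "apply_shift",
    "extract_seed",
    "make_site_motif",
    "make_extended_motif",
    "read_mature_fasta",
    "read_isomir_table",
]

RNA_BASES = frozenset("ACGU")

#: seed windows as 0-based half-open slices of the mature sequence
SEED_SPANS: dict[str, tuple[int, int]] = {"6mer": (1, 7), "7mer-m8": (1, 8)}
SEED_TYPES = tuple(SEED_SPANS)

MIN_MATURE_LENGTH = 16
MIN_DERIVED_LENGTH = 10


class IsomirError(ValueError):
    """Invalid miRNA/isomiR sequence, shift or notation."""


def _clean_rna(seq: str, what: str) -> str:
    s = str(seq).strip().upper()
    bad = set(s) - RNA_BASES
    if bad:
        raise IsomirError(
            f"{what} contains non-RNA characters {sorted(bad)!r}; "
            "expected A/C/G/U (transcribe DNA input first)"
        )
    return s


@dataclass(frozen=True)
class MatureMiRNA:
    """A canonical mature miRNA: name plus 5'->3' RNA sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _clean_rna(self.sequence, f"{self.name} sequence"))
        if len(self.sequence) < MIN_MATURE_LENGTH:
            raise IsomirError(
                f"{self.name}: mature sequence length {len(self.sequence)} "
                f"< {MIN_MATURE_LENGTH}"
            )

    def isomir(self, shift5: int = 0, mod3: str = "") -> "IsomiR":
        return IsomiR(self, shift5=shift5, mod3=mod3)


def apply_shift(parent: MatureMiRNA, shift5: int, mod3: str = "") -> str:
    """Derive the isomiR sequence: trim ``shift5`` nt from the 5' end, append ``mod3``."""
    if shift5 < 0:
        raise IsomirError(
            f"{parent.name}: negative 5' shift {shift5} (5' extensions) not supported; "
            "they require genomic context absent from the mature sequence"
        )
    if len(parent.sequence) - shift5 < MIN_DERIVED_LENGTH:
        raise IsomirError(
            f"{parent.name}: shift {shift5} leaves fewer than "
            f"{MIN_DERIVED_LENGTH} nt of the {len(parent.sequence)}-nt parent"
        )
    mod3 = _clean_rna(mod3, f"{parent.name} 3' modification") if mod3 else ""
    return parent.sequence[shift5:] + mod3


@dataclass(frozen=True)
class IsomiR:
    """A 5'-isomiR: parent miRNA, 5' shift and optional 3' additions.

    ``shift5 == 0`` and empty ``mod3`` denotes the canonical form.
    """

    parent: MatureMiRNA
    shift5: int = 0
    mod3: str = ""

    def __post_init__(self) -> None:
        # validates shift range and mod3 alphabet
        seq = apply_shift(self.parent, self.shift5, self.mod3)
        object.__setattr__(self, "mod3", seq[len(self.parent.sequence) - self.shift5:])

    @property
    def sequence(self) -> str:
        return apply_shift(self.parent, self.shift5, self.mod3)

    @property
    def is_canonical(self) -> bool:
        return self.shift5 == 0 and not self.mod3

    @property
    def label(self) -> str:
        if self.is_canonical:
            return self.parent.name
        parts = [self.parent.name, f"+{self.shift5}" if self.shift5 else "0"]
        if self.mod3:
            if len(set(self.mod3)) == 1:
                parts.append(f"+{len(self.mod3)}{self.mod3[0]}")
            else:
                parts.append(f"+{self.mod3}")
        return "|".join(parts)

    def seed(self, seed_type: str) -> str:
        return extract_seed(self.sequence, seed_type)

    def seed_motif(self, seed_type: str) -> "SeedMotif":
        return SeedMotif.from_sequence(self.sequence, seed_type, owner=self.label)


def extract_seed(sequence: str, seed_type: str) -> str:
    """Seed subsequence: mature nucleotides 2-7 (6mer) or 2-8 (7mer-m8), 1-based."""
    if seed_type not in SEED_SPANS:
        raise IsomirError(f"unknown seed type {seed_type!r}; expected one of {SEED_TYPES}")
    sequence = _clean_rna(sequence, "sequence")
    if len(sequence) < 8:
        raise IsomirError(f"sequence of length {len(sequence)} too short for a seed (need >= 8)")
    lo, hi = SEED_SPANS[seed_type]
    return sequence[lo:hi]


def make_site_motif(seed_seq: str) -> str:
    """mRNA-sense site motif: reverse complement of the seed in the DNA alphabet."""
    seed_seq = _clean_rna(seed_seq, "seed")
    return str(Seq(seed_seq.replace("U", "T")).reverse_complement())


@dataclass(frozen=True)
class SeedMotif:
    """A seed plus the DNA-space site string searched for in transcripts."""

    seed_type: str
    seed_seq: str
    site_seq: str
    owner: str = ""

    @classmethod
    def from_sequence(cls, sequence: str, seed_type: str, owner: str = "") -> "SeedMotif":
        seed = extract_seed(sequence, seed_type)
        return cls(seed_type=seed_type, seed_seq=seed, site_seq=make_site_motif(seed), owner=owner)

    @property
    def motif_id(self) -> str:
        return f"{self.owner or 'motif'}:{self.seed_type}"

    def __len__(self) -> int:
        return len(self.site_seq)


@dataclass(frozen=True)
class ExtendedMotif:
    """Contiguous site spanning both the canonical 6mer and a +k isomiR 7mer-m8.

    For a shift of k the mRNA match covers canonical nucleotides 2..(k+8),
    i.e. k+7 nt (11 nt for the +4 isomiR). By construction the canonical
    6mer site is the 3'-most 6 nt of the site string and the isomiR 7mer-m8
    site is its first 7 nt.
    """

    shift5: int
    span_seq: str
    site_seq: str
    owner: str = ""

    @classmethod
    def from_parent(cls, parent: MatureMiRNA, shift5: int) -> "ExtendedMotif":
        return make_extended_motif(parent, shift5)

    @property
    def length(self) -> int:
        return len(self.site_seq)

    @property
    def motif_id(self) -> str:
        return f"{self.owner or 'motif'}:ext+{self.shift5}"

    def __len__(self) -> int:
        return len(self.site_seq)


def make_extended_motif(parent: MatureMiRNA, shift5: int) -> ExtendedMotif:
    if shift5 < 1:
        raise IsomirError(f"extended motif needs shift5 >= 1, got {shift5}")
    if len(parent.sequence) < shift5 + 8:
        raise IsomirError(
            f"{parent.name}: length {len(parent.sequence)} too short for an "
            f"extended motif at shift {shift5} (need >= {shift5 + 8})"
        )
    span = parent.sequence[1 : shift5 + 8]
    return ExtendedMotif(
        shift5=shift5, span_seq=span, site_seq=make_site_motif(span), owner=parent.name
    )


_LABEL_RE = re.compile(r"^(?P<name>[^|\s]+)(?:\|(?P<shift>[^|]+))?(?:\|(?P<mod>[^|]+))?$")
_MOD_COUNTED_RE = re.compile(r"^\+(?P<n>\d*)(?P<base>[ACGU])$")
_MOD_PLAIN_RE = re.compile(r"^\+(?P<bases>[ACGU]+)$")


def parse_isomir_notation(label: str) -> tuple[str, int, str]:
    """Parse pipe-delimited isomiR notation into ``(name, shift5, mod3)``.

    Accepted forms: ``name``, ``name|+k`` (or ``name|0``), and
    ``name|+k|+nX`` where ``X`` is a nucleotide and ``n`` a repeat count
    (``+2U`` == ``UU``); a trailing ``|0`` denotes no 3' modification.
    """
    label = label.strip()
    m = _LABEL_RE.match(label)
    if not m or not m.group("name"):
        raise IsomirError(f"malformed isomiR label {label!r}")
    name = m.group("name")

    shift5 = 0
    if m.group("shift") is not None:
        tok = m.group("shift").strip()
        try:
            shift5 = int(tok)
        except ValueError:
            raise IsomirError(f"{label!r}: non-integer 5' shift token {tok!r}") from None

    mod3 = ""
    if m.group("mod") is not None:
        tok = m.group("mod").strip().upper()
        if tok == "0":
            mod3 = ""
        elif (cm := _MOD_COUNTED_RE.match(tok)) is not None:
            count = int(cm.group("n") or 1)
            mod3 = cm.group("base") * count
        elif (pm := _MOD_PLAIN_RE.match(tok)) is not None:
            mod3 = pm.group("bases")
        else:
            raise IsomirError(f"{label!r}: unrecognized 3' modification token {tok!r}")

    return name, shift5, mod3


def read_mature_fasta(path: str | Path) -> dict[str, MatureMiRNA]:
    """Read a miRBase-style mature-miRNA FASTA (name = first header token)."""
    mirnas: dict[str, MatureMiRNA] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("T", "U")  # miRBase ships both dialects
        mirnas[record.id] = MatureMiRNA(record.id, seq)
    if not mirnas:
        raise IsomirError(f"no records in mature FASTA {path}")
    return mirnas


def read_isomir_table(
    path: str | Path, mirnas: Mapping[str, MatureMiRNA]
) -> list[IsomiR]:
    """Read a TSV of isomiR labels (first column, pipe notation) against a mature set."""
    isomirs: list[IsomiR] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.lower().startswith("label"):
            continue
        label = line.split("\t")[0].strip()
        name, shift5, mod3 = parse_isomir_notation(label)
        if name not in mirnas:
            raise IsomirError(f"isomiR label {label!r} references unknown miRNA {name!r}")
        isomirs.append(IsomiR(mirnas[name], shift5=shift5, mod3=mod3))
    return isomirs
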