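"""Nucleotide records and six-frame translation.

Domain motifs are protein-level objects while metagenome contigs are
nucleotide sequences, so every downstream scan runs on the six conceptual
translation frames of each contig.  Coordinates are kept 0-based half-open
internally and converted to 1-based inclusive forward-strand coordinates at
reporting boundaries; each :class:`PeptideFrame` knows how to map an
amino-acid span back to the contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence (typically an assembled contig)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        seq = self.seq.upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-nucleotide characters: "
                f"{''.join(sorted(bad))}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


def read_nucleotide_fasta(path) -> list[SequenceRecord]:
    """Read contigs from a FASTA file.

    Raises ``ValueError`` on an empty file, on duplicate ids (naming the id)
    and on characters outside ``{A,C,G,T,N}`` (naming the record).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_nucleotide_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i:i + 60] + "\n")


@dataclass(frozen=True)
class PeptideFrame:
    """One reading frame of a contig.

    ``frame`` is +1..+3 (forward strand) or -1..-3 (reverse complement);
    ``offset`` is the 0-based offset of the first translated codon on the
    strand that was translated.  ``source_length`` is the contig length,
    needed to map reverse-frame positions back to forward coordinates.
    """

    contig_id: str
    frame: int
    offset: int
    peptide: str
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def nt_span(self, aa_start0: int, aa_end0: int) -> tuple[int, int]:
        """Map a 0-based half-open aa span to 1-based inclusive forward-strand
        nucleotide coordinates."""
        if not 0 <= aa_start0 < aa_end0 <= len(self.peptide):
            raise ValueError("aa span out of frame bounds")
        off, L = self.offset, self.source_length
        if self.frame > 0:
            return off + 3 * aa_start0 + 1, off + 3 * aa_end0
        return L - (off + 3 * aa_end0) + 1, L - (off + 3 * aa_start0)

    def aa_position(self, nt_pos1: int) -> int:
        """Map a 1-based forward-strand nucleotide position to the 0-based aa
        index of the codon covering it (inverse of :meth:`nt_span`)."""
        p0 = nt_pos1 - 1
        if self.frame > 0:
            idx = (p0 - self.offset) // 3
        else:
            idx = (self.source_length - 1 - p0 - self.offset) // 3
        if not 0 <= idx < len(self.peptide):
            raise ValueError("nucleotide position outside translated frame")
        return idx


@lru_cache(maxsize=None)
def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


def translate_frame(seq: str, offset: int, table_id: int = 1) -> str:
    """Translate one frame; codons containing N become 'X', trailing partial
    codons are dropped, stops are kept as '*'."""
    mapping = _codon_map(table_id)
    usable = len(seq) - offset
    out = []
    for i in range(offset, offset + usable - usable % 3, 3):
        out.append(mapping.get(seq[i:i + 3], "X"))
    return "".join(out)


def six_frame_translate(record: SequenceRecord, genetic_code: int = 1) -> list[PeptideFrame]:
    """All six translation frames of a contig (+1,+2,+3,-1,-2,-3)."""
    if len(record.seq) < 3:
        raise ValueError(f"sequence {record.id!r} shorter than one codon")
    rc = reverse_complement(record.seq)
    frames = []
    for off in range(3):
        frames.append(PeptideFrame(record.id, off + 1, off,
                                   translate_frame(record.seq, off, genetic_code),
                                   len(record.seq)))
    for off in range(3):
        frames.append(PeptideFrame(record.id, -(off + 1), off,
                                   translate_frame(rc, off, genetic_code),
                                   len(record.seq)))
    return frames
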