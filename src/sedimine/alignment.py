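"""Local-alignment confirmation and alignment-based domain search.

Motif hits are cheap but noisy; each hit is therefore confirmed by local
alignment (Smith-Waterman, BLOSUM62, affine gaps open 11 / extend 1)
against curated reference domain proteins of the same class.  Adenylation
(A) domains have no specific short motif, so alignment search over
stop-delimited peptides is their only detection route; it also provides an
independent route for KS and C domains.

Default thresholds (identity >= 60% over >= 15 aligned amino acids) follow
common metagenome-annotation cut-offs and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .hits import DomainHit
from .sequences import PeptideFrame

DOMAIN_CLASSES = ("KS", "C", "A")


@dataclass(frozen=True)
class ReferenceDomain:
    """A reference domain protein (e.g. from a curated NP-domain database)."""

    id: str
    domain_class: str
    peptide: str

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if len(self.peptide) < 15:
            raise ValueError(f"reference {self.id!r} shorter than 15 aa")


def read_reference_fasta(path, domain_class: str) -> list[ReferenceDomain]:
    refs = [ReferenceDomain(rec.id, domain_class, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
    if not refs:
        raise ValueError(f"no reference sequences in {path}")
    return refs


def read_alignment_fasta(path) -> list[str]:
    """Read an aligned protein FASTA (gap character '-') as rows."""
    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no aligned sequences in {path}")
    return rows


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _identity(alignment) -> tuple[float, int]:
    """(identity %, aligned length incl. gaps) of a local alignment."""
    counts = alignment.counts()
    aligned_len = counts.gaps + counts.identities + counts.mismatches
    if aligned_len == 0:
        return 0.0, 0
    return 100.0 * counts.identities / aligned_len, aligned_len


def _best_reference(aligner, peptide: str, refs: Sequence[ReferenceDomain]):
    """Best-scoring reference for a query peptide; ties break to the
    lexicographically lowest reference id.  Returns (ref, alignment) or
    (None, None) if nothing aligns."""
    best = None
    for ref in sorted(refs, key=lambda r: r.id):
        alignments = aligner.align(peptide, ref.peptide)
        try:
            aln = alignments[0]
        except IndexError:
            continue
        if best is None or aln.score > best[1].score:
            best = (ref, aln)
    return best if best is not None else (None, None)


def _group_by_class(references: Iterable[ReferenceDomain]) -> dict[str, list[ReferenceDomain]]:
    by_class: dict[str, list[ReferenceDomain]] = {}
    for ref in references:
        by_class.setdefault(ref.domain_class, []).append(ref)
    return by_class


def _frame_index(frames: Iterable[PeptideFrame]) -> Mapping[tuple[str, int], PeptideFrame]:
    return {(f.contig_id, f.frame): f for f in frames}


def flanked_peptide(hit: DomainHit, frame: PeptideFrame, flank_aa: int) -> str:
    """The hit's matched peptide extended by ``flank_aa`` residues on each
    side, truncated at frame bounds and at stop codons."""
    pep = frame.peptide
    a0, a1 = hit.aa_start - 1, hit.aa_end  # 0-based half-open
    s = max(0, a0 - flank_aa)
    e = min(len(pep), a1 + flank_aa)
    left = pep.rfind("*", s, a0)
    if left != -1:
        s = left + 1
    right = pep.find("*", a1, e)
    if right != -1:
        e = right
    return pep[s:e]


def align_confirm(hits: Sequence[DomainHit], frames: Iterable[PeptideFrame],
                  references: Sequence[ReferenceDomain],
                  min_identity_pct: float = 60.0, min_aln_len_aa: int = 15,
                  flank_aa: int = 50) -> list[DomainHit]:
    """Confirm motif hits by local alignment against same-class references.

    Confirmation is a flag, not a filter: the output has the same hits in
    the same order, with ``confirmed``, ``score`` and ``identity_pct`` set.
    """
    if not references:
        raise ValueError("reference set is empty")
    by_class = _group_by_class(references)
    index = _frame_index(frames)
    aligner = make_aligner()
    out: list[DomainHit] = []
    for hit in hits:
        refs = by_class.get(hit.domain_class)
        if not refs:
            raise ValueError(f"no references for domain class {hit.domain_class!r}")
        frame = index[(hit.contig_id, hit.frame)]
        query = flanked_peptide(hit, frame, flank_aa)
        ref, aln = _best_reference(aligner, query, refs)
        if aln is None:
            out.append(replace(hit, confirmed=False))
            continue
        identity, aligned_len = _identity(aln)
        ok = identity >= min_identity_pct and aligned_len >= min_aln_len_aa
        out.append(replace(hit, confirmed=ok, score=float(aln.score),
                           identity_pct=round(identity, 2)))
    return out


def _stop_delimited(peptide: str) -> list[tuple[int, str]]:
    """(offset, segment) pairs for the stop-free segments of a peptide."""
    segments = []
    start = 0
    for i, aa in enumerate(peptide + "*"):
        if aa == "*":
            if i > start:
                segments.append((start, peptide[start:i]))
            start = i + 1
    return segments


def align_search(frames: Iterable[PeptideFrame],
                 references: Sequence[ReferenceDomain],
                 min_identity_pct: float = 60.0,
                 min_aln_len_aa: int = 15) -> list[DomainHit]:
    """Alignment-only domain search over stop-delimited frame peptides.

    At most one hit per (peptide segment, domain class): the best-scoring
    reference is kept (ties to the lowest reference id).  Hits passing both
    identity and length thresholds are returned confirmed, with coordinates
    covering the locally aligned region of the query.
    """
    if not references:
        raise ValueError("reference set is empty")
    by_class = _group_by_class(references)
    aligner = make_aligner()
    hits: list[DomainHit] = []
    for frame in frames:
        for seg_off, segment in _stop_delimited(frame.peptide):
            if len(segment) < min_aln_len_aa:
                continue
            for domain_class in sorted(by_class):
                ref, aln = _best_reference(aligner, segment, by_class[domain_class])
                if aln is None:
                    continue
                identity, aligned_len = _identity(aln)
                if identity < min_identity_pct or aligned_len < min_aln_len_aa:
                    continue
                if len(aln.aligned[0]) == 0:
                    continue
                qs = int(aln.aligned[0][0][0])
                qe = int(aln.aligned[0][-1][1])
                a0 = seg_off + qs
                a1 = seg_off + qe
                nt_start, nt_end = frame.nt_span(a0, a1)
                hits.append(DomainHit(
                    contig_id=frame.contig_id, domain_class=domain_class,
                    strand=frame.strand, frame=frame.frame,
                    aa_start=a0 + 1, aa_end=a1,
                    nt_start=nt_start, nt_end=nt_end,
                    matched_peptide=segment[qs:qe], method="alignment",
                    confirmed=True, score=float(aln.score),
                    identity_pct=round(identity, 2)))
    return hits
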