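"""Domain hit records and their tabular/GFF3 exports."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

HIT_COLUMNS = ["contig_id", "domain_class", "method", "strand", "frame",
               "nt_start", "nt_end", "aa_start", "aa_end", "matched_peptide",
               "score", "identity_pct", "confirmed"]


@dataclass(frozen=True)
class DomainHit:
    """One detected KS/C/A domain occurrence on a contig.

    Coordinates are 1-based inclusive; ``nt_start <= nt_end`` always, with
    orientation carried by ``strand``.  The nucleotide span is exactly three
    times the amino-acid span.
    """

    contig_id: str
    domain_class: str
    strand: str
    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    matched_peptide: str
    method: str
    confirmed: bool
    score: Optional[float] = None
    identity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.nt_start > self.nt_end:
            raise ValueError("nt_start must be <= nt_end")
        aa_len = self.aa_end - self.aa_start + 1
        nt_len = self.nt_end - self.nt_start + 1
        if nt_len != 3 * aa_len:
            raise ValueError(
                f"nt span {nt_len} is not 3x the aa span {aa_len} "
                f"({self.contig_id}:{self.nt_start}-{self.nt_end})")
        if len(self.matched_peptide) != aa_len:
            raise ValueError("matched peptide length disagrees with aa span")


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    rows = [asdict(h) for h in hits]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(DomainHit(
            contig_id=str(row.contig_id), domain_class=str(row.domain_class),
            strand=str(row.strand), frame=int(row.frame),
            aa_start=int(row.aa_start), aa_end=int(row.aa_end),
            nt_start=int(row.nt_start), nt_end=int(row.nt_end),
            matched_peptide=str(row.matched_peptide), method=str(row.method),
            confirmed=bool(row.confirmed),
            score=None if pd.isna(row.score) else float(row.score),
            identity_pct=None if pd.isna(row.identity_pct) else float(row.identity_pct),
        ))
    return hits


def write_hits_gff3(hits: Iterable[DomainHit], path, source: str = "sedimine") -> None:
    """GFF3 export (type ``polypeptide_motif``, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, 1):
            score = "." if h.score is None else f"{h.score:g}"
            attrs = (f"ID=hit{i};domain_class={h.domain_class};"
                     f"method={h.method};confirmed={str(h.confirmed).lower()}")
            fh.write("\t".join([
                h.contig_id, source, "polypeptide_motif",
                str(h.nt_start), str(h.nt_end), score, h.strand,
                ".", attrs]) + "\n")
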