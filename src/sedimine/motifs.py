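"""Catalytic-motif patterns and contig scanning.

The ketosynthase (KS) domain of type-I polyketide synthases and the
condensation (C) domain of non-ribosomal peptide synthetases carry short
conserved catalytic motifs.  A motif is modelled as an ordered list of
residue classes (:class:`MotifSpec`): a singleton class is a fixed residue,
a larger class records the substitutions tolerated at that position.
Patterns can be derived from a protein alignment around a wildcard anchor
(``derive_motif``) or written directly in a compact bracket syntax, e.g.
``GP[ACQS]{5}TA[CQSY][ST][AS]`` for KS-PKS and ``HH[A-Z]{3}DG`` for C-NRPS.

``[A-Z]`` is narrowed to the 20 proteinogenic amino-acid letters: stop
('*') and unknown ('X') are not catalytic residues and never match.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hits import DomainHit
from .sequences import PeptideFrame

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

KS_PKS = "KS_PKS"
C_NRPS = "C_NRPS"
CUSTOM = "custom"

#: motif domain_class -> the class label used on hits
HIT_CLASS = {KS_PKS: "KS", C_NRPS: "C", CUSTOM: "custom"}


@dataclass(frozen=True)
class MotifSpec:
    """A domain class's catalytic-motif pattern."""

    domain_class: str
    anchor: str
    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if self.anchor and len(self.positions) != len(self.anchor):
            raise ValueError("positions and anchor lengths differ")
        for pos in self.positions:
            if not pos:
                raise ValueError("empty residue class in motif")
            if not pos <= _AA_SET:
                raise ValueError(f"non-amino-acid residues in class: {set(pos)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def pattern(self) -> str:
        """Canonical textual serialization with run-length compression."""
        tokens: list[str] = []
        i = 0
        while i < len(self.positions):
            pos = self.positions[i]
            run = 1
            while i + run < len(self.positions) and self.positions[i + run] == pos:
                run += 1
            if len(pos) == 1:
                tokens.append(next(iter(pos)) * run)
            else:
                cls = "[A-Z]" if pos == _AA_SET else "[" + "".join(sorted(pos)) + "]"
                tokens.append(cls + (f"{{{run}}}" if run > 1 else ""))
            i += run
        return "".join(tokens)

    @classmethod
    def from_pattern(cls, pattern: str, domain_class: str = CUSTOM,
                     anchor: str = "") -> "MotifSpec":
        """Parse a bracket pattern.  Accepts plain residue letters,
        ``[ABC]`` / ``[A,B,C]`` residue classes, ``[A-Z]`` for any amino
        acid, and ``{n}`` repeats after a class."""
        positions: list[frozenset] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                body = pattern[i + 1:j].replace(",", "")
                residues = _AA_SET if body == "A-Z" else frozenset(body)
                i = j + 1
                run = 1
                if i < len(pattern) and pattern[i] == "{":
                    j = pattern.index("}", i)
                    run = int(pattern[i + 1:j])
                    i = j + 1
                positions.extend([residues] * run)
            elif ch in _AA_SET:
                positions.append(frozenset(ch))
                i += 1
            else:
                raise ValueError(f"cannot parse pattern at {pattern[i:]!r}")
        if not anchor:
            anchor = "".join(next(iter(p)) if len(p) == 1 else "X" for p in positions)
        return cls(domain_class=domain_class, anchor=anchor,
                   positions=tuple(positions))

    def to_regex(self) -> re.Pattern:
        parts = []
        for pos in self.positions:
            if len(pos) == 1:
                parts.append(re.escape(next(iter(pos))))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=(" + "".join(parts) + "))")

    def matches(self, peptide: str) -> bool:
        return len(peptide) == len(self) and all(
            aa in pos for aa, pos in zip(peptide, self.positions))


def ks_motif() -> MotifSpec:
    """KS-PKS catalytic-centre pattern, GP[ACQS]{5}TA[CQSY][ST][AS]."""
    return MotifSpec.from_pattern("GP[ACQS]{5}TA[CQSY][ST][AS]",
                                  domain_class=KS_PKS, anchor="GPXXXXXTACSS")


def c_motif(variant: str = "printed") -> MotifSpec:
    """C-NRPS catalytic-centre pattern.

    ``printed`` is the double-histidine form HH[A-Z]{3}DG; ``relaxed`` is
    H[A-Z]{4}DG, matching the single-H anchor HXXXDG.
    """
    if variant == "printed":
        return MotifSpec.from_pattern("HH[A-Z]{3}DG",
                                      domain_class=C_NRPS, anchor="HHXXXDG")
    if variant == "relaxed":
        return MotifSpec.from_pattern("H[A-Z]{4}DG",
                                      domain_class=C_NRPS, anchor="HXXXXDG")
    raise ValueError(f"unknown C-motif variant {variant!r}")


def derive_motif(alignment: Sequence[str], anchor: str,
                 min_freq: float = 0.05, domain_class: str = CUSTOM) -> MotifSpec:
    """Derive a residue-class pattern from an aligned protein set.

    The anchor (fixed residues plus ``X`` wildcards) is located as the
    window of aligned columns maximizing the number of rows whose fixed
    columns match it exactly.  Each wildcard column becomes the residue
    class seen at that column: residues at column frequency >= ``min_freq``
    plus every residue contributed by an anchor-matching row, so that each
    row matching the fixed columns also matches the derived pattern.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("aligned sequences must all have the same length")
    W = len(anchor)
    fixed = [(k, aa) for k, aa in enumerate(anchor) if aa != "X"]

    best_start, best_count = -1, 0
    for start in range(width - W + 1):
        count = sum(all(row[start + k] == aa for k, aa in fixed)
                    for row in alignment)
        if count > best_count:
            best_start, best_count = start, count
    if best_count == 0:
        raise ValueError(f"anchor {anchor!r} not found in any alignment window")

    window = [row[best_start:best_start + W] for row in alignment]
    for k in range(W):
        if all(row[k] == "-" for row in window):
            raise ValueError(f"all-gap column {best_start + k} inside anchor window")

    matching = [row for row in window if all(row[k] == aa for k, aa in fixed)]
    n = len(alignment)
    positions: list[frozenset] = []
    for k, aa in enumerate(anchor):
        if aa != "X":
            positions.append(frozenset(aa))
            continue
        col = Counter(row[k] for row in window if row[k] in _AA_SET)
        residues = {r for r, c in col.items() if c / n >= min_freq}
        residues |= {row[k] for row in matching if row[k] in _AA_SET}
        if not residues:
            raise ValueError(f"no admissible residues in wildcard column {k}")
        positions.append(frozenset(residues))
    return MotifSpec(domain_class=domain_class, anchor=anchor,
                     positions=tuple(positions))


def scan_motifs(frames: Iterable[PeptideFrame],
                motifs: Sequence[MotifSpec]) -> list[DomainHit]:
    """Report every (overlapping) motif occurrence in every frame peptide.

    Patterns range over amino-acid classes only, so matches never span a
    stop ('*') or unknown ('X') residue.  Coordinates are 1-based inclusive
    on the forward strand; hits carry ``method='motif'`` and are
    unconfirmed until :func:`sedimine.alignment.align_confirm` runs.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    hits: list[DomainHit] = []
    for frame in frames:
        for motif in motifs:
            regex = motif.to_regex()
            W = len(motif)
            for m in regex.finditer(frame.peptide):
                a0 = m.start()
                nt_start, nt_end = frame.nt_span(a0, a0 + W)
                hits.append(DomainHit(
                    contig_id=frame.contig_id,
                    domain_class=HIT_CLASS.get(motif.domain_class, motif.domain_class),
                    strand=frame.strand,
                    frame=frame.frame,
                    aa_start=a0 + 1,
                    aa_end=a0 + W,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    matched_peptide=m.group(1),
                    method="motif",
                    confirmed=False,
                ))
    return hits


def match_probability(motif: MotifSpec,
                      residue_probs: Mapping[str, float] | None = None) -> float:
    """Per-position probability that an i.i.d. peptide matches the motif.

    With no ``residue_probs`` the residues are uniform over the 20 amino
    acids (the classical decoy model); otherwise probabilities may include
    '*' and 'X' so translated-background rates can be computed exactly.
    """
    p = 1.0
    for pos in motif.positions:
        if residue_probs is None:
            p *= len(pos) / 20.0
        else:
            p *= sum(residue_probs.get(r, 0.0) for r in pos)
    return p


def expected_match_count(motif: MotifSpec, peptide_lengths: Iterable[int],
                         residue_probs: Mapping[str, float] | None = None) -> float:
    """Expected chance match count over peptides of the given lengths."""
    p = match_probability(motif, residue_probs)
    windows = sum(max(0, n - len(motif) + 1) for n in peptide_lengths)
    return windows * p
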