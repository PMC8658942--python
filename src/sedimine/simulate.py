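"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of the real inputs — assembled mangrove-
sediment contigs screened for PKS/NRPS domains, reference domain proteins,
cluster-predictor region tables, and MS/MS spectral families — while
recording exactly what was planted where, so recovery can be scored
against truth.  Everything is driven by one ``numpy`` Generator per call:
the same seed gives byte-identical FASTA/MGF output.

Background contigs are i.i.d. nucleotides at a configurable GC fraction;
planted peptides are reverse-translated with uniformly random synonymous
codons.  Spectral families perturb a template's peak m/z by bounded uniform
jitter and intensities by lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .masses import CompoundRecord, parse_formula
from .motifs import AMINO_ACIDS, MotifSpec
from .networking import Spectrum
from .sequences import SequenceRecord, reverse_complement


# ---------------------------------------------------------------------------
# planted-motif contigs

@dataclass(frozen=True)
class PlantSpec:
    """What to plant: a fixed peptide or a sampler over a motif's residue
    classes, on a given strand, ``count`` times."""

    domain_class: str
    strand: str
    count: int
    peptide: Optional[str] = None
    motif: Optional[MotifSpec] = None

    def __post_init__(self) -> None:
        if (self.peptide is None) == (self.motif is None):
            raise ValueError("specify exactly one of peptide or motif")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count <= 0:
            raise ValueError("count must be positive")
        if self.peptide is not None and ("*" in self.peptide or "X" in self.peptide):
            raise ValueError("plant peptides must be stop- and ambiguity-free")


@dataclass(frozen=True)
class ContigSimConfig:
    seed: int
    n_contigs: int = 50
    contig_length_range: tuple[int, int] = (2000, 10000)
    gc_fraction: float = 0.5
    plants: tuple[PlantSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_contigs <= 0:
            raise ValueError("n_contigs must be positive")
        lo, hi = self.contig_length_range
        if not 3 <= lo <= hi:
            raise ValueError("bad contig length range")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0,1]")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for one planted domain stretch (1-based inclusive
    forward-strand coordinates, reading frame, encoded peptide)."""

    contig_id: str
    domain_class: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    peptide: str


_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
for _aa in _BACK_TABLE:
    _BACK_TABLE[_aa].sort()


def sample_motif_peptide(motif: MotifSpec, rng: np.random.Generator) -> str:
    """A peptide drawn uniformly from a motif's residue classes."""
    return "".join(sorted(pos)[rng.integers(len(pos))] for pos in motif.positions)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Encode a peptide with uniformly random synonymous codons."""
    return "".join(_BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))]
                   for aa in peptide)


def _random_contig(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def simulate_contigs(config: ContigSimConfig
                     ) -> tuple[list[SequenceRecord], list[PlantTruth]]:
    """Contigs with planted domain-encoding stretches at known coordinates.

    Plants are placed uniformly at random without overlapping one another;
    an infeasible packing (no free slot after bounded retries) raises.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.contig_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_contigs)]
    contigs = [_random_contig(rng, n, config.gc_fraction) for n in lengths]
    ids = [f"contig_{i + 1:04d}" for i in range(config.n_contigs)]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.n_contigs)}
    truths: list[PlantTruth] = []

    for plant in config.plants:
        for _ in range(plant.count):
            peptide = (plant.peptide if plant.peptide is not None
                       else sample_motif_peptide(plant.motif, rng))
            coding = reverse_translate(peptide, rng)
            insert = coding if plant.strand == "+" else reverse_complement(coding)
            m = len(insert)
            placed = False
            for _attempt in range(200):
                ci = int(rng.integers(config.n_contigs))
                L = lengths[ci]
                if L < m:
                    continue
                p = int(rng.integers(0, L - m + 1))
                if any(p < e and s < p + m for s, e in occupied[ci]):
                    continue
                contigs[ci][p:p + m] = list(insert)
                occupied[ci].append((p, p + m))
                if plant.strand == "+":
                    frame = p % 3 + 1
                else:
                    frame = -((L - p - m) % 3 + 1)
                truths.append(PlantTruth(
                    contig_id=ids[ci], domain_class=plant.domain_class,
                    strand=plant.strand, frame=frame,
                    nt_start=p + 1, nt_end=p + m, peptide=peptide))
                placed = True
                break
            if not placed:
                raise ValueError("infeasible packing: could not place plant")
    records = [SequenceRecord(id=ids[i], seq="".join(contigs[i]))
               for i in range(config.n_contigs)]
    return records, truths


def simulate_reference_domains(rng: np.random.Generator, domain_class: str,
                               n: int, length: int = 200) -> list:
    """Random decoy reference proteins of one domain class (uniform i.i.d.
    residues) — background for alignment searches."""
    from .alignment import ReferenceDomain
    aa = np.array(list(AMINO_ACIDS))
    return [ReferenceDomain(id=f"{domain_class}_ref_{i + 1:03d}",
                            domain_class=domain_class,
                            peptide="".join(rng.choice(aa, size=length)))
            for i in range(n)]


def mutate_peptide(peptide: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues uniformly to the requested identity fraction."""
    n_mut = round(len(peptide) * (1 - identity))
    positions = rng.choice(len(peptide), size=n_mut, replace=False)
    out = list(peptide)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# translated-background statistics

def translated_aa_probs(gc_fraction: float = 0.5,
                        table_id: int = 1) -> dict[str, float]:
    """Residue distribution (incl. '*') of translating i.i.d. nucleotides
    with the given GC fraction — the null model for chance motif matches on
    six-frame-translated background contigs."""
    pnt = {"A": (1 - gc_fraction) / 2, "T": (1 - gc_fraction) / 2,
           "C": gc_fraction / 2, "G": gc_fraction / 2}
    table = CodonTable.unambiguous_dna_by_id[table_id]
    probs: dict[str, float] = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                aa = table.forward_table.get(codon, "*")
                probs[aa] = probs.get(aa, 0.0) + pnt[b1] * pnt[b2] * pnt[b3]
    return probs


# ---------------------------------------------------------------------------
# spectral families

@dataclass(frozen=True)
class SpectraSimConfig:
    seed: int
    n_families: int = 3
    spectra_per_family: int = 5
    peaks_per_spectrum: int = 8
    mz_jitter_da: float = 0.005
    intensity_noise_cv: float = 0.2
    precursor_offset_da: float = 0.0
    family_mz_block: float = 100.0
    mz_start: float = 150.0

    def __post_init__(self) -> None:
        if min(self.n_families, self.spectra_per_family,
               self.peaks_per_spectrum) <= 0:
            raise ValueError("counts must be positive")
        if self.mz_jitter_da < 0 or self.intensity_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")


def simulate_spectra(config: SpectraSimConfig
                     ) -> tuple[list[Spectrum], dict[str, int]]:
    """Spectrum families with a known partition.

    Each family draws a template peak set on its own disjoint m/z block
    (blocks are ``family_mz_block`` Da wide, peaks >= 1 Da apart), then each
    member jitters peak positions by at most ``mz_jitter_da`` and scales
    intensities by lognormal noise with the configured CV.  A non-zero
    ``precursor_offset_da`` shifts each member's precursor AND all its
    peaks, exercising the shifted-match path of the modified cosine.
    Returns the spectra and the spectrum-id -> family-index truth map.
    """
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log(1 + config.intensity_noise_cv ** 2))
    spectra: list[Spectrum] = []
    truth: dict[str, int] = {}
    for fam in range(config.n_families):
        block_lo = config.mz_start + fam * config.family_mz_block
        usable = config.family_mz_block - 20.0
        # template peaks spaced >= 1 Da inside the family's block
        offsets = np.sort(rng.uniform(0, usable - config.peaks_per_spectrum,
                                      size=config.peaks_per_spectrum))
        template_mz = block_lo + offsets + np.arange(config.peaks_per_spectrum)
        template_int = rng.uniform(10.0, 100.0, size=config.peaks_per_spectrum)
        precursor = float(block_lo + usable + 10.0)
        for k in range(config.spectra_per_family):
            jitter = rng.uniform(-config.mz_jitter_da, config.mz_jitter_da,
                                 size=config.peaks_per_spectrum)
            noise = (np.exp(rng.normal(0.0, sigma, size=config.peaks_per_spectrum))
                     if sigma > 0 else np.ones(config.peaks_per_spectrum))
            shift = config.precursor_offset_da * k
            sid = f"F{fam + 1:02d}S{k + 1:02d}"
            spectra.append(Spectrum(
                id=sid,
                precursor_mz=precursor + shift,
                mz=template_mz + jitter + shift,
                intensity=template_int * noise))
            truth[sid] = fam
    return spectra, truth


# ---------------------------------------------------------------------------
# printed-table fixtures

#: Annotated compounds of the reference dereplication table:
#: (name, molecular formula, sample tags).
_LIBRARY_ROWS = [
    ("Small bacteriocin", "C18H31NO4", ("TMa", "TM", "TA")),
    ("Bacteriocin 28b", "C12H11N3O2", ("TMa", "TM")),
    ("Salinosporamide B", "C15H21NO4", ("TMa", "TM")),
    ("Salinosporamide E", "C16H23NO4", ("TM",)),
    ("Erythronolide A", "C21H38O8", ("TM", "TA")),
    ("Jamaicamide C", "C27H39ClN2O4", ("TMa", "TM")),
    ("Soraphen A", "C28H42O8", ("TA",)),
    ("Soraphen S", "C27H40O8", ("TMa", "TM", "TA")),
    ("Tetronomycin", "C34H50O8", ("TMa", "TM", "TA")),
    ("Actiphenol", "C15H17NO4", ("TM",)),
    ("Secocycloheximide A", "C15H23NO4", ("TMa", "TM")),
    ("Lumichrome", "C12H10N4O2", ("TMa", "TM")),
]

#: Observed ions of the same table: (compound, adduct, observed m/z).
OBSERVED_IONS = [
    ("Small bacteriocin", "[M+H]+", 326.232),
    ("Small bacteriocin", "[M+Na]+", 348.214),
    ("Bacteriocin 28b", "[M-H]-", 228.078),
    ("Salinosporamide B", "[M+H]+", 280.154),
    ("Salinosporamide B", "[M+Na]+", 302.136),
    ("Salinosporamide E", "[M+H]+", 294.17),
    ("Erythronolide A", "[M+Na]+", 441.248),
    ("Jamaicamide C", "[M+H]+", 491.266),
    ("Soraphen A", "[M+H]+", 507.296),
    ("Soraphen A", "[M+Na]+", 529.278),
    ("Soraphen S", "[M-H]-", 491.266),
    ("Soraphen S", "[M+H]+", 493.281),
    ("Soraphen S", "[M+Na]+", 515.263),
    ("Tetronomycin", "[M+H]+", 587.359),
    ("Tetronomycin", "[M+Na]+", 609.341),
    ("Actiphenol", "[M-H]-", 274.109),
    ("Secocycloheximide A", "[M-H]-", 280.155),
    ("Lumichrome", "[M+H]+", 243.088),
]


def reference_compound_library() -> list[CompoundRecord]:
    """The 12-compound dereplication library; exact masses are computed
    from the formulas, never hard-coded."""
    return [CompoundRecord(name=name, formula=parse_formula(formula),
                           samples=samples)
            for name, formula, samples in _LIBRARY_ROWS]


#: Reference per-sample counts (A, C, KS domains; predicted clusters) for
#: seven mangrove-sediment metagenomes — the worked aggregation example's input.
SAMPLE_COUNTS = {
    "MR": dict(a=136, c=12, ks=17, clusters=85),
    "MA": dict(a=250, c=13, ks=29, clusters=335),
    "MC": dict(a=235, c=15, ks=27, clusters=224),
    "T0": dict(a=85, c=26, ks=29, clusters=163),
    "TA": dict(a=76, c=27, ks=12, clusters=63),
    "TM": dict(a=43, c=27, ks=23, clusters=118),
    "TMa": dict(a=15, c=8, ks=14, clusters=63),
}

#: Sampling-campaign grouping of those samples (2017 environmental sediments
#: vs 2018 sediments and their enrichment treatments).
SAMPLE_GROUPS = {
    "MR": "2017", "MA": "2017", "MC": "2017",
    "T0": "2018", "TA": "2018", "TM": "2018", "TMa": "2018",
}


def synthesize_hits_from_counts(counts: dict[str, dict] = SAMPLE_COUNTS):
    """Materialize per-sample domain-hit lists and cluster annotations whose
    tallies equal a given count table (distinct loci per hit, so nothing is
    lost to deduplication)."""
    from .aggregate import ClusterAnnotation
    from .hits import DomainHit
    hits_by_sample: dict[str, list[DomainHit]] = {}
    clusters: list[ClusterAnnotation] = []
    for sample, row in counts.items():
        hits = []
        locus = 1
        for domain_class, key in (("A", "a"), ("C", "c"), ("KS", "ks")):
            for _ in range(row[key]):
                start = locus * 100
                hits.append(DomainHit(
                    contig_id=f"{sample}_ctg", domain_class=domain_class,
                    strand="+", frame=1, aa_start=1, aa_end=15,
                    nt_start=start, nt_end=start + 44,
                    matched_peptide="M" * 15, method="alignment",
                    confirmed=True))
                locus += 1
        hits_by_sample[sample] = hits
        for k in range(row["clusters"]):
            clusters.append(ClusterAnnotation(
                sample=sample, contig_id=f"{sample}_bgc_{k + 1}",
                nt_start=1, nt_end=5000, product_class="NRPS"))
    return hits_by_sample, clusters
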