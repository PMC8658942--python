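"""Monoisotopic masses, adduct m/z values and ppm-tolerance dereplication.

Untargeted LC-MS/MS features are annotated against a compound library by
exact mass: for each library compound the neutral monoisotopic mass is the
sum of the most-abundant-isotope masses of its atoms; candidate ions are
formed by adding an adduct delta ([M+H]+, [M+Na]+, [M-H]-); an observed ion
is annotated when the relative deviation

    ppm = (observed - theoretical) / theoretical * 1e6

is within tolerance (default 5 ppm).

Two sodium conventions are supported.  ``paper`` (default) adds the mass of
a neutral sodium atom, which is how the reference annotation table was
computed; ``strict`` uses ion masses throughout (Na+ = neutral Na minus an
electron).  [M+H]+/[M-H]- use the proton mass under both conventions.

Reporting precision is masses 4 decimals, m/z 3 decimals, ppm 1 decimal
(half-up); all arithmetic is done at full float precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Monoisotopic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "Na": 22.9897693,
    "Cl": 34.96885268,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.99840322,
    "K": 38.9637069,
    "Br": 78.9183376,
    "I": 126.904473,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding for report columns (banker's rounding would
    flip several printed values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map; parses from and serializes to Hill notation."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {element!r}")
            if n <= 0:
                raise ValueError(f"non-positive count for {element}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for element, n in other.counts:
            merged[element] = merged.get(element, 0) + n
        return MolecularFormula.from_counts(merged)

    @property
    def hill(self) -> str:
        """Hill-order string: C then H then the rest alphabetically (all
        alphabetical when there is no carbon)."""
        counts = self.as_dict()
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(e for e in counts if e not in ("C", "H")))
        else:
            order.extend(sorted(counts))
        return "".join(f"{e}{counts[e] if counts[e] > 1 else ''}" for e in order)

    def __str__(self) -> str:
        return self.hill


def parse_formula(text: str) -> MolecularFormula:
    """Parse a molecular formula string such as ``C27H39ClN2O4``."""
    if not text:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"zero count for {element} in formula {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return MolecularFormula.from_counts(counts)


def monoisotopic_mass(formula: MolecularFormula | str) -> float:
    """Neutral monoisotopic (exact) mass in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts)


@dataclass(frozen=True)
class AdductSpec:
    """An observed-ion adduct: a named mass shift at unit charge."""

    name: str
    polarity: str
    delta_da: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in "+-":
            raise ValueError(f"bad polarity {self.polarity!r}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


def builtin_adducts(convention: str = "paper") -> list[AdductSpec]:
    """The three built-in adducts under the requested sodium convention."""
    if convention == "paper":
        na_delta = MONOISOTOPIC_MASS["Na"]  # neutral sodium atom
    elif convention == "strict":
        na_delta = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
    else:
        raise ValueError(f"unknown adduct convention {convention!r}")
    return [
        AdductSpec("[M+H]+", "+", PROTON_MASS),
        AdductSpec("[M+Na]+", "+", na_delta),
        AdductSpec("[M-H]-", "-", -PROTON_MASS),
    ]


_ADDUCT_ALIASES = {
    "[M+H]+": "[M+H]+", "[M + H]+": "[M+H]+",
    "[M+Na]+": "[M+Na]+", "[M + Na]+": "[M+Na]+",
    "[M-H]-": "[M-H]-", "[M - H]-": "[M-H]-", "[M−H]−": "[M-H]-",
}


def get_adduct(name: str, convention: str = "paper") -> AdductSpec:
    canonical = _ADDUCT_ALIASES.get(name.replace("−", "-").replace(" ", ""))
    canonical = canonical or name
    for adduct in builtin_adducts(convention):
        if adduct.name == canonical:
            return adduct
    raise ValueError(f"unknown adduct {name!r}")


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + adduct.delta_da


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound with its computed exact mass."""

    name: str
    formula: MolecularFormula
    exact_mass: float = field(default=0.0)
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        computed = monoisotopic_mass(self.formula)
        if self.exact_mass == 0.0:
            object.__setattr__(self, "exact_mass", computed)
        elif abs(self.exact_mass - computed) > 5e-4:
            raise ValueError(
                f"{self.name}: stated exact mass {self.exact_mass} deviates "
                f"from computed {computed:.4f} by more than 5e-4 Da")


@dataclass(frozen=True)
class ObservedIon:
    """An observed precursor/feature m/z with its ionization polarity."""

    mz: float
    polarity: str
    sample: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("observed m/z must be positive")
        if self.polarity not in "+-":
            raise ValueError(f"bad polarity {self.polarity!r}")


@dataclass(frozen=True)
class AnnotationHit:
    """A compound/adduct annotation of an observed ion."""

    compound: str
    adduct: str
    theoretical_mz: float
    observed_mz: float
    ppm: float
    samples: tuple[str, ...] = ()


def dereplicate(ions: Sequence[ObservedIon], library: Sequence[CompoundRecord],
                adducts: Sequence[AdductSpec] | None = None,
                tol_ppm: float = 5.0) -> list[AnnotationHit]:
    """Annotate observed ions against a compound library.

    For each ion every polarity-matching (compound, adduct) pair within
    ``tol_ppm`` is emitted, sorted by absolute ppm (ties by compound name).
    """
    if not library:
        raise ValueError("compound library is empty")
    if adducts is None:
        adducts = builtin_adducts()
    hits: list[AnnotationHit] = []
    for ion in ions:
        candidates = []
        for compound in library:
            for adduct in adducts:
                if adduct.polarity != ion.polarity:
                    continue
                theo = adduct_mz(compound.exact_mass, adduct)
                ppm = ppm_error(ion.mz, theo)
                if abs(ppm) <= tol_ppm:
                    candidates.append(AnnotationHit(
                        compound=compound.name, adduct=adduct.name,
                        theoretical_mz=theo, observed_mz=ion.mz, ppm=ppm,
                        samples=(ion.sample,) if ion.sample else ()))
        candidates.sort(key=lambda h: (abs(h.ppm), h.compound))
        hits.extend(candidates)
    return hits


def read_compound_library(path) -> list[CompoundRecord]:
    """Compound library CSV with columns ``name, formula[, samples]``."""
    df = pd.read_csv(path)
    missing = [c for c in ("name", "formula") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        samples = getattr(row, "samples", None)
        tags = tuple() if samples is None or pd.isna(samples) else \
            tuple(t.strip() for t in str(samples).split(";") if t.strip())
        records.append(CompoundRecord(name=str(row.name),
                                      formula=parse_formula(str(row.formula)),
                                      samples=tags))
    return records


def read_ion_csv(path) -> list[ObservedIon]:
    """Observed-ion CSV with columns ``mz, polarity[, sample]``."""
    df = pd.read_csv(path)
    missing = [c for c in ("mz", "polarity") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    return [ObservedIon(mz=float(row.mz), polarity=str(row.polarity),
                        sample=str(getattr(row, "sample", "") or ""))
            for row in df.itertuples(index=False)]


def annotations_to_frame(hits: Sequence[AnnotationHit],
                         library: Sequence[CompoundRecord] = ()) -> pd.DataFrame:
    """Annotation table mirroring a dereplication report: compound, formula,
    exact mass, observed ion, adduct, ppm, samples."""
    formulas = {c.name: c for c in library}
    rows = []
    for h in hits:
        compound = formulas.get(h.compound)
        rows.append({
            "compound": h.compound,
            "formula": compound.formula.hill if compound else "",
            "exact_mass": round_half_up(compound.exact_mass, 4) if compound else "",
            "observed_mz": round_half_up(h.observed_mz, 3),
            "adduct": h.adduct,
            "ppm": round_half_up(h.ppm, 1),
            "samples": ";".join(h.samples),
        })
    return pd.DataFrame(rows, columns=["compound", "formula", "exact_mass",
                                       "observed_mz", "adduct", "ppm", "samples"])


def write_annotations_csv(hits: Sequence[AnnotationHit], path,
                          library: Sequence[CompoundRecord] = ()) -> None:
    annotations_to_frame(hits, library).to_csv(path, index=False)
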