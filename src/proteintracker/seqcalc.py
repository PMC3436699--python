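"""Sequence-derived properties and mass bookkeeping for protein records.

All quantities that the tracker computes automatically at record
submission live here as pure functions: average-isotopic molecular
weight, molar extinction coefficient at 280 nm (reduced and oxidized
cysteine conventions), the 0.1% (1 mg/mL) absorbance, N-glycosylation
sequon counts, and the purified-batch mass arithmetic.

Conventions
-----------
* Molecular weight is the sum of *average* residue masses plus one water
  (18.0153 Da), i.e. the mass of the condensed polypeptide. Monoisotopic
  mass is deliberately not offered.
* The 280 nm extinction coefficient follows the Gill & von Hippel / Pace
  values: Trp 5500, Tyr 1490, cystine 125 M^-1 cm^-1. The *reduced* value
  assumes all cysteines free; the *oxidized* value adds 125 per cystine
  pair, i.e. ``125 * floor(nCys / 2)``.
* A280(0.1%) = extinction_reduced / MW, in mL mg^-1 cm^-1. Zero is a
  legal result for a chromophore-free sequence.
* A sequon is N-X-S/T with X != P; overlapping sequons each count.
* Reported values: masses and A280 to 2 decimals (round half to even),
  extinction coefficients are exact integers. Internal computation is at
  full float precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from Bio import SeqIO

from .errors import (
    AliquotBoundsViolation,
    EmptySequence,
    IllegalResidue,
    NegativeQuantity,
)

__all__ = [
    "AMINO_ACIDS",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "SequenceProperties",
    "MassRecord",
    "normalize_sequence",
    "molecular_weight",
    "molecular_weight_exact",
    "extinction_coefficient",
    "absorbance_0_1pct",
    "count_nglyc_sites",
    "sequence_properties",
    "batch_mass",
    "remaining_mass",
    "mass_record",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Average (isotope-abundance-weighted) residue masses in daltons, i.e.
# the free amino-acid mass minus one water. 4-decimal precision.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

WATER_MASS = 18.0153  # Da, added once per chain for the terminal H and OH

EXT_TRP = 5500  # M^-1 cm^-1 at 280 nm
EXT_TYR = 1490
EXT_CYSTINE = 125

# characters silently stripped during normalization: whitespace, digits
# (sequence numbering pasted from viewers) and the stop mark '*'
_STRIP_RE = re.compile(r"[\s\d*]+")


@dataclass(frozen=True)
class SequenceProperties:
    """The five derived fields stored on every construct record."""

    molecular_weight: float          # Da, average isotopic, 2 decimals
    extinction_reduced: int          # M^-1 cm^-1, all Cys free
    extinction_oxidized: int         # M^-1 cm^-1, all Cys paired
    absorbance_0_1pct: float         # mL mg^-1 cm^-1, 2 decimals
    n_glyc_sites: int                # N-X-S/T sequons, X != P


@dataclass(frozen=True)
class MassRecord:
    """Mass bookkeeping for a purified protein batch."""

    total_mass: float        # mg = concentration * volume
    remaining_mass: float    # mg, proportional to remaining aliquots
    concentration: float     # mg/mL
    volume: float            # mL
    original_aliquots: int
    current_aliquots: int


def normalize_sequence(raw: str) -> str:
    """Clean free text into a validated one-letter amino-acid sequence.

    Whitespace, digits and ``*`` are stripped and lowercase letters are
    uppercased. Raises :class:`EmptySequence` if nothing remains and
    :class:`IllegalResidue` (with the 1-based position in the cleaned
    sequence) for any character outside the 20 standard codes —
    ambiguity codes B, J, O, U, X, Z included.
    """
    cleaned = _STRIP_RE.sub("", raw or "").upper()
    if not cleaned:
        raise EmptySequence("no residues remain after normalization")
    for i, ch in enumerate(cleaned, start=1):
        if ch not in AVERAGE_RESIDUE_MASS:
            raise IllegalResidue(ch, i)
    return cleaned


def molecular_weight_exact(seq: str) -> float:
    """Average molecular weight in Da at full float precision."""
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da, reported to 2 decimals."""
    return round(molecular_weight_exact(seq), 2)


def extinction_coefficient(seq: str) -> tuple[int, int]:
    """(reduced, oxidized) molar extinction coefficients at 280 nm.

    reduced  = 5500*nTrp + 1490*nTyr
    oxidized = reduced + 125*floor(nCys/2)
    """
    reduced = EXT_TRP * seq.count("W") + EXT_TYR * seq.count("Y")
    oxidized = reduced + EXT_CYSTINE * (seq.count("C") // 2)
    return reduced, oxidized


def absorbance_0_1pct(seq: str) -> float:
    """A280 of a 1 mg/mL (0.1%) solution: eps_reduced / MW, 2 decimals."""
    reduced, _ = extinction_coefficient(seq)
    return round(reduced / molecular_weight_exact(seq), 2)


def count_nglyc_sites(seq: str) -> int:
    """Number of N-X-S/T sequons (X != P); overlapping sequons all count."""
    n = 0
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            n += 1
    return n


def sequence_properties(seq: str) -> SequenceProperties:
    """All five derived fields for a validated sequence."""
    reduced, oxidized = extinction_coefficient(seq)
    return SequenceProperties(
        molecular_weight=molecular_weight(seq),
        extinction_reduced=reduced,
        extinction_oxidized=oxidized,
        absorbance_0_1pct=absorbance_0_1pct(seq),
        n_glyc_sites=count_nglyc_sites(seq),
    )


def batch_mass(concentration: float, volume: float) -> float:
    """Total purified mass in mg = concentration (mg/mL) x volume (mL)."""
    if concentration < 0 or volume < 0:
        raise NegativeQuantity(
            f"concentration={concentration}, volume={volume}: both must be >= 0"
        )
    return round(concentration * volume, 2)


def remaining_mass(
    total_mass: float, original_aliquots: int, current_aliquots: int
) -> float:
    """Remaining mass in mg, proportional to the remaining aliquot fraction.

    The batch record tracks only aliquot *counts*, so the remaining mass
    is total * current / original.
    """
    if original_aliquots < 1 or current_aliquots < 0:
        raise AliquotBoundsViolation(
            f"original={original_aliquots}, current={current_aliquots}"
        )
    if current_aliquots > original_aliquots:
        raise AliquotBoundsViolation(
            f"current aliquots ({current_aliquots}) exceed original "
            f"({original_aliquots})"
        )
    if total_mass < 0:
        raise NegativeQuantity(f"total_mass={total_mass}")
    return round(total_mass * current_aliquots / original_aliquots, 2)


def mass_record(
    concentration: float,
    volume: float,
    original_aliquots: int,
    current_aliquots: int,
) -> MassRecord:
    """Compute the full mass bookkeeping block for a batch."""
    total = batch_mass(concentration, volume)
    return MassRecord(
        total_mass=total,
        remaining_mass=remaining_mass(total, original_aliquots, current_aliquots),
        concentration=concentration,
        volume=volume,
        original_aliquots=original_aliquots,
        current_aliquots=current_aliquots,
    )


@dataclass(frozen=True)
class FastaRecord:
    name: str
    description: str
    sequence: str  # normalized


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file; every sequence is normalized and validated.

    Multi-record files are allowed (batch import); callers wanting a
    single sequence use the first record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            FastaRecord(
                name=rec.id,
                description=rec.description,
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    if not records:
        raise EmptySequence(f"no FASTA records in {path}")
    return records
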