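"""Sequence-derived protein masses, N-terminal Met-loss variants, isoelectric
points, and assignment of candidate proteins to observed intact-cell peaks.

Intact-cell MALDI peaks of proteins above a few kDa are unresolved isotopic
envelopes, so the observed m/z tracks the *average* molecular mass; the
monoisotopic mass is also computed for completeness.  Co-translational
excision of the initiator methionine is the dominant N-terminal processing
event in bacteria, so every sequence starting with Met additionally gets
"−Met" mass variants (mass minus one Met residue).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Residue (amino-acid minus water) masses in Da: monoisotopic, average.
RESIDUE_MASS: dict[str, tuple[float, float]] = {
    "G": (57.02146, 57.05192),
    "A": (71.03711, 71.07880),
    "S": (87.03203, 87.07820),
    "P": (97.05276, 97.11668),
    "V": (99.06841, 99.13256),
    "T": (101.04768, 101.10508),
    "C": (103.00919, 103.13880),
    "L": (113.08406, 113.15944),
    "I": (113.08406, 113.15944),
    "N": (114.04293, 114.10384),
    "D": (115.02694, 115.08860),
    "Q": (128.05858, 128.13072),
    "K": (128.09496, 128.17408),
    "E": (129.04259, 129.11548),
    "M": (131.04049, 131.19261),
    "H": (137.05891, 137.14108),
    "F": (147.06841, 147.17656),
    "R": (156.10111, 156.18748),
    "Y": (163.06333, 163.17596),
    "W": (186.07931, 186.21320),
}

WATER_MONO = 18.01056
WATER_AVG = 18.01528
MET_MONO = RESIDUE_MASS["M"][0]
MET_AVG = RESIDUE_MASS["M"][1]
PROTON = 1.00728

# Side-chain and terminal pKa values (Bjellqvist set, as used by common
# sequence-based pI calculators).
PKA_POSITIVE = {"nterm": 7.50, "K": 10.00, "R": 12.00, "H": 5.98}
PKA_NEGATIVE = {"cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00}


class SequenceError(ValueError):
    """Sequence contains a non-canonical residue."""


def _validate(sequence: str) -> str:
    if not sequence:
        raise SequenceError("empty sequence")
    seq = sequence.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in RESIDUE_MASS:
            raise SequenceError(
                f"non-canonical residue {aa!r} at position {pos}")
    return seq


def protein_masses(sequence: str) -> tuple[float, float]:
    """(monoisotopic, average) neutral mass of an unmodified protein chain."""
    seq = _validate(sequence)
    mono = sum(RESIDUE_MASS[aa][0] for aa in seq) + WATER_MONO
    avg = sum(RESIDUE_MASS[aa][1] for aa in seq) + WATER_AVG
    return mono, avg


def met_loss_masses(mono_mass: float, avg_mass: float,
                    sequence: str) -> tuple[float, float] | None:
    """Masses after N-terminal Met excision, or None if the sequence does
    not start with methionine."""
    seq = _validate(sequence)
    if not seq.startswith("M"):
        return None
    return mono_mass - MET_MONO, avg_mass - MET_AVG


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of the sequence at a given pH."""
    seq = _validate(sequence)
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(sequence: str, precision: float = 0.01) -> float:
    """pH at which the modeled net charge crosses zero (bisection on
    [0, 14] to the requested precision)."""
    lo, hi = 0.0, 14.0
    while hi - lo > precision:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


# ---------------------------------------------------------------------------
# Protein records and peak assignment
# ---------------------------------------------------------------------------

VARIANTS = ("mono", "avg", "mono_noMet", "avg_noMet")


@dataclass
class ProteinRecord:
    """Sequence-derived mass variants of one candidate protein."""

    accession: str
    name: str = ""
    sequence: str = ""
    mono_mass: float = 0.0
    avg_mass: float = 0.0
    mono_mass_noMet: float | None = None
    avg_mass_noMet: float | None = None
    pi: float | None = None

    @classmethod
    def from_sequence(cls, accession: str, sequence: str,
                      name: str = "") -> "ProteinRecord":
        mono, avg = protein_masses(sequence)
        nomet = met_loss_masses(mono, avg, sequence)
        return cls(accession=accession, name=name, sequence=sequence,
                   mono_mass=mono, avg_mass=avg,
                   mono_mass_noMet=None if nomet is None else nomet[0],
                   avg_mass_noMet=None if nomet is None else nomet[1],
                   pi=isoelectric_point(sequence))

    def variant_mass(self, variant: str) -> float | None:
        return {"mono": self.mono_mass, "avg": self.avg_mass,
                "mono_noMet": self.mono_mass_noMet,
                "avg_noMet": self.avg_mass_noMet}[variant]


@dataclass
class Assignment:
    accession: str
    matched_peak_mz: float
    variant_used: str
    delta_da: float   # variant mass − peak m/z convention: peak − mass
    delta_ppm: float


def match_masses_to_peaks(proteins: list[ProteinRecord],
                          peaks,
                          tol: float = 6.0,
                          tol_mode: str = "da",
                          variants: tuple[str, ...] = ("avg", "avg_noMet"),
                          proton_adjust: bool = False,
                          ) -> tuple[list[Assignment], list[str]]:
    """Assign each candidate protein to its best-matching observed peak.

    For every protein the (variant, peak) pair minimising |Δ| over the enabled
    mass variants and all peaks is selected, and emitted when |Δ| is within
    the tolerance (absolute Da or ppm).  With ``proton_adjust`` the expected
    m/z is mass + 1.00728 ([M+H]+); by default neutral masses are compared
    directly, matching how sequence-derived masses are usually tabulated
    against intact-cell peaks.  Returns (assignments sorted by peak m/z,
    accessions of unmatched proteins).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if tol_mode not in ("da", "ppm"):
        raise ValueError("tol_mode must be 'da' or 'ppm'")
    bad = [v for v in variants if v not in VARIANTS]
    if bad:
        raise ValueError(f"unknown variants: {bad}")
    peaks = np.sort(np.asarray(peaks, dtype=float))

    assignments: list[Assignment] = []
    unmatched: list[str] = []
    for prot in proteins:
        best: Assignment | None = None
        for variant in variants:
            mass = prot.variant_mass(variant)
            if mass is None:
                continue
            expected = mass + PROTON if proton_adjust else mass
            for peak in peaks:
                delta = peak - expected
                if best is None or abs(delta) < abs(best.delta_da):
                    best = Assignment(
                        accession=prot.accession, matched_peak_mz=float(peak),
                        variant_used=variant, delta_da=float(delta),
                        delta_ppm=float(1e6 * delta / expected))
        if best is None:
            unmatched.append(prot.accession)
            continue
        within = (abs(best.delta_da) <= tol if tol_mode == "da"
                  else abs(best.delta_ppm) <= tol)
        if within:
            assignments.append(best)
        else:
            unmatched.append(prot.accession)
    assignments.sort(key=lambda a: (a.matched_peak_mz, a.accession))
    return assignments, unmatched


# ---------------------------------------------------------------------------
# FASTA input and reference data
# ---------------------------------------------------------------------------

def read_fasta_records(path) -> list[ProteinRecord]:
    """Read candidate proteins from FASTA and derive all mass variants."""
    from Bio import SeqIO
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord.from_sequence(
            accession=rec.id, sequence=str(rec.seq), name=name))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def records_from_mass_table(df: pd.DataFrame) -> list[ProteinRecord]:
    """Build ProteinRecords from a table of precomputed masses (columns:
    accession, optional name, mono_mass, avg_mass, optional *_noMet, pi)."""
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(ProteinRecord(
            accession=str(d["accession"]),
            name=str(d.get("name", "")),
            mono_mass=float(d["mono_mass"]),
            avg_mass=float(d["avg_mass"]),
            mono_mass_noMet=(float(d["mono_mass_nomet"])
                             if pd.notna(d.get("mono_mass_nomet")) else None),
            avg_mass_noMet=(float(d["avg_mass_nomet"])
                            if pd.notna(d.get("avg_mass_nomet")) else None),
            pi=float(d["pi"]) if pd.notna(d.get("pi")) else None))
    return out


def load_ccala043_reference() -> pd.DataFrame:
    """Published reference table for Chroococcidiopsis cubana CCALA 043:
    proteins identified by LC-MS/MS with sequence-derived masses (with and
    without the initiator Met), isoelectric points, and the intact-cell
    spectrum peak each was assigned to.  All masses in Da."""
    ref = importlib.resources.files("icmaldi.data") / "ccala043_reference.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")
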