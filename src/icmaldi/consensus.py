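"""Consensus ("virtual") reference spectra from replicate peak lists.

A virtual spectrum keeps the peaks that recur in a minimum fraction of the
replicate acquisitions (default 70%) within a fixed m/z tolerance (default
±2 Da), mirroring the reproducibility-based filtering used when building
reference libraries for intact-cell MALDI typing.  Clustering of the pooled
replicate peaks is single-linkage on the sorted m/z axis with a gap threshold
equal to the tolerance, followed by a span-repair step so that every member
lies within ±tolerance of the cluster's median m/z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import EmptyInputError, FormatError, PeakList


class IdentityError(ValueError):
    """Inputs that must share (or must not share) an identifier do not."""


@dataclass
class ConsensusParams:
    """tol_da: m/z matching tolerance (±Da); min_fraction: minimum fraction
    of replicates that must contain a peak; min_replicates: minimum distinct
    replicates regardless of fraction."""

    tol_da: float = 2.0
    min_fraction: float = 0.70
    min_replicates: int = 1

    def __post_init__(self) -> None:
        if self.tol_da <= 0:
            raise ValueError("tol_da must be positive")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be ≥ 1")


@dataclass
class ConsensusPeak:
    mz: float            # median of member m/z
    support: int         # distinct replicates contributing
    mean_intensity: float


@dataclass
class VirtualSpectrum:
    sample_id: str
    n_replicates: int
    peaks: list[ConsensusPeak]
    params: ConsensusParams = field(default_factory=ConsensusParams)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def _split_clusters(mz: np.ndarray, tol_da: float) -> list[slice]:
    """Single-linkage partition of sorted m/z: break where the gap > tol."""
    if mz.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(mz) > tol_da) + 1
    bounds = [0, *breaks.tolist(), mz.size]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _repair_span(mz: np.ndarray, members: list[int],
                 tol_da: float) -> list[list[int]]:
    """Recursively split a cluster whose span exceeds 2·tol at its largest
    internal gap, so the ±tol membership invariant holds for the median."""
    if mz[members[-1]] - mz[members[0]] <= 2 * tol_da or len(members) < 2:
        return [members]
    gaps = np.diff(mz[members])
    cut = int(np.argmax(gaps)) + 1
    return (_repair_span(mz, members[:cut], tol_da)
            + _repair_span(mz, members[cut:], tol_da))


def build_virtual_spectrum(peaklists: list[PeakList],
                           p: ConsensusParams | None = None) -> VirtualSpectrum:
    """Build the consensus spectrum of one sample from replicate peak lists.

    Pools all replicate peaks, clusters them by single-linkage with gap
    threshold ``tol_da``, keeps at most one peak per replicate per cluster
    (the most intense), and retains clusters supported by at least
    ``ceil(min_fraction × n_replicates)`` distinct replicates.  The result is
    independent of the order of the input peak lists.
    """
    if p is None:
        p = ConsensusParams()
    if not peaklists:
        raise EmptyInputError("no replicate peak lists given")
    sample_ids = {pl.sample_id for pl in peaklists}
    if len(sample_ids) > 1:
        raise IdentityError(f"mixed sample ids: {sorted(sample_ids)}")
    sample_id = peaklists[0].sample_id

    # canonical replicate order so that list order cannot matter
    reps = sorted({pl.replicate_id for pl in peaklists})
    rep_index = {r: i for i, r in enumerate(reps)}
    n_replicates = len(reps)
    min_support = max(int(np.ceil(p.min_fraction * n_replicates)),
                      p.min_replicates)

    mz = np.concatenate([pl.mz for pl in peaklists]) if peaklists else np.array([])
    inten = np.concatenate([pl.intensity for pl in peaklists])
    rep = np.concatenate([
        np.full(len(pl), rep_index[pl.replicate_id], dtype=int)
        for pl in peaklists])
    order = np.lexsort((rep, inten, mz))  # total order -> determinism
    mz, inten, rep = mz[order], inten[order], rep[order]

    kept: list[ConsensusPeak] = []
    for sl in _split_clusters(mz, p.tol_da):
        for members in _repair_span(mz, list(range(sl.start, sl.stop)), p.tol_da):
            # one peak per replicate: keep its most intense member
            best: dict[int, int] = {}
            for i in members:
                r = rep[i]
                if r not in best or (inten[i], mz[i]) > (inten[best[r]], mz[best[r]]):
                    best[r] = i
            chosen = sorted(best.values())
            if len(chosen) < min_support:
                continue
            kept.append(ConsensusPeak(
                mz=float(np.median(mz[chosen])),
                support=len(chosen),
                mean_intensity=float(np.mean(inten[chosen]))))

    kept.sort(key=lambda cp: cp.mz)
    return VirtualSpectrum(sample_id=sample_id, n_replicates=n_replicates,
                           peaks=kept, params=p)


# ---------------------------------------------------------------------------
# Consensus-library JSON
# ---------------------------------------------------------------------------

def write_library(specs: list[VirtualSpectrum], path) -> None:
    doc = {
        "format": "icmaldi-consensus-library",
        "version": 1,
        "spectra": [
            {
                "sample_id": vs.sample_id,
                "n_replicates": vs.n_replicates,
                "params": {
                    "tol_da": vs.params.tol_da,
                    "min_fraction": vs.params.min_fraction,
                    "min_replicates": vs.params.min_replicates,
                },
                "peaks": [
                    {"mz": cp.mz, "support": cp.support,
                     "mean_intensity": cp.mean_intensity}
                    for cp in vs.peaks
                ],
            }
            for vs in specs
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_library(path) -> list[VirtualSpectrum]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "icmaldi-consensus-library":
        raise FormatError(f"{path}: not a consensus-library document")
    out = []
    try:
        for entry in doc["spectra"]:
            params = ConsensusParams(**entry["params"])
            peaks = [ConsensusPeak(mz=float(pk["mz"]), support=int(pk["support"]),
                                   mean_intensity=float(pk["mean_intensity"]))
                     for pk in entry["peaks"]]
            out.append(VirtualSpectrum(sample_id=entry["sample_id"],
                                       n_replicates=int(entry["n_replicates"]),
                                       peaks=peaks, params=params))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: schema violation ({exc})") from exc
    return out
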