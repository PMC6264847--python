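"""Synthetic strain fingerprints and replicate spectra.

Emulates the statistical structure the pipeline assumes about intact-cell
MALDI data: each strain has a ground-truth line spectrum ("fingerprint") over
m/z 1000–20,000; strains within a clade share part of their peaks; replicate
acquisitions jitter peak positions by well under the ±2 Da matching tolerance,
drop true peaks at random, add spurious peaks, and scatter intensities
log-normally.  Defaults follow the acquisition regime of replicate spot
measurements (10 replicates per sample, ±2 Da m/z reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import PeakList, Spectrum

MZ_LO, MZ_HI = 1000.0, 20000.0


class FeasibilityError(ValueError):
    """The requested peak count cannot satisfy the minimum-gap constraint."""


@dataclass
class StrainFingerprint:
    """Ground-truth line spectrum of one strain."""

    sample_id: str
    clade_id: str
    true_peaks: np.ndarray       # m/z, sorted, pairwise gaps > 2×tolerance
    true_intensities: np.ndarray

    def __post_init__(self) -> None:
        self.true_peaks = np.asarray(self.true_peaks, dtype=float)
        self.true_intensities = np.asarray(self.true_intensities, dtype=float)
        if np.any(np.diff(self.true_peaks) <= 0):
            raise ValueError("true peaks must be strictly increasing")


@dataclass
class SimConfig:
    """Simulation conditions.

    mz_jitter_sd of 0.6 Da keeps ~99.9% of replicate m/z draws within the
    ±2 Da matching tolerance; min_gap_da > 2×tolerance makes ground truth
    unambiguous when consensus peaks are matched back to it.
    """

    n_clades: int = 3
    strains_per_clade: int = 4
    shared_frac: float = 0.7
    n_peaks_per_strain: int = 30
    n_replicates: int = 10
    mz_jitter_sd: float = 0.6
    dropout_p: float = 0.1
    spurious_rate: float = 2.0
    intensity_cv: float = 0.3
    min_gap_da: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_p <= 1 and 0 <= self.shared_frac <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.mz_jitter_sd < 0 or self.spurious_rate < 0 or self.intensity_cv < 0:
            raise ValueError("sd, rate and cv must be non-negative")
        if min(self.n_clades, self.strains_per_clade, self.n_peaks_per_strain,
               self.n_replicates) < 1:
            raise ValueError("counts must be ≥ 1")


def _draw_gapped(rng: np.random.Generator, n: int, existing: np.ndarray,
                 min_gap: float, max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n peaks on [MZ_LO, MZ_HI] keeping every pairwise gap
    (including against ``existing``) above min_gap."""
    taken = list(existing)
    drawn = []
    tries = 0
    while len(drawn) < n:
        tries += 1
        if tries > max_tries:
            raise FeasibilityError(
                f"cannot place {n} peaks with gap > {min_gap} Da")
        cand = rng.uniform(MZ_LO, MZ_HI)
        if all(abs(cand - t) > min_gap for t in taken):
            taken.append(cand)
            drawn.append(cand)
    return np.sort(np.array(drawn))


def generate_fingerprints(cfg: SimConfig) -> list[StrainFingerprint]:
    """Draw clade-level shared peak pools and per-strain private peaks.

    Each strain takes ``shared_frac`` of its peaks from its clade's pool and
    the remainder privately; all draws respect the minimum-gap constraint.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_shared = int(round(cfg.shared_frac * cfg.n_peaks_per_strain))
    n_private = cfg.n_peaks_per_strain - n_shared

    fingerprints = []
    all_peaks = np.array([])
    for c in range(cfg.n_clades):
        clade_id = f"clade{c + 1}"
        pool = _draw_gapped(rng, n_shared, all_peaks, cfg.min_gap_da)
        all_peaks = np.concatenate([all_peaks, pool])
        for s in range(cfg.strains_per_clade):
            private = _draw_gapped(rng, n_private, all_peaks, cfg.min_gap_da)
            all_peaks = np.concatenate([all_peaks, private])
            peaks = np.sort(np.concatenate([pool, private]))
            intens = rng.uniform(10.0, 100.0, size=peaks.size)
            fingerprints.append(StrainFingerprint(
                sample_id=f"{clade_id}_strain{s + 1}", clade_id=clade_id,
                true_peaks=peaks, true_intensities=intens))
    return fingerprints


def simulate_replicates(fp: StrainFingerprint, cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> list[PeakList]:
    """Replicate peak lists of one strain: per-peak dropout, Gaussian m/z
    jitter, log-normal intensity scatter, Poisson-count spurious peaks."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma_ln = np.sqrt(np.log(1.0 + cfg.intensity_cv ** 2))
    out = []
    for r in range(cfg.n_replicates):
        keep = rng.random(fp.true_peaks.size) >= cfg.dropout_p
        mz = fp.true_peaks[keep] + rng.normal(
            0.0, cfg.mz_jitter_sd, size=int(keep.sum()))
        inten = fp.true_intensities[keep] * rng.lognormal(
            -0.5 * sigma_ln ** 2, sigma_ln, size=int(keep.sum()))
        n_spur = rng.poisson(cfg.spurious_rate)
        spur_mz = rng.uniform(MZ_LO, MZ_HI, size=n_spur)
        spur_int = rng.uniform(5.0, 30.0, size=n_spur)
        all_mz = np.concatenate([mz, spur_mz])
        all_int = np.concatenate([inten, spur_int])
        order = np.argsort(all_mz)
        all_mz, all_int = all_mz[order], all_int[order]
        # numerically coincident draws are vanishingly rare; nudge if present
        dup = np.flatnonzero(np.diff(all_mz) <= 0)
        all_mz[dup + 1] = np.nextafter(all_mz[dup], np.inf) + 1e-9
        snr = all_int / max(all_int.min(), 1e-9) * 3.0
        out.append(PeakList(sample_id=fp.sample_id, replicate_id=f"rep{r + 1}",
                            mz=all_mz, intensity=all_int, snr=snr))
    return out


def simulate_study(cfg: SimConfig):
    """All fingerprints plus replicate peak lists for the whole panel, with a
    single seed threaded through every draw."""
    rng = np.random.default_rng(cfg.seed)
    fingerprints = generate_fingerprints(cfg)
    replicates = {fp.sample_id: simulate_replicates(fp, cfg, rng)
                  for fp in fingerprints}
    return fingerprints, replicates


def render_profile(pl: PeakList, resolution_fwhm_da: float = 8.0,
                   baseline_level: float = 5.0, noise_sd: float = 1.0,
                   grid_step: float = 1.0,
                   rng: np.random.Generator | None = None) -> Spectrum:
    """Render a peak list as a continuous profile spectrum: sum of Gaussian
    peak shapes on a uniform grid plus constant baseline plus i.i.d. noise."""
    if min(resolution_fwhm_da, grid_step) <= 0 or noise_sd < 0 or baseline_level < 0:
        raise ValueError("shape parameters must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    grid = np.arange(MZ_LO, MZ_HI + grid_step, grid_step)
    sigma = resolution_fwhm_da / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    trace = np.full(grid.size, float(baseline_level))
    for mz, inten in zip(pl.mz, pl.intensity):
        lo = np.searchsorted(grid, mz - 6 * sigma)
        hi = np.searchsorted(grid, mz + 6 * sigma)
        seg = grid[lo:hi]
        trace[lo:hi] += inten * np.exp(-0.5 * ((seg - mz) / sigma) ** 2)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=grid.size)
    trace = np.clip(trace, 0.0, None)
    return Spectrum(sample_id=pl.sample_id, replicate_id=pl.replicate_id,
                    mz=grid, intensity=trace, mode="profile",
                    meta={"synthetic": "true"})
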