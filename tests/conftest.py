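import numpy as np
import pytest

from icmaldi import PeakList, SimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study():
    """A small simulated panel: 2 clades × 2 strains, 6 replicates each."""
    cfg = SimConfig(n_clades=2, strains_per_clade=2, n_peaks_per_strain=15,
                    n_replicates=6, seed=11)
    return simulate_study(cfg)


def make_peaklist(mz, intensity=None, sample_id="s", replicate_id="r1"):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.full(mz.size, 50.0)
    return PeakList(sample_id=sample_id, replicate_id=replicate_id,
                    mz=mz, intensity=np.asarray(intensity, dtype=float),
                    snr=np.full(mz.size, 10.0))
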