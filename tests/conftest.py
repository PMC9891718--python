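import numpy as np
import pytest

from flagcal.synth import SynthConfig, make_ca_kymograph, make_dual_kymograph, make_ift_kymograph


@pytest.fixture(scope="session")
def ca_dataset():
    """One seeded GCaMP kymograph with mild bleaching, plus its truth."""
    cfg = SynthConfig(bleach_rate=0.005)
    kymo, truth = make_ca_kymograph(cfg, seed=11)
    return cfg, kymo, truth


@pytest.fixture(scope="session")
def ift_dataset():
    """One seeded IFT kymograph at the default train rates, plus truth."""
    cfg = SynthConfig()
    kymo, truth = make_ift_kymograph(cfg, seed=11)
    return cfg, kymo, truth


@pytest.fixture(scope="session")
def dual_dataset():
    """Dual-channel movie with spike-released retrograde pauses."""
    cfg = SynthConfig(
        duration=120.0,
        spike_rate=0.03,
        pause_prob=0.7,
        reactivate_on_spike=True,
    )
    gcamp, mscarlet, truth = make_dual_kymograph(cfg, seed=7)
    return cfg, gcamp, mscarlet, truth


def match_spikes(detected, truth_spikes, tol_s=0.25):
    """(n_truth_matched, n_detected_matched) by peak-in-span containment."""
    tp_truth = sum(
        1
        for te in truth_spikes
        if any(de.onset_s - tol_s <= te.peak_time_s <= de.end_s + tol_s for de in detected)
    )
    tp_det = sum(
        1
        for de in detected
        if any(de.onset_s - tol_s <= te.peak_time_s <= de.end_s + tol_s for te in truth_spikes)
    )
    return tp_truth, tp_det
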