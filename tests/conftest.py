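import numpy as np
import pytest

import rotacue as rc
from rotacue.preprocessing import (apply_eog_removal, bandpass, common_average,
                                   extract_lowfreq_features, fit_eog_removal)


@pytest.fixture(scope="session")
def printed_schedule():
    """100-trial schedule with the published velocity-law parameters."""
    return rc.generate_cue_schedule(rc.ParadigmConfig())


@pytest.fixture(scope="session")
def small_schedule():
    return rc.generate_cue_schedule(rc.ParadigmConfig(n_trials=25))


@pytest.fixture(scope="session")
def high_snr_subject():
    """Subject whose MRCP dwarfs the background noise (0.5 uV RMS)."""
    return rc.SubjectModel.default(seed=3, noise_scale=0.5)


@pytest.fixture(scope="session")
def cued_run_small(small_schedule, high_snr_subject):
    return rc.simulate_cued_run(small_schedule, high_snr_subject, seed=11)


@pytest.fixture(scope="session")
def calibration_run(high_snr_subject):
    return rc.simulate_eye_calibration(240.0, high_snr_subject, seed=12)


@pytest.fixture(scope="session")
def eog_model(calibration_run):
    return fit_eog_removal(bandpass(calibration_run))


@pytest.fixture(scope="session")
def decode_setup(small_schedule, high_snr_subject, eog_model):
    """Three preprocessed cue-based runs plus a self-paced run."""

    def prep(rec):
        return common_average(extract_lowfreq_features(
            apply_eog_removal(eog_model, bandpass(rec))))

    runs = []
    for seed in (21, 22, 23):
        rec = rc.simulate_cued_run(small_schedule, high_snr_subject, seed=seed)
        feats = prep(rec)
        onsets = rc.detect_onsets(rc.compute_speed(rec.motion_xy))
        runs.append((feats, onsets))
    onsets_sp = rc.simulate_self_paced_timeline(150.0, high_snr_subject,
                                                seed=31)
    sp = rc.simulate_self_paced_run(onsets_sp, high_snr_subject, seed=31,
                                    duration=150.0)
    feats_sp = prep(sp)
    detected_sp = rc.detect_onsets(rc.compute_speed(sp.motion_xy))
    return {"train": runs, "self_paced": sp, "features_sp": feats_sp,
            "onsets_sp": detected_sp}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
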