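"""Shared fixtures: small synthetic timelines and recordings.

Everything is generated programmatically with fixed seeds; the reduced
protocol (2 blocks/session, short baselines) keeps per-test runtimes low
while preserving the full signal structure.
"""

import numpy as np
import pytest

import nirsdecode as nd


@pytest.fixture(scope="session")
def small_protocol() -> nd.ProtocolConfig:
    return nd.ProtocolConfig(blocks_per_session=2, baseline_start_s=60.0,
                             baseline_end_s=30.0)


@pytest.fixture(scope="session")
def small_timeline(small_protocol) -> nd.EventTimeline:
    return nd.generate_timeline(small_protocol, seed=2)


@pytest.fixture(scope="session")
def small_recording(small_timeline) -> nd.RawRecording:
    """12 motor trials, default effect sizes, with biosignals."""
    return nd.simulate_recording(small_timeline, nd.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def noiseless_recording(small_timeline) -> nd.RawRecording:
    """Strong effect, no noise/drift/contaminants: exact forward model."""
    cfg = nd.SimulationConfig(seed=4, od_noise_sd=0.0, od_drift_sd=0.0,
                              cardiac_amp_mM=0.0, resp_amp_mM=0.0,
                              mayer_amp_mM=0.0, bio_noise_sd=0.0)
    return nd.simulate_recording(small_timeline, cfg)


@pytest.fixture(scope="session")
def small_processed(small_recording) -> nd.ProcessedFNIRS:
    return nd.preprocess_fnirs(small_recording)


@pytest.fixture(scope="session")
def small_ans(small_recording) -> nd.ANSFeatures:
    return nd.assemble_biosignals(small_recording)


@pytest.fixture(scope="session")
def small_pairs(small_timeline, small_processed):
    return nd.extract_trial_pairs(small_timeline, small_processed)


@pytest.fixture(scope="session")
def small_observations(small_pairs, small_processed, small_ans):
    weights = nd.fit_feature_weights(small_pairs, small_processed, 0)
    signals = nd.apply_weights(small_processed, weights)
    return {
        "fnirs_only": nd.build_observations(small_pairs, signals, None,
                                            "fnirs_only"),
        "combined": nd.build_observations(small_pairs, signals, small_ans,
                                          "combined"),
    }


def sample_lr_hmm_sequences(n_seq: int, length: int, seed: int,
                            means=((-1.0, 0.0), (2.0, 1.0)),
                            self_prob: float = 0.9,
                            noise_sd: float = 0.5):
    """Draw sequences from a known 2-state left-to-right Gaussian HMM."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means)
    seqs = []
    for _ in range(n_seq):
        state = 0
        rows = []
        for _ in range(length):
            rows.append(rng.normal(means[state], noise_sd))
            if state == 0 and rng.uniform() > self_prob:
                state = 1
        seqs.append(np.asarray(rows))
    return np.stack(seqs)
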