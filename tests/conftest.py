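"""Shared fixtures: canonical synthetic objects and session-scoped pipeline runs."""

import numpy as np
import pytest

from osteotap import cli, extraction, synthcohort

RATE = 4000


@pytest.fixture(scope="session")
def default_chain():
    return synthcohort.ChainModel()


@pytest.fixture(scope="session")
def chain_ir(default_chain):
    return synthcohort.synth_chain_ir(default_chain, RATE)


@pytest.fixture(scope="session")
def chain_response(chain_ir):
    return extraction.estimate_chain_response(chain_ir, RATE, nfft=16384)


@pytest.fixture(scope="session")
def inverse_filter(chain_response):
    return extraction.design_inverse_filter(chain_response)


@pytest.fixture(scope="session")
def canonical_bone_ir():
    """A representative healthy-class impulse response (800 samples)."""
    modes = [synthcohort.ModeSpec(95.0, 22.0, 0.5),
             synthcohort.ModeSpec(230.0, 90.0, 0.2)]
    return synthcohort.synth_bone_ir(modes, RATE, 800)


@pytest.fixture(scope="session")
def single_tap_recording():
    """One default-chain tap at a known onset in 20 dB-SNR noise, with truth."""
    cfg = synthcohort.CohortConfig()
    rng = np.random.default_rng(7)
    patient = synthcohort.draw_patient(rng, "P001", "OK", cfg)
    patient.tap_count = 1
    rec, truth = synthcohort.synth_recording(
        patient, synthcohort.ChainModel(),
        synthcohort.NoiseConfig(snr_db=20.0, n_rumble=0, n_clicks=0),
        seed=11, rate=RATE, lead_in=1.0)
    return rec, truth


@pytest.fixture(scope="session")
def pilot_run():
    """Default-separation 12-patient pilot pipeline (seed 1)."""
    return cli.run_pipeline(cli.load_config(), seed=1)


@pytest.fixture(scope="session")
def separated_pilot_run():
    """Well-separated 12-patient pilot pipeline (seed 1)."""
    cfg = cli.load_config(overrides={"cohort": {"preset": "well_separated"}})
    return cli.run_pipeline(cfg, seed=1)


@pytest.fixture(scope="session")
def extended_run():
    """110-patient cohort, 330/330 split, block-trained 378-120-40-1 (seed 1)."""
    cfg = cli.load_config(overrides={"mode": "extended"})
    return cli.run_pipeline(cfg, seed=1)


def match_onsets(detected_s, truth_s, tol=0.010):
    """Greedy one-to-one matching of detected to true onsets within ±tol s."""
    detected_s = np.asarray(detected_s, float)
    used, matched = set(), 0
    for t in truth_s:
        if detected_s.size == 0:
            continue
        d = np.abs(detected_s - t)
        i = int(np.argmin(d))
        if d[i] <= tol and i not in used:
            matched += 1
            used.add(i)
    return matched


@pytest.fixture(scope="session")
def extraction_suite_stats():
    """Recall / false-detection rate over 20 artifact-laden recordings."""
    cfg = synthcohort.CohortConfig()
    chain = synthcohort.ChainModel()
    matched = total = detections = matched_det = 0
    for s in range(1, 21):
        rng = np.random.default_rng(1000 + s)
        patient = synthcohort.draw_patient(rng, f"P{s:03d}", "OK", cfg)
        patient.tap_count = 10
        rec, truth = synthcohort.synth_recording(
            patient, chain, cfg.noise, seed=2000 + s, rate=RATE)
        segs = extraction.extract_segments(rec)
        det = np.array([g.onset_index for g in segs]) / rec.rate
        m = match_onsets(det, truth.onset_times)
        matched += m
        matched_det += m
        total += len(truth.onset_times)
        detections += len(det)
    return {"recall": matched / total,
            "false_detection_rate": (detections - matched_det) / max(detections, 1),
            "n_taps": total}
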