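"""Reading and writing the pipeline's on-disk artifacts.

Recordings are mono 16-bit PCM WAV; patient tables, feature matrices and
metrics tables are plain CSV with an optional ``#``-prefixed metadata
header line; network checkpoints and ground truth go to JSON.  All
writers are deterministic byte-for-byte for identical inputs.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

PCM_FULL_SCALE = 32767  # positive full scale of signed 16-bit PCM

REQUIRED_COHORT_COLUMNS = ("patient_id", "label", "t_score")
VALID_LABELS = ("OP", "OK")
#: WHO operational cut-off: a DEXA t-score at or below this is osteoporotic.
T_SCORE_CUTOFF = -2.5


@dataclass
class Recording:
    """A mono pressure recording with full scale ±1 and a patient identity."""

    samples: np.ndarray
    rate: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording requires a 1-D mono sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording samples must be finite")
        if self.rate <= 0:
            raise ValueError("Recording rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def write_recording(recording: Recording, path) -> None:
    """Write a recording as RIFF PCM 16-bit little-endian mono WAV.

    Values outside ±1 full scale are a contract violation (they would
    clip on quantization) and raise instead of being silently clamped.
    """
    x = recording.samples
    if x.size and np.max(np.abs(x)) > 1.0:
        raise ValueError("samples exceed ±1 full scale; rescale before writing")
    q = np.round(x * PCM_FULL_SCALE).astype("<i2")
    wavfile.write(str(path), int(recording.rate), q)


def read_recording(path, patient_id: str = "") -> Recording:
    """Read a mono 16-bit PCM WAV into a float recording scaled to ±1."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: multi-channel WAV not supported (mono only)")
    if data.dtype != np.int16:
        raise ValueError(f"{path}: unsupported encoding {data.dtype}, expected 16-bit PCM")
    return Recording(samples=data.astype(float) / PCM_FULL_SCALE,
                     rate=int(rate), patient_id=patient_id)


def write_cohort_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    _validate_cohort(table)
    write_table(table, path, meta=meta)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a patient table CSV (patient_id, label, t_score)."""
    table = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    _validate_cohort(table)
    return table


def _validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    dup = table["patient_id"][table["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id values: {sorted(set(dup))}")
    bad = set(table["label"]) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"labels outside {VALID_LABELS}: {sorted(bad)}")
    # Labels are clinical diagnoses: t-score informs but does not dictate
    # them (lifestyle, family history...), so disagreement with the -2.5
    # rule is only worth a warning.
    t = table["t_score"].to_numpy(float)
    odd = ((t <= T_SCORE_CUTOFF) & (table["label"] == "OK").to_numpy()) | (
        (t > T_SCORE_CUTOFF) & (table["label"] == "OP").to_numpy()
    )
    for _, row in table[odd].iterrows():
        log.warning(
            "patient %s: label %s disagrees with t-score %.2f (clinical override assumed)",
            row["patient_id"], row["label"], row["t_score"],
        )


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV, optionally preceded by one '# key=value ...' metadata line."""
    buf = io.StringIO()
    if meta:
        buf.write("# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items())) + "\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_segments(segments, path, meta: dict | None = None) -> None:
    """Write IR segments as CSV: patient_id, onset_sample, s0..s799."""
    n = len(segments[0].samples) if segments else 800
    cols = {"patient_id": [s.patient_id for s in segments],
            "onset_sample": [s.onset_index for s in segments]}
    mat = np.array([s.samples for s in segments]) if segments else np.empty((0, n))
    for j in range(n):
        cols[f"s{j}"] = mat[:, j] if len(segments) else []
    write_table(pd.DataFrame(cols), path, meta=meta)


def read_segments(path):
    from .extraction import IRSegment  # local import to avoid a cycle

    df = read_table(path)
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    out = []
    for _, row in df.iterrows():
        out.append(IRSegment(samples=row[sample_cols].to_numpy(float),
                             onset_index=int(row["onset_sample"]),
                             patient_id=str(row["patient_id"])))
    return out


def save_model(net, path, extra: dict | None = None) -> None:
    """Save a network checkpoint as portable JSON (sizes + flattened arrays)."""
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "seed": net.seed,
        "extra": extra or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path):
    from .neuralnet import NetworkModel

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return NetworkModel(
        layer_sizes=list(payload["layer_sizes"]),
        weights=[np.array(w, dtype=float) for w in payload["weights"]],
        biases=[np.array(b, dtype=float) for b in payload["biases"]],
        seed=payload.get("seed"),
    ), payload.get("extra", {})


def write_ground_truth(truth, path, meta: dict | None = None) -> None:
    payload = {
        "onset_times": [float(t) for t in truth.onset_times],
        "tap_modes": [
            [
                {"natural_frequency": m.natural_frequency,
                 "decay_rate": m.decay_rate,
                 "amplitude": m.amplitude}
                for m in modes
            ]
            for modes in truth.tap_modes
        ],
        "rumble_intervals": [[float(a), float(b)] for a, b in truth.rumble_intervals],
        "click_times": [float(t) for t in truth.click_times],
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_ground_truth(path):
    from .synthcohort import GroundTruth, ModeSpec

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        onset_times=list(payload["onset_times"]),
        tap_modes=[[ModeSpec(**m) for m in modes] for modes in payload["tap_modes"]],
        rumble_intervals=[tuple(iv) for iv in payload["rumble_intervals"]],
        click_times=list(payload["click_times"]),
    )
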