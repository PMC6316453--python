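"""Synthetic vibro-acoustic cohorts for tibia percussion screening.

Each hammer tap excites a set of exponentially damped bone modes — a
fundamental in the 75–110 Hz band plus a far more damped 200–250 Hz
cluster — whose stiffness dependence follows the rod model f0 = sqrt(k/m)
(kept exactly in that dimensional form): reduced stiffness lowers the
fundamental.  The tap waveform is coloured by a soft-tissue low-pass and
by the hammer/stethoscope measurement chain (resonant boost around
10–40 Hz, flat to 600 Hz, −24 dB/oct roll-off towards 1.2 kHz), placed at
jittered onsets in additive broadband noise, and contaminated by
low-frequency rumble bursts and millisecond clicks.  Everything is
seeded, and each recording is emitted with exact ground truth so the
extraction and classification stages can be scored.

Osteoporotic (OP) patients draw their fundamental from a band shifted
down by a configurable fraction and decay rates scaled up, emulating the
stiffness loss / extra damping expected of porous bone; the magnitude of
that separation is a simulation knob, not a physiological claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import Recording

DEFAULT_RATE = 4000  # Hz; makes the 0.03 s / 0.01 s hop framing of an
# 800-sample segment come out at exactly 18 windows.


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ModeSpec:
    """One damped vibration mode: x(t) = amplitude · e^{−decay·t} · sin(2π f t)."""

    natural_frequency: float  # Hz
    decay_rate: float = 0.0  # 1/s exponential amplitude decay
    amplitude: float = 1.0
    stiffness: float | None = None  # N/m
    mass: float | None = None  # kg

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.stiffness is not None and self.mass is not None:
            f0 = math.sqrt(self.stiffness / self.mass)
            if not math.isclose(f0, self.natural_frequency, rel_tol=1e-9):
                raise ValueError(
                    "natural_frequency inconsistent with rod model sqrt(stiffness/mass)"
                )


def mode_from_stiffness(stiffness: float, mass: float,
                        decay_rate: float = 0.0, amplitude: float = 1.0) -> ModeSpec:
    """Rod-model mode: f0 = sqrt(k/m), kept in this bare dimensional form.

    Stiffer rods ring higher; halving stiffness at fixed mass scales the
    frequency by 1/sqrt(2).
    """
    if stiffness <= 0 or mass <= 0:
        raise ValueError("stiffness and mass must be positive")
    return ModeSpec(natural_frequency=math.sqrt(stiffness / mass),
                    decay_rate=decay_rate, amplitude=amplitude,
                    stiffness=stiffness, mass=mass)


@dataclass
class ChainModel:
    """Parametric magnitude model of the hammer+stethoscope measurement chain."""

    stethoscope_resonance_band: tuple[float, float] = (10.0, 40.0)
    resonance_gain_db: float = 9.0
    flat_band_edge: float = 600.0  # Hz
    rolloff_slope: float = -24.0  # dB/octave above flat_band_edge
    rolloff_end: float = 1200.0  # Hz
    hammer_contact_duration: float = 0.0015  # s; << 1/flat_band_edge, so flat here
    is_identity: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.stethoscope_resonance_band
        if not (0 <= lo < hi <= self.flat_band_edge):
            raise ValueError("resonance band must lie below flat_band_edge")
        if self.rolloff_end <= self.flat_band_edge:
            raise ValueError("rolloff_end must exceed flat_band_edge")
        if self.hammer_contact_duration <= 0:
            raise ValueError("hammer_contact_duration must be positive")

    @classmethod
    def identity(cls) -> "ChainModel":
        """A transparent chain: synth_chain_ir returns a unit impulse."""
        return cls(is_identity=True)


@dataclass
class SyntheticPatient:
    patient_id: str
    label: str  # "OP" | "OK"
    t_score: float
    bone_modes: list[ModeSpec]
    tissue_decay: float  # 1/s; 0 means transparent (delta) tissue
    tap_count: int


@dataclass
class GroundTruth:
    """Exact truth for one synthetic recording (onsets, modes, artifacts)."""

    onset_times: list[float] = field(default_factory=list)  # s
    tap_modes: list[list[ModeSpec]] = field(default_factory=list)
    rumble_intervals: list[tuple[float, float]] = field(default_factory=list)  # s
    click_times: list[float] = field(default_factory=list)  # s


@dataclass
class NoiseConfig:
    snr_db: float | None = 20.0  # tap-power to white-noise-power ratio; None = clean
    floor_sigma: float = 0.01  # absolute noise sigma for tap-free recordings
    n_rumble: int = 2  # low-frequency bursts per recording
    rumble_duration: float = 0.5  # s
    rumble_cutoff: float = 20.0  # Hz
    rumble_amplitude: float = 0.4  # relative to tap peak
    n_clicks: int = 4  # short spurious transients per recording
    click_duration: tuple[float, float] = (0.001, 0.002)  # s
    click_amplitude: float = 0.8  # relative to tap peak


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort (defaults: the 110-patient set)."""

    n_patients: int = 110
    n_op: int = 34
    tap_count: int = 10
    rate: int = DEFAULT_RATE
    # healthy-class mode distributions
    ok_f0_band: tuple[float, float] = (75.0, 110.0)
    ok_f0_mean: float = 92.5
    ok_f0_sd: float = 7.0
    ok_decay_mean: float = 22.0  # 1/s
    ok_decay_sd: float = 4.0
    fund_amplitude: float = 0.5
    cluster_band: tuple[float, float] = (200.0, 250.0)
    cluster_decay_scale: float = 4.0  # "much more damped" secondary modes
    cluster_amplitude: float = 0.2
    # osteoporotic offsets: lowered fundamental, extra damping
    op_freq_shift: float = 0.15
    op_decay_factor: float = 1.5
    # soft tissue
    tissue_decay_mean: float = 30.0  # 1/s
    tissue_decay_sd: float = 8.0
    # tap placement and variability
    tap_refractory: float = 0.5  # s minimum onset spacing
    onset_jitter: float = 0.2  # fractional spacing jitter
    amp_jitter: float = 0.3  # fractional per-tap amplitude spread
    freq_tap_jitter: float = 0.01  # fractional per-tap frequency spread
    lead_in: float = 0.3  # s before the first onset
    tail: float = 0.3  # s after the last tap window
    # clinical scores
    op_t_range: tuple[float, float] = (-3.5, -2.55)
    ok_t_range: tuple[float, float] = (-2.45, 0.6)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_op > self.n_patients:
            raise ValueError("n_op cannot exceed n_patients")

    @classmethod
    def pilot(cls, op_freq_shift: float | None = None, **overrides) -> "CohortConfig":
        """The 12-patient pilot conditions (3 OP, 9 OK)."""
        kw = dict(n_patients=12, n_op=3, tap_count=10)
        if op_freq_shift is not None:
            kw["op_freq_shift"] = op_freq_shift
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def well_separated(cls, **overrides) -> "CohortConfig":
        """Class distributions with essentially no overlap.

        Separation is about between-class distance relative to
        within-class spread: a 25% fundamental shift with the population
        spreads halved puts the class means ~6.6 standard deviations
        apart while every fundamental stays in the physiological
        75–110 Hz neighbourhood (a larger shift would push osteoporotic
        taps under the extractor's 50 Hz rumble screen).  Used to
        demonstrate ceiling behaviour of the voting stage.
        """
        kw = dict(op_freq_shift=0.25, ok_f0_sd=3.5, ok_decay_sd=2.0)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# component synthesis

def synth_bone_ir(modes: list[ModeSpec], rate: float, length: int) -> np.ndarray:
    """Sum of exponentially damped sinusoids sampled at `rate` for `length` samples."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    t = np.arange(int(length)) / rate
    x = np.zeros(int(length))
    for m in modes:
        x += m.amplitude * np.exp(-m.decay_rate * t) * np.sin(2 * np.pi * m.natural_frequency * t)
    return x


def synth_tissue_ir(tissue_decay: float, rate: float) -> np.ndarray:
    """First-order low-pass impulse response h[n] = (1−a)·aⁿ, a = e^{−decay/rate}.

    Unit DC gain, so it damps and smears without changing overall level.
    ``tissue_decay <= 0`` means transparent tissue (a unit impulse) — the
    degenerate configuration used to verify the convolution chain.
    """
    if tissue_decay <= 0:
        return np.array([1.0])
    a = math.exp(-tissue_decay / rate)
    n = max(1, int(math.ceil(math.log(1e-8) / math.log(a))))
    h = (1 - a) * a ** np.arange(n)
    return h


def chain_magnitude_db(freqs: np.ndarray, chain: ChainModel) -> np.ndarray:
    """Target magnitude (dB re passband) of the measurement chain."""
    f = np.asarray(freqs, dtype=float)
    db = np.zeros_like(f)
    lo, hi = chain.stethoscope_resonance_band
    c, w = 0.5 * (lo + hi), 0.5 * (hi - lo)
    in_band = np.abs(f - c) < w
    db[in_band] = chain.resonance_gain_db * np.cos(0.5 * np.pi * (f[in_band] - c) / w) ** 2
    above = f > chain.flat_band_edge
    db[above] += chain.rolloff_slope * np.log2(f[above] / chain.flat_band_edge)
    return db


def synth_chain_ir(chain: ChainModel, rate: float, taps: int = 2049) -> np.ndarray:
    """Causal minimum-phase FIR realisation of the chain's magnitude model.

    A linear-phase prototype is designed for the *squared* magnitude by
    frequency sampling (Hamming taper) and converted to minimum phase,
    which takes its square root: the result has the target magnitude but
    no bulk delay or pre-ringing, so percussion onsets stay sharp — as
    they do through a real, causal hammer/stethoscope chain.  The
    default 2049 taps at 4 kHz resolve the narrow 10–40 Hz resonance.
    """
    if chain.is_identity:
        return np.array([1.0])
    if rate < 2 * chain.rolloff_end:
        raise ValueError("rate too low to represent rolloff_end (need rate >= 2*rolloff_end)")
    grid = np.linspace(0.0, rate / 2, 4097)
    gains = 10.0 ** (chain_magnitude_db(grid, chain) / 20.0)
    proto = sps.firwin2(2 * taps - 1, grid / (rate / 2), gains ** 2, window="hamming")
    return sps.minimum_phase(proto, method="homomorphic")


# ---------------------------------------------------------------------------
# patients and recordings

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def draw_patient(rng: np.random.Generator, patient_id: str, label: str,
                 cfg: CohortConfig) -> SyntheticPatient:
    """Draw one patient's modal parameters and t-score from its class distribution."""
    shift = cfg.op_freq_shift if label == "OP" else 0.0
    dfac = cfg.op_decay_factor if label == "OP" else 1.0
    lo, hi = cfg.ok_f0_band
    f0 = _trunc_normal(rng, cfg.ok_f0_mean * (1 - shift), cfg.ok_f0_sd,
                       lo * (1 - shift), hi * (1 - shift))
    decay = dfac * _trunc_normal(rng, cfg.ok_decay_mean, cfg.ok_decay_sd,
                                 max(1.0, cfg.ok_decay_mean - 3 * cfg.ok_decay_sd),
                                 cfg.ok_decay_mean + 3 * cfg.ok_decay_sd)
    clo, chi = cfg.cluster_band
    fc = rng.uniform(clo * (1 - shift), chi * (1 - shift))
    modes = [
        ModeSpec(natural_frequency=f0, decay_rate=decay, amplitude=cfg.fund_amplitude),
        ModeSpec(natural_frequency=fc, decay_rate=decay * cfg.cluster_decay_scale,
                 amplitude=cfg.cluster_amplitude),
    ]
    t_lo, t_hi = cfg.op_t_range if label == "OP" else cfg.ok_t_range
    t_score = float(rng.uniform(t_lo, t_hi))
    tissue = _trunc_normal(rng, cfg.tissue_decay_mean, cfg.tissue_decay_sd,
                           5.0, cfg.tissue_decay_mean + 3 * cfg.tissue_decay_sd)
    return SyntheticPatient(patient_id=patient_id, label=label, t_score=t_score,
                            bone_modes=modes, tissue_decay=tissue,
                            tap_count=cfg.tap_count)


def _jitter_modes(rng: np.random.Generator, modes: list[ModeSpec],
                  freq_jitter: float, amp_jitter: float) -> list[ModeSpec]:
    scale = 1.0 + rng.uniform(-amp_jitter, amp_jitter)
    out = []
    for m in modes:
        f = m.natural_frequency * (1.0 + rng.normal(0.0, freq_jitter))
        out.append(ModeSpec(natural_frequency=max(f, 1.0), decay_rate=m.decay_rate,
                            amplitude=m.amplitude * scale))
    return out


def synth_recording(patient: SyntheticPatient, chain: ChainModel,
                    noise_cfg: NoiseConfig | None, seed: int, *,
                    rate: int = DEFAULT_RATE, ir_length: int = 800,
                    tap_refractory: float = 0.5, onset_jitter: float = 0.2,
                    amp_jitter: float = 0.3, freq_tap_jitter: float = 0.01,
                    lead_in: float = 0.3, tail: float = 0.3,
                    ) -> tuple[Recording, GroundTruth]:
    """Simulate one patient's percussion session: y = bone ⊛ tissue ⊛ chain + noise.

    Taps are placed at jittered onsets no closer than the refractory
    interval; white noise is scaled to the configured SNR against the
    mean power over the tap windows; rumble bursts and clicks are added
    at recorded positions.
    """
    if patient.tap_count < 0:
        raise ValueError("tap_count must be >= 0")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()

    onsets_s: list[float] = []
    t_cursor = lead_in + rng.uniform(0, tap_refractory * onset_jitter)
    for _ in range(patient.tap_count):
        onsets_s.append(t_cursor)
        t_cursor += tap_refractory * (1.0 + rng.uniform(0, 2 * onset_jitter))
    duration = (onsets_s[-1] if onsets_s else lead_in) + ir_length / rate + tail
    n = int(round(duration * rate))
    clean = np.zeros(n)

    chain_ir = synth_chain_ir(chain, rate)
    tissue_ir = synth_tissue_ir(patient.tissue_decay, rate)

    for t0 in onsets_s:
        modes = _jitter_modes(rng, patient.bone_modes, freq_tap_jitter, amp_jitter)
        wave = synth_bone_ir(modes, rate, ir_length)
        wave = np.convolve(wave, tissue_ir)
        wave = np.convolve(wave, chain_ir)
        i0 = int(round(t0 * rate))
        seg = wave[: n - i0]
        clean[i0:i0 + len(seg)] += seg
        truth.onset_times.append(t0)
        truth.tap_modes.append(modes)

    x = clean.copy()
    tap_peak = float(np.max(np.abs(clean))) if onsets_s else 1.0

    if noise_cfg is not None:
        if noise_cfg.snr_db is not None:
            if onsets_s:
                active = np.zeros(n, dtype=bool)
                for t0 in onsets_s:
                    i0 = int(round(t0 * rate))
                    active[i0:i0 + ir_length] = True
                p_sig = float(np.mean(clean[active] ** 2))
                sigma = math.sqrt(p_sig * 10 ** (-noise_cfg.snr_db / 10))
            else:
                sigma = noise_cfg.floor_sigma
            x = x + rng.normal(0.0, sigma, n)

        burst_len = int(round(noise_cfg.rumble_duration * rate))
        for _ in range(noise_cfg.n_rumble):
            if n <= burst_len:
                break
            i0 = int(rng.integers(0, n - burst_len))
            b, a = sps.butter(4, noise_cfg.rumble_cutoff / (rate / 2), "low")
            burst = sps.lfilter(b, a, rng.normal(0.0, 1.0, burst_len))
            burst *= np.hanning(burst_len)
            peak = np.max(np.abs(burst))
            if peak > 0:
                burst *= noise_cfg.rumble_amplitude * tap_peak / peak
            x[i0:i0 + burst_len] += burst
            truth.rumble_intervals.append((i0 / rate, (i0 + burst_len) / rate))

        for _ in range(noise_cfg.n_clicks):
            w_lo, w_hi = noise_cfg.click_duration
            width = int(max(2, round(rng.uniform(w_lo, w_hi) * rate)))
            if n <= width:
                break
            i0 = int(rng.integers(0, n - width))
            pulse = np.hanning(width) * noise_cfg.click_amplitude * tap_peak
            x[i0:i0 + width] += pulse * rng.choice([-1.0, 1.0])
            truth.click_times.append(i0 / rate)

    rec = Recording(samples=x, rate=rate, patient_id=patient.patient_id)
    return rec, truth


def synth_cohort(cfg: CohortConfig, seed: int,
                 ) -> tuple[list[Recording], pd.DataFrame, list[GroundTruth]]:
    """Generate a full cohort: one recording + ground truth per patient.

    Deterministic per (cfg, seed); patient sub-seeds are drawn from a
    master generator so recordings are independent but reproducible.
    """
    master = np.random.default_rng(seed)
    chain = ChainModel()
    recordings, truths, rows = [], [], []
    for i in range(cfg.n_patients):
        label = "OP" if i < cfg.n_op else "OK"
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng(int(master.integers(0, 2 ** 31)))
        patient = draw_patient(prng, pid, label, cfg)
        rec, truth = synth_recording(
            patient, chain, cfg.noise, seed=int(master.integers(0, 2 ** 31)),
            rate=cfg.rate, tap_refractory=cfg.tap_refractory,
            onset_jitter=cfg.onset_jitter, amp_jitter=cfg.amp_jitter,
            freq_tap_jitter=cfg.freq_tap_jitter, lead_in=cfg.lead_in, tail=cfg.tail)
        recordings.append(rec)
        truths.append(truth)
        rows.append({"patient_id": pid, "label": label, "t_score": round(patient.t_score, 2)})
    table = pd.DataFrame(rows)
    return recordings, table, truths
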