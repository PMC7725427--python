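"""Dichotic screening stimuli: Huggins Pitch (HP), Anti-Phase (AP) and Beat (BT) tests.

Each screening test is a three-alternative forced choice (3AFC): three
one-second intervals, exactly one of which carries a cue that is audible
over headphones but destroyed (or inverted) when the two channels mix
acoustically, as they do over loudspeakers.

* HP: two diotic white-noise intervals plus one interval in which a narrow
  band (+/- 6%) around 600 Hz is phase-inverted in the right channel.  Over
  headphones this evokes a faint Huggins-pitch tone; either channel alone is
  indistinguishable from plain noise.
* AP: three 200-Hz tones -- a diotic standard, a diotic target at -6 dB, and
  a "foil" whose right channel is the polarity-inverted left channel.  Over
  loudspeakers the foil cancels acoustically and is mistaken for the target.
* BT: three tone pairs (f1 drawn from 1800-2500 Hz, f2 = f1 + 30 Hz).  The
  standards present both tones diotically and beat at 30 Hz; the target puts
  one tone in each ear, which is smooth over headphones (no binaural beat at
  these frequencies) but beats once the channels mix over loudspeakers.

All synthesis is deterministic given (config, seed).  Trials are grouped
into pre-generated pools of 12 with target positions balanced 4/4/4 across
the three slots, mirroring how the screening tests are deployed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "DEFAULT_RATE",
    "RMS_REFERENCE",
    "StereoWaveform",
    "HPConfig",
    "APConfig",
    "BTConfig",
    "TrialSpec",
    "TrialPool",
    "generate_white_noise",
    "make_huggins_pair",
    "make_hp_trial",
    "make_ap_trial",
    "make_bt_trial",
    "make_example_trial",
    "apply_ramp",
    "raised_cosine_envelope",
    "build_trial_pool",
    "trial_seed_sequence",
    "default_config",
    "write_trial_wav",
    "write_pool",
]

#: Sampling rate of the published stimuli (samples per second).
DEFAULT_RATE = 44100

#: All intervals are normalised to this RMS (full-scale units) before any
#: per-test level offset (AP -6 dB target, BT rove).  Absolute playback level
#: is delegated to a listener-side volume calibration and is out of scope.
RMS_REFERENCE = 0.05

#: Silence between the three intervals of a trial (seconds).
DEFAULT_GAP_S = 0.5

_TEST_KINDS = ("HP", "AP", "BT")


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StereoWaveform:
    """A two-channel sampled signal; the unit of all stimulus construction.

    Samples are dimensionless amplitudes, nominally within [-1, 1].
    """

    left: np.ndarray
    right: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=np.float64)
        right = np.asarray(self.right, dtype=np.float64)
        if left.ndim != 1 or right.ndim != 1 or left.shape != right.shape:
            raise ValueError("left and right channels must be 1-D and equal length")
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise ValueError("waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def n_samples(self) -> int:
        return self.left.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def is_diotic(self) -> bool:
        """True when both ears receive the identical signal, sample for sample."""
        return bool(np.array_equal(self.left, self.right))

    def scaled(self, gain: float) -> "StereoWaveform":
        return StereoWaveform(self.left * gain, self.right * gain, self.rate)

    @classmethod
    def diotic(cls, mono: np.ndarray, rate: int) -> "StereoWaveform":
        mono = np.asarray(mono, dtype=np.float64)
        return cls(mono, mono.copy(), rate)


@dataclass(frozen=True)
class HPConfig:
    """Huggins-pitch stimulus parameters.

    The phase-inverted band spans ``center_hz * (1 +/- band_fraction)``;
    with the defaults, 564-636 Hz.  ``onset_ramp_s`` guards against onset
    clicks (an artifactual monaural cue); set to 0 to disable.
    """

    center_hz: float = 600.0
    band_fraction: float = 0.06
    phase_shift: float = math.pi
    duration_s: float = 1.0
    onset_ramp_s: float = 0.005
    gap_s: float = DEFAULT_GAP_S
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 <= self.band_fraction < 1:
            raise ValueError("band_fraction must lie in [0, 1)")
        if self.center_hz * (1 + self.band_fraction) >= self.rate / 2:
            raise ValueError("phase-shifted band exceeds the Nyquist frequency")

    @property
    def band_lo_hz(self) -> float:
        return self.center_hz * (1 - self.band_fraction)

    @property
    def band_hi_hz(self) -> float:
        return self.center_hz * (1 + self.band_fraction)


@dataclass(frozen=True)
class APConfig:
    """Anti-phase (intensity-discrimination) stimulus parameters."""

    tone_hz: float = 200.0
    target_level_db: float = -6.0
    duration_s: float = 1.0
    ramp_s: float = 0.1
    gap_s: float = DEFAULT_GAP_S
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.target_level_db >= 0:
            raise ValueError("target_level_db must be negative (a softer target)")
        if 2 * self.ramp_s > self.duration_s:
            raise ValueError("ramps longer than half the tone duration")


@dataclass(frozen=True)
class BTConfig:
    """Beat-test stimulus parameters.

    Each interval carries a tone pair (f1, f2 = f1 + beat_hz); per-interval
    level rove removes loudness as a usable cue.
    """

    f1_min_hz: float = 1800.0
    f1_max_hz: float = 2500.0
    beat_hz: float = 30.0
    duration_s: float = 1.0
    ramp_s: float = 0.005
    rove_db_max: float = 4.0
    gap_s: float = DEFAULT_GAP_S
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        if self.rove_db_max < 0:
            raise ValueError("rove_db_max must be non-negative")
        if self.f1_max_hz + self.beat_hz >= self.rate / 2:
            raise ValueError("tone frequencies exceed the Nyquist frequency")
        if self.f1_min_hz > self.f1_max_hz:
            raise ValueError("f1_min_hz must not exceed f1_max_hz")


AnyConfig = HPConfig | APConfig | BTConfig

_CONFIG_CLASSES: Mapping[str, type] = {"HP": HPConfig, "AP": APConfig, "BT": BTConfig}


def default_config(test_kind: str) -> AnyConfig:
    """Default stimulus configuration for a test kind ('HP', 'AP' or 'BT')."""
    try:
        return _CONFIG_CLASSES[test_kind.upper()]()
    except KeyError:
        raise ValueError(f"unknown test kind {test_kind!r}") from None


@dataclass(frozen=True)
class TrialSpec:
    """One 3AFC trial: three intervals, one of which carries the target cue."""

    test_kind: str
    target_position: int
    intervals: tuple[StereoWaveform, StereoWaveform, StereoWaveform]
    gap_s: float = DEFAULT_GAP_S
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.test_kind not in _TEST_KINDS:
            raise ValueError(f"test_kind must be one of {_TEST_KINDS}")
        if self.target_position not in (1, 2, 3):
            raise ValueError("target_position must be 1, 2 or 3")
        if len(self.intervals) != 3:
            raise ValueError("a 3AFC trial requires exactly three intervals")
        rates = {w.rate for w in self.intervals}
        if len(rates) != 1:
            raise ValueError("all intervals must share one sampling rate")

    @property
    def rate(self) -> int:
        return self.intervals[0].rate


@dataclass(frozen=True)
class TrialPool:
    """A pre-generated pool of 12 trials with balanced target positions."""

    trials: tuple[TrialSpec, ...]
    test_kind: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != 12:
            raise ValueError("a trial pool holds exactly 12 trials")
        counts = np.bincount([t.target_position for t in self.trials], minlength=4)[1:]
        if not np.all(counts == 4):
            raise ValueError("each target position must occur exactly 4 times")

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, i: int) -> TrialSpec:
        return self.trials[i]


# --------------------------------------------------------------------------
# Primitive signal operations
# --------------------------------------------------------------------------

def generate_white_noise(duration_s: float, rate: int, seed) -> np.ndarray:
    """Gaussian white noise: zero-mean draws at ``rate``, normalised to RMS_REFERENCE.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a ``Generator``.
    The spectrum is flat up to the Nyquist frequency (rate / 2).
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration_s and rate must be positive")
    rng = np.random.default_rng(seed)
    n = round(duration_s * rate)
    x = rng.standard_normal(n)
    return x * (RMS_REFERENCE / _rms(x))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def raised_cosine_envelope(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Unit gain envelope with half-Hann (raised-cosine) on/off ramps.

    The ramp follows g(k) = (1 - cos(pi k / (r - 1))) / 2 so the first and
    last samples are exactly zero and the ramp midpoint sits at gain 0.5.
    """
    if ramp_samples < 0 or 2 * ramp_samples > n_samples:
        raise ValueError("ramp longer than half the waveform")
    env = np.ones(n_samples)
    if ramp_samples > 1:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_samples) / (ramp_samples - 1)))
        env[:ramp_samples] = ramp
        env[-ramp_samples:] = ramp[::-1]
    elif ramp_samples == 1:
        env[0] = 0.0
        env[-1] = 0.0
    return env


def apply_ramp(waveform, ramp_s: float, rate: int | None = None):
    """Apply raised-cosine onset and offset ramps of ``ramp_s`` seconds.

    Accepts a mono array (``rate`` required) or a :class:`StereoWaveform`
    (both channels are ramped with the identical envelope).  ``ramp_s = 0``
    is a no-op; a ramp longer than half the duration raises ``ValueError``.
    """
    if isinstance(waveform, StereoWaveform):
        env = raised_cosine_envelope(waveform.n_samples, round(ramp_s * waveform.rate))
        return StereoWaveform(waveform.left * env, waveform.right * env, waveform.rate)
    if rate is None:
        raise ValueError("rate is required for mono input")
    x = np.asarray(waveform, dtype=np.float64)
    return x * raised_cosine_envelope(x.size, round(ramp_s * rate))


def make_huggins_pair(noise: np.ndarray, cfg: HPConfig) -> StereoWaveform:
    """Build a Huggins-pitch stereo pair from a mono noise segment.

    The left channel is the noise unchanged.  The right channel is the same
    noise with every FFT bin whose centre frequency lies within
    ``[center*(1-band_fraction), center*(1+band_fraction)]`` (inclusive)
    phase-shifted; at the default 180 degrees the in-band coefficients are
    multiplied by exactly -1, leaving all magnitudes untouched.  Working on
    the one-sided (rfft) spectrum keeps the output purely real.
    """
    noise = np.asarray(noise, dtype=np.float64)
    if not np.all(np.isfinite(noise)):
        raise ValueError("noise must be finite")
    if cfg.band_hi_hz >= cfg.rate / 2:
        raise ValueError("phase-shifted band exceeds the Nyquist frequency")
    if cfg.band_fraction == 0:  # zero-width band: nothing to shift
        return StereoWaveform(noise.copy(), noise.copy(), cfg.rate)
    spectrum = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(noise.size, d=1.0 / cfg.rate)
    in_band = (freqs >= cfg.band_lo_hz) & (freqs <= cfg.band_hi_hz)
    # exp(i*pi) carries ~1e-16 of imaginary residue; the 180-degree case is
    # the definition of the stimulus, so make it exact.
    phase = float(cfg.phase_shift)
    factor = -1.0 if math.isclose(phase, math.pi) else np.exp(1j * phase)
    shifted = spectrum.copy()
    shifted[in_band] *= factor
    right = np.fft.irfft(shifted, n=noise.size)
    return StereoWaveform(noise.copy(), right, cfg.rate)


def _tone(freq_hz: float, duration_s: float, rate: int) -> np.ndarray:
    t = np.arange(round(duration_s * rate)) / rate
    return np.sin(2 * np.pi * freq_hz * t)


def _normalized(x: np.ndarray, rms: float = RMS_REFERENCE) -> np.ndarray:
    return x * (rms / _rms(x))


# --------------------------------------------------------------------------
# Trial construction
# --------------------------------------------------------------------------

def make_hp_trial(cfg: HPConfig, target_position: int, seed) -> TrialSpec:
    """One HP trial: fresh noise per interval; only the target is dichotic."""
    _check_position(target_position)
    rng = np.random.default_rng(seed)
    intervals = []
    for pos in (1, 2, 3):
        noise = generate_white_noise(cfg.duration_s, cfg.rate, rng)
        if pos == target_position:
            wave = make_huggins_pair(noise, cfg)
        else:
            wave = StereoWaveform.diotic(noise, cfg.rate)
        intervals.append(apply_ramp(wave, cfg.onset_ramp_s))
    return TrialSpec(
        test_kind="HP",
        target_position=target_position,
        intervals=tuple(intervals),
        gap_s=cfg.gap_s,
        metadata={"seed": _seed_repr(seed)},
    )


def make_ap_trial(cfg: APConfig, target_position: int, seed=0) -> TrialSpec:
    """One AP trial: diotic standard, diotic -6 dB target, anti-phase foil.

    The target occupies ``target_position``; the standard and foil are
    assigned to the two remaining slots uniformly at random (``seed``).
    The foil's per-channel amplitude equals the standard's exactly.
    """
    _check_position(target_position)
    if cfg.target_level_db == 0:
        raise ValueError("degenerate target: target_level_db must be non-zero")
    rng = np.random.default_rng(seed)
    mono = _normalized(apply_ramp(_tone(cfg.tone_hz, cfg.duration_s, cfg.rate),
                                  cfg.ramp_s, cfg.rate))
    standard = StereoWaveform.diotic(mono, cfg.rate)
    target = standard.scaled(10.0 ** (cfg.target_level_db / 20.0))
    foil = StereoWaveform(mono.copy(), -mono, cfg.rate)

    slots: list[StereoWaveform | None] = [None, None, None]
    slots[target_position - 1] = target
    free = [i for i in range(3) if slots[i] is None]
    if rng.random() < 0.5:
        free = free[::-1]
    slots[free[0]], slots[free[1]] = standard, foil
    foil_position = free[1] + 1
    return TrialSpec(
        test_kind="AP",
        target_position=target_position,
        intervals=tuple(slots),  # type: ignore[arg-type]
        gap_s=cfg.gap_s,
        metadata={"seed": _seed_repr(seed), "foil_position": foil_position},
    )


def make_bt_trial(cfg: BTConfig, target_position: int, seed) -> TrialSpec:
    """One BT trial: two diotic beating tone pairs and one dichotic pair.

    One f1 is drawn per trial from [f1_min_hz, f1_max_hz]; f2 = f1 + beat_hz.
    The dichotic target puts one tone in each ear (assignment randomised).
    Each interval is independently attenuated by 0..rove_db_max dB, so
    pairwise level differences never exceed rove_db_max.
    """
    _check_position(target_position)
    rng = np.random.default_rng(seed)
    f1 = float(rng.uniform(cfg.f1_min_hz, cfg.f1_max_hz))
    f2 = f1 + cfg.beat_hz
    tone1 = _normalized(apply_ramp(_tone(f1, cfg.duration_s, cfg.rate), cfg.ramp_s, cfg.rate))
    tone2 = _normalized(apply_ramp(_tone(f2, cfg.duration_s, cfg.rate), cfg.ramp_s, cfg.rate))
    pair = _normalized(apply_ramp(_tone(f1, cfg.duration_s, cfg.rate)
                                  + _tone(f2, cfg.duration_s, cfg.rate),
                                  cfg.ramp_s, cfg.rate))
    f1_ear = "left" if rng.random() < 0.5 else "right"
    rove_db = rng.uniform(0.0, cfg.rove_db_max, size=3)
    intervals = []
    for pos in (1, 2, 3):
        if pos == target_position:
            left, right = (tone1, tone2) if f1_ear == "left" else (tone2, tone1)
            wave = StereoWaveform(left.copy(), right.copy(), cfg.rate)
        else:
            wave = StereoWaveform.diotic(pair, cfg.rate)
        intervals.append(wave.scaled(10.0 ** (-rove_db[pos - 1] / 20.0)))
    return TrialSpec(
        test_kind="BT",
        target_position=target_position,
        intervals=tuple(intervals),
        gap_s=cfg.gap_s,
        metadata={
            "seed": _seed_repr(seed),
            "f1_hz": f1,
            "f1_ear": f1_ear,
            "rove_db": [float(g) for g in rove_db],
        },
    )


def make_example_trial(
    test_kind: str,
    cfg: AnyConfig | None = None,
    target_position: int = 2,
    seed=0,
    tone_to_noise_db: float = 0.0,
) -> TrialSpec:
    """A fully diotic practice trial whose target is audible on any equipment.

    HP: a diotic 600-Hz tone added to one noise interval at
    ``tone_to_noise_db`` (tone RMS relative to noise RMS).  AP: two equal
    standards and a softer diotic target.  BT: two diotic beating pairs and
    one diotic single tone (a protocol-completeness extension; the published
    tests describe examples for HP and AP only).
    """
    test_kind = test_kind.upper()
    _check_position(target_position)
    cfg = cfg if cfg is not None else default_config(test_kind)
    rng = np.random.default_rng(seed)
    if test_kind == "HP":
        assert isinstance(cfg, HPConfig)
        intervals = []
        for pos in (1, 2, 3):
            noise = generate_white_noise(cfg.duration_s, cfg.rate, rng)
            if pos == target_position:
                tone = _normalized(_tone(cfg.center_hz, cfg.duration_s, cfg.rate),
                                   rms=_rms(noise) * 10.0 ** (tone_to_noise_db / 20.0))
                noise = noise + tone
            intervals.append(apply_ramp(StereoWaveform.diotic(noise, cfg.rate),
                                        cfg.onset_ramp_s))
        meta = {"seed": _seed_repr(seed), "tone_to_noise_db": tone_to_noise_db}
    elif test_kind == "AP":
        assert isinstance(cfg, APConfig)
        mono = _normalized(apply_ramp(_tone(cfg.tone_hz, cfg.duration_s, cfg.rate),
                                      cfg.ramp_s, cfg.rate))
        standard = StereoWaveform.diotic(mono, cfg.rate)
        target = standard.scaled(10.0 ** (cfg.target_level_db / 20.0))
        intervals = [target if pos == target_position else standard for pos in (1, 2, 3)]
        meta = {"seed": _seed_repr(seed)}
    elif test_kind == "BT":
        assert isinstance(cfg, BTConfig)
        f1 = float(rng.uniform(cfg.f1_min_hz, cfg.f1_max_hz))
        pair = _normalized(apply_ramp(_tone(f1, cfg.duration_s, cfg.rate)
                                      + _tone(f1 + cfg.beat_hz, cfg.duration_s, cfg.rate),
                                      cfg.ramp_s, cfg.rate))
        single = _normalized(apply_ramp(_tone(f1, cfg.duration_s, cfg.rate),
                                        cfg.ramp_s, cfg.rate))
        intervals = [
            StereoWaveform.diotic(single if pos == target_position else pair, cfg.rate)
            for pos in (1, 2, 3)
        ]
        meta = {"seed": _seed_repr(seed), "f1_hz": f1, "synthetic_extension": True}
    else:
        raise ValueError(f"unknown test kind {test_kind!r}")
    return TrialSpec(test_kind=test_kind, target_position=target_position,
                     intervals=tuple(intervals), gap_s=cfg.gap_s, metadata=meta)


def _check_position(position: int) -> None:
    if position not in (1, 2, 3):
        raise ValueError("target_position must be 1, 2 or 3")


def _seed_repr(seed) -> object:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return repr(seed)


# --------------------------------------------------------------------------
# Trial pools
# --------------------------------------------------------------------------

_POSITION_STREAM = 0
_TRIAL_STREAM = 1


def trial_seed_sequence(pool_seed: int, trial_index: int) -> np.random.SeedSequence:
    """Seed for trial ``trial_index`` (0-based) of the pool with ``pool_seed``.

    Each trial draws from an independent child stream so a single trial can
    be regenerated in isolation from (pool_seed, index).
    """
    return np.random.SeedSequence((pool_seed, _TRIAL_STREAM, trial_index))


def build_trial_pool(test_kind: str, cfg: AnyConfig | None = None, seed: int = 0) -> TrialPool:
    """Pre-generate the 12-trial pool for one test.

    Target positions are a seeded shuffle of (1,1,1,1,2,2,2,2,3,3,3,3); all
    stochastic content (noise segments, f1 draws, roves, slot assignments)
    differs across trials.  Deterministic given (cfg, seed).
    """
    test_kind = test_kind.upper()
    cfg = cfg if cfg is not None else default_config(test_kind)
    positions = np.repeat([1, 2, 3], 4)
    np.random.default_rng(
        np.random.SeedSequence((seed, _POSITION_STREAM))
    ).shuffle(positions)
    makers = {"HP": make_hp_trial, "AP": make_ap_trial, "BT": make_bt_trial}
    make = makers[test_kind]
    trials = tuple(
        make(cfg, int(positions[i]), trial_seed_sequence(seed, i)) for i in range(12)
    )
    return TrialPool(trials=trials, test_kind=test_kind, seed=seed)


# --------------------------------------------------------------------------
# File output
# --------------------------------------------------------------------------

def _trial_samples(trial: TrialSpec) -> np.ndarray:
    """Concatenate the three intervals with silent gaps into an (n, 2) array."""
    gap = np.zeros((round(trial.gap_s * trial.rate), 2))
    chunks = []
    for i, w in enumerate(trial.intervals):
        chunks.append(np.column_stack([w.left, w.right]))
        if i < 2:
            chunks.append(gap)
    return np.concatenate(chunks, axis=0)


def write_trial_wav(trial: TrialSpec, path: str | Path) -> Path:
    """Write one trial as a stereo 16-bit PCM WAV (channel 0 = left)."""
    samples = _trial_samples(trial)
    peak = np.max(np.abs(samples))
    if peak > 1.0:  # guard: PCM clipping would add spurious cues
        samples = samples / peak
    path = Path(path)
    wavfile.write(path, trial.rate, np.round(samples * 32767.0).astype(np.int16))
    return path


def write_pool(pool: TrialPool, out_dir: str | Path, cfg: AnyConfig | None = None,
               per_interval: bool = False) -> Path:
    """Write a pool's WAV files and its JSON manifest (the answer key).

    Files are named ``<test>_<poolindex>_<targetpos>.wav``.  The manifest
    echoes the configuration and records per-trial seeds and metadata.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg if cfg is not None else default_config(pool.test_kind)
    entries = []
    for i, trial in enumerate(pool.trials):
        name = f"{pool.test_kind.lower()}_{i}_{trial.target_position}.wav"
        write_trial_wav(trial, out_dir / name)
        if per_interval:
            for j, w in enumerate(trial.intervals, start=1):
                wavfile.write(out_dir / f"{pool.test_kind.lower()}_{i}_interval{j}.wav",
                              w.rate, np.round(np.column_stack([w.left, w.right])
                                               * 32767.0).astype(np.int16))
        entries.append({
            "index": i,
            "file": name,
            "target_position": trial.target_position,
            "seed_scheme": {"pool_seed": pool.seed, "trial_index": i},
            "metadata": {k: v for k, v in trial.metadata.items() if k != "seed"},
        })
    manifest = {
        "test_kind": pool.test_kind,
        "pool_seed": pool.seed,
        "config": dataclasses.asdict(cfg),
        "trials": entries,
    }
    manifest_path = out_dir / f"{pool.test_kind.lower()}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
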