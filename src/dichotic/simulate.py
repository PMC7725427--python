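"""Virtual listeners: playback mixing models and per-test decision statistics.

No human data accompany the screening tests, so downstream statistics are
validated against simulated cohorts.  The simulator has two ingredients:

1. A *playback model*: a 2x2 mixing matrix (optionally with a cross-path
   delay) mapping the stereo channels to the two ears.  Headphones are the
   identity; loudspeakers mix the channels, which is exactly the physical
   effect the screening tests exploit.  With the symmetric full mix, both
   ears receive (L + R) / 2: the Huggins-pitch band cancels into a notch,
   the anti-phase foil cancels to silence, and the dichotic tone pair sums
   into a beating pair.

2. A *decision statistic* per test -- the simplest physics-faithful detector
   of each cue (interaural band power for HP, mean ear level for AP,
   envelope modulation depth at the beat rate for BT) -- plus zero-mean
   Gaussian internal noise added at the statistic level.  The listener
   chooses the extremal interval; exact ties break uniformly at random.

These listeners exist to validate the analysis pipeline end to end, not to
model human audition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .protocol import BLOCK_SIZE, sample_block
from .stimuli import (
    AnyConfig,
    BTConfig,
    HPConfig,
    StereoWaveform,
    TrialPool,
    TrialSpec,
    build_trial_pool,
    default_config,
)

__all__ = [
    "PlaybackModel",
    "HEADPHONES",
    "FULL_MIX",
    "crosstalk",
    "delayed_mix",
    "ListenerConfig",
    "CohortSpec",
    "apply_playback",
    "hp_statistics",
    "ap_statistics",
    "bt_statistics",
    "hp_decision",
    "ap_decision",
    "bt_decision",
    "decide_block",
    "simulate_cohort",
    "mixed_equipment_cohort_spec",
    "fixed_model_sampler",
    "crosstalk_grid_sampler",
]


# --------------------------------------------------------------------------
# Playback models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaybackModel:
    """Linear channel-to-ear mixing: ear = matrix @ (channel L, channel R).

    ``matrix`` is ((a_LL, a_LR), (a_RL, a_RR)); the cross terms (a_LR, a_RL)
    may additionally be delayed by ``delay_samples`` to emulate off-centre
    listening positions in front of loudspeakers.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]]
    delay_samples: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2) or not np.all(np.isfinite(m)):
            raise ValueError("mixing matrix must be a finite 2x2 matrix")
        if self.delay_samples < 0:
            raise ValueError("delay_samples must be non-negative")
        object.__setattr__(self, "matrix",
                           tuple(tuple(float(v) for v in row) for row in m))

    def key(self) -> tuple:
        """Hashable identity used for statistic caching."""
        return (self.matrix, self.delay_samples)


#: Ideal headphones: each channel reaches its own ear only.
HEADPHONES = PlaybackModel(((1.0, 0.0), (0.0, 1.0)), name="headphones")

#: Symmetric loudspeaker mix: both ears receive (L + R) / 2.
FULL_MIX = PlaybackModel(((0.5, 0.5), (0.5, 0.5)), name="full_mix")


def crosstalk(c: float) -> PlaybackModel:
    """Leakage model: each ear gets (1-c) of its own channel and c of the other.

    c = 0 is ideal headphones; c = 0.5 is the symmetric full mix.
    """
    if not 0.0 <= c <= 0.5:
        raise ValueError("crosstalk fraction must lie in [0, 0.5]")
    return PlaybackModel(((1.0 - c, c), (c, 1.0 - c)), name=f"crosstalk({c:g})")


def delayed_mix(c: float, delay_samples: int) -> PlaybackModel:
    """Crosstalk with a cross-path delay (off-centre loudspeaker geometry)."""
    model = crosstalk(c)
    return replace(model, delay_samples=int(delay_samples),
                   name=f"delayed_mix({c:g},{delay_samples})")


def _delayed(x: np.ndarray, d: int) -> np.ndarray:
    if d == 0:
        return x
    out = np.zeros_like(x)
    out[d:] = x[:-d]
    return out


def apply_playback(trial: TrialSpec, model: PlaybackModel) -> TrialSpec:
    """Propagate every interval through the mixing model to ear signals.

    The operation is linear sample-wise; the delay applies to the cross
    terms only.  Returns a trial whose "channels" are ear signals.
    """
    (a_ll, a_lr), (a_rl, a_rr) = model.matrix
    mixed = []
    for w in trial.intervals:
        cross_r = _delayed(w.right, model.delay_samples)
        cross_l = _delayed(w.left, model.delay_samples)
        ear_l = a_ll * w.left + a_lr * cross_r
        ear_r = a_rl * cross_l + a_rr * w.right
        mixed.append(StereoWaveform(ear_l, ear_r, w.rate))
    return replace(trial, intervals=tuple(mixed))


# --------------------------------------------------------------------------
# Decision statistics
# --------------------------------------------------------------------------

def hp_statistics(ear_trial: TrialSpec, cfg: HPConfig) -> np.ndarray:
    """Interaural-difference band power per interval, relative to broadband power.

    statistic_i = power of (earL - earR) within the phase-shifted band,
    divided by the broadband power of earL.  Strictly positive only where a
    dichotic band is present.
    """
    stats = np.empty(3)
    for i, w in enumerate(ear_trial.intervals):
        diff_spec = np.fft.rfft(w.left - w.right)
        left_spec = np.fft.rfft(w.left)
        freqs = np.fft.rfftfreq(w.n_samples, d=1.0 / w.rate)
        band = (freqs >= cfg.band_lo_hz) & (freqs <= cfg.band_hi_hz)
        broadband = np.sum(np.abs(left_spec) ** 2)
        stats[i] = (np.sum(np.abs(diff_spec[band]) ** 2) / broadband
                    if broadband > 0 else 0.0)
    return stats


def ap_statistics(ear_trial: TrialSpec) -> np.ndarray:
    """Perceived level per interval: the mean of the two per-ear RMS levels."""
    return np.array([
        0.5 * (np.sqrt(np.mean(w.left ** 2)) + np.sqrt(np.mean(w.right ** 2)))
        for w in ear_trial.intervals
    ])


def bt_statistics(ear_trial: TrialSpec, cfg: BTConfig) -> np.ndarray:
    """Envelope-modulation depth at the beat rate, per interval.

    Per ear: the Hilbert-envelope is trimmed by the ramp duration at each
    end, truncated to a whole number of beat periods (so a constant
    envelope contributes exactly zero, without spectral leakage from the
    segment ends), and the modulation depth is the normalised magnitude of
    the envelope's Fourier component at ``beat_hz`` (2|E(f)| / mean
    envelope).  The two ears are averaged.  Diotic tone pairs beat
    strongly; a single tone per ear has an essentially flat envelope.
    """
    stats = np.empty(3)
    for i, w in enumerate(ear_trial.intervals):
        trim = round(cfg.ramp_s * w.rate)
        depths = []
        for x in (w.left, w.right):
            env = np.abs(hilbert(x))
            if trim > 0:
                env = env[trim:-trim]
            period = w.rate / cfg.beat_hz
            n_keep = int(env.size // period * period)
            env = env[:n_keep]
            t = np.arange(env.size) / w.rate
            mean = np.mean(env)
            if mean <= 0:
                depths.append(0.0)
                continue
            component = np.mean(env * np.exp(-2j * np.pi * cfg.beat_hz * t))
            depths.append(2.0 * np.abs(component) / mean)
        stats[i] = float(np.mean(depths))
    return stats


@dataclass
class ListenerConfig:
    """A virtual listener: internal noise level and a private RNG.

    ``internal_noise_sd`` is in the units of the decision statistic it is
    added to (dimensionless for HP and BT; RMS amplitude for AP).
    """

    internal_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be non-negative")
        self.rng = np.random.default_rng(self.seed)


def _choose(stats: np.ndarray, noise_sd: float, rng: np.random.Generator,
            largest: bool) -> int:
    vals = np.asarray(stats, dtype=float)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    if not largest:
        vals = -vals
    best = np.max(vals)
    # physically identical intervals can differ by float round-off; treat
    # near-ties (1e-9 relative) as exact ties and break them uniformly
    tol = 1e-9 * max(1.0, float(np.max(np.abs(vals))))
    ties = np.flatnonzero(vals >= best - tol)
    pick = ties[0] if ties.size == 1 else rng.choice(ties)
    return int(pick) + 1


def hp_decision(ear_trial: TrialSpec, listener: ListenerConfig,
                cfg: HPConfig | None = None) -> int:
    """Choose the interval with the largest noisy interaural band-power statistic."""
    cfg = cfg if cfg is not None else HPConfig(rate=ear_trial.rate)
    return _choose(hp_statistics(ear_trial, cfg), listener.internal_noise_sd,
                   listener.rng, largest=True)


def ap_decision(ear_trial: TrialSpec, listener: ListenerConfig) -> int:
    """Choose the quietest interval (smallest noisy mean ear level)."""
    return _choose(ap_statistics(ear_trial), listener.internal_noise_sd,
                   listener.rng, largest=False)


def bt_decision(ear_trial: TrialSpec, listener: ListenerConfig,
                cfg: BTConfig | None = None) -> int:
    """Choose the smoothest interval (smallest noisy beat-modulation depth)."""
    cfg = cfg if cfg is not None else BTConfig(rate=ear_trial.rate)
    return _choose(bt_statistics(ear_trial, cfg), listener.internal_noise_sd,
                   listener.rng, largest=False)


def trial_statistics(trial: TrialSpec, model: PlaybackModel,
                     cfg: AnyConfig) -> np.ndarray:
    """Per-interval decision statistics for a trial heard through ``model``."""
    ear_trial = apply_playback(trial, model)
    if trial.test_kind == "HP":
        return hp_statistics(ear_trial, cfg)
    if trial.test_kind == "AP":
        return ap_statistics(ear_trial)
    return bt_statistics(ear_trial, cfg)


_LARGEST = {"HP": True, "AP": False, "BT": False}


def decide_block(trials: Sequence[TrialSpec], model: PlaybackModel,
                 listener: ListenerConfig, cfg: AnyConfig,
                 _cache: dict | None = None) -> int:
    """Run the listener on a block and return its number of correct choices.

    ``_cache`` maps (trial id, model key) to precomputed interval statistics;
    statistics are deterministic per (trial, model), so cohort simulations
    reuse them across subjects.
    """
    n_correct = 0
    for trial in trials:
        if _cache is not None:
            key = (id(trial), model.key())
            stats = _cache.get(key)
            if stats is None:
                stats = trial_statistics(trial, model, cfg)
                _cache[key] = stats
        else:
            stats = trial_statistics(trial, model, cfg)
        choice = _choose(stats, listener.internal_noise_sd, listener.rng,
                         largest=_LARGEST[trial.test_kind])
        n_correct += int(choice == trial.target_position)
    return n_correct


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

ModelSampler = Callable[[np.random.Generator], PlaybackModel]


def fixed_model_sampler(model: PlaybackModel) -> ModelSampler:
    """Every subject uses the same playback model."""
    return lambda rng: model


def crosstalk_grid_sampler(values: Sequence[float]) -> ModelSampler:
    """Each subject draws a crosstalk fraction uniformly from a fixed grid.

    A discrete grid keeps the number of distinct models small, so interval
    statistics are shared across subjects.
    """
    models = tuple(crosstalk(float(v)) for v in values)
    return lambda rng: models[int(rng.integers(len(models)))]


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    Each subject performs every test in ``tests`` twice: once through a
    headphone model and once through a loudspeaker model, both drawn per
    subject.  Internal noise is drawn per subject, uniformly from
    ``noise_sd_range``.  ``pool_policy`` is "shared" (one pre-generated
    12-trial pool per test, as deployed) or "per_subject".
    """

    n_subjects: int
    tests: tuple[str, ...] = ("HP", "AP")
    configs: Mapping[str, AnyConfig] = field(default_factory=dict)
    headphone_sampler: ModelSampler = field(
        default_factory=lambda: fixed_model_sampler(HEADPHONES))
    loudspeaker_sampler: ModelSampler = field(
        default_factory=lambda: fixed_model_sampler(FULL_MIX))
    noise_sd_range: tuple[float, float] = (0.0, 0.0)
    trials_per_block: int = BLOCK_SIZE
    pool_policy: str = "shared"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.pool_policy not in ("shared", "per_subject"):
            raise ValueError("pool_policy must be 'shared' or 'per_subject'")
        lo, hi = self.noise_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("noise_sd_range must satisfy 0 <= lo <= hi")
        self.configs = {t: self.configs.get(t, default_config(t))
                        for t in self.tests}


def mixed_equipment_cohort_spec(n_subjects: int,
                                tests: tuple[str, ...] = ("HP", "AP")) -> CohortSpec:
    """Study conditions emulating realistic equipment variability.

    Headphones carry 0-40% channel bleed (uniform over a 9-point grid):
    bleed above ~25% makes the anti-phase foil quieter than the -6 dB
    target, so it degrades the AP test well before it degrades the
    Huggins-pitch cue.  Loudspeakers use the symmetric full mix.  Internal
    noise is drawn per subject from a small uniform range, scaled to the
    Huggins-pitch statistic (target value ~0.013) so headphone HP
    performance is near ceiling with occasional 5/6 scores.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        tests=tests,
        headphone_sampler=crosstalk_grid_sampler(np.linspace(0.0, 0.4, 9)),
        loudspeaker_sampler=fixed_model_sampler(FULL_MIX),
        noise_sd_range=(0.0005, 0.004),
    )


def simulate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate a cohort and return its subject table.

    Output is long format with columns ``subject_id``, ``test``,
    ``equipment`` ("headphones" / "loudspeakers") and ``n_correct`` (0-6).
    Fully reproducible from (spec, seed).
    """
    pool_rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))

    def fresh_pools() -> dict[str, TrialPool]:
        return {t: build_trial_pool(t, spec.configs[t],
                                    seed=int(pool_rng.integers(2 ** 31)))
                for t in spec.tests}

    shared_pools = fresh_pools() if spec.pool_policy == "shared" else None
    cache: dict = {}
    rows = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1, s)))
        hp_model = spec.headphone_sampler(rng)
        ls_model = spec.loudspeaker_sampler(rng)
        noise_sd = float(rng.uniform(*spec.noise_sd_range))
        listener = ListenerConfig(internal_noise_sd=noise_sd)
        listener.rng = rng
        pools = shared_pools if shared_pools is not None else fresh_pools()
        for test in spec.tests:
            for equipment, model in (("headphones", hp_model),
                                     ("loudspeakers", ls_model)):
                block = sample_block(pools[test], spec.trials_per_block, seed=rng)
                n_correct = decide_block(block, model, listener,
                                         spec.configs[test], _cache=cache)
                rows.append({"subject_id": f"S{s:04d}", "test": test,
                             "equipment": equipment, "n_correct": n_correct})
    return pd.DataFrame(rows)
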