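"""Headphone-proportion estimation by score-distribution mixture fitting.

When a cohort's equipment is unknown, its score distribution on each test
is modelled as a convex combination of reference distributions measured in
a cohort whose equipment was verified:

    modelled = p * headphone_reference + (1 - p) * loudspeaker_reference

with a single proportion p shared across the tests.  p is fit by grid
search over 0, 0.01, ..., 1, minimising the sum of squared errors between
modelled and observed proportions across all tests and all seven score
bins.  The estimator is deliberately the plain least-squares grid search;
histograms are compared as proportions, and the two tests are weighted
equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .sdt import MAX_SCORE, ScoreHistogram

__all__ = [
    "MixtureReference",
    "MixtureFit",
    "PROPORTION_GRID",
    "mix_distributions",
    "estimate_headphone_proportion",
    "bootstrap_proportion_interval",
]

#: Grid of candidate headphone proportions (0 to 1 in steps of 0.01).
PROPORTION_GRID = np.round(np.arange(101) / 100.0, 2)


@dataclass(frozen=True)
class MixtureReference:
    """Reference score distributions from an equipment-verified cohort.

    ``components`` maps a test name to its (headphone, loudspeaker)
    histogram pair.
    """

    components: Mapping[str, tuple[ScoreHistogram, ScoreHistogram]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("reference must cover at least one test")
        for test, pair in self.components.items():
            if len(pair) != 2:
                raise ValueError(f"test {test!r} needs (headphone, loudspeaker) histograms")


@dataclass(frozen=True)
class MixtureFit:
    """Result of the grid search.

    ``prop_headphones`` is the estimated proportion of headphone users;
    ``sse_profile`` holds the sum of squared errors at every grid value and
    ``modeled`` the best-fitting histogram per test.  ``tie`` flags multiple
    grid values attaining the minimum (the smallest proportion is reported).
    """

    prop_headphones: float
    sse: float
    sse_profile: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: PROPORTION_GRID.copy())
    modeled: Mapping[str, ScoreHistogram] = field(default_factory=dict)
    tie: bool = False


def mix_distributions(hist_phones: ScoreHistogram, hist_speaker: ScoreHistogram,
                      prop_headphones: float) -> ScoreHistogram:
    """Convex combination p*headphones + (1-p)*loudspeakers, bin-wise."""
    if not 0.0 <= prop_headphones <= 1.0:
        raise ValueError("prop_headphones must lie in [0, 1]")
    mixed = (prop_headphones * hist_phones.proportions
             + (1.0 - prop_headphones) * hist_speaker.proportions)
    return ScoreHistogram(mixed)


def estimate_headphone_proportion(
    unknown: Mapping[str, ScoreHistogram],
    reference: MixtureReference,
) -> MixtureFit:
    """Fit the shared headphone proportion to the unknown cohort's histograms.

    ``unknown`` maps test names (a subset of the reference's) to observed
    histograms.  SSE sums over every test and all 7 bins; ties on the grid
    resolve to the smallest proportion and set the ``tie`` flag.
    """
    if not unknown:
        raise ValueError("at least one unknown histogram is required")
    missing = set(unknown) - set(reference.components)
    if missing:
        raise ValueError(f"reference lacks tests: {sorted(missing)}")
    grid = PROPORTION_GRID
    sse = np.zeros(grid.size)
    for test, observed in unknown.items():
        phones, speaker = reference.components[test]
        modeled = (grid[:, None] * phones.proportions[None, :]
                   + (1.0 - grid[:, None]) * speaker.proportions[None, :])
        sse += np.sum((modeled - observed.proportions[None, :]) ** 2, axis=1)
    best = int(np.argmin(sse))  # argmin returns the first, i.e. smallest, proportion
    tie = bool(np.sum(np.isclose(sse, sse[best], rtol=0.0, atol=1e-12)) > 1)
    p_hat = float(grid[best])
    modeled_best = {
        test: mix_distributions(*reference.components[test], p_hat)
        for test in unknown
    }
    return MixtureFit(prop_headphones=p_hat, sse=float(sse[best]),
                      sse_profile=sse, modeled=modeled_best, tie=tie)


def bootstrap_proportion_interval(
    unknown: Mapping[str, ScoreHistogram],
    reference: MixtureReference,
    n_unknown: int,
    n_boot: int = 1000,
    seed=None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval for the headphone proportion.

    Resamples each unknown histogram as a multinomial of ``n_unknown``
    subjects and re-runs the grid search.  An extension beyond the core
    estimator; off by default in the CLI.
    """
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        resampled = {
            test: ScoreHistogram(rng.multinomial(n_unknown, hist.proportions)
                                 / n_unknown)
            for test, hist in unknown.items()
        }
        estimates[b] = estimate_headphone_proportion(resampled, reference).prop_headphones
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
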