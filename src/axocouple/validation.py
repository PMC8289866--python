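"""Statistical controls for detected couplings.

Two independent lines of evidence back a detected coupling:

* **Amplitude identity** — if the coupled spikes come from one postsynaptic
  neuron, their amplitude distribution should be a discrete subset of the
  target electrode's full amplitude distribution, not a random sample of
  it.  Two-sample KS tests against repeated random draws quantify this.
* **Timing specificity** — rebuilding the target train from a random
  permutation of its inter-spike intervals (ISI shuffle) preserves the
  firing pattern statistics while destroying fine timing; the
  chance-coupling ratio collapses for genuine couplings and is unchanged
  for spurious ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .mea_io import Recording, SpikeTrain

__all__ = [
    "KSComparison",
    "ShuffleResult",
    "ks_two_sample",
    "coupled_vs_random_amplitude_test",
    "isi_shuffle",
    "chance_coupling_ratio",
    "shuffle_control",
]


@dataclass(frozen=True)
class KSComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    label: str = "coupled-vs-random"

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= 1.0 and 0.0 <= self.p_value <= 1.0):
            raise ValueError("KS statistic and p-value must lie in [0, 1]")


@dataclass
class ShuffleResult:
    original_ratio: float
    shuffled_ratios: np.ndarray
    n_reps: int
    seed: int

    @property
    def mean_reduction(self) -> float:
        """Mean fractional drop of the coupling ratio under shuffling."""
        if self.original_ratio == 0:
            return 0.0
        return float(1.0 - np.mean(self.shuffled_ratios) / self.original_ratio)


def ks_two_sample(a, b, label: str = "coupled-vs-random", method: str = "auto") -> KSComparison:
    """Two-sided two-sample Kolmogorov–Smirnov comparison."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSComparison(float(res.statistic), float(res.pvalue), a.size, b.size, label)


def coupled_vs_random_amplitude_test(
    coupled_amps,
    all_amps,
    n_draws: int = 100,
    seed: int = 0,
    mode: str = "coupled-vs-random",
) -> list[KSComparison]:
    """Repeated KS comparisons of the coupled amplitude set against random
    subsets of the electrode's full amplitude distribution.

    Each draw samples ``len(coupled_amps)`` amplitudes without replacement
    from ``all_amps``.  In ``"random-vs-random"`` mode two independent draws
    are compared instead — the null reference in which ~95% of comparisons
    should exceed the 5% significance threshold.
    """
    coupled = np.abs(np.asarray(coupled_amps, dtype=float))
    full = np.abs(np.asarray(all_amps, dtype=float))
    if coupled.size > full.size:
        raise ValueError("coupled set larger than the full amplitude set")
    if mode not in {"coupled-vs-random", "random-vs-random"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[KSComparison] = []
    for _ in range(n_draws):
        draw = rng.choice(full, size=coupled.size, replace=False)
        if mode == "coupled-vs-random":
            out.append(ks_two_sample(coupled, draw, label=mode))
        else:
            draw2 = rng.choice(full, size=coupled.size, replace=False)
            out.append(ks_two_sample(draw, draw2, label=mode))
    return out


def isi_shuffle(train: SpikeTrain, seed: int | np.random.Generator = 0) -> SpikeTrain:
    """Surrogate train from a random permutation of the inter-spike
    intervals.

    Preserves the spike count, the ISI multiset, the first spike time and
    the total span; amplitudes keep their original sequence order (the
    control concerns timing, not amplitudes).  Trains with fewer than two
    spikes are returned unchanged.
    """
    if train.n_spikes < 2:
        return train
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isis = rng.permutation(train.isis())
    times = np.concatenate(([train.times[0]], train.times[0] + np.cumsum(isis)))
    return replace(train, times=times, amplitudes=train.amplitudes.copy())


def chance_coupling_ratio(
    ref_times,
    target: SpikeTrain | np.ndarray,
    window: tuple[float, float] = (0.5, 10.0),
) -> float:
    """Number of target spikes falling in the window after any reference
    spike (each target spike counted once) divided by the number of
    reference spikes.  May exceed 1."""
    r = np.asarray(ref_times, dtype=float)
    if r.size == 0:
        raise ValueError("no reference spikes")
    t = target.times if isinstance(target, SpikeTrain) else np.asarray(target, dtype=float)
    if t.size == 0:
        return 0.0
    lo_s, hi_s = window[0] * 1e-3, window[1] * 1e-3
    # a target spike at t is covered iff some ref lies in [t - hi, t - lo]
    lo = np.searchsorted(r, t - hi_s, side="left")
    hi = np.searchsorted(r, t - lo_s, side="right")
    covered = int(np.count_nonzero(hi > lo))
    return covered / r.size


def shuffle_control(
    ref_times,
    target: SpikeTrain,
    n_reps: int = 20,
    seed: int = 0,
    window: tuple[float, float] = (0.5, 10.0),
) -> ShuffleResult:
    """ISI-shuffle surrogate distribution of the chance-coupling ratio.

    The original ratio is computed on the intact target train, then on
    ``n_reps`` independently ISI-shuffled surrogates.  Fully reproducible
    given the seed.
    """
    rng = np.random.default_rng(seed)
    original = chance_coupling_ratio(ref_times, target, window)
    shuffled = np.array(
        [
            chance_coupling_ratio(ref_times, isi_shuffle(target, rng), window)
            for _ in range(n_reps)
        ]
    )
    return ShuffleResult(original, shuffled, n_reps, seed)
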