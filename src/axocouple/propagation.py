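"""Detection of axonal propagation signals from pairwise cross-correlograms.

A propagation signal is a cohort of electrodes that detect the same axon's
action potential in a fixed order with fixed sub-millisecond delays.  Spikes
belonging to such a cohort are self-classified as coming from one neuron,
without spike sorting.

Detection works pairwise: for every ordered electrode pair a cross-
correlogram (CCG) of spike-time differences within ±2 ms is built; if the
largest 0.5 ms moving-window count exceeds 30% of the reference electrode's
spike count the pair has a consistent delay.  A reference electrode whose
consistent partners all lag it (non-negative delays) is the origin of a
propagation signal.  The signal's spike times are then computed from
co-occurrences on its two anchor electrodes: the earliest electrode e1 and
the electrode with the most spikes other than e1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .mea_io import Recording, SpikeTrain

__all__ = [
    "CCGResult",
    "PropagationSignal",
    "LatencyStats",
    "pairwise_ccg",
    "propagation_ratio",
    "detect_propagation_signals",
    "assign_signal_spike_times",
    "latency_stats",
]


def _event_times(x) -> np.ndarray:
    if isinstance(x, SpikeTrain):
        return x.times
    return np.asarray(x, dtype=float)


def _range_concat(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo[i], hi[i]) for all i, vectorised."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.intp)
    starts = np.repeat(lo, counts)
    offsets = np.arange(total) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    return starts + offsets


@dataclass
class CCGResult:
    """A windowed cross-correlogram between reference events and a target
    spike train.

    ``deltas`` are the raw latencies Δt = t_target − t_ref in ms, retained
    for latency statistics; ``target_indices`` maps each delta back to the
    index of the contributing target spike.
    """

    reference_id: str
    target_id: str
    window: tuple[float, float]  # ms
    bin_width: float  # ms
    counts: np.ndarray  # per-bin counts
    deltas: np.ndarray  # ms
    n_ref: int
    target_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def bin_edges(self) -> np.ndarray:
        lo, hi = self.window
        return lo + self.bin_width * np.arange(len(self.counts) + 1)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def pairwise_ccg(
    ref,
    target,
    window: tuple[float, float] = (-2.0, 2.0),
    bin_width: float = 0.05,
    reference_id: str = "",
    target_id: str = "",
) -> CCGResult:
    """All-pairs CCG: every (reference event, target spike) pair with
    Δt = t_target − t_ref inside ``window`` (ms, inclusive) contributes one
    count.

    ``ref`` and ``target`` may be SpikeTrains or arrays of event times (s).
    """
    lo_ms, hi_ms = window
    if not lo_ms < hi_ms:
        raise ValueError("window must be ordered (t_min < t_max)")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    r = _event_times(ref)
    t = _event_times(target)
    if isinstance(ref, SpikeTrain) and not reference_id:
        reference_id = ref.electrode
    if isinstance(target, SpikeTrain) and not target_id:
        target_id = target.electrode

    n_bins = int(round((hi_ms - lo_ms) / bin_width))
    edges = lo_ms + bin_width * np.arange(n_bins + 1)
    if r.size == 0 or t.size == 0:
        return CCGResult(
            reference_id, target_id, (lo_ms, hi_ms), bin_width,
            np.zeros(n_bins, dtype=np.intp), np.empty(0), r.size,
        )
    lo = np.searchsorted(t, r + lo_ms * 1e-3, side="left")
    hi = np.searchsorted(t, r + hi_ms * 1e-3, side="right")
    idx = _range_concat(lo, hi)
    deltas = (t[idx] - np.repeat(r, hi - lo)) * 1e3
    counts, _ = np.histogram(deltas, bins=edges)
    return CCGResult(
        reference_id, target_id, (lo_ms, hi_ms), bin_width,
        counts.astype(np.intp), deltas, r.size, idx,
    )


class PeakWindow(NamedTuple):
    n_win: int
    start_bin: int
    n_bins: int
    mask: np.ndarray  # selects deltas inside the maximizing window


def peak_window(ccg: CCGResult, moving_window: float) -> PeakWindow:
    """Locate the moving window (slid one bin at a time) with the largest
    count sum; the mask selects the raw deltas falling in it."""
    w_bins = max(1, int(round(moving_window / ccg.bin_width)))
    counts = ccg.counts
    if w_bins > len(counts):
        raise ValueError("moving window exceeds CCG span")
    sums = np.convolve(counts, np.ones(w_bins, dtype=np.intp), mode="valid")
    start = int(np.argmax(sums))  # ties -> earliest window
    n_win = int(sums[start])
    if ccg.deltas.size:
        dbin = np.clip(
            ((ccg.deltas - ccg.window[0]) / ccg.bin_width).astype(int),
            0, len(counts) - 1,
        )
        mask = (dbin >= start) & (dbin < start + w_bins)
    else:
        mask = np.zeros(0, dtype=bool)
    return PeakWindow(n_win, start, w_bins, mask)


def propagation_ratio(
    ccg: CCGResult, moving_window: float = 0.5
) -> tuple[float, float]:
    """Consistency ratio n_win/n_all and the delay of the maximizing window.

    n_win is the largest count sum in any ``moving_window`` ms window of the
    CCG and n_all is the number of reference spikes.  The delay is the mean
    of the raw deltas inside the maximizing window (count-weighted by
    construction).  Returns (0.0, nan) when there are no reference events.
    """
    if ccg.n_ref == 0:
        return 0.0, float("nan")
    pw = peak_window(ccg, moving_window)
    ratio = pw.n_win / ccg.n_ref
    delay = float(np.mean(ccg.deltas[pw.mask])) if pw.n_win else float("nan")
    return ratio, delay


@dataclass
class PropagationSignal:
    """One identified neuron: an ordered electrode cohort with delays.

    ``electrodes`` holds (electrode, delay_ms, co_occurrence_count) sorted by
    delay; the origin electrode has delay 0.  ``spike_times`` (s) are
    assigned from anchor co-occurrences by
    :func:`assign_signal_spike_times`.
    """

    signal_id: str
    electrodes: list[tuple[str, float, int]]
    anchor_first: str
    anchor_second: str | None
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        delays = [d for _, d, _ in self.electrodes]
        if any(d < 0 for d in delays):
            raise ValueError("propagation signal delays must be non-negative")
        if delays != sorted(delays):
            raise ValueError("electrodes must be sorted by delay")
        if self.electrodes and self.electrodes[0][0] != self.anchor_first:
            raise ValueError("anchor_first must be the earliest electrode")
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("signal spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def electrode_labels(self) -> list[str]:
        return [e for e, _, _ in self.electrodes]

    def delay_of(self, electrode: str) -> float:
        for e, d, _ in self.electrodes:
            if e == electrode:
                return d
        raise KeyError(electrode)

    @property
    def anchor_offset_ms(self) -> float:
        """Mean delay of the two anchors: the offset between the signal's
        assigned spike times and the neuron's origin-electrode spike times."""
        second = self.anchor_second if self.anchor_second is not None else self.anchor_first
        return 0.5 * (self.delay_of(self.anchor_first) + self.delay_of(second))


def detect_propagation_signals(
    rec: Recording,
    ratio_threshold: float = 0.3,
    window: tuple[float, float] = (-2.0, 2.0),
    moving_window: float = 0.5,
    bin_width: float = 0.05,
    min_cohort: int = 2,
    dedup_delay_tol: float = 0.2,
) -> list[PropagationSignal]:
    """Scan every electrode as a reference and emit propagation signals.

    For a reference electrode e_i, every other electrode whose CCG ratio
    strictly exceeds ``ratio_threshold`` is a consistent partner with a
    recorded delay.  If all partners have non-negative delays, e_i is the
    earliest electrode of a propagation signal spanning e_i plus its
    partners.  Signals sharing the same cohort (≥2 common electrodes with
    delay profiles agreeing within ``dedup_delay_tol`` ms after offsetting)
    are merged, keeping the variant with the most electrodes and earliest
    origin.
    """
    labels = [e for e in rec.electrode_map.labels if rec.train(e).n_spikes > 0]
    trains = {e: rec.train(e) for e in labels}
    raw: list[PropagationSignal] = []
    for ref_label in labels:
        ref = trains[ref_label]
        hits: list[tuple[str, float, int]] = []
        negative = False
        for tgt_label in labels:
            if tgt_label == ref_label:
                continue
            tgt = trains[tgt_label]
            ccg = pairwise_ccg(ref, tgt, window, bin_width)
            # cheap upper bound: the ratio cannot exceed total/n_ref
            if ccg.n_total <= ratio_threshold * ccg.n_ref:
                continue
            pw = peak_window(ccg, moving_window)
            if pw.n_win <= ratio_threshold * ccg.n_ref:
                continue
            delay = float(np.mean(ccg.deltas[pw.mask]))
            if delay < 0:
                negative = True
                break
            hits.append((tgt_label, delay, pw.n_win))
        if negative or not hits:
            continue
        cohort = [(ref_label, 0.0, ref.n_spikes)] + sorted(hits, key=lambda h: h[1])
        if len(cohort) < min_cohort:
            continue
        second = max(
            (e for e, _, _ in cohort[1:]), key=lambda e: trains[e].n_spikes
        )
        raw.append(
            PropagationSignal(
                signal_id=f"sig_{ref_label}",
                electrodes=cohort,
                anchor_first=ref_label,
                anchor_second=second,
            )
        )
    return _merge_duplicates(raw, dedup_delay_tol)


def _merge_duplicates(
    signals: list[PropagationSignal], delay_tol: float
) -> list[PropagationSignal]:
    """Merge signals whose electrode sets overlap on ≥2 electrodes with
    mutually consistent delays (within ``delay_tol`` ms after offsetting)."""
    kept: list[PropagationSignal] = []
    for sig in signals:
        absorbed = False
        for i, other in enumerate(kept):
            common = set(sig.electrode_labels) & set(other.electrode_labels)
            if len(common) < 2:
                continue
            offs = [sig.delay_of(e) - other.delay_of(e) for e in common]
            if max(offs) - min(offs) > delay_tol:
                continue
            # duplicates: keep the larger cohort; tie -> earlier origin
            # (the one whose origin the other sees at positive delay)
            if len(sig.electrodes) > len(other.electrodes):
                kept[i] = sig
            elif len(sig.electrodes) == len(other.electrodes) and np.mean(offs) < 0:
                kept[i] = sig
            absorbed = True
            break
        if not absorbed:
            kept.append(sig)
    return kept


def assign_signal_spike_times(
    sig: PropagationSignal,
    rec: Recording,
    co_occurrence_window: float = 2.0,
) -> PropagationSignal:
    """Assign the signal's spike times from anchor co-occurrences.

    A co-occurrence is a pair of spikes in quick succession on the two
    anchor electrodes: each e1 spike is matched greedily, in time order, to
    its nearest unused e2 spike within ``co_occurrence_window`` ms.  The
    signal spike time is the mean of the two spike times; unmatched spikes
    are dropped.
    """
    if sig.anchor_second is None:
        raise ValueError(f"{sig.signal_id}: no second anchor electrode")
    t1 = rec.train(sig.anchor_first).times
    t2 = rec.train(sig.anchor_second).times
    w = co_occurrence_window * 1e-3
    used = np.zeros(t2.size, dtype=bool)
    times: list[float] = []
    for t in t1:
        lo = np.searchsorted(t2, t - w, side="left")
        hi = np.searchsorted(t2, t + w, side="right")
        best = -1
        best_d = np.inf
        for j in range(lo, hi):
            if used[j]:
                continue
            d = abs(t2[j] - t)
            if d < best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            times.append(0.5 * (t + t2[best]))
    if not times:
        warnings.warn(
            f"{sig.signal_id}: anchors {sig.anchor_first}/{sig.anchor_second} "
            f"have zero co-occurrences",
            stacklevel=2,
        )
    out = np.unique(np.asarray(times))
    return replace(sig, spike_times=out)


class LatencyStats(NamedTuple):
    mean: float
    sd: float
    cv: float
    n: int


def latency_stats(deltas: Sequence[float] | np.ndarray) -> LatencyStats:
    """Mean, sample sd, coefficient of variation (sd/mean) and n of a set of
    latencies (ms).  Requires n ≥ 2 for the sample sd/CV to be defined."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("latency CV undefined for fewer than 2 latencies")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    cv = sd / mean if mean != 0 else float("inf")
    return LatencyStats(mean, sd, cv, int(d.size))
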