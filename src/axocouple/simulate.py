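"""Synthetic MEA recordings with known ground truth.

The simulator emulates the statistical structure of dissociated-culture
recordings on a 120-electrode array: Poisson-firing units with a refractory
period, axonal propagation cohorts (each unit spike appears on each cohort
electrode at a fixed sub-millisecond delay plus small Gaussian jitter),
synaptically coupled follower units (each presynaptic spike triggers a
postsynaptic spike with a fixed probability and a 1–5 ms jittered latency),
per-(unit, electrode) Gaussian amplitude modes (multimodal electrodes arise
when several units share an electrode), and Poisson background spikes with
a distinct amplitude mode.

Default parameter regimes: unit rate 2 Hz, cohort delay step 0.3 ms with
jitter sd 0.015 ms (inter-anchor latency CV ≈ 0.07), coupling latency mean
2.79 ms with per-coupling sd 0.6 ms, unit amplitude mode −45 µV, background
mode −20 µV at 0.5 Hz, refractory 2 ms.

:func:`score_recovery` compares detector output against the planted ground
truth, accounting for the timestamp convention (a detected signal's spike
times are co-occurrence means, offset from the unit's origin time by the
mean anchor delay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import Coupling
from .mea_io import ElectrodeMap, Recording, SpikeTrain, VoltageRecording
from .propagation import PropagationSignal

__all__ = [
    "UnitSpec",
    "CouplingSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_raw_traces",
    "score_recovery",
    "RecoveryScore",
    "benchmark_config",
    "null_config",
    "coupled_pair_config",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class UnitSpec:
    """One simulated neuron: its firing rate, electrode cohort with true
    propagation delays, jitter, and per-electrode amplitude model."""

    unit_id: str
    rate_hz: float
    electrodes: tuple[str, ...]
    delays_ms: tuple[float, ...]
    jitter_sd_ms: float = 0.015
    amplitude_uv: tuple[float, float] = (-45.0, 4.0)  # (mean, sd), mean < 0
    detect_p: float = 1.0

    def __post_init__(self) -> None:
        if len(self.electrodes) != len(self.delays_ms):
            raise ValueError("electrodes and delays must align")
        if self.delays_ms and self.delays_ms[0] != 0.0:
            raise ValueError("origin electrode must have delay 0")
        if any(d < 0 for d in self.delays_ms):
            raise ValueError("delays must be non-negative")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter sd must be non-negative")
        if not 0.0 <= self.detect_p <= 1.0:
            raise ValueError("detect_p must be in [0, 1]")
        if self.amplitude_uv[0] >= 0:
            raise ValueError("amplitude mean must be negative")


@dataclass(frozen=True)
class CouplingSpec:
    pre: str
    post: str
    probability: float
    latency_mean_ms: float = 2.79
    latency_sd_ms: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("coupling probability must be in [0, 1]")
        if not 0.5 < self.latency_mean_ms < 10.0:
            raise ValueError("latency mean must lie inside (0.5, 10) ms")
        if self.latency_sd_ms < 0:
            raise ValueError("latency sd must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    duration_s: float
    units: tuple[UnitSpec, ...]
    couplings: tuple[CouplingSpec, ...] = ()
    background_rate_hz: float = 0.5
    background_amplitude_uv: tuple[float, float] = (-20.0, 3.0)
    refractory_ms: float = 2.0
    electrode_map: ElectrodeMap = field(default_factory=ElectrodeMap.default_120)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("unit ids must be unique")
        for c in self.couplings:
            if c.pre not in ids or c.post not in ids:
                raise ValueError(f"coupling {c.pre}->{c.post} names unknown units")
        for u in self.units:
            for e in u.electrodes:
                if e not in self.electrode_map:
                    raise ValueError(f"unit {u.unit_id}: electrode {e!r} not in map")


@dataclass
class GroundTruth:
    """Simulator-side record of what was planted."""

    units: dict[str, UnitSpec]
    unit_trains: dict[str, np.ndarray]  # final spike times (s) per unit
    couplings: tuple[CouplingSpec, ...]
    triggered: dict[tuple[str, str], np.ndarray]  # coupled post-spike times
    electrode_units: dict[str, list[str]]  # per-electrode composition
    spike_labels: dict[str, np.ndarray]  # per-electrode provenance per spike

    def multi_electrode_units(self) -> list[str]:
        return [u for u, spec in self.units.items() if len(spec.electrodes) >= 2]

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(c.pre, c.post) for c in self.couplings}

    def realized_probability(self, pre: str, post: str) -> float:
        """Fraction of presynaptic spikes that actually triggered a
        postsynaptic spike in this realisation — the recoverable ground
        truth, which differs from the generating parameter by binomial
        sampling noise."""
        n_pre = self.unit_trains[pre].size
        if n_pre == 0:
            return 0.0
        return self.triggered[(pre, post)].size / n_pre


def _poisson_train(rng: np.random.Generator, rate: float, duration: float,
                   refractory_s: float) -> np.ndarray:
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    return _enforce_refractory(t, refractory_s)


def _enforce_refractory(t: np.ndarray, refractory_s: float) -> np.ndarray:
    if t.size == 0 or refractory_s <= 0:
        return t
    keep = np.ones(t.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if ti - last < refractory_s:
            keep[i] = False
        else:
            last = ti
    return t[keep]


def simulate_recording(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate a Recording plus its GroundTruth; fully reproducible given
    ``cfg.seed``.

    Coupled postsynaptic spikes are inserted into the follower unit's train
    and merged with its intrinsic Poisson spikes under the refractory
    period, with the coupled spike winning ties.
    """
    rng = np.random.default_rng(cfg.seed)
    refr = cfg.refractory_ms * 1e-3

    unit_trains: dict[str, np.ndarray] = {}
    coupled_marks: dict[str, list[np.ndarray]] = {u.unit_id: [] for u in cfg.units}
    for u in cfg.units:
        unit_trains[u.unit_id] = _poisson_train(rng, u.rate_hz, cfg.duration_s, refr)

    triggered: dict[tuple[str, str], np.ndarray] = {}
    for c in cfg.couplings:
        pre_t = unit_trains[c.pre]
        fire = rng.random(pre_t.size) < c.probability
        lat = rng.normal(c.latency_mean_ms, c.latency_sd_ms, size=int(fire.sum()))
        lat = np.clip(lat, 0.501, 9.999) * 1e-3
        new = np.sort(pre_t[fire] + lat)
        new = new[new < cfg.duration_s]
        coupled_marks[c.post].append(new)
        triggered[(c.pre, c.post)] = new

    # merge coupled spikes into the follower's train; coupled spikes win ties
    for u in cfg.units:
        marks = coupled_marks[u.unit_id]
        if not marks:
            continue
        coupled = _enforce_refractory(np.sort(np.concatenate(marks)), refr)
        intrinsic = unit_trains[u.unit_id]
        if coupled.size and intrinsic.size:
            # keep intrinsic spikes at least one refractory away from any coupled spike
            idx = np.searchsorted(coupled, intrinsic)
            d_prev = np.where(idx > 0, intrinsic - coupled[np.maximum(idx - 1, 0)], np.inf)
            d_next = np.where(
                idx < coupled.size, coupled[np.minimum(idx, coupled.size - 1)] - intrinsic, np.inf
            )
            intrinsic = intrinsic[(d_prev >= refr) & (d_next >= refr)]
        merged = np.sort(np.concatenate([coupled, intrinsic]))
        unit_trains[u.unit_id] = _enforce_refractory(merged, refr)

    # project units onto their cohort electrodes, add background, assemble
    per_electrode: dict[str, list[tuple[np.ndarray, np.ndarray, str]]] = {}
    electrode_units: dict[str, list[str]] = {}
    for u in cfg.units:
        base = unit_trains[u.unit_id]
        for e, delay in zip(u.electrodes, u.delays_ms):
            t = base + delay * 1e-3
            if u.jitter_sd_ms > 0:
                t = t + rng.normal(0.0, u.jitter_sd_ms * 1e-3, size=t.size)
            if u.detect_p < 1.0:
                t = t[rng.random(t.size) < u.detect_p]
            t = np.sort(t)
            t = t[(t >= 0) & (t <= cfg.duration_s)]
            a = rng.normal(u.amplitude_uv[0], u.amplitude_uv[1], size=t.size)
            a = np.minimum(a, -1.0)
            per_electrode.setdefault(e, []).append((t, a, u.unit_id))
            electrode_units.setdefault(e, []).append(u.unit_id)

    if cfg.background_rate_hz > 0:
        mu, sd = cfg.background_amplitude_uv
        for e in cfg.electrode_map.labels:
            n = rng.poisson(cfg.background_rate_hz * cfg.duration_s)
            t = np.sort(rng.uniform(0.0, cfg.duration_s, size=n))
            a = np.minimum(rng.normal(mu, sd, size=n), -1.0)
            per_electrode.setdefault(e, []).append((t, a, BACKGROUND))
            electrode_units.setdefault(e, []).append(BACKGROUND)

    trains: dict[str, SpikeTrain] = {}
    spike_labels: dict[str, np.ndarray] = {}
    for e, parts in per_electrode.items():
        t = np.concatenate([p[0] for p in parts])
        a = np.concatenate([p[1] for p in parts])
        lab = np.concatenate([np.full(p[0].size, p[2], dtype=object) for p in parts])
        order = np.argsort(t, kind="stable")
        t, a, lab = t[order], a[order], lab[order]
        # break exact ties so spike times are strictly increasing
        for i in np.flatnonzero(np.diff(t) <= 0):
            t[i + 1] = np.nextafter(t[i], np.inf)
        trains[e] = SpikeTrain(e, t, a)
        spike_labels[e] = lab

    rec = Recording(
        trains, cfg.electrode_map, duration=cfg.duration_s,
        metadata={"seed": cfg.seed, "simulated": True},
    )
    truth = GroundTruth(
        units={u.unit_id: u for u in cfg.units},
        unit_trains=unit_trains,
        couplings=cfg.couplings,
        triggered=triggered,
        electrode_units=electrode_units,
        spike_labels=spike_labels,
    )
    return rec, truth


def default_waveform(sampling_rate: float = 20000.0) -> np.ndarray:
    """Biphasic eAP template, ~1.2 ms, normalised so the minimum is −1."""
    t = np.arange(-0.4e-3, 0.8e-3, 1.0 / sampling_rate)
    w = -np.exp(-0.5 * (t / 0.15e-3) ** 2) + 0.3 * np.exp(-0.5 * ((t - 0.3e-3) / 0.25e-3) ** 2)
    return w / -w.min()


def simulate_raw_traces(
    rec: Recording,
    waveform: np.ndarray | None = None,
    noise_sd: float = 3.0,
    sampling_rate: float = 20000.0,
    seed: int = 0,
) -> VoltageRecording:
    """Render a Recording into raw voltage traces: each spike is a scaled
    template (peak = amplitude) at its time, plus additive Gaussian noise.
    Spikes closer than the template length add up (documented overlap)."""
    rng = np.random.default_rng(seed)
    w = default_waveform(sampling_rate) if waveform is None else np.asarray(waveform)
    peak_at = int(np.argmin(w))
    n_samples = int(np.ceil(rec.duration * sampling_rate)) + 1
    channels: dict[str, np.ndarray] = {}
    for e in rec.electrode_map.labels:
        v = (
            rng.normal(0.0, noise_sd, size=n_samples)
            if noise_sd > 0
            else np.zeros(n_samples)
        )
        tr = rec.train(e)
        for t, a in zip(tr.times, tr.amplitudes):
            i0 = int(round(t * sampling_rate)) - peak_at
            lo, hi = max(i0, 0), min(i0 + w.size, n_samples)
            if hi > lo:
                v[lo:hi] += (-a) * w[lo - i0 : hi - i0]
        channels[e] = v
    return VoltageRecording(sampling_rate, channels, rec.electrode_map)


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryScore:
    cohort_precision: float
    cohort_recall: float
    coupling_precision: float
    coupling_recall: float
    probability_errors: dict[tuple[str, str], float]
    latency_errors: dict[tuple[str, str], float]
    signal_to_unit: dict[str, str]
    spurious_signals: list[str]
    spurious_pairs: set[tuple[str, str]]

    @property
    def max_probability_error(self) -> float:
        return max(self.probability_errors.values(), default=0.0)

    @property
    def max_latency_error(self) -> float:
        return max(self.latency_errors.values(), default=0.0)


def _match_signal(
    sig: PropagationSignal,
    truth: GroundTruth,
    min_shared: int = 2,
    delay_tol_ms: float = 0.2,
) -> str | None:
    for uid, spec in truth.units.items():
        tdel = dict(zip(spec.electrodes, spec.delays_ms))
        common = [e for e in sig.electrode_labels if e in tdel]
        if len(common) < min_shared:
            continue
        offs = [sig.delay_of(e) - tdel[e] for e in common]
        if max(offs) - min(offs) <= delay_tol_ms:
            return uid
    return None


def score_recovery(
    truth: GroundTruth,
    signals: list[PropagationSignal],
    couplings: list[Coupling] | None = None,
    delay_tol_ms: float = 0.2,
) -> RecoveryScore:
    """Precision/recall of cohort and coupling recovery plus per-coupling
    probability and latency errors.

    A detected signal matches a planted unit when they share ≥2 electrodes
    with delay profiles agreeing within ``delay_tol_ms``.  A detected
    coupling matches a planted (pre, post) pair when its reference signal
    maps to pre and its target (a signal, or an electrode hosting the post
    unit) maps to post; detections of the same unit pair are pooled.  With
    no detections, recall is 0 and precision is reported as 1 with zero
    support.

    Probability errors compare the detected coupling probability with the
    realisation's triggered fraction (see
    :meth:`GroundTruth.realized_probability`), so they measure detector
    error rather than the generator's binomial sampling noise.

    Latency errors are computed in the signal-time frame: the expected
    measured latency of a planted coupling is its latency mean plus the
    post anchor offset minus the pre anchor offset, because signal spike
    times are co-occurrence means, not origin-electrode times.
    """
    s2u: dict[str, str] = {}
    spurious_signals: list[str] = []
    for sig in signals:
        uid = _match_signal(sig, truth, delay_tol_ms=delay_tol_ms)
        if uid is None:
            spurious_signals.append(sig.signal_id)
        elif uid not in s2u.values():
            s2u[sig.signal_id] = uid
        else:
            spurious_signals.append(sig.signal_id)  # duplicate of a matched unit
    units_expected = truth.multi_electrode_units()
    cohort_recall = (
        len(set(s2u.values()) & set(units_expected)) / len(units_expected)
        if units_expected
        else 1.0
    )
    cohort_precision = len(s2u) / len(signals) if signals else 1.0

    sig_by_id = {s.signal_id: s for s in signals}
    planted = truth.planted_pairs()
    by_spec = {(c.pre, c.post): c for c in truth.couplings}
    detected_pairs: set[tuple[str, str]] = set()
    spurious_pairs: set[tuple[str, str]] = set()
    best: dict[tuple[str, str], Coupling] = {}
    for c in couplings or []:
        pre = s2u.get(c.reference_id)
        if pre is None:
            spurious_pairs.add((c.reference_id, c.target_id))
            continue
        if c.target_kind == "signal":
            post = s2u.get(c.target_id)
        else:
            hosts = [
                u for u in truth.electrode_units.get(c.target_id, []) if u != BACKGROUND
            ]
            planted_hosts = [u for u in hosts if (pre, u) in planted]
            post = planted_hosts[0] if planted_hosts else (hosts[0] if hosts else None)
        if post is None or (pre, post) not in planted:
            spurious_pairs.add((pre, post if post else c.target_id))
            continue
        detected_pairs.add((pre, post))
        # prefer the signal-level detection for error measurement
        if (pre, post) not in best or (
            best[(pre, post)].target_kind != "signal" and c.target_kind == "signal"
        ):
            best[(pre, post)] = c

    n_detected = len(detected_pairs) + len(spurious_pairs)
    coupling_precision = len(detected_pairs) / n_detected if n_detected else 1.0
    coupling_recall = len(detected_pairs & planted) / len(planted) if planted else 1.0

    prob_err: dict[tuple[str, str], float] = {}
    lat_err: dict[tuple[str, str], float] = {}
    for pair, c in best.items():
        spec = by_spec[pair]
        prob_err[pair] = abs(c.coupling_probability - truth.realized_probability(*pair))
        pre_sig = sig_by_id[c.reference_id]
        off_pre = pre_sig.anchor_offset_ms
        if c.target_kind == "signal":
            off_post = sig_by_id[c.target_id].anchor_offset_ms
        else:
            post_spec = truth.units[pair[1]]
            off_post = dict(zip(post_spec.electrodes, post_spec.delays_ms))[c.target_id]
        expected = spec.latency_mean_ms + off_post - off_pre
        lat_err[pair] = abs(c.mean_latency_ms - expected)

    return RecoveryScore(
        cohort_precision=cohort_precision,
        cohort_recall=cohort_recall,
        coupling_precision=coupling_precision,
        coupling_recall=coupling_recall,
        probability_errors=prob_err,
        latency_errors=lat_err,
        signal_to_unit=s2u,
        spurious_signals=spurious_signals,
        spurious_pairs=spurious_pairs,
    )


# ---------------------------------------------------------------------------
# canonical study configurations


def _cohort_rows(emap: ElectrodeMap, n_units: int, cohort_size: int) -> list[tuple[str, ...]]:
    """Disjoint electrode cohorts, one per unit, laid out on distinct rows."""
    by_row: dict[str, list[str]] = {}
    for lab in emap.labels:
        by_row.setdefault(lab[0], []).append(lab)
    rows = [r for r in by_row.values() if len(r) >= cohort_size]
    if len(rows) < n_units:
        raise ValueError("electrode map too small for the requested units")
    step = max(1, len(rows) // n_units)
    out = []
    for i in range(n_units):
        row = rows[(i * step) % len(rows)]
        mid = len(row) // 2 - cohort_size // 2
        out.append(tuple(row[mid : mid + cohort_size]))
    return out


def benchmark_config(
    seed: int,
    duration_s: float = 300.0,
    n_units: int = 5,
    rate_hz: float = 2.0,
    cohort_size: int = 3,
    delay_step_ms: float = 0.3,
    jitter_sd_ms: float = 0.015,
    background_rate_hz: float = 0.5,
    coupling_probabilities: tuple[float, ...] = (0.2, 0.8, 0.5, 0.35),
    coupling_latencies_ms: tuple[float, ...] = (2.2, 2.79, 3.2, 2.5),
    latency_sd_ms: float = 0.6,
    electrode_map: ElectrodeMap | None = None,
) -> SimulationConfig:
    """The planted-recovery study condition: a full 120-electrode array,
    5 propagating units, and 4 couplings converging from units 0–3 onto
    unit 4.  Distinct presynaptic units and no chains keep every planted
    coupling direct: siblings with a shared driver would be correlated with
    each other, which a CCG detector cannot distinguish from coupling (the
    common-input ambiguity)."""
    emap = electrode_map or ElectrodeMap.default_120()
    cohorts = _cohort_rows(emap, n_units, cohort_size)
    delays = tuple(delay_step_ms * i for i in range(cohort_size))
    units = tuple(
        UnitSpec(
            unit_id=f"u{i}",
            rate_hz=rate_hz,
            electrodes=cohorts[i],
            delays_ms=delays,
            jitter_sd_ms=jitter_sd_ms,
        )
        for i in range(n_units)
    )
    pre_post = [("u0", "u4"), ("u1", "u4"), ("u2", "u4"), ("u3", "u4")]
    couplings = tuple(
        CouplingSpec(pre, post, p, lat, latency_sd_ms)
        for (pre, post), p, lat in zip(
            pre_post[: len(coupling_probabilities)],
            coupling_probabilities,
            coupling_latencies_ms,
        )
    )
    return SimulationConfig(
        duration_s=duration_s,
        units=units,
        couplings=couplings,
        background_rate_hz=background_rate_hz,
        electrode_map=emap,
        seed=seed,
    )


def null_config(
    seed: int,
    duration_s: float = 300.0,
    n_units: int = 6,
    rate_hz: float = 2.0,
    background_rate_hz: float = 0.5,
    electrode_map: ElectrodeMap | None = None,
) -> SimulationConfig:
    """Independent propagating units only — the false-positive control."""
    emap = electrode_map or ElectrodeMap.grid(6, 5)
    cohorts = _cohort_rows(emap, n_units, 2)
    units = tuple(
        UnitSpec(
            unit_id=f"u{i}",
            rate_hz=rate_hz,
            electrodes=cohorts[i],
            delays_ms=(0.0, 0.3),
        )
        for i in range(n_units)
    )
    return SimulationConfig(
        duration_s=duration_s,
        units=units,
        couplings=(),
        background_rate_hz=background_rate_hz,
        electrode_map=emap,
        seed=seed,
    )


def coupled_pair_config(
    seed: int,
    probability: float = 0.35,
    duration_s: float = 300.0,
    pre_rate_hz: float = 2.0,
    post_rate_hz: float = 0.5,
    latency_mean_ms: float = 2.79,
    latency_sd_ms: float = 0.6,
    background_rate_hz: float = 0.0,
) -> SimulationConfig:
    """One presynaptic propagating unit driving one follower unit on a
    single electrode — the shuffle-control scenario.  The follower's low
    intrinsic rate reflects the coupled electrodes of interest being
    dominated by the coupled unit."""
    emap = ElectrodeMap.grid(3, 3)
    pre = UnitSpec("pre", pre_rate_hz, ("A1", "A2"), (0.0, 0.3))
    post = UnitSpec("post", post_rate_hz, ("C3",), (0.0,))
    return SimulationConfig(
        duration_s=duration_s,
        units=(pre, post),
        couplings=(CouplingSpec("pre", "post", probability, latency_mean_ms, latency_sd_ms),),
        background_rate_hz=background_rate_hz,
        electrode_map=emap,
        seed=seed,
    )
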