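"""Short-latency (putatively synaptic) coupling detection.

Reference events (a propagation signal's spike times, or stimulation
onsets) are compared against target spike trains with a one-sided CCG over
0.5–10 ms.  A coupling is accepted when four criteria hold:

1. n1/n > v1      — overall coupling ratio (n1 = total CCG counts,
                    n = reference spike count),
2. n2/n1 > v2     — peak concentration (n2 = largest count sum in any 3 ms
                    moving window),
3. v3 ≤ mean peak-window latency ≤ v4 (ms),
4. sd of all Δt < v5 (ms).

The coupling probability is n2/n — the fraction of reference spikes
followed by a target spike in the CCG peak.  For single-electrode targets a
verification flag is raised when the electrode's amplitude coefficient of
variation exceeds v6, suggesting multi-unit contamination worth manual
review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .mea_io import Recording, SpikeTrain
from .propagation import CCGResult, PropagationSignal, pairwise_ccg, peak_window

__all__ = [
    "CouplingCriteria",
    "Coupling",
    "CouplingRejection",
    "coupling_ccg",
    "evaluate_coupling",
    "detect_all_couplings",
    "stimulation_coupling",
    "coupled_spike_amplitudes",
    "upstream_inputs",
    "UpstreamInput",
]


@dataclass(frozen=True)
class CouplingCriteria:
    """Acceptance thresholds v1–v6 and the CCG geometry.

    Defaults are the calibrated values: v1=0.1, v2=0.57, v3=1 ms, v4=5 ms,
    v5=2.7 ms, v6=0.25, window 0.5–10 ms, peak window 3 ms.  All of them may
    be user defined.
    """

    v1: float = 0.1
    v2: float = 0.57
    v3: float = 1.0
    v4: float = 5.0
    v5: float = 2.7
    v6: float = 0.25
    ccg_window: tuple[float, float] = (0.5, 10.0)
    peak_window_ms: float = 3.0
    bin_width: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.v1 <= 1):
            raise ValueError("v1 must be in (0, 1]")
        if not (0 < self.v2 <= 1):
            raise ValueError("v2 must be in (0, 1]")
        if not self.v3 < self.v4:
            raise ValueError("require v3 < v4")
        if self.v5 <= 0:
            raise ValueError("v5 must be positive")


@dataclass
class Coupling:
    """One accepted directed short-latency relationship."""

    reference_id: str
    target_id: str
    target_kind: str  # "electrode" | "signal" | "stimulation-target"
    coupling_probability: float
    mean_latency_ms: float
    sd_latency_ms: float
    n_coupled: int
    n_ref: int
    flag: int
    coupled_spike_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_probability <= 1.0:
            raise ValueError("coupling probability must be in [0, 1]")


@dataclass
class CouplingRejection:
    """A pair that failed one of the acceptance criteria, with the reason."""

    reference_id: str
    target_id: str
    reason: str
    details: dict = field(default_factory=dict)


def coupling_ccg(
    ref_times,
    target,
    window: tuple[float, float] = (0.5, 10.0),
    bin_width: float = 0.05,
    reference_id: str = "",
    target_id: str = "",
) -> CCGResult:
    """One-sided CCG of target spikes 0.5–10 ms after reference events.

    Deltas retain a mapping back to target spike indices so that coupled
    spikes' amplitudes can be extracted downstream.
    """
    return pairwise_ccg(
        ref_times, target, window=window, bin_width=bin_width,
        reference_id=reference_id, target_id=target_id,
    )


def evaluate_coupling(
    ccg: CCGResult,
    criteria: CouplingCriteria | None = None,
    target_amplitudes: np.ndarray | None = None,
    target_kind: str = "electrode",
) -> Coupling | CouplingRejection:
    """Apply the v1–v5 criteria to a coupling CCG.

    ``target_amplitudes`` are all spike amplitudes on the target electrode
    (signed or absolute); they drive the v6 verification flag and are
    required when the target is a single electrode.
    """
    c = criteria or CouplingCriteria()
    n = ccg.n_ref
    if n == 0:
        return CouplingRejection(ccg.reference_id, ccg.target_id, "no reference spikes")
    n1 = ccg.n_total
    if n1 / n <= c.v1:
        return CouplingRejection(
            ccg.reference_id, ccg.target_id, "coupling ratio below v1",
            {"n1": n1, "n": n, "ratio": n1 / n},
        )
    pw = peak_window(ccg, c.peak_window_ms)
    n2 = pw.n_win
    if n2 / n1 <= c.v2:
        return CouplingRejection(
            ccg.reference_id, ccg.target_id, "peak concentration below v2",
            {"n2": n2, "n1": n1, "ratio": n2 / n1},
        )
    peak_deltas = ccg.deltas[pw.mask]
    mean_latency = float(np.mean(peak_deltas))
    if not (c.v3 <= mean_latency <= c.v4):
        return CouplingRejection(
            ccg.reference_id, ccg.target_id, "mean latency outside [v3, v4]",
            {"mean_latency_ms": mean_latency},
        )
    sd_all = float(np.std(ccg.deltas, ddof=1)) if ccg.deltas.size > 1 else float("nan")
    if not sd_all < c.v5:
        return CouplingRejection(
            ccg.reference_id, ccg.target_id, "latency spread at or above v5",
            {"sd_all_ms": sd_all},
        )
    flag = 0
    if target_kind == "electrode":
        if target_amplitudes is None:
            raise ValueError("target_amplitudes required for electrode targets")
        amps = np.abs(np.asarray(target_amplitudes, dtype=float))
        if amps.size > 1 and np.mean(amps) > 0:
            amp_cv = float(np.std(amps, ddof=1) / np.mean(amps))
            flag = int(amp_cv > c.v6)
    sd_latency = (
        float(np.std(peak_deltas, ddof=1)) if peak_deltas.size > 1 else 0.0
    )
    return Coupling(
        reference_id=ccg.reference_id,
        target_id=ccg.target_id,
        target_kind=target_kind,
        coupling_probability=min(1.0, n2 / n),
        mean_latency_ms=mean_latency,
        sd_latency_ms=sd_latency,
        n_coupled=n2,
        n_ref=n,
        flag=flag,
        coupled_spike_indices=ccg.target_indices[pw.mask]
        if ccg.target_indices.size
        else np.empty(0, dtype=np.intp),
    )


def detect_all_couplings(
    signals: Sequence[PropagationSignal],
    rec: Recording,
    criteria: CouplingCriteria | None = None,
) -> tuple[list[Coupling], list[CouplingRejection]]:
    """Evaluate every (signal, other signal) and (signal, electrode) pair.

    Electrodes belonging to the reference signal's own cohort are excluded.
    Signal targets are evaluated against the target signal's assigned spike
    times.  Returns accepted couplings and a rejection log.
    """
    c = criteria or CouplingCriteria()
    accepted: list[Coupling] = []
    rejected: list[CouplingRejection] = []
    for sig in signals:
        if sig.n_spikes == 0:
            rejected.append(
                CouplingRejection(sig.signal_id, "*", "no reference spikes")
            )
            continue
        own = set(sig.electrode_labels)
        for other in signals:
            if other.signal_id == sig.signal_id:
                continue
            ccg = coupling_ccg(
                sig.spike_times, other.spike_times,
                window=c.ccg_window, bin_width=c.bin_width,
                reference_id=sig.signal_id, target_id=other.signal_id,
            )
            res = evaluate_coupling(ccg, c, target_kind="signal")
            (accepted if isinstance(res, Coupling) else rejected).append(res)
        for label in rec.electrode_map.labels:
            if label in own:
                continue
            tr = rec.train(label)
            if tr.n_spikes == 0:
                continue
            ccg = coupling_ccg(
                sig.spike_times, tr,
                window=c.ccg_window, bin_width=c.bin_width,
                reference_id=sig.signal_id, target_id=label,
            )
            res = evaluate_coupling(
                ccg, c, target_amplitudes=tr.amplitudes, target_kind="electrode"
            )
            (accepted if isinstance(res, Coupling) else rejected).append(res)
    return accepted, rejected


def stimulation_coupling(
    stim_times,
    target: SpikeTrain,
    criteria: CouplingCriteria | None = None,
    blanking_ms: float = 1.5,
    reference_id: str = "stim",
) -> Coupling | CouplingRejection:
    """Coupling evaluation with stimulation onsets as reference events.

    Latency is measured from stimulation onset.  ``blanking_ms`` is the
    post-stimulus interval with no usable voltage data; target spikes
    earlier than the blanking end are masked by raising the lower CCG
    window bound to the blanking end.
    """
    c = criteria or CouplingCriteria()
    lo = max(c.ccg_window[0], blanking_ms)
    ccg = coupling_ccg(
        np.asarray(stim_times, dtype=float), target,
        window=(lo, c.ccg_window[1]), bin_width=c.bin_width,
        reference_id=reference_id, target_id=target.electrode,
    )
    return evaluate_coupling(
        ccg, c, target_amplitudes=target.amplitudes, target_kind="stimulation-target"
    )


def coupled_spike_amplitudes(coupling: Coupling, target: SpikeTrain) -> np.ndarray:
    """|amplitudes| of the peak-window coupled spikes on an electrode
    target, for downstream KS validation."""
    if coupling.target_kind == "signal":
        raise ValueError("coupled_spike_amplitudes applies to electrode targets only")
    return np.abs(target.amplitudes[coupling.coupled_spike_indices])


class UpstreamInput(NamedTuple):
    candidate_id: str
    probability: float
    mean_latency_ms: float
    n_post: int


def upstream_inputs(
    post_times,
    candidates: Mapping[str, np.ndarray | SpikeTrain],
    window: tuple[float, float] = (-10.0, -0.5),
) -> list[UpstreamInput]:
    """Reverse (presynaptic-input) analysis.

    For each candidate, the probability is the fraction of postsynaptic
    spikes with at least one candidate spike inside ``window`` ms before
    them (at-least-one counting, unlike the forward coupling probability).
    The latency is the mean gap to the nearest preceding candidate spike
    among those postsynaptic spikes.
    """
    post = np.asarray(post_times, dtype=float)
    if post.size == 0:
        raise ValueError("no postsynaptic spikes")
    lo_s, hi_s = window[0] * 1e-3, window[1] * 1e-3
    if not lo_s < hi_s:
        raise ValueError("window must be ordered")
    out: list[UpstreamInput] = []
    for cid, cand in candidates.items():
        t = cand.times if isinstance(cand, SpikeTrain) else np.asarray(cand, dtype=float)
        if t.size == 0:
            out.append(UpstreamInput(cid, 0.0, float("nan"), post.size))
            continue
        lo = np.searchsorted(t, post + lo_s, side="left")
        hi = np.searchsorted(t, post + hi_s, side="right")
        has = hi > lo
        prob = float(np.mean(has))
        if np.any(has):
            nearest = t[hi[has] - 1]  # latest candidate spike inside the window
            lat = float(np.mean((post[has] - nearest) * 1e3))
        else:
            lat = float("nan")
        out.append(UpstreamInput(cid, prob, lat, post.size))
    return out
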