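"""Spike detection and burst segmentation on voltage traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import Trace


@dataclass
class SpikeTrain:
    """Detected spike times (ms) with an optional burst partition."""

    times: np.ndarray
    threshold: float
    bursts: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def spikes_per_burst(self) -> list[int]:
        return [len(b) for b in self.bursts]

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def detect_spikes(
    trace: Trace | tuple[np.ndarray, np.ndarray],
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """Upward threshold crossings separated by more than the refractory gap.

    Crossing times are linearly interpolated between samples, so the
    result is robust to non-uniform time grids.
    """
    if isinstance(trace, Trace):
        t, V = trace.t, trace.V
    else:
        t, V = np.asarray(trace[0], float), np.asarray(trace[1], float)
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times: list[float] = []
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if not times or tc - times[-1] > refractory:
            times.append(tc)
    return SpikeTrain(np.array(times), threshold)


def burst_statistics(spikes: SpikeTrain, gap_threshold: float = 30.0) -> SpikeTrain:
    """Partition a spike train into bursts at inter-spike gaps longer than
    ``gap_threshold`` ms; returns the train with ``bursts`` filled in."""
    if len(spikes) == 0:
        raise ValueError("burst statistics require at least one spike")
    bursts: list[list[int]] = [[0]]
    for i in range(1, len(spikes)):
        if spikes.times[i] - spikes.times[i - 1] > gap_threshold:
            bursts.append([])
        bursts[-1].append(i)
    spikes.bursts = bursts
    return spikes


def burst_period(spikes: SpikeTrain) -> float:
    """Mean interval between burst onsets (ms); NaN with fewer than 2 bursts."""
    if len(spikes.bursts) < 2:
        return float("nan")
    onsets = np.array([spikes.times[b[0]] for b in spikes.bursts])
    return float(np.mean(np.diff(onsets)))


def isi_cv(spikes: SpikeTrain) -> float:
    """Coefficient of variation of the inter-spike intervals."""
    isis = spikes.isis
    if isis.size < 2:
        return float("nan")
    return float(np.std(isis) / np.mean(isis))
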