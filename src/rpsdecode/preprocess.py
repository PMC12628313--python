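"""Epoch-level preprocessing: reference, repair, downsample, baseline, bin.

The decoder consumes one feature per channel per 250 ms time bin. This
module turns phase-locked epoch tensors (trials x channels x samples,
including a -200..0 ms baseline window) into that representation:

1. common-average reference (per trial and sample);
2. interpolation of bad channels from neighbors in normalized sensor space;
3. integer-factor downsampling (block-mean by default, no temporal filter);
4. baseline correction over -200..0 ms;
5. averaging post-onset samples into 250 ms bins and concatenating the
   decision (8 bins), response (8 bins) and feedback (4 bins) phases into
   20 bins spanning the 0..5000 ms game time-course.

All operations are pure: they return new tensors and never mutate input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .layout import SensorLayout

__all__ = [
    "Phase",
    "EpochTensor",
    "BinnedFeatures",
    "BIN_WIDTH_MS",
    "rereference_common_average",
    "interpolate_bad_channels",
    "downsample",
    "baseline_correct",
    "bin_phase",
    "bin_and_concat",
]

BIN_WIDTH_MS = 250


class Phase(Enum):
    """The three within-game screens, each decoded relative to its own onset."""

    DECISION = "decision"
    RESPONSE = "response"
    FEEDBACK = "feedback"

    @property
    def duration_ms(self) -> int:
        return {"decision": 2000, "response": 2000, "feedback": 1000}[self.value]

    @property
    def n_bins(self) -> int:
        return self.duration_ms // BIN_WIDTH_MS


#: Concatenation order of phases along the 20-bin axis.
PHASE_ORDER = (Phase.DECISION, Phase.RESPONSE, Phase.FEEDBACK)


@dataclass(frozen=True)
class EpochTensor:
    """Phase-locked epochs: trials x channels x samples with a time axis.

    ``t0_ms`` is the time of the first sample relative to phase onset
    (-200 by convention, giving a baseline window before the screen).
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    phase: Phase
    layout: SensorLayout
    bad_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError(
                f"{self.data.shape[1]} data channels != "
                f"{self.layout.n_channels} layout channels"
            )
        unknown = set(self.bad_channels) - set(self.layout.channel_names)
        if unknown:
            raise ValueError(f"bad channels not in layout: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.t0_ms + np.arange(n) * (1000.0 / self.fs_hz)


def n_samples_for(phase: Phase, fs_hz: float, t0_ms: float = -200.0) -> int:
    """Number of samples covering t0..phase end at the given rate."""
    return int(np.ceil((phase.duration_ms - t0_ms) * fs_hz / 1000.0))


def rereference_common_average(tensor: EpochTensor) -> EpochTensor:
    """Subtract the instantaneous mean over channels from every channel."""
    if tensor.data.shape[1] < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    data = tensor.data - tensor.data.mean(axis=1, keepdims=True)
    return replace(tensor, data=data)


def interpolate_bad_channels(
    tensor: EpochTensor,
    bad: set[str] | frozenset[str] | None = None,
    radius: float = 0.5,
) -> EpochTensor:
    """Replace each bad channel by the unweighted mean of its good neighbors.

    Neighbors are good channels within ``radius`` in the normalized 2-D
    layout. A bad channel with no good neighbor in range cannot be repaired
    and raises an error naming it.
    """
    bad = frozenset(tensor.bad_channels if bad is None else bad)
    if not bad:
        return replace(tensor, bad_channels=frozenset())
    unknown = bad - set(tensor.layout.channel_names)
    if unknown:
        raise ValueError(f"bad channels not in layout: {sorted(unknown)}")

    dist = tensor.layout.distances()
    names = tensor.layout.channel_names
    good_idx = [i for i, c in enumerate(names) if c not in bad]
    data = tensor.data.copy()
    for name in sorted(bad):
        i = tensor.layout.index(name)
        nbrs = [j for j in good_idx if j != i and dist[i, j] <= radius]
        if not nbrs:
            raise ValueError(
                f"channel {name!r} has no good neighbor within {radius}; cannot interpolate"
            )
        data[:, i, :] = tensor.data[:, nbrs, :].mean(axis=1)
    return replace(tensor, data=data, bad_channels=frozenset())


def downsample(
    tensor: EpochTensor, target_fs: float = 256.0, method: str = "blockmean"
) -> EpochTensor:
    """Downsample by an integer factor without temporal filtering.

    ``blockmean`` averages each consecutive group of ``factor`` samples
    (a binning operation, consistent with the later 250 ms averaging);
    ``naive`` keeps every ``factor``-th sample. Trailing samples that do
    not fill a block are dropped.
    """
    ratio = tensor.fs_hz / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"sampling rate {tensor.fs_hz} is not an integer multiple of {target_fs}"
        )
    if factor == 1:
        return tensor
    n_out = tensor.data.shape[2] // factor
    trimmed = tensor.data[:, :, : n_out * factor]
    if method == "blockmean":
        data = trimmed.reshape(*trimmed.shape[:2], n_out, factor).mean(axis=3)
        # block-mean sample represents the center of its block
        t0 = tensor.t0_ms + (factor - 1) / 2 * (1000.0 / tensor.fs_hz)
    elif method == "naive":
        data = trimmed[:, :, ::factor]
        t0 = tensor.t0_ms
    else:
        raise ValueError(f"unknown downsample method {method!r}")
    return replace(tensor, data=data, fs_hz=target_fs, t0_ms=t0)


def baseline_correct(tensor: EpochTensor) -> EpochTensor:
    """Subtract each trial's per-channel mean over the -200..0 ms window."""
    t = tensor.times_ms
    window = (t >= -200.0) & (t < 0.0)
    if tensor.t0_ms > -200.0 or not window.any():
        raise ValueError("epoch lacks the -200..0 ms baseline window")
    baseline = tensor.data[:, :, window].mean(axis=2, keepdims=True)
    return replace(tensor, data=tensor.data - baseline)


@dataclass(frozen=True)
class BinnedFeatures:
    """Decoder feature space: trials x channels x 20 bins over 0..5000 ms."""

    data: np.ndarray
    bin_edges_ms: np.ndarray  # (n_bins + 1,) on the concatenated 0..5000 axis
    phase_of_bin: tuple[Phase, ...]
    layout: SensorLayout
    bin_width_ms: int = BIN_WIDTH_MS

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.phase_of_bin):
            raise ValueError("data must be trials x channels x n_bins")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def bins_of_phase(self, phase: Phase) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.phase_of_bin) if p is phase])


def bin_phase(tensor: EpochTensor) -> np.ndarray:
    """Average post-onset samples into consecutive 250 ms bins.

    Bins are half-open ``[start, start + 250)`` ms, so the onset sample
    belongs to the first bin and baseline samples (t < 0) contribute to
    none.
    """
    t = tensor.times_ms
    n_bins = tensor.phase.n_bins
    out = np.empty((*tensor.data.shape[:2], n_bins))
    for b in range(n_bins):
        lo, hi = b * BIN_WIDTH_MS, (b + 1) * BIN_WIDTH_MS
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(f"no samples fall in bin {lo}..{hi} ms")
        out[:, :, b] = tensor.data[:, :, mask].mean(axis=2)
    return out


def bin_and_concat(
    decision: EpochTensor, response: EpochTensor, feedback: EpochTensor
) -> BinnedFeatures:
    """Concatenate per-phase 250 ms bin means into the 20-bin feature space."""
    tensors = {Phase.DECISION: decision, Phase.RESPONSE: response, Phase.FEEDBACK: feedback}
    for phase, tensor in tensors.items():
        if tensor.phase is not phase:
            raise ValueError(f"tensor passed as {phase.value} is tagged {tensor.phase.value}")
    n_trials = {t.n_trials for t in tensors.values()}
    if len(n_trials) != 1:
        raise ValueError(f"phases have mismatched trial counts: {sorted(n_trials)}")
    layouts = {id(t.layout) for t in tensors.values()}
    if len(layouts) != 1 and len({t.layout.channel_names for t in tensors.values()}) != 1:
        raise ValueError("phases have mismatched layouts")

    blocks = [bin_phase(tensors[p]) for p in PHASE_ORDER]
    phase_of_bin = tuple(p for p in PHASE_ORDER for _ in range(p.n_bins))
    edges = np.arange(len(phase_of_bin) + 1) * float(BIN_WIDTH_MS)
    return BinnedFeatures(
        data=np.concatenate(blocks, axis=2),
        bin_edges_ms=edges,
        phase_of_bin=phase_of_bin,
        layout=decision.layout,
    )
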