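"""Trial averaging and responsiveness filtering of ΔF/F trace sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol, trial_windows, stimulus_window, gap_window
from .synthetic import TraceSet


@dataclass
class TrialAverage:
    """Per-neuron ΔF/F averaged across the protocol's trials (neurons × T_trial)."""

    fish_id: str
    data: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (neurons × T_trial)")
        if self.data.shape[1] != self.protocol.trial_samples:
            raise ValueError(
                f"trial average has {self.data.shape[1]} samples, protocol trial is "
                f"{self.protocol.trial_samples}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial average contains non-finite values")

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def t_trial(self) -> int:
        return self.data.shape[1]


def trial_average(ts: TraceSet) -> TrialAverage:
    """Average each neuron's trace across the protocol's trial windows."""
    p = ts.protocol
    wins = trial_windows(p)
    if wins[-1][2] > ts.n_timepoints:
        raise ValueError(
            f"timeline of {ts.n_timepoints} samples is shorter than the protocol's "
            f"last trial window (ends at {wins[-1][2]})"
        )
    blocks = np.stack([ts.dff[:, a:b] for _, a, b in wins], axis=0)
    return TrialAverage(fish_id=ts.fish_id, data=blocks.mean(axis=0), protocol=p)


def responsive_mask(ts: TraceSet, z_thresh: float = 3.0) -> np.ndarray:
    """Boolean mask of neurons responsive in *every* trial.

    A neuron passes a trial if at least one direction's stimulus-window mean
    ΔF/F strictly exceeds baseline_mean + z_thresh × baseline_SD, where the
    baseline is that trial's pooled within-trial gray-gap samples.
    """
    if z_thresh < 0:
        raise ValueError("z_thresh must be non-negative")
    p = ts.protocol
    mask = np.ones(ts.n_neurons, dtype=bool)
    for _, t0, _ in trial_windows(p):
        gaps = np.concatenate(
            [ts.dff[:, t0 + a : t0 + b] for a, b in (gap_window(p, d) for d in range(p.n_directions))],
            axis=1,
        )
        base_mean = gaps.mean(axis=1)
        base_sd = gaps.std(axis=1, ddof=0)
        stim_means = np.stack(
            [
                ts.dff[:, t0 + a : t0 + b].mean(axis=1)
                for a, b in (stimulus_window(p, d) for d in range(p.n_directions))
            ],
            axis=1,
        )
        mask &= (stim_means > (base_mean + z_thresh * base_sd)[:, None]).any(axis=1)
    return mask


def filter_responsive(ts: TraceSet, z_thresh: float = 3.0) -> TraceSet:
    """Retain only neurons responsive in every trial, preserving their order."""
    mask = responsive_mask(ts, z_thresh)
    return TraceSet(
        fish_id=ts.fish_id,
        genotype=ts.genotype,
        dff=ts.dff[mask],
        protocol=ts.protocol,
    )
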