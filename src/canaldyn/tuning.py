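"""Single-neuron orientation/direction tuning statistics.

Per-direction response amplitudes F(θ) are extracted from trial-averaged
traces as the mean ΔF/F over each grating's on-window minus the mean over
the preceding gray window, rectified at zero.  From F(θ) we compute

    OSI = (F_preferred − F_orthogonal) / (F_preferred + F_orthogonal)
    DSI = (F_preferred − F_opposite)  / (F_preferred + F_opposite)

where F_preferred is the maximal response over the stimulus directions,
F_orthogonal the mean of the responses at ±90° from the preferred
direction, and F_opposite the response at 180°.  The preferred direction is
the circular vector average of the stimulus angles weighted by F(θ), and a
neuron is called direction selective when its DSI strictly exceeds the
threshold (default 1/3, the F_preferred = 2·F_opposite boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, stimulus_window, gap_window
from .traces import TrialAverage

DSI_THRESHOLD = 1.0 / 3.0


@dataclass
class DirectionResponses:
    """Rectified per-direction response amplitudes (neurons × directions)."""

    F: np.ndarray
    directions_deg: np.ndarray
    fish_id: str = ""

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        if self.F.ndim != 2 or self.F.shape[1] != len(self.directions_deg):
            raise ValueError("F must be (neurons × n_directions)")
        if np.any(self.F < 0):
            raise ValueError("responses must be rectified (non-negative)")


@dataclass
class PolarHistogram:
    """Counts of preferred directions binned at the stimulus directions."""

    bin_centers_deg: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    group: str = ""
    empty: bool = False


def direction_responses(ta: TrialAverage, p: StimulusProtocol | None = None) -> DirectionResponses:
    """Extract F(θ) from a trial average.

    The baseline for direction θ is the *later half* of the gray gap of the
    previous direction slot (the early gap samples still carry indicator
    decay from that slot's response); for the first direction, whose grating
    opens the trial, the baseline wraps circularly to the trial's final gap.
    Differences below numerical precision are treated as zero before
    rectification.
    """
    p = p if p is not None else ta.protocol
    if p.trial_samples != ta.t_trial:
        raise ValueError("trial average length does not match the protocol")
    n_dir = p.n_directions
    scale = max(1.0, float(np.abs(ta.data).max()))
    F = np.zeros((ta.n_neurons, n_dir))
    for d in range(n_dir):
        s0, s1 = stimulus_window(p, d)
        g0, g1 = gap_window(p, (d - 1) % n_dir)
        stim = ta.data[:, s0:s1].mean(axis=1)
        if g1 > g0:
            base = ta.data[:, g0 + (g1 - g0) // 2 : g1].mean(axis=1)
        else:
            base = np.zeros(ta.n_neurons)
        diff = stim - base
        diff[np.abs(diff) <= 1e-12 * scale] = 0.0
        F[:, d] = np.maximum(diff, 0.0)
    return DirectionResponses(F=F, directions_deg=np.asarray(p.directions_deg), fish_id=ta.fish_id)


def _preferred_index(F: np.ndarray) -> np.ndarray:
    """Index of the maximal response per neuron; ties go to the lowest index."""
    return np.argmax(F, axis=1)


def _offset_index(directions_deg: np.ndarray, pref_idx: np.ndarray, offset_deg: float) -> np.ndarray:
    """Index of the direction nearest preferred + offset (circular)."""
    n = len(directions_deg)
    target = (directions_deg[pref_idx] + offset_deg) % 360.0
    diff = np.abs((directions_deg[None, :] - target[:, None] + 180.0) % 360.0 - 180.0)
    return np.argmin(diff, axis=1) if n > 1 else np.zeros(len(pref_idx), dtype=int)


def osi(dr: DirectionResponses, orthogonal_mode: str = "both") -> np.ndarray:
    """Orientation selectivity index per neuron; NaN where all F(θ) are zero.

    ``orthogonal_mode='both'`` (default) takes F_orthogonal as the mean of
    the responses at +90° and −90° from preferred; ``'plus'`` uses +90° only.
    """
    if orthogonal_mode not in ("both", "plus"):
        raise ValueError("orthogonal_mode must be 'both' or 'plus'")
    pref = _preferred_index(dr.F)
    rows = np.arange(dr.F.shape[0])
    f_pref = dr.F[rows, pref]
    plus = dr.F[rows, _offset_index(dr.directions_deg, pref, 90.0)]
    if orthogonal_mode == "both":
        minus = dr.F[rows, _offset_index(dr.directions_deg, pref, -90.0)]
        f_orth = 0.5 * (plus + minus)
    else:
        f_orth = plus
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (f_pref - f_orth) / (f_pref + f_orth)
    out[f_pref == 0] = np.nan
    return out


def dsi(dr: DirectionResponses) -> np.ndarray:
    """Direction selectivity index per neuron; NaN where all F(θ) are zero."""
    pref = _preferred_index(dr.F)
    rows = np.arange(dr.F.shape[0])
    f_pref = dr.F[rows, pref]
    f_opp = dr.F[rows, _offset_index(dr.directions_deg, pref, 180.0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (f_pref - f_opp) / (f_pref + f_opp)
    out[f_pref == 0] = np.nan
    return out


def preferred_direction(dr: DirectionResponses) -> tuple[np.ndarray, np.ndarray]:
    """Response-weighted circular mean direction and mean resultant length.

    The preferred angle is arg Σ_θ F(θ)·e^{iθ} in [0, 360); the resultant
    length is |Σ F e^{iθ}| / Σ F.  Neurons with zero total response or a
    vanishing resultant (antipodal cancellation) get NaN angles.
    """
    theta = np.deg2rad(dr.directions_deg)
    z = dr.F @ np.exp(1j * theta)
    total = dr.F.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        resultant = np.abs(z) / total
    angle = np.rad2deg(np.angle(z)) % 360.0
    undefined = (total == 0) | np.isclose(np.abs(z), 0.0, atol=1e-12)
    angle[undefined] = np.nan
    resultant[total == 0] = np.nan
    return angle, resultant


def tuning_table(
    ta: TrialAverage,
    p: StimulusProtocol | None = None,
    dsi_threshold: float = DSI_THRESHOLD,
    orthogonal_mode: str = "both",
) -> pd.DataFrame:
    """Per-neuron tuning statistics as a tidy DataFrame.

    Columns: fish_id, neuron, osi, dsi, preferred_direction_deg,
    resultant_length, is_direction_selective (strict ``dsi > threshold``).
    """
    dr = direction_responses(ta, p)
    osi_v = osi(dr, orthogonal_mode=orthogonal_mode)
    dsi_v = dsi(dr)
    angle, resultant = preferred_direction(dr)
    selective = np.where(np.isnan(dsi_v), False, dsi_v > dsi_threshold)
    return pd.DataFrame(
        dict(
            fish_id=ta.fish_id,
            neuron=np.arange(ta.n_neurons),
            osi=osi_v,
            dsi=dsi_v,
            preferred_direction_deg=angle,
            resultant_length=resultant,
            is_direction_selective=selective,
        )
    )


def direction_histogram(
    table: pd.DataFrame,
    directions_deg: np.ndarray,
    group: str = "",
) -> PolarHistogram:
    """Polar histogram of preferred directions of direction-selective cells.

    Each selective neuron's preferred direction is assigned to the nearest
    stimulus direction (bins of one inter-stimulus step centered on the
    stimulus angles); cells may be pooled across animals by concatenating
    their tables first.
    """
    if table.empty:
        raise ValueError("tuning table is empty")
    directions_deg = np.asarray(directions_deg, dtype=float)
    sel = table[table["is_direction_selective"] & table["preferred_direction_deg"].notna()]
    counts = np.zeros(len(directions_deg), dtype=int)
    if len(sel) == 0:
        return PolarHistogram(
            bin_centers_deg=directions_deg, counts=counts,
            fractions=counts.astype(float), group=group, empty=True,
        )
    angles = sel["preferred_direction_deg"].to_numpy()
    diff = np.abs((directions_deg[None, :] - angles[:, None] + 180.0) % 360.0 - 180.0)
    nearest = np.argmin(diff, axis=1)
    for b in nearest:
        counts[b] += 1
    return PolarHistogram(
        bin_centers_deg=directions_deg,
        counts=counts,
        fractions=counts / counts.sum(),
        group=group,
        empty=False,
    )
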