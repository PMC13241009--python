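"""Latent neural dynamics: PCA neural modes and cross-individual alignment.

A *neural mode* is a principal-component axis of the trial-averaged
population activity; its *latent dynamics* is the time course obtained by
projecting the (per-neuron mean-centered) activity onto that axis.  Modes
fitted independently per individual come out in an individual-specific
order and with an arbitrary sign, so comparing individuals requires
placing modes in a common order and sign.  That is done by maximizing the
summed absolute Pearson correlation between mode time courses under an
optimal one-to-one assignment, then flipping each matched mode to the sign
of its correlation with the reference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .synthetic import TraceSet
from .traces import TrialAverage
from .protocol import trial_windows


@dataclass
class LatentModel:
    """PCA decomposition of one individual's trial-averaged activity.

    ``loadings`` (neurons × k) has orthonormal columns; ``dynamics``
    (k × T_trial) are the projections of the centered data (PCA scores over
    time); ``variance_explained`` holds the top-k fractions of total
    variance (descending); ``all_variance_explained`` the full spectrum,
    which sums to 1.
    """

    loadings: np.ndarray
    dynamics: np.ndarray
    variance_explained: np.ndarray
    k: int
    neuron_means: np.ndarray
    fish_id: str = ""
    all_variance_explained: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class ModeSet:
    """k mode time courses (k × T) with provenance, in some order and sign."""

    modes: np.ndarray
    fish_id: str = ""
    trial: str = "trial-averaged"

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        if self.modes.ndim != 2:
            raise ValueError("modes must be 2-D (k × T)")
        if not np.all(np.isfinite(self.modes)):
            raise ValueError("modes contain non-finite values")

    @property
    def k(self) -> int:
        return self.modes.shape[0]


@dataclass
class AlignmentResult:
    """Mode matching of a target ModeSet onto a reference.

    ``permutation[m]`` is the index of the target mode matched to reference
    mode m; ``signs[m]`` the ±1 flip applied to it; ``per_mode_r[m]`` the
    resulting non-negative Pearson correlation; ``score`` their sum.
    """

    permutation: np.ndarray
    signs: np.ndarray
    per_mode_r: np.ndarray
    score: float
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]


def fit_latent(ta: TrialAverage, k: int = 5) -> LatentModel:
    """PCA of a trial average: time samples are observations, neurons variables.

    Centering is per-neuron mean subtraction only (ΔF/F is already a
    normalized unit, so no variance scaling).
    """
    n, T = ta.data.shape
    if n < 2:
        raise ValueError("at least 2 neurons are required for PCA")
    if k < 1 or k > min(n, T):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(neurons={n}, T={T})")
    X = ta.data.T  # (T × neurons)
    pca = PCA(n_components=min(n, T), svd_solver="full")
    scores = pca.fit_transform(X)
    return LatentModel(
        loadings=pca.components_[:k].T.copy(),
        dynamics=scores[:, :k].T.copy(),
        variance_explained=pca.explained_variance_ratio_[:k].copy(),
        k=k,
        neuron_means=pca.mean_.copy(),
        fish_id=ta.fish_id,
        all_variance_explained=pca.explained_variance_ratio_.copy(),
    )


def project_matrix(data: np.ndarray, model: LatentModel, fish_id: str = "", trial: str = "") -> ModeSet:
    """Center a (neurons × T) block with the model's means and project it."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] != model.loadings.shape[0]:
        raise ValueError(
            f"data has {data.shape[0]} neurons but the model was fit on "
            f"{model.loadings.shape[0]}"
        )
    Y = model.loadings.T @ (data - model.neuron_means[:, None])
    return ModeSet(modes=Y, fish_id=fish_id or model.fish_id, trial=trial or "projection")


def project_trial(ts: TraceSet, trial_index: int, model: LatentModel) -> ModeSet:
    """Latent dynamics of one trial under a model fit on the trial average."""
    wins = trial_windows(ts.protocol)
    if not (0 <= trial_index < len(wins)):
        raise IndexError(f"trial_index {trial_index} out of range")
    _, a, b = wins[trial_index]
    return project_matrix(ts.dff[:, a:b], model, fish_id=ts.fish_id, trial=f"trial-{trial_index}")


def _corr_matrix(target: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations of every target mode with every reference mode.

    Zero-variance modes get correlation 0 (flagged) rather than NaN.
    """
    t_sd = target.std(axis=1)
    r_sd = reference.std(axis=1)
    degenerate = (t_sd[:, None] == 0) | (r_sd[None, :] == 0)
    tc = target - target.mean(axis=1, keepdims=True)
    rc = reference - reference.mean(axis=1, keepdims=True)
    denom = np.outer(t_sd, r_sd) * target.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (tc @ rc.T) / denom
    C[~np.isfinite(C)] = 0.0
    return C, degenerate


def align_modes(target: ModeSet, reference: ModeSet) -> AlignmentResult:
    """Best order-and-sign matching of target modes onto reference modes.

    Solves the optimal assignment maximizing Σ_m |r(target_perm(m), ref_m)|;
    the sign of each matched mode is the sign of its (pre-flip) correlation
    (zero → +1).  Guaranteed to score at least the identity matching.
    """
    if target.modes.shape != reference.modes.shape:
        raise ValueError("target and reference must have equal k and T")
    C, degenerate = _corr_matrix(target.modes, reference.modes)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(target.k, dtype=int)
    perm[cols] = rows
    chosen = C[perm, np.arange(target.k)]
    signs = np.where(chosen < 0, -1, 1).astype(int)
    per_mode_r = np.abs(chosen)
    flags = degenerate[perm, np.arange(target.k)]
    if flags.any():
        warnings.warn("zero-variance mode encountered during alignment; its r is 0")
    return AlignmentResult(
        permutation=perm,
        signs=signs,
        per_mode_r=per_mode_r,
        score=float(per_mode_r.sum()),
        degenerate=flags,
    )


def apply_alignment(target: ModeSet, result: AlignmentResult) -> ModeSet:
    """Reorder and sign-flip a ModeSet according to an AlignmentResult."""
    modes = result.signs[:, None] * target.modes[result.permutation]
    return ModeSet(modes=modes, fish_id=target.fish_id, trial=target.trial)


def brute_force_align(target: ModeSet, reference: ModeSet) -> AlignmentResult:
    """Exhaustive search over all k! × 2^k order/sign combinations.

    Independent oracle for :func:`align_modes`; intended for k ≤ 5.
    """
    C, degenerate = _corr_matrix(target.modes, reference.modes)
    k = target.k
    best_score, best_perm = -np.inf, None
    for perm in itertools.permutations(range(k)):
        score = float(np.abs(C[list(perm), np.arange(k)]).sum())
        if score > best_score + 1e-12:
            best_score, best_perm = score, perm
    perm = np.array(best_perm, dtype=int)
    chosen = C[perm, np.arange(k)]
    # the best sign pattern is the one matching each correlation's sign
    signs = np.where(chosen < 0, -1, 1).astype(int)
    return AlignmentResult(
        permutation=perm,
        signs=signs,
        per_mode_r=np.abs(chosen),
        score=best_score,
        degenerate=degenerate[perm, np.arange(k)],
    )


def mean_modes(modesets: list[ModeSet], fish_id: str = "group-average") -> ModeSet:
    """Element-wise mean of a list of equally shaped ModeSets."""
    if not modesets:
        raise ValueError("cannot average an empty list of ModeSets")
    stack = np.stack([m.modes for m in modesets], axis=0)
    return ModeSet(modes=stack.mean(axis=0), fish_id=fish_id, trial="average")


def align_to_reference(modesets: list[ModeSet], reference: ModeSet) -> list[ModeSet]:
    """Align every ModeSet to a common reference and apply the alignments."""
    return [apply_alignment(m, align_modes(m, reference)) for m in modesets]


def canonical_order(
    cohort_modes: list[ModeSet], reference_policy: str | int | ModeSet = "first"
) -> tuple[list[ModeSet], ModeSet]:
    """Place a cohort's modes in a common order and sign.

    Two-pass procedure: align everyone to a seed individual, average the
    aligned dynamics, then re-align everyone to that average.  Returns the
    aligned ModeSets (input order preserved) and the final group-average
    ModeSet.

    ``reference_policy``: ``"first"`` uses the individual with the lowest
    sorted fish_id as seed; an integer indexes the input list; a ModeSet is
    used directly as the pass-1 reference.
    """
    if not cohort_modes:
        raise ValueError("canonical_order requires at least one individual")
    if isinstance(reference_policy, ModeSet):
        seed = reference_policy
    elif reference_policy == "first":
        seed = min(cohort_modes, key=lambda m: m.fish_id)
    elif isinstance(reference_policy, int):
        seed = cohort_modes[reference_policy]
    else:
        raise ValueError(f"unknown reference policy: {reference_policy!r}")
    pass1 = align_to_reference(cohort_modes, seed)
    avg1 = mean_modes(pass1)
    pass2 = align_to_reference(cohort_modes, avg1)
    return pass2, mean_modes(pass2)
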