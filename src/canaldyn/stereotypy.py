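"""Correlation-based stereotypy (canalization) statistics for cohorts.

All quantities are Pearson correlations between latent-dynamics time
courses: within an individual across trials (response reliability), between
each individual and a group-average reference (stereotypy relative to wild
type), between all pairs of individuals within a group (within-group
spread, the canalization readout), and between whole-group averages
(whether averaging suppresses individual variation).  Pooling all
within-group pairwise correlations across the retained modes gives the
cumulative distribution used to compare genotypes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.distributions.empirical_distribution import ECDF

from .synthetic import TraceSet
from .latent import LatentModel, ModeSet, mean_modes, project_trial


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, with zero-variance inputs yielding 0 (warned) instead of NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance time course in correlation; r set to 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def trial_consistency(ts: TraceSet, model: LatentModel) -> np.ndarray:
    """Per-mode mean Pearson r over all pairs of single-trial dynamics.

    Each trial is projected onto the individual's trial-averaged loadings;
    with the standard three trials this averages the three pairwise
    correlations.
    """
    n_trials = ts.protocol.n_trials
    if n_trials < 2:
        raise ValueError("trial_consistency requires at least 2 trials")
    projections = [project_trial(ts, t, model).modes for t in range(n_trials)]
    k = model.k
    out = np.zeros(k)
    pairs = list(itertools.combinations(range(n_trials), 2))
    for m in range(k):
        out[m] = np.mean([safe_pearson(projections[a][m], projections[b][m]) for a, b in pairs])
    return out


def reference_correlations(
    cohort: list[ModeSet],
    reference_group: list[ModeSet] | None = None,
    loo: bool = False,
) -> np.ndarray:
    """Correlate each individual's modes with a group-average reference.

    ``loo=True`` (control group): individual i is compared with the average
    of the *other* n−1 members of its own cohort.  ``loo=False``: each
    individual is compared with the full average of ``reference_group``.
    Returns an (n_fish × k) array of r values.
    """
    if loo:
        if len(cohort) < 2:
            raise ValueError("leave-one-out requires at least 2 individuals")
        refs = [
            mean_modes([m for j, m in enumerate(cohort) if j != i]) for i in range(len(cohort))
        ]
    else:
        if not reference_group:
            raise ValueError("reference_group is required when loo=False")
        ref = mean_modes(reference_group)
        refs = [ref] * len(cohort)
    k = cohort[0].k
    out = np.zeros((len(cohort), k))
    for i, (m, ref) in enumerate(zip(cohort, refs)):
        for mode in range(k):
            out[i, mode] = safe_pearson(m.modes[mode], ref.modes[mode])
    return out


def pairwise_within_group(cohort: list[ModeSet]) -> np.ndarray:
    """All C(n,2) within-group Pearson correlations, per mode (k × n_pairs)."""
    n = len(cohort)
    if n < 2:
        raise ValueError("pairwise correlations require at least 2 individuals")
    k = cohort[0].k
    pairs = list(itertools.combinations(range(n), 2))
    out = np.zeros((k, len(pairs)))
    for j, (a, b) in enumerate(pairs):
        for m in range(k):
            out[m, j] = safe_pearson(cohort[a].modes[m], cohort[b].modes[m])
    return out


def group_average_and_compare(
    group_a: list[ModeSet], group_b: list[ModeSet]
) -> tuple[ModeSet, ModeSet, np.ndarray]:
    """Average dynamics within each group, then correlate the averages per mode.

    Both groups must already be in the same canonical mode order.
    """
    avg_a = mean_modes(group_a, fish_id="groupA-average")
    avg_b = mean_modes(group_b, fish_id="groupB-average")
    if avg_a.modes.shape != avg_b.modes.shape:
        raise ValueError("groups have mismatched mode count or length")
    r = np.array(
        [safe_pearson(avg_a.modes[m], avg_b.modes[m]) for m in range(avg_a.k)]
    )
    return avg_a, avg_b, r


def pooled_distribution(pairwise_r: np.ndarray) -> tuple[np.ndarray, ECDF]:
    """Pool per-mode pairwise correlations and return them with their ECDF."""
    pairwise_r = np.asarray(pairwise_r, dtype=float)
    if pairwise_r.ndim == 1:
        pairwise_r = pairwise_r[None, :]
    if pairwise_r.shape[0] < 1:
        raise ValueError("at least one mode is required")
    pooled = pairwise_r.ravel()
    return pooled, ECDF(pooled)


@dataclass
class StereotypyReport:
    """All correlation-based canalization statistics for one group.

    Arrays are indexed fish × mode or mode × pair; ``cross_group_r`` is set
    when the group has been compared with a control average.
    """

    group: str
    fish_ids: list[str]
    trial_to_trial_rbar: np.ndarray | None = None   # (n_fish × k)
    r_to_reference: np.ndarray | None = None        # (n_fish × k)
    pairwise_r: np.ndarray | None = None            # (k × n_pairs)
    group_average: ModeSet | None = None
    pooled_r: np.ndarray | None = None
    cross_group_r: np.ndarray | None = None         # (k,)
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (statistic, fish/pair, mode)."""
        rows = []
        k = None
        if self.trial_to_trial_rbar is not None:
            k = self.trial_to_trial_rbar.shape[1]
            for i, fid in enumerate(self.fish_ids):
                for m in range(k):
                    rows.append(
                        dict(group=self.group, fish_a=fid, fish_b="", mode=m + 1,
                             r=self.trial_to_trial_rbar[i, m], statistic_type="trial_to_trial")
                    )
        if self.r_to_reference is not None:
            k = self.r_to_reference.shape[1]
            for i, fid in enumerate(self.fish_ids):
                for m in range(k):
                    rows.append(
                        dict(group=self.group, fish_a=fid, fish_b="reference", mode=m + 1,
                             r=self.r_to_reference[i, m], statistic_type="r_to_reference")
                    )
        if self.pairwise_r is not None:
            k = self.pairwise_r.shape[0]
            pairs = list(itertools.combinations(range(len(self.fish_ids)), 2))
            for m in range(k):
                for j, (a, b) in enumerate(pairs):
                    rows.append(
                        dict(group=self.group, fish_a=self.fish_ids[a], fish_b=self.fish_ids[b],
                             mode=m + 1, r=self.pairwise_r[m, j], statistic_type="pairwise")
                    )
        if self.cross_group_r is not None:
            for m, r in enumerate(self.cross_group_r):
                rows.append(
                    dict(group=self.group, fish_a="group-average", fish_b="control-average",
                         mode=m + 1, r=r, statistic_type="cross_group")
                )
        return pd.DataFrame(rows)
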