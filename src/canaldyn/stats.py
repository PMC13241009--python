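"""Hypothesis tests for group comparisons.

Three tests cover the pipeline's needs: Dunnett's many-to-one comparison of
group means against a control (family-wise error controlled), Dunn's
rank-based pairwise post-hoc test for comparing correlation distributions,
and the two-sample Watson U² test for circular (preferred-direction)
distributions, with a permutation p-value as the primary result and the
asymptotic series p-value reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    method: str
    statistic: np.ndarray
    p_value: np.ndarray
    comparisons: list[str]
    adjustment: str = "none"
    extras: dict = field(default_factory=dict)


def _as_groups(groups, min_n: int) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(out):
        if len(g) < min_n:
            raise ValueError(f"group {i} has {len(g)} values; at least {min_n} required")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return out


def dunnett_many_to_one(
    groups: list[np.ndarray], control: np.ndarray, labels: list[str] | None = None
) -> TestResult:
    """Dunnett's test of each treatment group against a shared control.

    Two-sided, family-wise error controlled via the multivariate-t
    distribution of the Dunnett statistics (scipy implementation).
    """
    groups = _as_groups(groups, min_n=2)
    control = np.asarray(control, dtype=float).ravel()
    if len(control) < 2:
        raise ValueError("control group needs at least 2 values")
    res = sps.dunnett(*groups, control=control)
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    return TestResult(
        method="dunnett",
        statistic=np.atleast_1d(res.statistic),
        p_value=np.atleast_1d(res.pvalue),
        comparisons=[f"{lab} vs control" for lab in labels],
        adjustment="family-wise (Dunnett)",
    )


def dunn_pairwise(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
) -> TestResult:
    """Dunn's post-hoc test: pairwise mean-rank comparisons with tie correction.

    Data are ranked jointly (Kruskal–Wallis framework); each pair (i, j) is
    compared by z = (R̄_i − R̄_j) / SE with
    SE² = (N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j), T = Σ(t³ − t) over tie
    groups.  Two-sided normal p-values, Bonferroni-adjusted by default.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    groups = _as_groups(groups, min_n=1)
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts))
    tie_term = T / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(groups)), 2))
    z = np.zeros(len(pairs))
    p = np.zeros(len(pairs))
    for m, (i, j) in enumerate(pairs):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z[m] = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p[m] = 2.0 * sps.norm.sf(abs(z[m])) if se > 0 else 1.0
    if adjust == "bonferroni":
        p = np.minimum(p * len(pairs), 1.0)
    return TestResult(
        method="dunn",
        statistic=z,
        p_value=p,
        comparisons=[f"{labels[i]} vs {labels[j]}" for i, j in pairs],
        adjustment=adjust,
        extras={"mean_ranks": mean_ranks},
    )


def watson_u2_statistic(angles_a: np.ndarray, angles_b: np.ndarray) -> float:
    """Two-sample Watson U² statistic from angles in degrees.

    With the combined sample sorted, d_j is the difference of the two
    empirical CDFs at each point and U² = (n·m/N²)(Σ d_j² − N·d̄²); the
    centering on d̄ makes the statistic invariant to rotating both samples
    by a common angle (choice of circular origin).
    """
    a = np.asarray(angles_a, dtype=float) % 360.0
    b = np.asarray(angles_b, dtype=float) % 360.0
    n, m = len(a), len(b)
    N = n + m
    combined = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n), np.zeros(m)])
    order = np.argsort(combined, kind="stable")
    is_a = labels[order]
    d = np.cumsum(is_a) / n - np.cumsum(1.0 - is_a) / m
    return float(n * m / N**2 * (np.sum(d**2) - N * d.mean() ** 2))


def _watson_asymptotic_p(u2: float, terms: int = 100) -> float:
    """Asymptotic tail probability 2·Σ (−1)^{k−1} exp(−2 k² π² U²)."""
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(np.clip(p, 0.0, 1.0))


def watsons_u2(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """Two-sample Watson U² test with a label-permutation p-value.

    The permutation p-value (1 + #{perm stat ≥ observed}) / (R + 1) is the
    primary result; the large-sample series p-value is reported in extras.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a = np.asarray(angles_a, dtype=float).ravel() % 360.0
    b = np.asarray(angles_b, dtype=float).ravel() % 360.0
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 angles")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("angles must be finite")
    n, m = len(a), len(b)
    N = n + m
    combined = np.concatenate([a, b])
    order = np.argsort(combined, kind="stable")
    base_labels = np.concatenate([np.ones(n), np.zeros(m)])
    observed = float(
        n * m / N**2
        * (
            np.sum((np.cumsum(base_labels[order]) / n
                    - np.cumsum(1.0 - base_labels[order]) / m) ** 2)
            - N * ((np.cumsum(base_labels[order]) / n
                    - np.cumsum(1.0 - base_labels[order]) / m).mean()) ** 2
        )
    )
    rng = np.random.default_rng(seed)
    # permute labels over the *sorted* positions: vectorized over replicates
    perm_labels = np.tile(base_labels, (n_permutations, 1))
    perm_labels = rng.permuted(perm_labels, axis=1)
    ca = np.cumsum(perm_labels, axis=1) / n
    cb = np.cumsum(1.0 - perm_labels, axis=1) / m
    d = ca - cb
    stats_perm = n * m / N**2 * (np.sum(d**2, axis=1) - N * d.mean(axis=1) ** 2)
    p_perm = (1.0 + np.sum(stats_perm >= observed - 1e-12)) / (n_permutations + 1.0)
    return TestResult(
        method="watson_u2",
        statistic=np.array([observed]),
        p_value=np.array([p_perm]),
        comparisons=["A vs B"],
        adjustment="none",
        extras={
            "p_asymptotic": _watson_asymptotic_p(observed),
            "n_permutations": n_permutations,
        },
    )
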