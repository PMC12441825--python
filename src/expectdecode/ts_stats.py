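"""Cluster-mass permutation statistics for subject x cell x time panels.

Per-timepoint 2x2 within-subject ANOVAs are thresholded at a cluster-forming
alpha; maximal runs of temporally adjacent suprathreshold timepoints form
clusters whose mass is the sum of F-values inside the run.  The null
distribution is the per-permutation maximum cluster mass (0 when a
permutation produces no cluster), where each permutation shuffles the four
condition labels within every subject — once per permutation, reused across
all timepoints so temporal autocorrelation is preserved.  A cluster is
significant when its mass exceeds the 95th percentile of the null; corrected
p-values use the (1 + k) / (1 + N) estimator.

A one-sample (sign-flipping) variant supports testing accuracy time courses
against chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .behav_stats import CONTRASTS, EFFECTS, jzs_bf10_from_t

__all__ = [
    "pointwise_f",
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
    "one_sample_cluster",
    "pointwise_bf",
]


def _contrast_f_panel(panel: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """F(t) of a 1-df contrast for a (subjects, 4, time) panel."""
    d = np.einsum("sct,c->st", panel, coef)
    return _one_sample_f(d)


def _one_sample_f(d: np.ndarray) -> np.ndarray:
    """Squared one-sample t along the first axis; 0/0 maps to F = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sd > 0.0, (mean * np.sqrt(n) / np.where(sd > 0, sd, 1.0)) ** 2,
                     np.where(mean == 0.0, 0.0, np.inf))
    return F


def pointwise_f(panel) -> dict:
    """Per-timepoint 2x2 RM-ANOVA F values, ``{effect: F(t)}``.

    ``panel`` is (n_subjects, 4, n_timepoints) with cells ordered
    [VEME, VEMU, VUME, VUMU].
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 3 or panel.shape[1] != 4:
        raise ValueError("panel must be (n_subjects, 4, n_timepoints)")
    if np.isnan(panel).any():
        raise ValueError("panel contains missing entries")
    return {e: _contrast_f_panel(panel, CONTRASTS[e]) for e in EFFECTS}


def _max_run_mass(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Maximum run-sum of ``x`` over maximal True-runs of ``mask`` (last axis).

    Vectorized over leading axes via the cumulative-sum / running-reset
    trick; rows without any True get 0.
    """
    x = np.where(mask, x, 0.0)
    r = np.cumsum(x, axis=-1)
    # value of the cumsum at the most recent sub-threshold position (the run
    # start baseline); r is nondecreasing so a running max recovers it
    resets = np.where(mask, -np.inf, r)
    base = np.maximum.accumulate(resets, axis=-1)
    base = np.maximum(base, 0.0)  # before the first reset the baseline is 0
    masses = np.where(mask, r - base, 0.0)
    return masses.max(axis=-1)


def _clusters_from_mask(F: np.ndarray, mask: np.ndarray):
    """(start, end_exclusive, mass) for each maximal suprathreshold run."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e), float(F[s:e].sum())) for s, e in zip(starts, ends)]


@dataclass
class Cluster:
    start: int
    end: int            # exclusive sample index
    mass: float
    p_corrected: float
    significant: bool


@dataclass
class ClusterResult:
    effect: str
    F: np.ndarray
    mask: np.ndarray
    clusters: list
    null_max_masses: np.ndarray
    f_threshold: float
    mass_threshold: float = field(default=np.nan)


def _permutation_indices(rng, n_perm: int, n_subjects: int) -> np.ndarray:
    """(n_perm, n_subjects, 4) permutations of the four cell labels."""
    return np.argsort(rng.random((n_perm, n_subjects, 4)), axis=-1)


def cluster_permutation(
    panel,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
    chunk: int = 250,
) -> dict:
    """Cluster-mass permutation 2x2 RM-ANOVA over time.

    Returns ``{effect: ClusterResult}`` for the two main effects and the
    interaction.  All three effects share the same within-subject shuffles
    of the four cell labels (omnibus exchangeability under the global null).
    Degenerate all-identical panels yield empty cluster lists, not errors.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 3 or panel.shape[1] != 4:
        raise ValueError("panel must be (n_subjects, 4, n_timepoints)")
    n_subj = panel.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    f_crit = float(stats.f.isf(cluster_alpha, 1, n_subj - 1))

    observed = pointwise_f(panel)
    coef_mat = np.stack([CONTRASTS[e] for e in EFFECTS])  # (3, 4)

    null = np.empty((len(EFFECTS), n_perm))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = _permutation_indices(rng, m, n_subj)          # (m, subj, 4)
        # permuted contrast coefficients per subject: coef[perm[s, c]] applied
        # to the fixed panel equals applying coef to the shuffled panel
        pc = coef_mat[:, perms]                               # (3, m, subj, 4)
        d = np.einsum("epsc,sct->epst", pc, panel)            # (3, m, subj, t)
        n = n_subj
        mean = d.mean(axis=2)
        sd = d.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Fp = np.where(sd > 0.0, (mean * np.sqrt(n)) ** 2 / np.where(sd > 0, sd, 1.0) ** 2, 0.0)
        null[:, done:done + m] = _max_run_mass(Fp, Fp > f_crit)
        done += m

    out = {}
    for ei, effect in enumerate(EFFECTS):
        F = observed[effect]
        mask = F > f_crit
        raw = _clusters_from_mask(F, mask)
        nulls = null[ei]
        thresh = float(np.percentile(nulls, 95))
        clusters = [
            Cluster(
                start=s, end=e, mass=mass,
                p_corrected=float((1 + np.sum(nulls >= mass)) / (1 + n_perm)),
                significant=bool(mass > thresh),
            )
            for s, e, mass in raw
        ]
        out[effect] = ClusterResult(
            effect=effect, F=F, mask=mask, clusters=clusters,
            null_max_masses=nulls, f_threshold=f_crit, mass_threshold=thresh,
        )
    return out


def one_sample_cluster(
    values,
    mu: float = 0.0,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
    chunk: int = 500,
) -> ClusterResult:
    """Sign-flipping cluster-mass test of (subjects, time) values against mu.

    The statistic is the squared one-sample t (two-sided); each permutation
    flips the sign of every subject's whole deviation time course.
    """
    d = np.asarray(values, dtype=float) - mu
    if d.ndim != 2:
        raise ValueError("values must be (n_subjects, n_timepoints)")
    n_subj = d.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    f_crit = float(stats.f.isf(cluster_alpha, 1, n_subj - 1))

    F = _one_sample_f(d)
    mask = F > f_crit

    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_subj))
        flipped = signs[:, :, None] * d[None, :, :]
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            Fp = np.where(sd > 0.0, (mean * np.sqrt(n_subj)) ** 2 / np.where(sd > 0, sd, 1.0) ** 2, 0.0)
        null[done:done + m] = _max_run_mass(Fp, Fp > f_crit)
        done += m

    thresh = float(np.percentile(null, 95))
    clusters = [
        Cluster(start=s, end=e, mass=mass,
                p_corrected=float((1 + np.sum(null >= mass)) / (1 + n_perm)),
                significant=bool(mass > thresh))
        for s, e, mass in _clusters_from_mask(F, mask)
    ]
    return ClusterResult(effect="vs_mu", F=F, mask=mask, clusters=clusters,
                         null_max_masses=null, f_threshold=f_crit,
                         mass_threshold=thresh)


def pointwise_bf(panel) -> dict:
    """Per-timepoint JZS paired Bayes factors, ``{effect: BF10(t)}``.

    Each effect's BF comes from the one-sample t of its subject-level
    contrast at that timepoint (main effects: difference of marginal means).
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 3 or panel.shape[1] != 4:
        raise ValueError("panel must be (n_subjects, 4, n_timepoints)")
    n = panel.shape[0]
    out = {}
    for effect in EFFECTS:
        d = np.einsum("sct,c->st", panel, CONTRASTS[effect])
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        bf = np.empty(d.shape[1])
        for t in range(d.shape[1]):
            if sd[t] == 0.0:
                bf[t] = np.inf if mean[t] != 0.0 else np.nan
            else:
                bf[t] = jzs_bf10_from_t(mean[t] * np.sqrt(n) / sd[t], n)
        out[effect] = bf
    return out
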