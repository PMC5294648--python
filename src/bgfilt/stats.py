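"""Statistics for filtered networks: barcode contrasts, trial-relabeling
permutation tests, group permutation, d-prime behavioral scores, and
behavior correlations.

All permutation p-values use the add-one estimator
``p = (1 + #{|t_null| >= |t_obs|}) / (1 + n_perm)`` and are two-sided on the
absolute statistic.  Trial equalization is re-applied inside every
permutation iteration with iteration-derived sub-seeds so the null mirrors
the observed pipeline exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .core_network import (
    SubjectData,
    _equalize_indices,
    _negative_distance_raw,
    _pearson_raw,
)
from .filtration import BettiCurve, _merge_eps_bipartite, _slm_bipartite

__all__ = [
    "BehavioralRecord",
    "DiffMaxValue",
    "PermutationResult",
    "FlaggedPair",
    "ElementwisePermutationResult",
    "diff_max",
    "network_type_contrast",
    "barcode_condition_permutation",
    "slm_condition_permutation",
    "slm_paired_t",
    "subject_slm_difference",
    "group_permutation",
    "dprime",
    "bonferroni",
    "behavior_correlation",
]

GOOD_PERFORMER_CUTOFF = 1.0  # d-prime threshold splitting good/poor performers


# ---------------------------------------------------------------------------
# behavioral scoring
# ---------------------------------------------------------------------------

def _guarded_rate(count: int, total: int) -> float:
    """Hit/false-alarm rate with the 1/(2N) extreme-rate guard."""
    if total < 1:
        raise ValueError("rate totals must be >= 1")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    rate = count / total
    lo, hi = 1.0 / (2 * total), 1.0 - 1.0 / (2 * total)
    return min(max(rate, lo), hi)


def dprime(hit_count: int, hit_total: int, fa_count: int, fa_total: int) -> float:
    """Standard signal-detection d-prime: z(hit rate) - z(fa rate).

    Rates of exactly 0 or 1 are replaced by ``1/(2N)`` and ``1 - 1/(2N)``
    before the normal-quantile transform.
    """
    hr = _guarded_rate(hit_count, hit_total)
    fr = _guarded_rate(fa_count, fa_total)
    return float(sps.norm.ppf(hr) - sps.norm.ppf(fr))


@dataclass
class BehavioralRecord:
    """Per-subject recognition counts and the derived d-prime scores."""

    subject_id: str
    r_hits: int
    r_trials: int
    nr_hits: int
    nr_trials: int
    false_alarms: int
    new_trials: int

    def __post_init__(self) -> None:
        for count, total, name in (
            (self.r_hits, self.r_trials, "r_hits"),
            (self.nr_hits, self.nr_trials, "nr_hits"),
            (self.false_alarms, self.new_trials, "false_alarms"),
        ):
            if total < 1:
                raise ValueError(f"{name}: trial total must be >= 1")
            if not 0 <= count <= total:
                raise ValueError(f"{name}: count {count} outside [0, {total}]")

    @property
    def compliance(self) -> float:
        """Instruction compliance: d-prime of R-hits minus NR-hits."""
        return dprime(self.r_hits, self.r_trials, self.nr_hits, self.nr_trials)

    @property
    def memory_performance(self) -> float:
        """Memory performance: d-prime of R-hits minus false alarms."""
        return dprime(self.r_hits, self.r_trials, self.false_alarms, self.new_trials)

    @property
    def performer_group(self) -> str:
        return "good" if self.memory_performance > GOOD_PERFORMER_CUTOFF else "poor"


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, p * m_tests)


def behavior_correlation(values: Sequence[float], behavior: Sequence[float],
                         m_tests: int) -> tuple[float, float, float]:
    """Pearson correlation with two-sided t-based p and Bonferroni correction.

    Returns ``(r, p, p_bonferroni)``; raises on zero-variance input.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(behavior, dtype=float)
    if v.shape != b.shape or v.ndim != 1:
        raise ValueError("values and behavior must be equal-length 1-D sequences")
    if len(v) < 4:
        raise ValueError("behavior_correlation needs n >= 4")
    if np.ptp(v) == 0 or np.ptp(b) == 0:
        raise ValueError("behavior_correlation: zero-variance input")
    res = sps.pearsonr(v, b)
    return float(res.statistic), float(res.pvalue), bonferroni(float(res.pvalue), m_tests)


# ---------------------------------------------------------------------------
# barcode contrast
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffMaxValue:
    """Signed Betti-curve difference at the filtration value where its
    absolute value peaks."""

    value: float
    epsilon_at_max: float


def _diff_max_from_eps(eps_a: np.ndarray, eps_b: np.ndarray) -> tuple[float, float]:
    """diff_max of two Betti curves given their sorted merge epsilons.

    The signed difference beta_a - beta_b is evaluated on the union of
    breakpoints (plus 0); step functions change nowhere else.  Ties on the
    absolute value resolve to the smallest epsilon.
    """
    grid = np.unique(np.concatenate([[0.0], eps_a, eps_b]))
    # beta_a - beta_b = (p - #merges_a<=eps) - (p - #merges_b<=eps)
    d = (np.searchsorted(eps_b, grid, side="right")
         - np.searchsorted(eps_a, grid, side="right"))
    k = int(np.argmax(np.abs(d)))  # argmax returns the earliest maximizer
    return float(d[k]), float(grid[k])


def diff_max(curve_a: BettiCurve, curve_b: BettiCurve) -> DiffMaxValue:
    """Signed difference of two Betti-0 curves where |difference| is maximal.

    Both curves must describe partitions of the same size.  Evaluation on
    the union of the two breakpoint sets covers every step change, so the
    result matches any dense-grid refinement.
    """
    if curve_a.size != curve_b.size:
        raise ValueError("diff_max: curves must cover partitions of equal size")
    value, eps = _diff_max_from_eps(curve_a.breakpoints, curve_b.breakpoints)
    return DiffMaxValue(value=value, epsilon_at_max=eps)


def network_type_contrast(per_subject_diffmax: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank of per-subject diff_max values vs 0.

    All-zero input returns ``(0.0, 1.0)`` by convention.
    """
    v = np.asarray(per_subject_diffmax, dtype=float)
    if len(v) < 5:
        raise ValueError("network_type_contrast needs n >= 5 subjects")
    if np.all(v == 0):
        return 0.0, 1.0
    res = sps.wilcoxon(v, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# permutation engines
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    sidedness: str = "two-sided"


@dataclass(frozen=True)
class FlaggedPair:
    cue_roi: str
    item_roi: str
    mean_diff: float
    se: float
    diff_range: tuple[float, float]
    t: float
    p: float
    sign: str


@dataclass
class ElementwisePermutationResult:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    observed_t: np.ndarray
    mean_diff: np.ndarray
    se: np.ndarray
    p: np.ndarray
    flagged: list
    n_perm: int
    alpha: float
    seed: int
    subject_diffs: np.ndarray = None  # (n_subjects, p, q) per-subject differences


def _one_sample_t(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    m = v.mean()
    s = v.std(ddof=1)
    if s == 0.0:
        return 0.0 if m == 0.0 else math.copysign(math.inf, m)
    return float(m / (s / math.sqrt(len(v))))


def _elementwise_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 with 0/0 -> 0 and m/0 -> signed inf."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    s = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / math.sqrt(n))
    zero_var = s == 0.0
    if zero_var.any():
        t = np.asarray(t)
        t[zero_var] = np.where(m[zero_var] == 0.0, 0.0,
                               np.copysign(np.inf, m[zero_var]))
    return t


def _add_one_p(null_abs_ge: np.ndarray | int, n_perm: int):
    return (1 + null_abs_ge) / (1 + n_perm)


def _cohort_arrays(cohort: Sequence[SubjectData]):
    out = []
    for s in cohort:
        out.append((
            s.table("R", "cue_alpha").values,
            s.table("R", "item_gamma").values,
            s.table("NR", "cue_alpha").values,
            s.table("NR", "item_gamma").values,
        ))
    return out


def _equalized_pair(cue_r, item_r, cue_nr, item_nr, rng):
    """Apply the trial-equalization subsample to one subject's two
    conditions (shared kept indices across band epochs)."""
    idx_r, idx_nr = _equalize_indices(len(cue_r), len(cue_nr), rng)
    if idx_r is not None:
        cue_r, item_r = cue_r[idx_r], item_r[idx_r]
    if idx_nr is not None:
        cue_nr, item_nr = cue_nr[idx_nr], item_nr[idx_nr]
    return cue_r, item_r, cue_nr, item_nr


def _bipartite_dist_raw(cue, item):
    return _negative_distance_raw(_pearson_raw(cue, item))


_PARTITION_AXIS = {"cue_alpha": 0, "item_gamma": 1}


def _subject_diffmax(cue_r, item_r, cue_nr, item_nr, axis: int, rng) -> float:
    cue_r, item_r, cue_nr, item_nr = _equalized_pair(cue_r, item_r, cue_nr, item_nr, rng)
    eps_r = _merge_eps_bipartite(_bipartite_dist_raw(cue_r, item_r))[axis]
    eps_nr = _merge_eps_bipartite(_bipartite_dist_raw(cue_nr, item_nr))[axis]
    return _diff_max_from_eps(eps_r, eps_nr)[0]


def _subject_slm_diff(cue_r, item_r, cue_nr, item_nr, rng) -> np.ndarray:
    cue_r, item_r, cue_nr, item_nr = _equalized_pair(cue_r, item_r, cue_nr, item_nr, rng)
    slm_r = _slm_bipartite(_bipartite_dist_raw(cue_r, item_r))
    slm_nr = _slm_bipartite(_bipartite_dist_raw(cue_nr, item_nr))
    return slm_r - slm_nr


def _pseudo_split(pooled_cue, pooled_item, n_r, rng):
    """Randomly re-assign a subject's pooled trials into two pseudo
    conditions of the original sizes."""
    perm = rng.permutation(len(pooled_cue))
    a, b = perm[:n_r], perm[n_r:]
    return pooled_cue[a], pooled_item[a], pooled_cue[b], pooled_item[b]


def _trial_relabeling_engine(
    cohort: Sequence[SubjectData],
    subject_stat: Callable,
    reduce_stat: Callable,
    n_perm: int,
    seed: int,
    progress: Callable[[int, int], None] | None = None,
    consume: Callable[[np.ndarray], None] | None = None,
):
    """Shared observed + trial-relabeling-null machinery.

    ``subject_stat(cue_r, item_r, cue_nr, item_nr, rng)`` maps one subject's
    (possibly pseudo) condition tables to a per-subject quantity;
    ``reduce_stat`` maps the stacked per-subject quantities to the test
    statistic.  If ``consume`` is given each null statistic is handed to it
    and not stored (keeps elementwise nulls out of memory); otherwise the
    null statistics are collected and returned.  Returns
    (observed_subject_values, observed_stat, null_stats list or None).
    """
    if len(cohort) < 3:
        raise ValueError("permutation tests need at least 3 subjects")
    arrays = _cohort_arrays(cohort)
    n_subj = len(arrays)
    pooled = [
        (np.vstack([cr, cn]), np.vstack([ir, inn]), len(cr))
        for cr, ir, cn, inn in arrays
    ]
    ss = np.random.SeedSequence(seed)
    obs_ss, null_ss = ss.spawn(2)
    obs_vals = [
        subject_stat(*arrays[i], np.random.default_rng(child))
        for i, child in enumerate(obs_ss.spawn(n_subj))
    ]
    obs_vals = np.asarray(obs_vals)
    observed = reduce_stat(obs_vals)
    null_stats = [] if consume is None else None
    for k, child in enumerate(null_ss.spawn(n_perm)):
        subj_children = child.spawn(n_subj)
        vals = []
        for i in range(n_subj):
            rng = np.random.default_rng(subj_children[i])
            cue, item, n_r = pooled[i]
            pr_c, pr_i, pn_c, pn_i = _pseudo_split(cue, item, n_r, rng)
            vals.append(subject_stat(pr_c, pr_i, pn_c, pn_i, rng))
        stat = reduce_stat(np.asarray(vals))
        if consume is None:
            null_stats.append(stat)
        else:
            consume(stat)
        if progress is not None:
            progress(k + 1, n_perm)
    return obs_vals, observed, null_stats


def barcode_condition_permutation(
    cohort: Sequence[SubjectData],
    partition: str,
    n_perm: int = 200,
    seed: int = 0,
    progress: Callable[[int, int], None] | None = None,
) -> PermutationResult:
    """Trial-relabeling permutation test of the R-vs-NR barcode contrast.

    Observed statistic: one-sample t across subjects of per-subject
    ``diff_max`` between the R and NR Betti curves of the given partition.
    Null: within every subject, R and NR trials are pooled and randomly
    re-split into pseudo-conditions of the original sizes (equalization
    re-applied), and the full pipeline is recomputed.
    """
    if partition not in _PARTITION_AXIS:
        raise ValueError(f"partition must be one of {tuple(_PARTITION_AXIS)}")
    axis = _PARTITION_AXIS[partition]

    def subject_stat(cr, ir, cn, inn, rng):
        return _subject_diffmax(cr, ir, cn, inn, axis, rng)

    _, t_obs, null = _trial_relabeling_engine(
        cohort, subject_stat, _one_sample_t, n_perm, seed, progress
    )
    null = np.asarray(null, dtype=float)
    p = float(_add_one_p(int(np.sum(np.abs(null) >= abs(t_obs))), n_perm))
    return PermutationResult(observed_stat=float(t_obs), null_stats=null,
                             p_value=p, n_perm=n_perm, seed=seed)


def subject_slm_difference(cohort: Sequence[SubjectData], seed: int = 0) -> np.ndarray:
    """Per-subject SLM_R - SLM_NR matrices, stacked (n_subjects, p, q).

    Uses the same observed-pipeline seeding as the permutation engines.
    """
    arrays = _cohort_arrays(cohort)
    obs_ss, _ = np.random.SeedSequence(seed).spawn(2)
    return np.stack([
        _subject_slm_diff(*arrays[i], np.random.default_rng(child))
        for i, child in enumerate(obs_ss.spawn(len(arrays)))
    ])


def slm_paired_t(cohort: Sequence[SubjectData], seed: int = 0):
    """Observed elementwise paired t of SLM_R - SLM_NR (no null).

    Returns ``(t_matrix, subject_diffs)``.
    """
    diffs = subject_slm_difference(cohort, seed)
    return _elementwise_t(diffs), diffs


def _flag_pairs(row_labels, col_labels, diffs, t_obs, p, alpha, sign_labels):
    lo_tag, hi_tag = sign_labels
    mean_diff = diffs.mean(axis=0)
    flagged = []
    for i, j in zip(*np.nonzero(p < alpha)):
        d_ij = diffs[:, i, j]
        flagged.append(FlaggedPair(
            cue_roi=row_labels[i],
            item_roi=col_labels[j],
            mean_diff=float(mean_diff[i, j]),
            se=float(d_ij.std(ddof=1) / math.sqrt(len(d_ij))),
            diff_range=(float(d_ij.min()), float(d_ij.max())),
            t=float(t_obs[i, j]),
            p=float(p[i, j]),
            sign=lo_tag if mean_diff[i, j] < 0 else hi_tag,
        ))
    flagged.sort(key=lambda f: (f.p, -abs(f.t)))
    return flagged


def slm_condition_permutation(
    cohort: Sequence[SubjectData],
    n_perm: int = 5000,
    alpha: float = 0.0005,
    seed: int = 0,
    progress: Callable[[int, int], None] | None = None,
) -> ElementwisePermutationResult:
    """Elementwise paired-t permutation test of SLM differences (R vs NR).

    Per (cue ROI, item ROI): observed paired t across subjects of
    ``SLM_R - SLM_NR``; null by trial relabeling, recomputing SLMs every
    iteration.  Two-sided elementwise add-one p-values; pairs with
    ``p < alpha`` are listed with a sign tag ("R < NR" = stronger negative
    coupling under R).  No multiple-comparison correction.
    """
    row_labels = cohort[0].roi_labels
    col_labels = cohort[0].roi_labels

    # The engine reduces the observed statistic before any null draw, so a
    # stateful reduce/consume pair lets the null t-matrices be folded into
    # exceedance counts without ever storing them.
    state: dict = {}

    def reduce_stat(vals: np.ndarray) -> np.ndarray:
        t = _elementwise_t(vals)
        if "abs_obs" not in state:  # first call = observed data
            state["abs_obs"] = np.abs(t)
            state["counts"] = np.zeros_like(t, dtype=int)
        return t

    def consume(t_null: np.ndarray) -> None:
        state["counts"] += np.abs(t_null) >= state["abs_obs"]

    diffs, t_obs, _ = _trial_relabeling_engine(
        cohort, _subject_slm_diff, reduce_stat, n_perm, seed, progress, consume
    )
    p = _add_one_p(state["counts"], n_perm)
    flagged = _flag_pairs(row_labels, col_labels, diffs, t_obs, p, alpha,
                          ("R < NR", "R > NR"))
    return ElementwisePermutationResult(
        row_labels=row_labels, col_labels=col_labels,
        observed_t=t_obs, mean_diff=diffs.mean(axis=0),
        se=diffs.std(axis=0, ddof=1) / math.sqrt(len(diffs)),
        p=p, flagged=flagged, n_perm=n_perm, alpha=alpha, seed=seed,
        subject_diffs=diffs,
    )


def group_permutation(
    per_subject_condition_diffs: np.ndarray,
    groups: Sequence[str],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    n_perm: int = 5000,
    alpha: float = 0.0005,
    seed: int = 0,
) -> ElementwisePermutationResult:
    """Good-vs-poor pseudo-group permutation on SLM condition differences.

    Observed statistic per (i, j): difference between group means of
    ``(SLM_R - SLM_NR)[i, j]``.  Null: permute subject group labels,
    preserving group sizes.  Two-sided elementwise add-one p-values.
    """
    diffs = np.asarray(per_subject_condition_diffs, dtype=float)
    g = np.asarray([str(x) == "good" for x in groups])
    if len(g) != len(diffs):
        raise ValueError("groups and matrices must align")
    if g.all() or (~g).all():
        raise ValueError("group_permutation: both groups must be non-empty")
    obs = diffs[g].mean(axis=0) - diffs[~g].mean(axis=0)
    abs_obs = np.abs(obs)
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(obs, dtype=int)
    for _ in range(n_perm):
        gp = g[rng.permutation(len(g))]
        stat = diffs[gp].mean(axis=0) - diffs[~gp].mean(axis=0)
        counts += np.abs(stat) >= abs_obs
    p = _add_one_p(counts, n_perm)
    t_obs = _group_t(diffs, g)
    flagged = _flag_pairs(tuple(row_labels), tuple(col_labels), diffs, t_obs, p,
                          alpha, ("good < poor", "good > poor"))
    return ElementwisePermutationResult(
        row_labels=tuple(row_labels), col_labels=tuple(col_labels),
        observed_t=t_obs, mean_diff=obs,
        se=diffs.std(axis=0, ddof=1) / math.sqrt(len(diffs)),
        p=p, flagged=flagged, n_perm=n_perm, alpha=alpha, seed=seed,
        subject_diffs=diffs,
    )


def _group_t(diffs: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Welch-style two-sample t per element (descriptive companion to the
    mean-difference permutation statistic)."""
    a, b = diffs[g], diffs[~g]
    na, nb = len(a), len(b)
    num = a.mean(axis=0) - b.mean(axis=0)
    if na < 2 or nb < 2:
        return np.where(num == 0.0, 0.0, np.sign(num) * np.inf)
    den = np.sqrt(a.var(axis=0, ddof=1) / na + b.var(axis=0, ddof=1) / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    zero = den == 0.0
    if zero.any():
        t = np.asarray(t)
        t[zero] = np.where(num[zero] == 0.0, 0.0, np.copysign(np.inf, num[zero]))
    return t
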