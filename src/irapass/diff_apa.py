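"""Differential APA calling between sample groups.

The effect size is the difference of group-mean PDUI,
``dPDUI = Mean_PDUI_GroupA - Mean_PDUI_GroupB`` (with group A = responders
by convention, so dPDUI > 0 means the 3'-UTR is shortened in
non-responders).  Significance comes from a two-sided label-permutation
test on dPDUI; Benjamini-Hochberg q-values are reported alongside, but the
default calling rule is the published one: |dPDUI| >= 0.1 (inclusive) and
raw permutation p < 0.05 (exclusive).

Also provides the one-vs-rest variant over the three T-cell-state patient
subgroups (TA/TS/TN), detection of PDUI gradients across the ordered
subgroups, and subgroup assignment from T-cell population proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from irapass.io import PduiTable, ValidationError

__all__ = [
    "GroupMeans",
    "DifferentialApaResult",
    "group_mean_pdui",
    "delta_pdui",
    "permutation_pvalues",
    "bh_fdr",
    "call_differential",
    "run_differential",
    "one_vs_rest_differential",
    "gradient_events",
    "assign_tcell_subgroup",
]

logger = logging.getLogger("irapass")

DELTA_THRESHOLD = 0.1
P_THRESHOLD = 0.05
MIN_PER_GROUP = 3

_TIE_EPS = 1e-12  # float slack when comparing |delta_perm| >= |delta_obs|


@dataclass
class GroupMeans:
    """Per-event mean PDUI per group, over non-missing values only.

    ``usable`` flags events with at least ``min_per_group`` non-missing
    values in every group; the rest are excluded from downstream calling.
    """

    means: pd.DataFrame          # events x groups
    counts: pd.DataFrame         # events x groups, non-missing sample counts
    usable: pd.Series            # bool per event
    group_labels: list[str]


@dataclass
class DifferentialApaResult:
    """Per-event differential call table.

    Columns: delta_pdui, perm_p, fdr_q, direction (shortened / lengthened /
    none, relative to group B = non-responders), n_used_a, n_used_b.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str

    def called(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "none"]


def _group_matrix(labels: pd.Series, groups: list[str]) -> np.ndarray:
    """Samples x groups 0/1 indicator matrix."""
    return np.stack([(labels == g).to_numpy(float) for g in groups], axis=1)


def group_mean_pdui(pdui: PduiTable, labels: pd.Series,
                    min_per_group: int = MIN_PER_GROUP) -> GroupMeans:
    """Average PDUI within each group, skipping missing values."""
    labels = labels.reindex(pdui.sample_ids).dropna().astype(str)
    groups = sorted(labels.unique())
    if not groups:
        raise ValidationError("no labelled samples")
    values = pdui.data[labels.index].to_numpy()
    present = ~np.isnan(values)
    filled = np.where(present, values, 0.0)
    ind = _group_matrix(labels, groups)
    counts = present.astype(float) @ ind
    if np.any(counts.sum(axis=0) == 0):
        empty = [g for g, c in zip(groups, counts.sum(axis=0)) if c == 0]
        raise ValidationError(f"group(s) with zero samples: {empty}")
    with np.errstate(invalid="ignore"):
        means = (filled @ ind) / counts
    means[counts == 0] = np.nan
    idx = pdui.data.index
    usable = pd.Series((counts >= min_per_group).all(axis=1), index=idx)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("group_mean_pdui: %d events excluded (<%d non-missing per group)",
                    n_dropped, min_per_group)
    return GroupMeans(
        means=pd.DataFrame(means, index=idx, columns=groups),
        counts=pd.DataFrame(counts.astype(int), index=idx, columns=groups),
        usable=usable,
        group_labels=groups,
    )


def delta_pdui(means: GroupMeans, group_a: str, group_b: str) -> pd.Series:
    """Signed per-event difference Mean_PDUI(A) - Mean_PDUI(B)."""
    for g in (group_a, group_b):
        if g not in means.group_labels:
            raise ValidationError(f"unknown group label {g!r}; have {means.group_labels}")
    return (means.means[group_a] - means.means[group_b]).rename("delta_pdui")


def _masked_group_deltas(values: np.ndarray, assign_a: np.ndarray) -> np.ndarray:
    """dPDUI for many label assignments at once.

    ``values`` is events x samples (NaN = missing); ``assign_a`` is
    samples x B with 1 marking membership of group A.  Returns events x B.
    """
    present = ~np.isnan(values)
    filled = np.where(present, values, 0.0)
    pres = present.astype(float)
    a_sum = filled @ assign_a
    a_cnt = pres @ assign_a
    tot_sum = filled.sum(axis=1, keepdims=True)
    tot_cnt = pres.sum(axis=1, keepdims=True)
    b_sum = tot_sum - a_sum
    b_cnt = tot_cnt - a_cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a_sum / a_cnt - b_sum / b_cnt
    out[(a_cnt == 0) | (b_cnt == 0)] = np.nan
    return out


def permutation_pvalues(pdui: PduiTable, labels: pd.Series, group_a: str, group_b: str,
                        B: int = 1000, seed: int = 0,
                        exhaustive: str = "auto") -> pd.Series:
    """Two-sided empirical p-values for dPDUI by joint label permutation.

    Labels are permuted jointly across all events, preserving between-event
    correlation.  When the number of distinct group-A subsets C(n, n_a) is
    <= B (and ``exhaustive`` is not ``"never"``), every relabelling is
    enumerated and p = #{|d_perm| >= |d_obs|} / C(n, n_a) — an exact test
    whose count includes the observed assignment, so p > 0.  Otherwise B
    random permutations are drawn and the add-one estimator
    p = (1 + #{|d_perm| >= |d_obs|}) / (B + 1) is used.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if B < 100:
        logger.warning("permutation_pvalues: B=%d is small; p-value floor is %.3f",
                       B, 1 / (B + 1))
    labels = labels.reindex(pdui.sample_ids).dropna().astype(str)
    labels = labels[labels.isin([group_a, group_b])]
    n_a = int((labels == group_a).sum())
    n_b = int((labels == group_b).sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(f"each group needs >= 2 samples (got {n_a} vs {n_b})")
    values = pdui.data[labels.index].to_numpy()
    n = n_a + n_b

    obs_assign = (labels == group_a).to_numpy(float)[:, None]
    delta_obs = _masked_group_deltas(values, obs_assign)[:, 0]

    n_exact = math.comb(n, n_a)
    use_exact = exhaustive == "always" or (exhaustive == "auto" and n_exact <= B)
    if use_exact:
        assign = np.zeros((n, n_exact))
        for j, combo in enumerate(itertools.combinations(range(n), n_a)):
            assign[list(combo), j] = 1.0
        denom = n_exact
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        assign = np.zeros((n, B))
        for j in range(B):
            assign[rng.permutation(n)[:n_a], j] = 1.0
        denom = B + 1
        add_one = 1

    # GEMM-friendly blocks keep memory flat for large event counts
    abs_obs = np.abs(delta_obs)[:, None]
    count = np.zeros(values.shape[0])
    block = 256
    for start in range(0, assign.shape[1], block):
        deltas = _masked_group_deltas(values, assign[:, start:start + block])
        count += np.nansum(np.abs(deltas) >= abs_obs - _TIE_EPS, axis=1)

    p = (add_one + count) / denom
    p = np.where(np.isnan(delta_obs), np.nan, np.clip(p, 0, 1))
    return pd.Series(p, index=pdui.data.index, name="perm_p")


def bh_fdr(p) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = pd.Series(p).astype(float)
    finite = p.dropna()
    if np.any((finite <= 0) | (finite > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    q = pd.Series(np.nan, index=p.index, name="fdr_q")
    if len(finite):
        q.loc[finite.index] = multipletests(finite.to_numpy(), method="fdr_bh")[1]
    return q


def call_differential(delta: pd.Series, p: pd.Series,
                      delta_threshold: float = DELTA_THRESHOLD,
                      p_threshold: float = P_THRESHOLD,
                      use_fdr: bool = False,
                      group_a: str = "PRCR", group_b: str = "PDSD",
                      counts: pd.DataFrame | None = None,
                      usable: pd.Series | None = None) -> DifferentialApaResult:
    """Apply the two-criterion calling rule.

    Called iff |dPDUI| >= ``delta_threshold`` (boundary inclusive) and
    p < ``p_threshold`` (exclusive).  With ``use_fdr`` the second criterion
    uses BH q instead of raw p.  Direction follows the A = responders
    convention: dPDUI > 0 => shortened (in non-responders), < 0 =>
    lengthened.
    """
    if len(delta) != len(p) or not delta.index.equals(p.index):
        raise ValidationError("delta and p must be aligned on the same events")
    q = bh_fdr(p)
    crit_p = q if use_fdr else p
    called = (delta.abs() >= delta_threshold) & (crit_p < p_threshold)
    if usable is not None:
        called &= usable.reindex(delta.index).fillna(False).astype(bool)
    called &= delta.notna() & crit_p.notna()
    direction = np.where(~called, "none", np.where(delta > 0, "shortened", "lengthened"))
    table = pd.DataFrame({
        "delta_pdui": delta,
        "perm_p": p,
        "fdr_q": q,
        "direction": direction,
    }, index=delta.index)
    if counts is not None:
        table["n_used_a"] = counts[group_a]
        table["n_used_b"] = counts[group_b]
    return DifferentialApaResult(table=table, group_a=group_a, group_b=group_b)


def run_differential(pdui: PduiTable, labels: pd.Series,
                     group_a: str = "PRCR", group_b: str = "PDSD",
                     B: int = 1000, seed: int = 0,
                     delta_threshold: float = DELTA_THRESHOLD,
                     p_threshold: float = P_THRESHOLD,
                     use_fdr: bool = False,
                     min_per_group: int = MIN_PER_GROUP) -> DifferentialApaResult:
    """Convenience wrapper: group means -> dPDUI -> permutation p -> calls."""
    sub = labels.reindex(pdui.sample_ids).dropna()
    sub = sub[sub.isin([group_a, group_b])]
    means = group_mean_pdui(pdui, sub, min_per_group=min_per_group)
    delta = delta_pdui(means, group_a, group_b)
    p = permutation_pvalues(pdui, sub, group_a, group_b, B=B, seed=seed)
    return call_differential(delta, p, delta_threshold, p_threshold, use_fdr,
                             group_a, group_b, counts=means.counts,
                             usable=means.usable)


def one_vs_rest_differential(pdui: PduiTable, subgroups: pd.Series,
                             B: int = 1000, seed: int = 0,
                             **kwargs) -> dict[str, DifferentialApaResult]:
    """Run the two-group machinery for each subgroup against the pooled rest.

    ``subgroups`` maps samples to TA / TS / TN; results are keyed by the
    focal subgroup.
    """
    subgroups = subgroups.reindex(pdui.sample_ids).dropna().astype(str)
    expected = {"TA", "TS", "TN"}
    missing = expected - set(subgroups.unique())
    if missing:
        raise ValidationError(f"missing subgroup(s): {sorted(missing)}")
    out = {}
    for k, focal in enumerate(sorted(expected)):
        labels = subgroups.map(lambda g: focal if g == focal else "rest")
        out[focal] = run_differential(pdui, labels, group_a=focal, group_b="rest",
                                      B=B, seed=seed + k, **kwargs)
    return out


def gradient_events(means: GroupMeans, order: tuple[str, str, str] = ("TA", "TS", "TN"),
                    delta_threshold: float = DELTA_THRESHOLD) -> pd.DataFrame:
    """Events whose group means are strictly monotone across ``order``.

    Reported iff the three means are strictly increasing or strictly
    decreasing along the stated order and max - min >= ``delta_threshold``.
    """
    for g in order:
        if g not in means.group_labels:
            raise ValidationError(f"group {g!r} absent from means")
    m = means.means[list(order)].to_numpy()
    ok = ~np.isnan(m).any(axis=1) & means.usable.to_numpy()
    inc = (m[:, 1] > m[:, 0]) & (m[:, 2] > m[:, 1])
    dec = (m[:, 1] < m[:, 0]) & (m[:, 2] < m[:, 1])
    span = m.max(axis=1) - m.min(axis=1)
    keep = ok & (inc | dec) & (span >= delta_threshold)
    out = pd.DataFrame({
        "direction": np.where(inc, "increasing", "decreasing")[keep],
        "span": span[keep],
    }, index=means.means.index[keep])
    for g in order:
        out[f"mean_{g}"] = means.means.loc[out.index, g]
    return out


def assign_tcell_subgroup(proportions: pd.DataFrame,
                          population_classes: dict[str, str],
                          tol: float = 1e-6) -> pd.Series:
    """Label each sample TA / TS / TN by its dominant T-cell state class.

    ``population_classes`` maps each population column to one of
    {activation, suppression, naive}.  The label is the class with the
    largest summed proportion; exact ties break by the fixed priority
    TA > TS > TN.
    """
    missing = [p for p in proportions.columns if p not in population_classes]
    if missing:
        raise ValidationError(f"populations missing from class map: {missing}")
    sums = proportions.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValidationError("per-sample proportions must sum to 1")
    class_to_label = {"activation": "TA", "suppression": "TS", "naive": "TN"}
    priority = ["TA", "TS", "TN"]
    class_sums = pd.DataFrame({
        lab: proportions[[p for p in proportions.columns
                          if class_to_label[population_classes[p]] == lab]].sum(axis=1)
        for lab in priority
    })
    # idxmax with column order = priority breaks exact ties as specified
    labels = class_sums[priority].idxmax(axis=1)
    n_ties = int((class_sums.max(axis=1).to_numpy()[:, None]
                  == class_sums.to_numpy()).sum(axis=1).max() > 1)
    if n_ties:
        logger.info("assign_tcell_subgroup: ties broken by priority TA > TS > TN")
    return labels.rename("subgroup")
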