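"""Expression-array group comparison and tissue-specific marker selection.

Implements the probe funnel used to separate leiomyosarcoma from leiomyoma
and normal myometrium on a two-colour expression array: quantile
normalisation, four-group one-way ANOVA with Benjamini-Hochberg correction,
a linear fold-change filter against the normal-myometrium reference, gene
symbol de-duplication, a flag/intensity tissue-specificity filter, and
per-sample up/down-regulation counts with cross-sample overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .design import GroupDesign, InvalidSpecError

__all__ = [
    "DeSelection",
    "quantile_normalize",
    "anova_bh",
    "fold_change_filter",
    "dedup_by_symbol",
    "select_specific_markers",
    "count_de_vs_reference",
]


@dataclass
class DeSelection:
    probe_id: str
    f_stat: float
    p: float
    q: float
    fold_changes: dict[str, float] = field(default_factory=dict)
    passed_stage: str = "anova"  # anova | fc | symbol


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common per-rank mean distribution.

    Each rank's target value is the mean across columns of the rank-th sorted
    values; ties within a column receive the mean of their ranks' targets, so
    tied input values stay tied.  Within-column order is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least two samples")
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="mergesort")
        col_sorted = values[order, j]
        target = ref.copy()
        # runs of tied input values all receive the mean target of their ranks
        run_start = 0
        for i in range(1, col_sorted.size + 1):
            if i == col_sorted.size or col_sorted[i] != col_sorted[run_start]:
                if i - run_start > 1:
                    target[run_start:i] = ref[run_start:i].mean()
                run_start = i
        out[order, j] = target
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def anova_bh(
    log2_matrix: pd.DataFrame,
    design: GroupDesign,
    alpha: float = 0.05,
) -> list[DeSelection]:
    """Per-probe one-way ANOVA across the design groups, BH-corrected.

    A probe is selected when its BH q-value is strictly below ``alpha``.
    Probes with zero variance both within and between groups get p = 1 by
    convention (no evidence of differential expression).
    """
    groups = design.groups
    cols = {g: [s for s in design.members(g) if s in log2_matrix.columns] for g in groups}
    cols = {g: c for g, c in cols.items() if c}
    if len(cols) < 2 or any(len(c) < 2 for c in cols.values()):
        raise ValueError("need ≥2 groups with ≥2 samples each")
    arrays = [log2_matrix[c].to_numpy(dtype=float) for c in cols.values()]
    ns = np.array([a.shape[1] for a in arrays], dtype=float)
    k = len(arrays)
    n_tot = ns.sum()
    grand = np.hstack(arrays).mean(axis=1)
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((a - m[:, None]) ** 2).sum(axis=1) for a, m in
                    zip(arrays, (means[:, i] for i in range(k))))
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    p = scipy.stats.f.sf(f, df_b, df_w)
    degenerate = np.isclose(ss_within, 0.0) & np.isclose(ss_between, 0.0)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    # within-group variance zero but groups differ: F infinite, p -> 0
    p = np.where(np.isinf(f), 0.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [
        DeSelection(probe_id=str(pid), f_stat=float(fi), p=float(pi), q=float(qi))
        for pid, fi, pi, qi in zip(log2_matrix.index, f, p, q)
        if qi < alpha
    ]


def fold_change_filter(
    selection: list[DeSelection],
    group_means: pd.DataFrame,
    contrasts: list[tuple[str, str]] = (("LMS", "NM"), ("LM", "NM")),
    fc: float = 2.0,
) -> list[DeSelection]:
    """Keep probes with linear fold change > fc or < 1/fc in ≥1 contrast (strict).

    ``group_means`` is a probe × group table of linear-scale means.
    """
    if (group_means.to_numpy() <= 0).any():
        raise ValueError("group means must be positive on the linear scale")
    out = []
    for sel in selection:
        fcs = {}
        keep = False
        for a, b in contrasts:
            ratio = float(group_means.at[sel.probe_id, a] / group_means.at[sel.probe_id, b])
            fcs[f"{a}_vs_{b}"] = ratio
            if ratio > fc or ratio < 1.0 / fc:
                keep = True
        if keep:
            sel.fold_changes = fcs
            sel.passed_stage = "fc"
            out.append(sel)
    return out


def dedup_by_symbol(
    selection: list[DeSelection],
    annotation: pd.Series,
) -> list[DeSelection]:
    """Drop probes without a gene symbol; keep one probe per symbol.

    Tie-break: the probe with the largest |log2 fold change| over its recorded
    contrasts survives; remaining ties resolve to the lexicographically
    smallest probe id.
    """
    def max_abs_l2fc(sel: DeSelection) -> float:
        if not sel.fold_changes:
            return 0.0
        return max(abs(np.log2(v)) for v in sel.fold_changes.values())

    by_symbol: dict[str, DeSelection] = {}
    for sel in selection:
        sym = annotation.get(sel.probe_id)
        if sym is None or (isinstance(sym, float) and np.isnan(sym)) or sym == "":
            continue
        cur = by_symbol.get(sym)
        if cur is None:
            by_symbol[sym] = sel
            continue
        a, b = max_abs_l2fc(sel), max_abs_l2fc(cur)
        if a > b or (a == b and sel.probe_id < cur.probe_id):
            by_symbol[sym] = sel
    out = sorted(by_symbol.values(), key=lambda s: s.probe_id)
    for sel in out:
        sel.passed_stage = "symbol"
    return out


TISSUE_GROUPS = ("NM", "LM", "LMS")


def select_specific_markers(
    log2_matrix: pd.DataFrame,
    flags: pd.DataFrame,
    design: GroupDesign,
    intensity_t: float = 6.0,
) -> dict[str, list[str]]:
    """Tissue-specificity filter on present/absent flags and log2 intensity.

    A probe is specific to a class C (any one or two of NM, LM, LMS) when in
    every sample of every group in C it is flagged present AND has log2
    intensity strictly above ``intensity_t``, while in every sample of every
    tissue group outside C it is flagged absent OR has intensity ≤
    ``intensity_t``.  Cell-line samples are not part of the specificity
    definition.

    Returns {class label: [probe ids]} with labels like "LMS" or "NM/LM".
    """
    classes = [
        cs for r in (1, 2) for cs in combinations(TISSUE_GROUPS, r)
    ]
    cols = {g: design.members(g) for g in TISSUE_GROUPS}
    vals = {g: log2_matrix[c].to_numpy(dtype=float) for g, c in cols.items()}
    pres = {g: (flags[c].to_numpy() == "present") for g, c in cols.items()}
    high = {g: (pres[g] & (vals[g] > intensity_t)).all(axis=1) for g in TISSUE_GROUPS}
    low = {g: (~pres[g] | (vals[g] <= intensity_t)).all(axis=1) for g in TISSUE_GROUPS}
    result: dict[str, list[str]] = {}
    index = log2_matrix.index
    for cs in classes:
        inside = np.logical_and.reduce([high[g] for g in cs])
        outside = np.logical_and.reduce(
            [low[g] for g in TISSUE_GROUPS if g not in cs]
        )
        mask = inside & outside
        result["/".join(cs)] = [str(p) for p in index[mask]]
    return result


def count_de_vs_reference(
    matrix: pd.DataFrame,
    design: GroupDesign,
    reference_group: str = "NM",
    up_fc: float = 2.0,
    down_fc: float = 0.5,
) -> pd.DataFrame:
    """Per-sample up/down-regulated probe counts against the reference mean,
    plus per-group overlap fractions.

    For each non-reference sample, a probe is up-regulated when its
    linear-scale value exceeds ``up_fc`` × the reference-group mean and
    down-regulated below ``down_fc`` × it (strict).  The "common" fraction of
    a group is |intersection| / |union| of its samples' up (resp. down) sets —
    a Venn-style concordance measure: leiomyosarcomas share most of their
    deregulated genes while leiomyomas are heterogeneous.

    Returns a tidy frame with columns sample_id, group, n_up, n_down,
    common_up_fraction, common_down_fraction (fractions repeated per group).
    """
    ref = design.members(reference_group)
    if not ref:
        raise InvalidSpecError(f"reference group {reference_group!r} is empty")
    ref_mean = matrix[ref].mean(axis=1).to_numpy(dtype=float)
    rows = []
    sets: dict[str, dict[str, tuple[set, set]]] = {}
    for sid, grp in design.samples:
        if grp == reference_group or sid not in matrix.columns:
            continue
        vals = matrix[sid].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = vals / ref_mean
        up = set(matrix.index[ratio > up_fc])
        down = set(matrix.index[ratio < down_fc])
        sets.setdefault(grp, {})[sid] = (up, down)
        rows.append({"sample_id": sid, "group": grp, "n_up": len(up), "n_down": len(down)})
    frame = pd.DataFrame(rows)
    for grp, per_sample in sets.items():
        ups = [u for u, _ in per_sample.values()]
        downs = [d for _, d in per_sample.values()]
        for name, fam in (("common_up_fraction", ups), ("common_down_fraction", downs)):
            union = set().union(*fam)
            inter = set.intersection(*fam) if fam else set()
            frac = len(inter) / len(union) if union else 0.0
            frame.loc[frame["group"] == grp, name] = frac
    return frame
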