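"""450K-style differential methylation analysis.

Beta values (M/(U+M+100)), detection-P quality control, group delta-beta with
strict ±0.2 hyper/hypo classification, tabulation by gene feature group and
CpG-island relation, ≥2-probe region binning with BED export, the two-sided
beta 0.6/0.1 marker filter with promoter refinement, gene-set overlap, and
per-sample global beta summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GroupDesign

__all__ = [
    "FEATURE_GROUPS",
    "CGI_RELATIONS",
    "DmCall",
    "DmRegion",
    "compute_beta",
    "qc_filter",
    "group_delta_beta",
    "tabulate_by_feature",
    "bin_regions",
    "regions_to_bed",
    "select_methylation_markers",
    "promoter_refine",
    "geneset_overlap",
    "global_stats",
]

#: mutually exclusive gene feature categories, in annotation precedence order
#: (a probe mapping to several features is assigned the highest-precedence one)
FEATURE_GROUPS = ("TSS200", "TSS1500", "UTR5_1stExon", "Body", "UTR3", "Intergenic")
CGI_RELATIONS = ("island", "shore_shelf", "open_sea")
PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200"})


@dataclass(frozen=True)
class DmCall:
    probe_id: str
    delta_beta: float
    status: str  # hyper | hypo | none


@dataclass(frozen=True)
class DmRegion:
    gene: str
    feature_group: str
    chrom: str
    start: int  # 1-based inclusive, first member probe
    end: int  # 1-based inclusive, last member probe
    n_probes: int
    direction: str  # hyper | hypo


def compute_beta(m, u, offset: float = 100.0):
    """Methylation beta value M/(U+M+offset), in [0, 1).

    The offset stabilises the ratio at low total intensity and keeps beta
    strictly below 1 even for fully methylated probes.  Accepts scalars or
    arrays.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    beta = m / (u + m + offset)
    return float(beta) if beta.ndim == 0 else beta


def qc_filter(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_t: float = 0.05,
) -> pd.DataFrame:
    """Drop every probe that fails detection in ANY sample.

    A probe is removed when any sample shows detection P > ``p_t`` or a blank
    (NaN) beta.  Filtering on the union of sample failures yields the single
    genome-wide surviving probe set that all downstream analyses share.
    """
    bad_p = (detection_p.reindex(index=beta.index, columns=beta.columns) > p_t).any(axis=1)
    bad_blank = beta.isna().any(axis=1)
    return beta.loc[~(bad_p | bad_blank)]


def group_delta_beta(
    beta: pd.DataFrame,
    design: GroupDesign,
    group_a: str,
    group_b: str,
    threshold: float = 0.2,
) -> list[DmCall]:
    """Mean-beta difference (group_a − group_b) per probe, classified.

    Status is hyper when delta-beta is strictly above ``threshold`` and hypo
    when strictly below −``threshold``; the boundary values themselves are
    not differential.
    """
    a_cols, b_cols = design.members(group_a), design.members(group_b)
    if not a_cols or not b_cols:
        raise ValueError("both groups must be non-empty")
    delta = beta[a_cols].mean(axis=1) - beta[b_cols].mean(axis=1)
    status = np.where(delta > threshold, "hyper", np.where(delta < -threshold, "hypo", "none"))
    return [
        DmCall(probe_id=str(p), delta_beta=float(d), status=str(s))
        for p, d, s in zip(beta.index, delta, status)
    ]


def tabulate_by_feature(
    calls: list[DmCall],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Count hyper/hypo probes per feature group and per CGI relation.

    Percentages are relative to each category's probe total among the calls,
    so feature rows (and CGI rows) partition the analysed probe set and their
    counts sum to the grand total — the layout of a per-category
    differential-methylation summary table.
    """
    probe_ids = [c.probe_id for c in calls]
    missing = [p for p in probe_ids if p not in manifest.index]
    if missing:
        raise KeyError(f"probes absent from manifest: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    sub = manifest.loc[probe_ids]
    status = pd.Series([c.status for c in calls], index=probe_ids)
    rows = []
    for axis, categories in (("feature_group", FEATURE_GROUPS), ("cgi_relation", CGI_RELATIONS)):
        for cat in categories:
            mask = sub[axis] == cat
            total = int(mask.sum())
            n_hyper = int((status[mask.to_numpy()] == "hyper").sum())
            n_hypo = int((status[mask.to_numpy()] == "hypo").sum())
            rows.append({
                "axis": axis,
                "category": cat,
                "n_probes": total,
                "n_hyper": n_hyper,
                "n_hypo": n_hypo,
                "pct_hyper": 100.0 * n_hyper / total if total else 0.0,
                "pct_hypo": 100.0 * n_hypo / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def bin_regions(
    calls: list[DmCall],
    manifest: pd.DataFrame,
    direction: str,
    min_probes: int = 2,
) -> list[DmRegion]:
    """Merge same-direction differential probes of one gene feature into regions.

    Probes that individually pass the delta-beta threshold in ``direction``
    and share both gene and feature group form one region when at least
    ``min_probes`` of them exist; its span runs from the first to the last
    member probe.  Intergenic probes carry no gene and are never binned.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    passing = [c for c in calls if c.status == direction]
    if not passing:
        return []
    sub = manifest.loc[[c.probe_id for c in passing]]
    regions = []
    grouped = sub[sub["gene"].notna() & (sub["gene"] != "")].groupby(
        ["gene", "feature_group"], sort=True, observed=True
    )
    for (gene, feature), g in grouped:
        if len(g) < min_probes:
            continue
        chroms = g["chrom"].unique()
        for chrom in sorted(chroms):
            gc = g[g["chrom"] == chrom]
            if len(gc) < min_probes:
                continue
            regions.append(
                DmRegion(
                    gene=str(gene),
                    feature_group=str(feature),
                    chrom=str(chrom),
                    start=int(gc["pos"].min()),
                    end=int(gc["pos"].max()),
                    n_probes=int(len(gc)),
                    direction=direction,
                )
            )
    return regions


def regions_to_bed(regions: list[DmRegion]) -> pd.DataFrame:
    """BED (0-based half-open) frame: name = gene|feature|direction."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start - 1,
                "end": r.end,
                "name": f"{r.gene}|{r.feature_group}|{r.direction}",
                "score": r.n_probes,
            }
            for r in sorted(regions, key=lambda r: (r.chrom, r.start))
        ],
        columns=["chrom", "start", "end", "name", "score"],
    )


def select_methylation_markers(
    beta: pd.DataFrame,
    design: GroupDesign,
    group_a: str = "LMS",
    group_b: str = "LM",
    hi: float = 0.6,
    lo: float = 0.1,
) -> pd.DataFrame:
    """Two-sided all-sample beta filter for diagnostic marker probes.

    A probe qualifies when every sample of one group has beta strictly above
    ``hi`` while every sample of the other group is strictly below ``lo`` —
    near-binary methylation differences robust enough for single-locus assays.

    Returns a frame indexed by probe id with a ``direction`` column:
    ``hyper_in_a`` (high in group_a) or ``hyper_in_b``.
    """
    a_cols, b_cols = design.members(group_a), design.members(group_b)
    if not a_cols or not b_cols:
        raise ValueError("both groups must be non-empty")
    a = beta[a_cols].to_numpy(dtype=float)
    b = beta[b_cols].to_numpy(dtype=float)
    hyper_a = (a > hi).all(axis=1) & (b < lo).all(axis=1)
    hyper_b = (b > hi).all(axis=1) & (a < lo).all(axis=1)
    frame = pd.DataFrame(index=beta.index[hyper_a | hyper_b])
    direction = np.where(hyper_a[hyper_a | hyper_b], "hyper_in_a", "hyper_in_b")
    frame["direction"] = direction
    return frame


def promoter_refine(
    markers: pd.DataFrame,
    manifest: pd.DataFrame,
    min_probes: int = 2,
) -> list[str]:
    """Genes with ≥ min_probes marker probes in their promoter (TSS1500/TSS200).

    Requiring multiple concordant promoter probes per gene trims the marker
    list to loci assayable by a single bisulfite PCR amplicon.
    """
    if markers.empty:
        return []
    sub = manifest.loc[[p for p in markers.index if p in manifest.index]]
    sub = sub[sub["feature_group"].isin(PROMOTER_FEATURES) & sub["gene"].notna() & (sub["gene"] != "")]
    counts = sub.groupby("gene").size()
    return sorted(counts[counts >= min_probes].index.astype(str))


def geneset_overlap(dm_genes: set[str], reference_set: set[str]) -> tuple[int, float]:
    """Overlap of differentially methylated genes with a reference gene set.

    Returns (count, fraction of the reference set) — e.g. what share of
    polycomb-target genes is hypermethylated in the tumour.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    count = len(set(dm_genes) & set(reference_set))
    return count, count / len(reference_set)


def global_stats(beta: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Five-number beta summary per sample plus its group; global methylation view.

    A depressed median in the malignant group reflects genome-wide
    hypomethylation.
    """
    if beta.empty:
        raise ValueError("beta matrix is empty")
    rows = []
    for sid, grp in design.samples:
        if sid not in beta.columns:
            continue
        col = beta[sid].dropna()
        if col.empty:
            raise ValueError(f"sample {sid} has no beta values")
        q = np.quantile(col.to_numpy(dtype=float), [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append({
            "sample_id": sid, "group": grp,
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
        })
    return pd.DataFrame(rows)
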