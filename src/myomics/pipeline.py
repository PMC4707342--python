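"""End-to-end orchestration, clustering/PCA reporting, and report bundles.

Runs the four analysis stages — copy-number burden, expression markers,
differential methylation, COBRA — in dependency order over either synthetic
or on-disk inputs, echoing the configuration and per-stage filter counts into
the output directory so that probe funnels (ANOVA → fold-change → symbol
de-duplication, QC → delta-beta → regions) are auditable from the reports
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from . import cnv, cobra_assay, expression, io, methylation, simulate
from .design import GroupDesign

logger = logging.getLogger("myomics")

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "cluster_samples",
    "pca_project",
    "meth_expr_scatter",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All stage thresholds, at the analysis defaults, plus run plumbing.

    In synthetic mode (``input_dir`` None) the generators produce a study-like
    dataset from ``seed``; in real mode the directory must hold design.tsv,
    manifest.tsv, expression.tsv, methylation.tsv, snp_<sample>.tsv per
    sample, bands.tsv and controls.tsv.
    """

    out_dir: str = "myomics_out"
    input_dir: str | None = None
    seed: int = 0
    # CNV stage
    gain_t: float = 0.10
    loss_t: float = -0.15
    min_probes_seg: int = 2
    cnloh_min_run: int = 50
    cnloh_band: tuple[float, float] = (0.15, 0.85)
    cnloh_min_span: int = 3_000_000
    # expression stage
    anova_alpha: float = 0.05
    fc: float = 2.0
    intensity_t: float = 6.0
    # methylation stage
    detection_p_t: float = 0.05
    delta_beta_t: float = 0.2
    beta_hi: float = 0.6
    beta_lo: float = 0.1
    region_min_probes: int = 2

    def validate(self) -> None:
        if not (self.loss_t < 0 < self.gain_t):
            raise ValueError("loss_t < 0 < gain_t required")
        if not (0 < self.anova_alpha < 1 and 0 < self.detection_p_t < 1):
            raise ValueError("alpha-style thresholds must be in (0,1)")
        if not (0 <= self.beta_lo < self.beta_hi <= 1):
            raise ValueError("need 0 ≤ beta_lo < beta_hi ≤ 1")
        if self.input_dir is not None:
            root = Path(self.input_dir)
            for name in ("design.tsv", "manifest.tsv", "expression.tsv",
                         "methylation.tsv", "bands.tsv", "controls.tsv"):
                if not (root / name).exists():
                    raise FileNotFoundError(f"real mode requires {root / name}")


@dataclass
class ReportBundle:
    out_dir: Path
    burden: pd.DataFrame
    de_counts: pd.DataFrame
    markers: dict[str, list[str]]
    dm_table: pd.DataFrame
    dm_regions: dict[str, list]
    meth_markers: list[str]
    cobra: pd.DataFrame
    clustering: dict
    pca: dict
    log: list[str] = field(default_factory=list)


def cluster_samples(
    matrix: pd.DataFrame,
    design: GroupDesign,
    k: int | None = None,
    method: str = "complete",
    metric: str = "euclidean",
) -> dict:
    """Agglomerative clustering of samples (columns) with purity vs the design.

    Complete linkage with Euclidean distance, the standard choice for
    expression/methylation heatmaps.  Purity at k clusters is the fraction of
    samples whose cluster's majority group matches their own; 1.0 means the
    dendrogram separates the tissue types perfectly.
    """
    samples = [s for s in design.sample_ids if s in matrix.columns]
    if len(samples) < 2:
        raise ValueError("need at least two samples to cluster")
    x = matrix[samples].to_numpy(dtype=float).T
    z = scipy.cluster.hierarchy.linkage(x, method=method, metric=metric)
    if k is None:
        k = len({design.group_of(s) for s in samples})
    labels = scipy.cluster.hierarchy.fcluster(z, t=k, criterion="maxclust")
    frame = pd.DataFrame(
        {"sample_id": samples, "group": [design.group_of(s) for s in samples],
         "cluster": labels}
    )
    correct = 0
    for _, sub in frame.groupby("cluster"):
        correct += int(sub["group"].value_counts().iloc[0])
    return {
        "linkage": z,
        "labels": frame,
        "k": k,
        "purity": correct / len(samples),
    }


def pca_project(matrix: pd.DataFrame, n_components: int = 3) -> dict:
    """Centered SVD projection of samples; variance-explained fractions.

    Features are rows, samples columns (the array convention); the projection
    places each sample in component space.  A constant matrix has zero
    variance and yields an empty projection.
    """
    x = matrix.to_numpy(dtype=float).T  # samples × features
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    xc = x - x.mean(axis=0, keepdims=True)
    total_var = float((xc**2).sum())
    if total_var == 0.0:
        return {
            "coordinates": pd.DataFrame(index=matrix.columns),
            "variance_explained": np.zeros(0),
        }
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ncomp = min(n_components, s.size)
    # sign convention: largest-magnitude coordinate of each component positive
    coords = u[:, :ncomp] * s[:ncomp]
    for j in range(ncomp):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return {
        "coordinates": pd.DataFrame(
            coords, index=matrix.columns, columns=[f"PC{i+1}" for i in range(ncomp)]
        ),
        "variance_explained": (s[:ncomp] ** 2) / total_var,
    }


def meth_expr_scatter(
    dm_calls: list[methylation.DmCall],
    manifest: pd.DataFrame,
    de_log2fc: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Pair promoter delta-beta with expression log2 fold change per gene.

    Restricts methylation calls to promoter probes (TSS1500/TSS200), averages
    delta-beta per gene, joins with the expression log2 fold changes (indexed
    by gene symbol) and reports the Spearman rank correlation — near zero when
    promoter methylation changes do not drive the expression differences.
    """
    promoter = manifest[manifest["feature_group"].isin(methylation.PROMOTER_FEATURES)]
    rows = {}
    for call in dm_calls:
        if call.probe_id in promoter.index:
            gene = promoter.at[call.probe_id, "gene"]
            if gene:
                rows.setdefault(gene, []).append(call.delta_beta)
    paired = pd.DataFrame(
        [
            {"gene": g, "promoter_delta_beta": float(np.mean(v)),
             "expr_log2fc": float(de_log2fc[g])}
            for g, v in rows.items()
            if g in de_log2fc.index
        ]
    )
    if paired.empty:
        raise ValueError("no genes shared between methylation and expression inputs")
    rho = scipy.stats.spearmanr(
        paired["promoter_delta_beta"], paired["expr_log2fc"]
    ).statistic
    return paired, float(rho)


# ---------------------------------------------------------------------------
# end-to-end run


def _default_synthetic_inputs(config: PipelineConfig):
    """A study-like synthetic dataset: 3 NM / 3 LM / 3 LMS (+3 cell lines),
    heavy aberration burden and global hypomethylation in the sarcoma group,
    a handful of planted marker genes."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    design = GroupDesign.default()
    manifest = simulate.make_manifest(
        n_genes=300, seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )
    # aberrations: LMS genomes are largely aberrant (two-thirds to ~nine
    # tenths of the probed autosomes in gain/loss/CN-LOH), LM genomes carry
    # at most a few percent
    aberrations = {}
    for i, sid in enumerate(design.members("LMS")):
        aberrations[sid] = [
            simulate.AberrationSpec("1", 2_000_000, 48_000_000, "gain", 1.0),
            simulate.AberrationSpec("2", 2_000_000, 48_000_000, "loss", 0.8),
            simulate.AberrationSpec("3", 5_000_000, 40_000_000, "cnloh", 1.0),
            simulate.AberrationSpec("4", 5_000_000, 15_000_000 + 12_000_000 * i, "gain", 1.0),
        ]
    for i, sid in enumerate(design.members("LM")):
        aberrations[sid] = [
            simulate.AberrationSpec("4", 20_000_000, 22_000_000 + 4_000_000 * i, "loss", 1.0),
        ]
    tracks, cnv_truth = simulate.generate_snp_array(
        design, aberrations, seed=int(seeds[1].generate_state(1)[0] % 2**31)
    )
    expr_spec = [
        simulate.ExpressionEffect(("LMS", "CELL"), 4.0, 40, specific=True),
        simulate.ExpressionEffect(("NM",), 3.0, 5, specific=True),
        simulate.ExpressionEffect(("LMS",), 0.2, 30),
        simulate.ExpressionEffect(("LM",), 2.5, 20),
    ]
    expr, expr_truth = simulate.generate_expression(
        design, n_probes=2000, de_spec=expr_spec,
        seed=int(seeds[2].generate_state(1)[0] % 2**31),
    )
    # methylation: promoter hypermethylation of island probes in LMS plus
    # broad open-sea hypomethylation (the malignant-genome signature); milder
    # LM-specific changes and a distinct cell-line profile so all four groups
    # are separable; two near-binary promoter marker loci (one per tumour type)
    promoter_mask = manifest["feature_group"].isin(("TSS200", "TSS1500"))
    promoter_genes = sorted(
        manifest[promoter_mask & (manifest["gene"] != "")]
        .groupby("gene").size().loc[lambda s: s >= 2].index
    )
    lms_marker_gene, lm_marker_gene = promoter_genes[-2], promoter_genes[-1]
    marker_probes = {
        g: tuple(manifest.index[promoter_mask & (manifest["gene"] == g)])
        for g in (lms_marker_gene, lm_marker_gene)
    }
    reserved = set().union(*marker_probes.values())
    island_promoter = [
        p for p in manifest.index[(manifest["cgi_relation"] == "island") & promoter_mask]
        if p not in reserved
    ][:60]
    open_sea = [
        p for p in manifest.index[manifest["cgi_relation"] == "open_sea"]
        if p not in reserved
    ][:400]
    shore = [
        p for p in manifest.index[manifest["cgi_relation"] == "shore_shelf"]
        if p not in reserved
    ][:120]
    body = [
        p for p in manifest.index[manifest["feature_group"] == "Body"]
        if p not in reserved and p not in set(open_sea) and p not in set(shore)
    ]
    dm_spec = [
        simulate.MethylationEffect(tuple(island_promoter), "LMS", 0.4),
        simulate.MethylationEffect(tuple(open_sea), "LMS", -0.4),
        simulate.MethylationEffect(tuple(shore), "LMS", -0.4),
        simulate.MethylationEffect(tuple(body[:80]), "LM", 0.35),
        simulate.MethylationEffect(tuple(body[80:140]), "CELL", 0.5),
        simulate.MethylationEffect(marker_probes[lms_marker_gene], "LMS", 0.85, anchor=0.02),
        simulate.MethylationEffect(marker_probes[lm_marker_gene], "LM", 0.85, anchor=0.02),
    ]
    meth, meth_truth = simulate.generate_methylation(
        design, manifest, dm_spec,
        seed=int(seeds[3].generate_state(1)[0] % 2**31),
    )
    true_frac = {s: 0.75 for s in design.members("NM") + design.members("LM")}
    true_frac.update({s: 0.45 for s in design.members("LMS")})
    bands, controls, cobra_truth = simulate.generate_cobra(
        true_frac, distortion=(0.9, 8.0), band_noise=1.0,
        seed=int(seeds[3].generate_state(2)[1] % 2**31),
    )
    truth = simulate.TruthTables(
        aberrations=cnv_truth.aberrations,
        de_probes=expr_truth.de_probes,
        dm_probes=meth_truth.dm_probes,
        cobra_truth=cobra_truth.cobra_truth,
    )
    return design, manifest, tracks, expr, meth, bands, controls, truth


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write one report per stage into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: {json.dumps(dataclasses.asdict(config), sort_keys=True)}"]

    if config.input_dir is None:
        (design, manifest, tracks, expr, meth, bands, controls, truth) = (
            _default_synthetic_inputs(config)
        )
        io.write_truth(truth, out / "truth.json")
        log.append("mode: synthetic")
    else:
        root = Path(config.input_dir)
        design = io.read_design(root / "design.tsv")
        manifest = io.read_manifest(root / "manifest.tsv")
        expr = io.read_expression(root / "expression.tsv", design)
        meth = io.read_methylation(root / "methylation.tsv", design)
        bands = io.read_bands(root / "bands.tsv")
        controls = io.read_controls(root / "controls.tsv")
        tracks = {}
        for sid in design.sample_ids:
            p = root / f"snp_{sid}.tsv"
            if p.exists():
                tracks[sid] = io.read_snp_track(p)
        log.append(f"mode: real ({root})")

    # --- CNV burden -------------------------------------------------------
    burden_rows = []
    for sid, track in tracks.items():
        segs = cnv.call_states(
            cnv.segment_lrr(track, min_probes=config.min_probes_seg),
            gain_t=config.gain_t, loss_t=config.loss_t,
        )
        loh = cnv.detect_cnloh(
            track, segs, min_run=config.cnloh_min_run,
            baf_het_band=config.cnloh_band, min_span=config.cnloh_min_span,
        )
        rep = cnv.burden_ratio(sid, segs + loh, track=track)
        burden_rows.append(dataclasses.asdict(rep))
    burden = pd.DataFrame(burden_rows)
    burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    log.append(f"cnv: {len(burden)} samples segmented")

    # --- expression -------------------------------------------------------
    norm = expression.quantile_normalize(expr.intensity)
    log2n = np.log2(norm)
    selected = expression.anova_bh(log2n, design, alpha=config.anova_alpha)
    log.append(f"expr: {len(selected)} probes pass ANOVA/BH q<{config.anova_alpha}")
    group_means = pd.DataFrame(
        {g: norm[design.members(g)].mean(axis=1) for g in design.groups}
    )
    after_fc = expression.fold_change_filter(selected, group_means, fc=config.fc)
    log.append(f"expr: {len(after_fc)} probes pass fold-change >{config.fc} or <{1/config.fc}")
    dedup = expression.dedup_by_symbol(after_fc, expr.symbols)
    log.append(f"expr: {len(dedup)} unique gene symbols")
    markers = expression.select_specific_markers(
        log2n, expr.flags, design, intensity_t=config.intensity_t
    )
    de_counts = expression.count_de_vs_reference(norm, design)
    de_counts.to_csv(out / "de_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"class": c, "probe_id": p, "symbol": expr.symbols.get(p, "")}
         for c, ps in markers.items() for p in ps]
    ).to_csv(out / "expression_markers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"probe_id": s.probe_id, "symbol": expr.symbols.get(s.probe_id, ""),
          "f": s.f_stat, "p": s.p, "q": s.q, **s.fold_changes}
         for s in dedup]
    ).to_csv(out / "de_genes.tsv", sep="\t", index=False)

    # --- methylation ------------------------------------------------------
    beta = meth.beta
    beta_qc = methylation.qc_filter(beta, meth.detection_p, p_t=config.detection_p_t)
    log.append(f"meth: {len(beta_qc)}/{len(beta)} probes pass QC")
    calls = methylation.group_delta_beta(
        beta_qc, design, "LMS", "NM", threshold=config.delta_beta_t
    )
    n_hyper = sum(c.status == "hyper" for c in calls)
    n_hypo = sum(c.status == "hypo" for c in calls)
    log.append(f"meth: {n_hyper} hyper / {n_hypo} hypo probes (LMS vs NM)")
    dm_table = methylation.tabulate_by_feature(calls, manifest)
    dm_table.to_csv(out / "dm_table.tsv", sep="\t", index=False)
    dm_regions = {}
    for direction in ("hyper", "hypo"):
        regions = methylation.bin_regions(
            calls, manifest, direction, min_probes=config.region_min_probes
        )
        dm_regions[direction] = regions
        io.write_bed(methylation.regions_to_bed(regions), out / f"regions_{direction}.bed")
    probe_markers = methylation.select_methylation_markers(
        beta_qc, design, "LMS", "LM", hi=config.beta_hi, lo=config.beta_lo
    )
    meth_markers = methylation.promoter_refine(
        probe_markers, manifest, min_probes=config.region_min_probes
    )
    pd.Series(meth_markers, name="gene").to_csv(
        out / "methylation_marker_genes.tsv", sep="\t", index=False
    )
    methylation.global_stats(beta_qc, design).to_csv(
        out / "beta_summary.tsv", sep="\t", index=False
    )

    # --- COBRA ------------------------------------------------------------
    curve = cobra_assay.fit_standard_curve(controls)
    cobra_rows = []
    for band in bands:
        raw = cobra_assay.methylation_index(band)
        cobra_rows.append({
            "sample_id": band.sample_id,
            "raw_index_pct": raw,
            "corrected_pct": cobra_assay.correct_index(raw, curve),
        })
    cobra_report = pd.DataFrame(cobra_rows)
    cobra_report.to_csv(out / "cobra.tsv", sep="\t", index=False)
    log.append(f"cobra: curve slope={curve.slope:.3f} intercept={curve.intercept:.2f} r2={curve.r2:.4f}")

    # --- clustering / PCA -------------------------------------------------
    clustering = cluster_samples(beta_qc, design)
    pca = pca_project(log2n)
    clustering["labels"].to_csv(out / "clusters.tsv", sep="\t", index=False)
    pca["coordinates"].to_csv(out / "pca.tsv", sep="\t", index_label="sample_id")
    log.append(f"clustering purity at k={clustering['k']}: {clustering['purity']:.3f}")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    for line in log:
        logger.info(line)
    return ReportBundle(
        out_dir=out, burden=burden, de_counts=de_counts, markers=markers,
        dm_table=dm_table, dm_regions=dm_regions, meth_markers=meth_markers,
        cobra=cobra_report, clustering=clustering, pca=pca, log=log,
    )
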