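"""Synthetic multi-omics data with known planted truth.

Every downstream stage of the pipeline — copy-number burden, expression
marker selection, differential methylation, COBRA quantification — can be
exercised end-to-end on data generated here, with the planted aberrations,
differentially expressed probes, differentially methylated probe sets and
true methylated fractions returned as an explicit truth table.

The generators emulate the probe-level summaries the real platforms deliver
(LRR/BAF tracks, intensity + present/absent flags, M/U intensities with
detection P), not the raw scanner output.

Noise models
------------
LRR noise is additive Gaussian (typical genotyping-array tracks show
sigma ≈ 0.1–0.2); beta-value noise is additive Gaussian on logit(beta),
which keeps beta inside (0, 1) and produces the familiar variance shrinkage
near 0 and 1.  Mosaicism attenuates LRR shifts linearly in the clonal
fraction f (gain +0.40·f, loss −0.55·f, near single-copy shifts on Illumina
arrays) and splits the heterozygous BAF band by delta(f) = f/(4 − 2f).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GroupDesign, InvalidSpecError
from .methylation import CGI_RELATIONS, FEATURE_GROUPS

__all__ = [
    "AberrationSpec",
    "ExpressionEffect",
    "MethylationEffect",
    "TruthTables",
    "ExpressionDataset",
    "MethylationDataset",
    "make_manifest",
    "generate_snp_array",
    "generate_expression",
    "generate_methylation",
    "generate_cobra",
]

# LRR shift per fully clonal single-copy event
GAIN_SHIFT = 0.40
LOSS_SHIFT = -0.55


@dataclass(frozen=True)
class AberrationSpec:
    """A planted chromosomal event in one sample."""

    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    state: str  # gain | loss | cnloh
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidSpecError("aberration start > end")
        if self.state not in ("gain", "loss", "cnloh"):
            raise InvalidSpecError(f"unknown aberration state {self.state!r}")
        if not (0.0 < self.mosaic_fraction <= 1.0):
            raise InvalidSpecError("mosaic_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionEffect:
    """A planted expression difference: ``fold_change`` applied to the listed
    groups relative to the common baseline; with ``specific`` the probe is
    silenced to background (absent flag) outside those groups."""

    groups: tuple[str, ...]
    fold_change: float
    n_probes: int
    specific: bool = False

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise InvalidSpecError("fold_change must be positive")
        if self.n_probes < 1:
            raise InvalidSpecError("n_probes must be ≥ 1")


@dataclass(frozen=True)
class MethylationEffect:
    """A planted beta shift of ``delta_beta`` in ``group`` at ``probes``.

    ``anchor`` is the clean baseline beta the unaffected groups sit at; by
    default hypermethylation plants start low (0.08) and hypomethylation
    plants start high (0.85).  A low anchor with a large positive delta
    yields the near-binary probes that the two-sided beta marker filter
    selects.
    """

    probes: tuple[str, ...]
    group: str
    delta_beta: float
    anchor: float | None = None

    def __post_init__(self) -> None:
        if abs(self.delta_beta) > 1:
            raise InvalidSpecError("|delta_beta| must be ≤ 1")
        if self.anchor is not None and not (0.0 < self.anchor < 1.0):
            raise InvalidSpecError("anchor must be inside (0, 1)")


@dataclass
class TruthTables:
    """Planted ground truth emitted alongside every synthetic dataset."""

    aberrations: dict[str, list[AberrationSpec]] = field(default_factory=dict)
    de_probes: dict[str, dict] = field(default_factory=dict)
    dm_probes: dict[str, dict] = field(default_factory=dict)
    cobra_truth: dict[str, float] = field(default_factory=dict)


@dataclass
class ExpressionDataset:
    intensity: pd.DataFrame  # probe × sample, linear scale
    flags: pd.DataFrame  # probe × sample, present/absent
    symbols: pd.Series  # probe -> gene symbol ('' = none)
    design: GroupDesign


@dataclass
class MethylationDataset:
    methylated: pd.DataFrame  # probe × sample M intensity
    unmethylated: pd.DataFrame  # probe × sample U intensity
    detection_p: pd.DataFrame
    design: GroupDesign

    @property
    def beta(self) -> pd.DataFrame:
        from .methylation import compute_beta

        return pd.DataFrame(
            compute_beta(self.methylated.to_numpy(), self.unmethylated.to_numpy()),
            index=self.methylated.index,
            columns=self.methylated.columns,
        )


# ---------------------------------------------------------------------------
# probe manifest


def make_manifest(
    n_genes: int,
    probes_per_feature: dict[str, int] | None = None,
    cgi_fraction: float = 0.31,
    shore_fraction: float | None = None,
    seed: int = 0,
    chrom_count: int = 4,
    gene_spacing: int = 1_000_000,
) -> pd.DataFrame:
    """Annotation table for a synthetic methylation array.

    Genes are laid out ``gene_spacing`` apart across ``chrom_count``
    autosomes; each gene receives ``probes_per_feature[f]`` probes in each
    feature category, positioned consistently with its transcription start
    site (TSS200 within 200 bp upstream, TSS1500 200–1500 bp upstream,
    5'UTR/first-exon then body then 3'UTR downstream).  Intergenic probes are
    placed between gene territories.  CGI relation is assigned independently:
    ``cgi_fraction`` island, ``shore_fraction`` shore/shelf (defaults to the
    island fraction), remainder open sea.

    Returns a frame indexed by probe_id with columns chrom, pos, gene,
    feature_group, cgi_relation.
    """
    if n_genes < 1:
        raise InvalidSpecError("n_genes must be ≥ 1")
    if probes_per_feature is None:
        probes_per_feature = {f: 2 for f in FEATURE_GROUPS}
    unknown = set(probes_per_feature) - set(FEATURE_GROUPS)
    if unknown:
        raise InvalidSpecError(f"unknown feature groups: {sorted(unknown)}")
    if any(v < 0 for v in probes_per_feature.values()):
        raise InvalidSpecError("probe counts must be non-negative")
    if shore_fraction is None:
        shore_fraction = cgi_fraction
    if not (0.0 <= cgi_fraction <= 1.0 and 0.0 <= shore_fraction <= 1.0
            and cgi_fraction + shore_fraction <= 1.0):
        raise InvalidSpecError("CGI fractions must be in [0,1] and sum ≤ 1")

    rng = np.random.default_rng(seed)
    # upstream offsets are subtracted from the TSS; downstream added
    windows = {
        "TSS200": (-200, -1),
        "TSS1500": (-1500, -201),
        "UTR5_1stExon": (0, 499),
        "Body": (500, 4999),
        "UTR3": (5000, 5999),
    }
    rows = []
    counter = 0
    for gi in range(n_genes):
        chrom = str(gi % chrom_count + 1)
        tss = 10_000 + (gi // chrom_count) * gene_spacing
        gene = f"GENE{gi + 1:05d}"
        for feature in FEATURE_GROUPS:
            k = probes_per_feature.get(feature, 0)
            if k == 0:
                continue
            if feature == "Intergenic":
                lo, hi = tss + 200_000, tss + 200_000 + 50_000
                gname = ""
            else:
                w = windows[feature]
                lo, hi = tss + w[0], tss + w[1]
                gname = gene
            offs = np.sort(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))
            for off in offs:
                counter += 1
                rows.append(
                    {
                        "probe_id": f"cg{counter:08d}",
                        "chrom": chrom,
                        "pos": int(off),
                        "gene": gname,
                        "feature_group": feature,
                    }
                )
    manifest = pd.DataFrame(rows).set_index("probe_id")
    u = rng.random(len(manifest))
    cgi = np.where(
        u < cgi_fraction,
        "island",
        np.where(u < cgi_fraction + shore_fraction, "shore_shelf", "open_sea"),
    )
    manifest["cgi_relation"] = cgi
    # positions must be unique per chromosome for downstream interval logic
    manifest = manifest.sort_values(["chrom", "pos"])
    dup = manifest.duplicated(subset=["chrom", "pos"])
    manifest = manifest[~dup]
    return manifest


# ---------------------------------------------------------------------------
# SNP array


def _check_overlaps(aberrations: list[AberrationSpec]) -> None:
    by_chrom: dict[str, list[AberrationSpec]] = {}
    for ab in aberrations:
        by_chrom.setdefault(ab.chrom, []).append(ab)
    for chrom, abs_ in by_chrom.items():
        abs_sorted = sorted(abs_, key=lambda a: a.start)
        for a, b in zip(abs_sorted, abs_sorted[1:]):
            if b.start <= a.end:
                raise InvalidSpecError(
                    f"overlapping aberrations on chromosome {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def baf_split(f: float) -> float:
    """Heterozygous BAF deviation from 0.5 for a one-copy event at clonal
    fraction f: delta(f) = f / (4 − 2f)."""
    return f / (4.0 - 2.0 * f)


def generate_snp_array(
    design: GroupDesign,
    aberrations: dict[str, list[AberrationSpec]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    probe_spacing: int = 20_000,
    noise_sd: float = 0.15,
    baf_noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], TruthTables]:
    """Per-sample LRR/BAF tracks with planted gains, losses and CN-LOH.

    Baseline LRR is centred at 0; genotypes are Hardy-Weinberg at allele
    frequency 0.5, giving BAF clusters near 0, 0.5 and 1.  Inside a planted
    event of clonal fraction f the LRR mean shifts by +0.40·f (gain) or
    −0.55·f (loss) and heterozygous BAF splits to 0.5 ± f/(4−2f); CN-LOH
    leaves LRR at 0 and re-draws a fraction f of heterozygous probes near
    {0, 1}.

    Returns ({sample_id: track frame}, truth).  Track columns: probe_id,
    chrom, pos, lrr, baf, genotype.
    """
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be ≥ 0")
    if baf_noise_sd is None:
        baf_noise_sd = noise_sd / 4.0
    if chrom_lengths is None:
        chrom_lengths = {str(c): 50_000_000 for c in range(1, 5)}
    aberrations = aberrations or {}
    for sample_abs in aberrations.values():
        _check_overlaps(sample_abs)

    rng = np.random.default_rng(seed)
    chroms, positions = [], []
    for chrom, length in chrom_lengths.items():
        pos = np.arange(probe_spacing, length + 1, probe_spacing)
        chroms.extend([chrom] * pos.size)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    chrom_all = np.array(chroms)
    n = pos_all.size
    probe_ids = np.array([f"rs{i + 1:07d}" for i in range(n)])

    tracks: dict[str, pd.DataFrame] = {}
    truth = TruthTables(aberrations={s: list(a) for s, a in aberrations.items()})
    for sid in design.sample_ids:
        geno = rng.choice(["AA", "AB", "BB"], size=n, p=[0.25, 0.5, 0.25])
        lrr = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        base_baf = np.where(geno == "AA", 0.0, np.where(geno == "AB", 0.5, 1.0))
        baf = base_baf + (
            rng.normal(0.0, baf_noise_sd, size=n) if baf_noise_sd > 0 else 0.0
        )
        for ab in aberrations.get(sid, ()):
            mask = (chrom_all == ab.chrom) & (pos_all >= ab.start) & (pos_all <= ab.end)
            het = mask & (geno == "AB")
            f = ab.mosaic_fraction
            if ab.state == "gain":
                lrr[mask] += GAIN_SHIFT * f
                sign = rng.choice([-1.0, 1.0], size=int(het.sum()))
                baf[het] += sign * baf_split(f)
            elif ab.state == "loss":
                lrr[mask] += LOSS_SHIFT * f
                sign = rng.choice([-1.0, 1.0], size=int(het.sum()))
                baf[het] += sign * baf_split(f)
            else:  # cnloh: no LRR shift; a fraction f of hets becomes homozygous
                nh = int(het.sum())
                flip = rng.random(nh) < f
                target = rng.choice([0.0, 1.0], size=nh)
                b = baf[het]
                b[flip] = target[flip] + (
                    rng.normal(0.0, baf_noise_sd, size=nh)[flip]
                    if baf_noise_sd > 0
                    else 0.0
                )
                baf[het] = b
        baf = np.clip(baf, 0.0, 1.0)
        tracks[sid] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chrom": chrom_all,
                "pos": pos_all,
                "lrr": lrr,
                "baf": baf,
                "genotype": geno,
            }
        )
    return tracks, truth


# ---------------------------------------------------------------------------
# expression array


def generate_expression(
    design: GroupDesign,
    n_probes: int = 2000,
    de_spec: list[ExpressionEffect] | None = None,
    background_log2: float = 5.0,
    baseline_log2: float = 8.0,
    baseline_spread: float = 1.5,
    noise_sd: float = 0.25,
    absent_fraction: float = 0.1,
    symbol_fraction: float = 0.9,
    duplicate_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionDataset, TruthTables]:
    """Expression matrix with planted group effects and present/absent flags.

    Null probes share one group-independent log-normal intensity
    distribution (log2 mean ``baseline_log2``, spread ``baseline_spread``,
    per-sample Gaussian noise ``noise_sd`` on the log2 scale).  A planted
    ``ExpressionEffect`` multiplies intensity by its linear fold change in
    the listed groups; ``specific`` effects instead pin expression to the
    background level (with absent flags) outside the listed groups.  A probe
    is flagged present when its log2 intensity exceeds ``background_log2``.

    ``absent_fraction`` of null probes sit at background (absent everywhere);
    ``symbol_fraction`` of probes carry a gene symbol, of which
    ``duplicate_fraction`` share a symbol with another probe.
    """
    de_spec = de_spec or []
    for eff in de_spec:
        for g in eff.groups:
            if g not in design.groups:
                raise InvalidSpecError(f"effect references unknown group {g!r}")
    n_planted = sum(e.n_probes for e in de_spec)
    if n_planted > n_probes:
        raise InvalidSpecError("more planted probes than probes")

    rng = np.random.default_rng(seed)
    samples = design.sample_ids
    probe_ids = [f"A_{i + 1:06d}" for i in range(n_probes)]
    base = rng.normal(baseline_log2, baseline_spread, size=n_probes)
    silent = rng.random(n_probes) < absent_fraction
    base[silent] = background_log2 - 1.5  # constitutively background probes
    # planted probes occupy the head of the index, shuffled at the end
    log2 = np.tile(base[:, None], (1, len(samples)))

    truth = TruthTables()
    cursor = 0
    for eff in de_spec:
        idx = np.arange(cursor, cursor + eff.n_probes)
        cursor += eff.n_probes
        base[idx] = np.maximum(base[idx], background_log2 + 2.0)  # expressed baseline
        log2[idx, :] = base[idx, None]
        in_cols = [
            j for j, s in enumerate(samples) if design.group_of(s) in eff.groups
        ]
        out_cols = [j for j in range(len(samples)) if j not in in_cols]
        if eff.specific:
            log2[np.ix_(idx, out_cols)] = background_log2 - 1.5
        log2[np.ix_(idx, in_cols)] += np.log2(eff.fold_change)
        for i in idx:
            truth.de_probes[probe_ids[i]] = {
                "groups": eff.groups,
                "fold_change": eff.fold_change,
                "specific": eff.specific,
            }
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, size=log2.shape)
    index = pd.Index(probe_ids, name="probe_id")
    intensity = pd.DataFrame(2.0**log2, index=index, columns=samples)
    flags = pd.DataFrame(
        np.where(log2 > background_log2, "present", "absent"),
        index=index,
        columns=samples,
    )
    symbols = pd.Series("", index=index, dtype=object)
    has_sym = rng.random(n_probes) < symbol_fraction
    sym_ids = np.cumsum(~(rng.random(n_probes) < duplicate_fraction))
    symbols[has_sym] = [f"GENE{k:05d}" for k in sym_ids[has_sym]]
    return ExpressionDataset(intensity, flags, symbols, design), truth


# ---------------------------------------------------------------------------
# methylation array


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_methylation(
    design: GroupDesign,
    manifest: pd.DataFrame,
    dm_spec: list[MethylationEffect] | None = None,
    noise_sd: float = 0.25,
    total_intensity: float = 10_000.0,
    fail_rate: float = 0.005,
    blank_rate: float = 0.0,
    seed: int = 0,
) -> tuple[MethylationDataset, TruthTables]:
    """M/U intensity matrices realising planted group beta differences.

    Baseline beta is bimodal in the way real arrays are: CpG-island probes
    are mostly unmethylated (beta ≈ 0.1), open-sea and shore probes mostly
    methylated (beta ≈ 0.75).  A ``MethylationEffect`` shifts the target beta
    of its probes by ``delta_beta`` in its group.  Per-sample noise is
    Gaussian on logit(beta) with sd ``noise_sd``; intensities are then
    realised so that M/(M+U+100) reproduces the noisy beta at total
    intensity ``total_intensity``.

    ``fail_rate`` of probe×sample cells draw detection P above 0.05;
    ``blank_rate`` cells are blanked (NaN intensities).
    """
    dm_spec = dm_spec or []
    for eff in dm_spec:
        missing = [p for p in eff.probes if p not in manifest.index]
        if missing:
            raise InvalidSpecError(f"dm_spec probes not in manifest: {missing[:5]}")
        if eff.group not in design.groups:
            raise InvalidSpecError(f"dm_spec references unknown group {eff.group!r}")

    rng = np.random.default_rng(seed)
    probes = manifest.index.to_numpy()
    n = probes.size
    samples = design.sample_ids
    island = (manifest["cgi_relation"] == "island").to_numpy()
    base_beta = np.where(
        island,
        rng.beta(2.0, 18.0, size=n),  # unmethylated islands
        rng.beta(15.0, 5.0, size=n),  # methylated elsewhere
    )
    base_beta = np.clip(base_beta, 0.01, 0.97)

    # per-group target beta
    group_target = {g: base_beta.copy() for g in design.groups}
    truth = TruthTables()
    probe_pos = {p: i for i, p in enumerate(probes)}
    for eff in dm_spec:
        idx = np.array([probe_pos[p] for p in eff.probes])
        # shift from a clean baseline so the planted delta is realised exactly:
        # hypermethylation plants start low, hypomethylation plants start high
        anchor = eff.anchor
        if anchor is None:
            anchor = 0.08 if eff.delta_beta > 0 else 0.85
        for g in design.groups:
            group_target[g][idx] = anchor
        group_target[eff.group][idx] = np.clip(anchor + eff.delta_beta, 0.01, 0.97)
        for p in eff.probes:
            truth.dm_probes.setdefault(p, {})[eff.group] = eff.delta_beta

    M = np.empty((n, len(samples)))
    U = np.empty((n, len(samples)))
    for j, sid in enumerate(samples):
        target = group_target[design.group_of(sid)]
        if noise_sd > 0:
            beta = _expit(_logit(target) + rng.normal(0.0, noise_sd, size=n))
        else:
            beta = target.copy()
        beta = np.clip(beta, 1e-4, 1.0 - 100.0 / total_intensity)
        M[:, j] = beta * total_intensity
        U[:, j] = total_intensity - 100.0 - M[:, j]
    detection_p = rng.uniform(0.0, 0.01, size=M.shape)
    fails = rng.random(M.shape) < fail_rate
    detection_p[fails] = rng.uniform(0.051, 1.0, size=int(fails.sum()))
    if blank_rate > 0:
        blanks = rng.random(M.shape) < blank_rate
        M[blanks] = np.nan
        U[blanks] = np.nan
    index = pd.Index(probes, name="probe_id")
    ds = MethylationDataset(
        methylated=pd.DataFrame(M, index=index, columns=samples),
        unmethylated=pd.DataFrame(U, index=index, columns=samples),
        detection_p=pd.DataFrame(detection_p, index=index, columns=samples),
        design=design,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# COBRA


def generate_cobra(
    true_fraction: dict[str, float],
    distortion: tuple[float, float] = (1.0, 0.0),
    band_noise: float = 0.0,
    control_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0),
    seed: int = 0,
) -> tuple[list, list[tuple[float, float]], TruthTables]:
    """Band intensities whose raw index follows a linear assay distortion.

    The raw index of a sample with true methylated fraction t is
    slope·(100·t) + intercept plus Gaussian noise (sd ``band_noise``, in
    percentage points), clamped to [0, 100]; band intensities are realised
    at that index with the 246/413 bp length weighting.  Control-ladder
    points at ``control_levels`` pass through the same measurement process.

    Returns (band measurements, control (true%, raw%) points, truth).
    """
    from .cobra_assay import CUT_LEN, UNCUT_LEN, BandMeasurement

    slope, intercept = distortion
    if slope <= 0:
        raise InvalidSpecError("distortion slope must be positive")
    if band_noise < 0:
        raise InvalidSpecError("band_noise must be ≥ 0")
    rng = np.random.default_rng(seed)

    def realise(idx_pct: float, scale: float) -> tuple[float, float]:
        frac = idx_pct / 100.0
        return frac * CUT_LEN * scale, (1.0 - frac) * UNCUT_LEN * scale

    bands = []
    truth = TruthTables(cobra_truth=dict(true_fraction))
    for sid, t in true_fraction.items():
        if not (0.0 <= t <= 1.0):
            raise InvalidSpecError("true_fraction must be in [0, 1]")
        raw = slope * (100.0 * t) + intercept
        if band_noise > 0:
            raw += rng.normal(0.0, band_noise)
        raw = float(np.clip(raw, 0.0, 100.0))
        cut, uncut = realise(raw, scale=10.0)
        bands.append(BandMeasurement(sample_id=sid, cut_intensity=cut, uncut_intensity=uncut))
    controls = []
    for level in control_levels:
        raw = slope * level + intercept
        if band_noise > 0:
            raw += rng.normal(0.0, band_noise)
        controls.append((float(level), float(np.clip(raw, 0.0, 100.0))))
    return bands, controls, truth
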