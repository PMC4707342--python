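"""Tab-separated readers and writers for every pipeline modality.

All tables are UTF-8 TSV with a header row and '.' decimals; BED output is
0-based half-open.  The synthetic generators write exactly the formats the
real-data readers consume, so the pipeline is agnostic to data provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GroupDesign
from .simulate import (
    AberrationSpec,
    ExpressionDataset,
    MethylationDataset,
    TruthTables,
)

__all__ = [
    "read_design", "write_design",
    "read_manifest", "write_manifest",
    "read_snp_track", "write_snp_track",
    "read_expression", "write_expression",
    "read_methylation", "write_methylation",
    "read_bands", "write_bands", "read_controls", "write_controls",
    "read_gene_set",
    "write_truth", "read_truth",
    "write_bed",
]


def write_design(design: GroupDesign, path: str | Path) -> None:
    pd.DataFrame(design.samples, columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_design(path: str | Path) -> GroupDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return GroupDesign(list(frame[["sample_id", "group"]].itertuples(index=False)))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str}
    ).set_index("probe_id")
    frame["gene"] = frame["gene"].fillna("")
    return frame


def write_snp_track(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_snp_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """One wide TSV: probe_id, symbol, then <sample> and <sample>_flag columns."""
    out = pd.DataFrame({"symbol": dataset.symbols})
    for sid in dataset.intensity.columns:
        out[sid] = dataset.intensity[sid]
        out[f"{sid}_flag"] = dataset.flags[sid]
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path: str | Path, design: GroupDesign) -> ExpressionDataset:
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str}).set_index("probe_id")
    samples = [s for s in design.sample_ids if s in frame.columns]
    intensity = frame[samples].astype(float)
    flags = frame[[f"{s}_flag" for s in samples]].copy()
    flags.columns = samples
    symbols = frame["symbol"].fillna("").astype(str)
    return ExpressionDataset(intensity, flags, symbols, design)


def write_methylation(dataset: MethylationDataset, path: str | Path) -> None:
    """Wide TSV: probe_id, then per sample <s>_M, <s>_U, <s>_detp columns."""
    out = pd.DataFrame(index=dataset.methylated.index)
    for sid in dataset.methylated.columns:
        out[f"{sid}_M"] = dataset.methylated[sid]
        out[f"{sid}_U"] = dataset.unmethylated[sid]
        out[f"{sid}_detp"] = dataset.detection_p[sid]
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_methylation(path: str | Path, design: GroupDesign) -> MethylationDataset:
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str}).set_index("probe_id")
    samples = [s for s in design.sample_ids if f"{s}_M" in frame.columns]
    m = frame[[f"{s}_M" for s in samples]].astype(float)
    u = frame[[f"{s}_U" for s in samples]].astype(float)
    p = frame[[f"{s}_detp" for s in samples]].astype(float)
    for sub in (m, u, p):
        sub.columns = samples
    return MethylationDataset(m, u, p, design)


def write_bands(bands: list, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": b.sample_id,
                "cut_intensity": b.cut_intensity,
                "uncut_intensity": b.uncut_intensity,
                "cut_len": b.cut_len,
                "uncut_len": b.uncut_len,
            }
            for b in bands
        ]
    ).to_csv(path, sep="\t", index=False)


def read_bands(path: str | Path) -> list:
    from .cobra_assay import BandMeasurement

    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        BandMeasurement(
            sample_id=r.sample_id,
            cut_intensity=float(r.cut_intensity),
            uncut_intensity=float(r.uncut_intensity),
            cut_len=int(r.cut_len),
            uncut_len=int(r.uncut_len),
        )
        for r in frame.itertuples(index=False)
    ]


def write_controls(controls: list[tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(controls, columns=["true_pct", "raw_pct"]).to_csv(
        path, sep="\t", index=False
    )


def read_controls(path: str | Path) -> list[tuple[float, float]]:
    frame = pd.read_csv(path, sep="\t")
    return [(float(a), float(b)) for a, b in frame[["true_pct", "raw_pct"]].itertuples(index=False)]


def read_gene_set(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_bed(bed: pd.DataFrame, path: str | Path) -> None:
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_truth(truth: TruthTables, path: str | Path) -> None:
    payload = {
        "aberrations": {
            s: [
                {"chrom": a.chrom, "start": a.start, "end": a.end,
                 "state": a.state, "mosaic_fraction": a.mosaic_fraction}
                for a in abs_
            ]
            for s, abs_ in truth.aberrations.items()
        },
        "de_probes": {p: {**d, "groups": list(d["groups"])} for p, d in truth.de_probes.items()},
        "dm_probes": truth.dm_probes,
        "cobra_truth": truth.cobra_truth,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> TruthTables:
    payload = json.loads(Path(path).read_text())
    return TruthTables(
        aberrations={
            s: [AberrationSpec(**a) for a in abs_]
            for s, abs_ in payload["aberrations"].items()
        },
        de_probes={
            p: {**d, "groups": tuple(d["groups"])}
            for p, d in payload["de_probes"].items()
        },
        dm_probes=payload["dm_probes"],
        cobra_truth=payload["cobra_truth"],
    )
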