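"""Combined bisulfite restriction analysis (COBRA) quantification.

After bisulfite PCR of LINE1 elements, HinfI digestion cuts only templates
that were methylated (the restriction site survives bisulfite conversion at
methylated CpGs).  Band intensities from an electropherogram are converted to
molar amounts by dividing by fragment length — 246 bp for the cut
(methylated) product and 413 bp for the uncut (unmethylated) amplicon — and
the methylation index is the cut molar fraction.  A standard curve from
fully-methylated / fully-unmethylated control mixes corrects the systematic
distortion of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "CUT_LEN",
    "UNCUT_LEN",
    "BandMeasurement",
    "StandardCurve",
    "methylation_index",
    "fit_standard_curve",
    "correct_index",
]

CUT_LEN = 246  # bp, methylated (HinfI-cut) fragment
UNCUT_LEN = 413  # bp, unmethylated (uncut) amplicon


@dataclass(frozen=True)
class BandMeasurement:
    sample_id: str
    cut_intensity: float
    uncut_intensity: float
    cut_len: int = CUT_LEN
    uncut_len: int = UNCUT_LEN

    def __post_init__(self) -> None:
        if self.cut_intensity < 0 or self.uncut_intensity < 0:
            raise ValueError("band intensities must be non-negative")
        if self.cut_intensity == 0 and self.uncut_intensity == 0:
            raise ValueError("at least one band must have signal")


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    points: tuple[tuple[float, float], ...]  # (true %, raw index %)


def methylation_index(band: BandMeasurement) -> float:
    """Raw methylation index in percent.

    index = (cut/cut_len) / ((cut/cut_len) + (uncut/uncut_len)) × 100

    Length normalisation converts intensity (proportional to mass) into molar
    amount, so the index is invariant to overall signal scale.
    """
    cut_molar = band.cut_intensity / band.cut_len
    uncut_molar = band.uncut_intensity / band.uncut_len
    return 100.0 * cut_molar / (cut_molar + uncut_molar)


def fit_standard_curve(controls: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares line raw% = slope · true% + intercept through control mixes."""
    if len(controls) < 2:
        raise ValueError("need at least two control points")
    x = np.array([c[0] for c in controls], dtype=float)
    y = np.array([c[1] for c in controls], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("control points must span distinct true methylation levels")
    fit = scipy.stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        points=tuple((float(a), float(b)) for a, b in controls),
    )


def correct_index(raw_pct: float, curve: StandardCurve) -> float:
    """Invert the standard curve; clamp the corrected index to [0, 100]."""
    corrected = (raw_pct - curve.intercept) / curve.slope
    return float(min(100.0, max(0.0, corrected)))
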