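"""Absolute qPCR quantification of Methanobrevibacter groups.

Two clade-specific assays are quantified against plasmid standard curves:
SGMT (M. smithii / gottschalkii / millerae / thaueri, associated with higher
CH4 emission) and RO (M. ruminantium / olleyae, associated with lower
emission).  A standard curve is an ordinary least-squares fit of Cq on
log10(copies); amplification efficiency follows from its slope; sample Cq
values are back-converted to copies per mL rumen fluid through the template
volume and pre-dilution.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssaySample",
    "fit_standard_curve",
    "efficiency",
    "quantify",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """A sample Cq fell outside the calibrated standard-curve range."""


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Log-linear standard curve Cq = intercept + slope * log10(copies).

    ``slope`` is Cq per decade (negative); ``efficiency_pct`` is the
    per-cycle amplification efficiency implied by the slope.  ``cq_range``
    is the (min, max) Cq spanned by the calibration points; quantification
    outside it warns of extrapolation.
    """

    slope: float
    intercept: float
    r2: float = float("nan")
    cq_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not np.isnan(self.r2) and not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be within [0, 1]")

    @property
    def efficiency_pct(self) -> float:
        return efficiency(self.slope)


@dataclasses.dataclass(frozen=True)
class AssaySample:
    """Replicate Cq measurements of one rumen-fluid DNA sample.

    ``dilution`` is the pre-analysis dilution of the template (1:50 or
    1:100 in the reference protocol); ``template_volume`` the reaction's
    template volume in microlitres.
    """

    cow_id: str
    period: object
    target: str  # "SGMT" or "RO"
    cq_replicates: tuple[float, ...]
    dilution: float
    template_volume: float = 3.0

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution factor must be positive")
        if len(self.cq_replicates) < 1:
            raise ValueError("at least one Cq replicate is required")


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares fit of Cq on log10(copies).

    ``points`` is a sequence of (copies, Cq) pairs; at least three distinct
    positive copy levels are required.
    """
    pts = list(points)
    copies = np.array([p[0] for p in pts], dtype=float)
    cq = np.array([p[1] for p in pts], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    levels = np.unique(copies)
    if len(levels) < 3:
        raise ValueError("at least 3 distinct copy levels are required")
    res = stats.linregress(np.log10(copies), cq)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        cq_range=(float(cq.min()), float(cq.max())),
    )


def efficiency(slope: float) -> float:
    """Amplification efficiency in % implied by a standard-curve slope.

    E = (10^(1/|slope|) - 1) * 100; a slope magnitude of log2(10)^-1 decades
    per cycle (about 3.32) corresponds to perfect doubling, 100 %.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return (10.0 ** (1.0 / abs(slope)) - 1.0) * 100.0


def quantify(sample: AssaySample, curve: StandardCurve) -> float:
    """Copies per mL rumen fluid for one assay sample.

    Replicate Cq values are averaged before back-transformation (equivalent
    to a geometric mean of per-replicate copy estimates); copies per reaction
    are scaled by the pre-dilution and template volume:
    copies/mL = copies_rxn * dilution / template_volume(uL) * 1000.
    """
    cq = float(np.mean(sample.cq_replicates))
    if curve.cq_range is not None:
        lo, hi = curve.cq_range
        if not lo <= cq <= hi:
            warnings.warn(
                f"Cq {cq:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]; "
                "extrapolating the standard curve",
                ExtrapolationWarning,
                stacklevel=2,
            )
    copies_rxn = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return copies_rxn * sample.dilution / sample.template_volume * 1000.0


def quantify_samples(samples_df, curve: StandardCurve):
    """Quantify a qPCR sample table into copies/mL per cow and period.

    Replicate wells of one (cow, period, dilution) are pooled on the Cq
    scale; the per-dilution copies/mL estimates are then averaged on the
    log10 scale (the 1:50 and 1:100 dilutions are treated as independent
    measurements of the same sample).
    """
    import pandas as pd

    out = []
    for (cow, period, target), sub in samples_df.groupby(
        ["cow_id", "period", "target"], sort=True
    ):
        logs = []
        for dil, wells in sub.groupby("dilution"):
            s = AssaySample(
                cow_id=str(cow),
                period=period,
                target=str(target),
                cq_replicates=tuple(wells["cq"]),
                dilution=float(dil),
            )
            logs.append(np.log10(quantify(s, curve)))
        out.append((cow, period, target, 10.0 ** float(np.mean(logs))))
    return pd.DataFrame(out, columns=["cow_id", "period", "target", "copies_per_ml"])
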