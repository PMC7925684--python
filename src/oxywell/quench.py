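"""Stern–Volmer calibration and intensity ↔ PO2 conversion.

The oxygen-sensitive probe (RTDP in buffer) is collisionally quenched by
dissolved O2 following the first-order Stern–Volmer relation

    I0 / I = 1 + Kq [O2]

where ``I0`` is the fluorescence intensity at zero oxygen, ``Kq`` the
Stern–Volmer constant (per µM) and ``[O2]`` the dissolved oxygen
concentration (µM).  Partial pressure and concentration are interconverted
through the solubility coefficient ``alpha`` (µM per mmHg), so that

    PO2 = (I0/I - 1) / (Kq * alpha).

``alpha`` is a property of the suspending medium, not of the probe; the
default of 1.3 µM/mmHg corresponds to aqueous buffer near room temperature
and is configurable on :class:`QuenchModel`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuenchModel",
    "CalibrationSeries",
    "IntensityTrace",
    "PO2Trace",
    "sv_ratio",
    "fit_stern_volmer",
    "intensity_to_po2",
    "po2_to_intensity",
]

#: Default dissolved-O2 solubility of aqueous buffer, µM per mmHg.
DEFAULT_ALPHA_UM_PER_MMHG = 1.3

#: Fraction of clamped (I > I0) frames above which a well fails QC.
CLAMP_QC_FRACTION = 0.10


@dataclass(frozen=True)
class QuenchModel:
    """Parameters of the Stern–Volmer quenching/conversion model.

    Parameters
    ----------
    kq : float
        Stern–Volmer constant, µM⁻¹.  Must be positive.
    i0 : float
        Fluorescence intensity at zero oxygen, arbitrary units.
    alpha : float
        O2 solubility used to interconvert [O2] (µM) and PO2 (mmHg).
    """

    kq: float
    i0: float
    alpha: float = DEFAULT_ALPHA_UM_PER_MMHG

    def __post_init__(self) -> None:
        if not (self.kq > 0):
            raise ValueError(f"Kq must be positive, got {self.kq}")
        if not (self.i0 > 0):
            raise ValueError(f"I0 must be positive, got {self.i0}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as a JSON config block; optionally write to *path*."""
        blob = json.dumps(
            {"kq_per_uM": self.kq, "i0_au": self.i0, "alpha_uM_per_mmHg": self.alpha},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob

    @classmethod
    def from_json(cls, source: str | Path) -> "QuenchModel":
        """Load from a JSON string or file path."""
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        d = json.loads(text)
        return cls(kq=d["kq_per_uM"], i0=d["i0_au"], alpha=d["alpha_uM_per_mmHg"])

    def with_i0(self, i0: float) -> "QuenchModel":
        return replace(self, i0=i0)


@dataclass
class CalibrationSeries:
    """Matched O2 concentrations (µM) and fluorescence intensities (AU)."""

    o2_conc: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.o2_conc = np.asarray(self.o2_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.o2_conc.shape != self.intensity.shape or self.o2_conc.ndim != 1:
            raise ValueError("o2_conc and intensity must be 1-D and equal length")
        if len(self.o2_conc) < 3:
            raise ValueError("calibration needs at least 3 points")
        if np.any(self.o2_conc < 0):
            raise ValueError("O2 concentrations must be non-negative")
        if np.all(self.o2_conc == self.o2_conc[0]):
            raise ValueError("O2 concentrations must not all be equal")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"o2_conc_uM": self.o2_conc, "intensity_au": self.intensity}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationSeries":
        df = pd.read_csv(path)
        return cls(df["o2_conc_uM"].to_numpy(), df["intensity_au"].to_numpy())


@dataclass
class IntensityTrace:
    """Per-well mean fluorescence intensity versus time."""

    well_id: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D and equal length")
        if np.any(self.intensity < 0):
            raise ValueError(f"well {self.well_id}: negative intensities")


@dataclass
class PO2Trace:
    """Per-well oxygen partial pressure (mmHg) versus time (s).

    ``n_clamped`` counts frames whose intensity exceeded I0 and were clamped
    to PO2 = 0 during conversion; ``qc_pass`` is False when more than 10% of
    frames were clamped.
    """

    well_id: str
    time: np.ndarray
    po2: np.ndarray
    n_clamped: int = 0
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        if self.time.shape != self.po2.shape or self.time.ndim != 1:
            raise ValueError("time and po2 must be 1-D and equal length")
        if not np.all(np.isfinite(self.po2)):
            raise ValueError(f"well {self.well_id}: non-finite PO2 values")


def sv_ratio(o2_conc, model: QuenchModel):
    """Stern–Volmer quenching ratio I0/I at concentration *o2_conc* (µM).

    Returns ``1 + Kq * [O2]``; strictly increasing in [O2] and exactly 1 at
    zero oxygen.
    """
    c = np.asarray(o2_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("O2 concentration must be non-negative")
    out = 1.0 + model.kq * c
    return float(out) if np.isscalar(o2_conc) else out


def fit_stern_volmer(
    cal: CalibrationSeries,
    i0: float | None = None,
    alpha: float = DEFAULT_ALPHA_UM_PER_MMHG,
) -> QuenchModel:
    """Fit the Stern–Volmer constant from a calibration series.

    I0 is taken from the zero-concentration point (mean intensity if several)
    unless supplied; the line through (``[O2]``, ``I0/I - 1``) is then fit
    through the origin, matching the first-order equation form.  On data
    generated by :func:`sv_ratio` the recovery is exact to round-off.
    """
    if i0 is None:
        at_zero = cal.intensity[cal.o2_conc == 0]
        if at_zero.size == 0:
            raise ValueError(
                "calibration has no zero-concentration point; supply i0 explicitly"
            )
        i0 = float(np.mean(at_zero))
    if np.allclose(cal.intensity, cal.intensity[0]):
        raise ValueError("degenerate calibration: all intensities equal")
    if np.any(cal.intensity <= 0):
        raise ValueError("calibration intensities must be positive")
    y = i0 / cal.intensity - 1.0
    x = cal.o2_conc
    kq = float(np.dot(x, y) / np.dot(x, x))  # through-origin least squares
    if kq <= 0:
        raise ValueError(f"fitted Kq is non-positive ({kq}); intensities do not quench")
    return QuenchModel(kq=kq, i0=i0, alpha=alpha)


def intensity_to_po2(
    trace: IntensityTrace,
    model: QuenchModel,
    i0_tolerance: float = 0.01,
) -> PO2Trace:
    """Convert an intensity trace to PO2 via the inverted Stern–Volmer relation.

    PO2(t) = (I0/I(t) − 1) / (Kq·alpha).  Intensities above I0 (implying
    negative oxygen) are clamped to PO2 = 0.  Frames within the noise
    tolerance — I ≤ I0·(1 + i0_tolerance) — are clamped silently, as a
    fully deoxygenated well's read noise routinely strays just above I0;
    frames beyond it are counted, and a well with more than 10% such frames
    is marked QC-failed (its I0 or calibration is suspect).
    """
    i = trace.intensity
    if np.any(i <= 0):
        raise ValueError(f"well {trace.well_id}: non-positive intensities")
    po2 = (model.i0 / i - 1.0) / (model.kq * model.alpha)
    clamped = po2 < 0
    n_clamped = int(np.count_nonzero(i > model.i0 * (1.0 + i0_tolerance)))
    if clamped.any():
        po2 = np.where(clamped, 0.0, po2)
    frac = n_clamped / len(i)
    qc_pass = frac <= CLAMP_QC_FRACTION
    if not qc_pass:
        warnings.warn(
            f"well {trace.well_id}: {frac:.0%} of frames exceeded I0; QC-failed",
            stacklevel=2,
        )
    return PO2Trace(trace.well_id, trace.time, po2, n_clamped=n_clamped, qc_pass=qc_pass)


def po2_to_intensity(po2, model: QuenchModel):
    """Forward rendering relation: I = I0 / (1 + Kq·alpha·PO2)."""
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("PO2 must be non-negative")
    out = model.i0 / (1.0 + model.kq * model.alpha * p)
    return float(out) if np.isscalar(po2) else out
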