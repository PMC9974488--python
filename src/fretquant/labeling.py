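"""Labeling-efficiency arithmetic from dual-channel gel band intensities.

A self-labeling protein pre-labeled in cells with the probe of interest is
back-labeled in lysate with a second dye (Alexa488) that only reacts with
the remaining unlabeled fraction, while a third dye (SiR) on an orthogonal
tag reports total protein.  The labeling efficiency is

    LE(%) = 100 * (1 - (S_A488/S_SiR) / (C_A488/C_SiR))

where S are sample and C fully-unlabeled-control band intensities
(background-corrected upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GelBandQuad:
    """Background-corrected band intensities for one lane plus its control."""

    s_alexa488: float
    s_sir: float
    c_alexa488: float
    c_sir: float

    def __post_init__(self) -> None:
        vals = (self.s_alexa488, self.s_sir, self.c_alexa488, self.c_sir)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("band intensities must be finite")
        if self.s_alexa488 < 0 or self.s_sir < 0:
            raise ValueError("sample intensities must be non-negative")
        if self.c_alexa488 <= 0 or self.c_sir <= 0:
            raise ValueError("control intensities must be strictly positive")


@dataclass
class LabelingEfficiency:
    percent: float
    out_of_range: bool = False


@dataclass
class PlateauResult:
    plateaued: bool
    plateau_time: float | None
    plateau_value: float | None
    flags: list[str] = field(default_factory=list)


def labeling_efficiency(q: GelBandQuad) -> LabelingEfficiency:
    """LE(%) = 100 (1 - (S_A488/S_SiR)/(C_A488/C_SiR)); flags values outside [0, 100]."""
    if q.s_sir == 0:
        raise ZeroDivisionError("sample SiR intensity is zero: ratio undefined")
    le = 100.0 * (1.0 - (q.s_alexa488 / q.s_sir) / (q.c_alexa488 / q.c_sir))
    return LabelingEfficiency(float(le), out_of_range=not 0.0 <= le <= 100.0)


def labeling_timecourse(times_h, ratios, rel_tol: float = 0.02) -> PlateauResult:
    """Detect when a labeling time-course has plateaued.

    The plateau is the earliest time point after which every consecutive
    relative change of the acceptor/donor intensity ratio stays below
    ``rel_tol`` (default 2%).  Returns the plateau onset time and the mean
    ratio over the plateau, or a "not plateaued" flag.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape:
        raise ValueError("times and ratios must have equal length")
    if t.size < 4:
        raise ValueError("at least 4 time points are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    scale = np.abs(r[1:])
    scale[scale == 0] = 1.0
    rel = np.abs(np.diff(r)) / scale
    flat = rel < rel_tol
    # earliest index i such that all steps from i onward are flat
    onset = None
    for i in range(flat.size, -1, -1):
        if np.all(flat[i:]):
            onset = i
        else:
            break
    if onset is None or onset == flat.size:
        return PlateauResult(False, None, None, ["not plateaued"])
    return PlateauResult(True, float(t[onset]), float(r[onset:].mean()))
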