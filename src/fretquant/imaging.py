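"""Sensitized-emission FRET imaging with spectral bleedthrough correction.

Three channels are acquired per field of view (FOV): the donor channel
(donor excitation/donor emission), the acceptor channel (acceptor
excitation/acceptor emission) and the FRET channel (donor excitation,
acceptor emission).  The FRET channel is contaminated by donor and acceptor
bleedthrough; the net FRET per pixel is

    netFRET = (I_FRET - I_donor * BT_d - I_acceptor * BT_a) / sqrt(I_donor * I_acceptor)

with the bleedthrough factors BT_d, BT_a measured on single-fluorophore
control samples.  Cells (ROIs) are segmented by intensity thresholding on
the donor channel; per-cell net FRET is normalized against a matched
fully-open control probe, and conditions are compared on FOV-level means
with a two-tailed unpaired t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass
class ImageSet:
    """One FOV's three-channel acquisition (donor / acceptor / FRET settings)."""

    donor_img: np.ndarray
    acceptor_img: np.ndarray
    fret_img: np.ndarray
    fov_id: str = ""
    condition: str = ""
    probe: str = ""  # e.g. responsive probe vs fully-open control
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.donor_img = np.asarray(self.donor_img, dtype=float)
        self.acceptor_img = np.asarray(self.acceptor_img, dtype=float)
        self.fret_img = np.asarray(self.fret_img, dtype=float)
        shapes = {self.donor_img.shape, self.acceptor_img.shape, self.fret_img.shape}
        if len(shapes) != 1:
            raise ValueError("channel images must share one shape")
        if self.donor_img.ndim != 2:
            raise ValueError("channels must be 2-D single-channel rasters")
        for name, img in (("donor", self.donor_img), ("acceptor", self.acceptor_img),
                          ("fret", self.fret_img)):
            if not np.all(np.isfinite(img)):
                raise ValueError(f"{name} image contains non-finite values")
            if np.any(img < 0):
                raise ValueError(f"{name} image contains negative intensities")


@dataclass
class BleedthroughFactors:
    """Fractions of pure donor/acceptor signal leaking into the FRET channel."""

    bt_donor: float = 0.0
    bt_acceptor: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.bt_donor) and np.isfinite(self.bt_acceptor)):
            raise ValueError("bleedthrough factors must be finite")
        if self.bt_donor < 0 or self.bt_acceptor < 0:
            raise ValueError("bleedthrough factors must be non-negative")


@dataclass
class ConditionComparison:
    condition: str
    control: str
    ratio_change_pct: float
    sem_pct: float
    n_condition: int
    n_control: int
    p_value: float
    warnings: list[str] = field(default_factory=list)


def estimate_background(img: np.ndarray) -> float:
    """Constant camera/detector background as the image median.

    Assumes cells cover well under half the field of view, so the median
    pixel is a background pixel; exact on noiseless images and unbiased
    under Poisson noise (the Poisson median tracks its mean closely).
    """
    return float(np.median(img))


def estimate_bleedthrough(control_images, channel: str, background_floor: float = 0.0,
                          subtract_background: bool = True) -> float:
    """Bleedthrough factor from single-fluorophore control images.

    Robust central (median) ratio of FRET-channel to source-channel intensity
    over pixels whose background-corrected source intensity exceeds
    ``background_floor``.  The median resists hot pixels; the per-channel
    constant background (image median, see :func:`estimate_background`) is
    subtracted from both channels first unless disabled, since an additive
    offset would otherwise inflate the ratio.
    """
    if channel not in ("donor", "acceptor"):
        raise ValueError("channel must be 'donor' or 'acceptor'")
    ratios = []
    for imgs in control_images:
        src = imgs.donor_img if channel == "donor" else imgs.acceptor_img
        fret = imgs.fret_img
        if subtract_background:
            src = src - estimate_background(src)
            fret = fret - estimate_background(fret)
        sel = src > background_floor
        if np.any(sel):
            ratios.append(fret[sel] / src[sel])
    if not ratios:
        raise ValueError("no pixels above the background floor in any control image")
    return float(np.median(np.concatenate(ratios)))


def net_fret_image(imgs: ImageSet, bt: BleedthroughFactors,
                   intensity_floor: float = 0.0,
                   background: tuple[float, float, float] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise bleedthrough-corrected net FRET raster and validity mask.

    Pixels whose donor*acceptor product does not exceed ``intensity_floor``
    squared (background, or either fluorophore absent) are masked invalid and
    set to 0 in the returned raster, never NaN.  ``background`` optionally
    gives per-channel constants (donor, acceptor, fret) subtracted before the
    computation; off by default.
    """
    if intensity_floor < 0:
        raise ValueError("intensity_floor must be non-negative")
    d, a, f = imgs.donor_img, imgs.acceptor_img, imgs.fret_img
    if background is not None:
        bg_d, bg_a, bg_f = background
        d, a, f = d - bg_d, a - bg_a, f - bg_f
    valid = (d > 0) & (a > 0) & (d * a > intensity_floor * intensity_floor)
    net = np.zeros_like(f)
    net[valid] = (f[valid] - d[valid] * bt.bt_donor - a[valid] * bt.bt_acceptor) \
        / np.sqrt(d[valid] * a[valid])
    return net, valid


def net_fret_reference(imgs: ImageSet, bt: BleedthroughFactors,
                       intensity_floor: float = 0.0,
                       background: tuple[float, float, float] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Scalar per-pixel reference implementation of :func:`net_fret_image`.

    A deliberate brute-force double loop in the same operation order, kept as
    an independent cross-check of the vectorized path.
    """
    bg_d, bg_a, bg_f = background if background is not None else (0.0, 0.0, 0.0)
    h, w = imgs.fret_img.shape
    net = np.zeros((h, w), dtype=float)
    valid = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            d = imgs.donor_img[i, j] - bg_d
            a = imgs.acceptor_img[i, j] - bg_a
            f = imgs.fret_img[i, j] - bg_f
            if d > 0 and a > 0 and d * a > intensity_floor * intensity_floor:
                valid[i, j] = True
                net[i, j] = (f - d * bt.bt_donor - a * bt.bt_acceptor) / np.sqrt(d * a)
    return net, valid


def segment_rois(gfp_img: np.ndarray, method: str = "otsu", min_pixels: int = 50) -> np.ndarray:
    """Label cells in a single-channel image by intensity thresholding.

    Otsu threshold on the donor (GFP) channel, 8-connected components,
    components below ``min_pixels`` dropped, labels renumbered 1..n in raster
    order.  Deterministic for fixed input.
    """
    gfp_img = np.asarray(gfp_img, dtype=float)
    if gfp_img.ndim != 2:
        raise ValueError("segmentation expects a 2-D single-channel image")
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    if np.ptp(gfp_img) == 0:
        warnings.warn("blank image: no ROIs found", stacklevel=2)
        return np.zeros(gfp_img.shape, dtype=int)
    thresh = threshold_otsu(gfp_img)
    labels = label(gfp_img > thresh, connectivity=2)
    out = np.zeros_like(labels)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_pixels:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no ROIs above the minimum size", stacklevel=2)
    return out


def roi_table(labels: np.ndarray, net: np.ndarray, valid: np.ndarray,
              fov_id: str = "", condition: str = "") -> pd.DataFrame:
    """Per-ROI mean net FRET over valid pixels.

    Columns: roi_id, pixel_count, mean_net_fret, fov_id, condition.  ROIs
    whose pixels are all invalid are dropped.
    """
    records = []
    for roi_id in np.unique(labels):
        if roi_id == 0:
            continue
        sel = (labels == roi_id) & valid
        if not np.any(sel):
            continue
        records.append({
            "roi_id": int(roi_id),
            "pixel_count": int(sel.sum()),
            "mean_net_fret": float(net[sel].mean()),
            "fov_id": fov_id,
            "condition": condition,
        })
    return pd.DataFrame(records, columns=["roi_id", "pixel_count", "mean_net_fret",
                                          "fov_id", "condition"])


def normalized_fret(net_taz: float, net_me: float, orientation: str = "printed") -> float:
    """Normalized FRET (%) of a responsive-probe ROI against its open control.

    ``printed`` orientation returns net_control/net_probe x 100 (the form the
    imaging plugin reports); ``inverted`` returns net_probe/net_control x 100
    (normalizing the probe against the fully open sensor).  Both are exposed
    because the two descriptions circulate; neither is asserted correct.
    """
    if orientation not in ("printed", "inverted"):
        raise ValueError("orientation must be 'printed' or 'inverted'")
    num, den = (net_me, net_taz) if orientation == "printed" else (net_taz, net_me)
    if den == 0:
        raise ZeroDivisionError("zero denominator in normalized FRET")
    return 100.0 * num / den


def ratio_change(cond_fov_means, ctrl_fov_means) -> tuple[float, float]:
    """Percent change of condition vs control normalized FRET, with s.e.m.

    FOV means are the statistical unit.  Returns
    100*(mean_cond - mean_ctrl)/mean_ctrl and its standard error propagated
    to first order across the two groups of FOV-level means.
    """
    a = np.asarray(cond_fov_means, dtype=float)
    b = np.asarray(ctrl_fov_means, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("at least 2 FOVs per group are required")
    ma, mb = a.mean(), b.mean()
    if mb == 0:
        raise ValueError("control mean is zero: ratio change undefined")
    sea = a.std(ddof=1) / np.sqrt(a.size)
    seb = b.std(ddof=1) / np.sqrt(b.size)
    pct = 100.0 * (ma - mb) / mb
    # delta method on r = a/b - 1
    sem = 100.0 * np.sqrt((sea / mb) ** 2 + (ma * seb / mb**2) ** 2)
    return float(pct), float(sem)


def compare_conditions(group_a, group_b) -> float:
    """Two-tailed unpaired (Student) t-test p-value on FOV-level means."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 FOVs for a t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("degenerate variance in both groups; p undefined", stacklevel=2)
            return float("nan")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def analyze_fovs(image_sets, bt: BleedthroughFactors | None = None,
                 min_pixels: int = 50, orientation: str = "printed",
                 subtract_background: bool = True
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full FOV workflow: bleedthrough, net FRET, ROIs, normalized FRET.

    ``image_sets`` mixes responsive-probe FOVs (probe ``"TAZ"``), matched
    open-control FOVs (probe ``"Me"``) and, when ``bt`` is not given,
    single-fluorophore controls (probe ``"donor-only"``/``"acceptor-only"``)
    from which the bleedthrough factors are estimated.  Per channel a
    constant background (image median) is subtracted and the validity floor
    is set to three Poisson standard deviations of the background.  Returns
    the per-ROI table and the per-FOV normalized-FRET table (each responsive
    FOV normalized against its condition's pooled open-control mean).
    """
    sets = list(image_sets)
    if bt is None:
        floor0 = _default_floor(sets[0]) if sets else 0.0
        donor_only = [s for s in sets if s.probe == "donor-only"]
        acc_only = [s for s in sets if s.probe == "acceptor-only"]
        if not donor_only or not acc_only:
            raise ValueError("bleedthrough controls missing and no factors given")
        bt = BleedthroughFactors(
            estimate_bleedthrough(donor_only, "donor", floor0,
                                  subtract_background=subtract_background),
            estimate_bleedthrough(acc_only, "acceptor", floor0,
                                  subtract_background=subtract_background))

    tables = []
    for s in sets:
        if s.probe not in ("TAZ", "Me"):
            continue
        if subtract_background:
            background = (estimate_background(s.donor_img),
                          estimate_background(s.acceptor_img),
                          estimate_background(s.fret_img))
            floor = 3.0 * math.sqrt(math.sqrt(max(background[0], 1e-12))
                                    * math.sqrt(max(background[1], 1e-12)))
        else:
            background, floor = None, 0.0
        net, valid = net_fret_image(s, bt, intensity_floor=floor, background=background)
        labels = segment_rois(s.donor_img, min_pixels=min_pixels)
        tab = roi_table(labels, net, valid, fov_id=s.fov_id, condition=s.condition)
        tab["probe"] = s.probe
        tables.append(tab)
    if not tables:
        raise ValueError("no responsive-probe or open-control FOVs supplied")
    rois = pd.concat(tables, ignore_index=True)

    fov_rows = []
    for cond, grp in rois.groupby("condition"):
        me = grp[grp["probe"] == "Me"]["mean_net_fret"]
        if me.empty:
            continue
        me_mean = float(me.mean())
        for fov, g in grp[grp["probe"] == "TAZ"].groupby("fov_id"):
            fov_rows.append({"condition": cond, "fov_id": fov,
                             "normalized_fret_pct": normalized_fret(
                                 float(g["mean_net_fret"].mean()), me_mean, orientation)})
    return rois, pd.DataFrame(fov_rows, columns=["condition", "fov_id",
                                                 "normalized_fret_pct"])


def _default_floor(imgs: ImageSet) -> float:
    bg_d = estimate_background(imgs.donor_img)
    bg_a = estimate_background(imgs.acceptor_img)
    return 3.0 * math.sqrt(math.sqrt(max(bg_d, 1e-12)) * math.sqrt(max(bg_a, 1e-12)))


def condition_comparison(condition: str, control: str, cond_fov_means,
                         ctrl_fov_means) -> ConditionComparison:
    """Bundle ratio change, s.e.m. and t-test for one condition vs its control."""
    pct, sem = ratio_change(cond_fov_means, ctrl_fov_means)
    p = compare_conditions(cond_fov_means, ctrl_fov_means)
    warns = [] if np.isfinite(p) else ["degenerate variance: p undefined"]
    return ConditionComparison(condition, control, pct, sem,
                               len(cond_fov_means), len(ctrl_fov_means), p, warns)
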