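"""Seeded generators for every input class the pipeline consumes.

The generators emulate the study designs the pipeline is built for:

* plate-reader titrations of the ratiometric sensor over a 12.8 nM - 1 mM
  concentration ladder with multiplicative Gaussian readout noise,
* fluorescence-polarization direct and competition series,
* three-channel confocal FOVs (512x512, >50 disc-shaped cells) composed with
  known bleedthrough mixing, constant background and Poisson shot noise,
* TCSPC decay histograms sampled multinomially from a multi-exponential
  model at 10^3 - 10^6 photons,
* gel-band quadruples for labeling efficiency.

Every generator takes a :class:`SyntheticScenario` whose fields ARE the
ground truth; truth is returned alongside each dataset so recovery can be
asserted.  No biology is simulated: truth values are injected.  A fixed seed
reproduces outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .binding import FPSeries, IsothermFit, TitrationSeries, fp_direct_forward, hyperbola
from .flim import DecayHistogram
from .imaging import BleedthroughFactors, ImageSet

#: (r_min, r_max, c50_uM) per sensor variant; dynamic range 2.8-fold with
#: half-response points spanning ~2.4 uM to ~1 mM across the variant series.
SENSOR_VARIANTS: dict[str, tuple[float, float, float]] = {
    "G41": (1.0, 2.8, 13.9),
    "G41S": (1.0, 2.8, 58.9),
    "G41N": (1.0, 2.8, 957.0),
    "V97T": (1.0, 2.8, 2.4),
}


@dataclass
class ImageGeometry:
    shape: tuple[int, int] = (512, 512)
    n_cells: int = 55
    radius_px: tuple[float, float] = (5.0, 9.0)
    background: float = 20.0
    acceptor_amplitude: tuple[float, float] = (200.0, 400.0)
    netfret_open: float = 0.2
    netfret_closed: float = 0.8
    max_placement_tries: int = 20000


@dataclass
class DecayTruth:
    n_bins: int = 256
    window_ns: float = 25.0  # one 40 MHz pulse period
    tau_donor_ns: float = 2.6
    tau_quenched_ns: float = 0.8
    e_min: float = 0.05
    e_max: float = 0.45
    photons_per_roi: float = 1e6


@dataclass
class SyntheticScenario:
    """Ground-truth description of one synthetic experiment."""

    seed: int = 0
    sensor_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(SENSOR_VARIANTS))
    concentration_ladder: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.0128, 1000.0, 12))
    ratio_noise_sd: float = 0.01
    n_replicates: int = 3
    image: ImageGeometry = field(default_factory=ImageGeometry)
    bt_donor: float = 0.15
    bt_acceptor: float = 0.10
    decay: DecayTruth = field(default_factory=DecayTruth)
    fp_tracer_uM: float = 0.05
    fp_kd_uM: float = 1.2
    fp_free: float = 0.05
    fp_bound: float = 0.30
    fp_noise_sd: float = 0.002  # 2 mFP
    compartment_truth: dict[str, float] = field(
        default_factory=lambda: {"cytosol": 75.0, "mitochondria": 500.0})

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def isotherm(self, variant: str) -> IsothermFit:
        rmin, rmax, c50 = self.sensor_params[variant]
        return IsothermFit(rmin, rmax, c50)


# ---------------------------------------------------------------------------
# titrations and FP
# ---------------------------------------------------------------------------


def gen_titration(scenario: SyntheticScenario, variant: str = "G41",
                  analyte: str = "CoA", noise: bool = True,
                  rng: np.random.Generator | None = None):
    """Noisy replicate titration of one sensor variant.

    Ratios are Eq-of-state means times (1 + eps), eps ~ N(0, sd^2), drawn
    independently per replicate and concentration.  Returns the pooled
    :class:`TitrationSeries` and a truth dict.
    """
    rng = rng or scenario.rng(1)
    rmin, rmax, c50 = scenario.sensor_params[variant]
    ladder = np.asarray(scenario.concentration_ladder, dtype=float)
    concs, ratios, reps = [], [], []
    for rep in range(scenario.n_replicates):
        mean = hyperbola(ladder, rmin, rmax, c50)
        eps = rng.normal(0.0, scenario.ratio_noise_sd, size=ladder.size) if noise else 0.0
        concs.append(ladder)
        ratios.append(mean * (1.0 + eps))
        reps.append(np.full(ladder.size, rep))
    series = TitrationSeries(analyte, np.concatenate(concs), np.concatenate(ratios),
                             np.concatenate(reps))
    truth = {"variant": variant, "r_min": rmin, "r_max": rmax, "c50_uM": c50,
             "noise_sd": scenario.ratio_noise_sd if noise else 0.0}
    return series, truth


def gen_fp_series(scenario: SyntheticScenario, mode: str = "direct",
                  competition_c50_uM: float = 13.9, n_points: int = 12,
                  noise: bool = True, rng: np.random.Generator | None = None):
    """FP series from the depletion quadratic (direct) or hyperbola (competition)."""
    rng = rng or scenario.rng(2)
    if mode == "direct":
        x = np.concatenate([[0.0], np.geomspace(scenario.fp_kd_uM / 30,
                                                scenario.fp_kd_uM * 30, n_points - 1)])
        mean = fp_direct_forward(x, scenario.fp_free, scenario.fp_bound,
                                 scenario.fp_kd_uM, scenario.fp_tracer_uM)
        truth = {"kd_uM": scenario.fp_kd_uM, "fp0": scenario.fp_free,
                 "fps": scenario.fp_bound, "tracer_uM": scenario.fp_tracer_uM}
    elif mode == "competition":
        x = np.concatenate([[0.0], np.geomspace(0.064, 5000.0, n_points - 1)])
        mean = hyperbola(x, scenario.fp_bound, scenario.fp_free, competition_c50_uM)
        truth = {"c50_uM": competition_c50_uM, "fp0": scenario.fp_bound,
                 "fps": scenario.fp_free}
    else:
        raise ValueError(f"unknown FP mode {mode!r}")
    fp = mean + (rng.normal(0.0, scenario.fp_noise_sd, size=x.size) if noise else 0.0)
    fp = np.clip(fp, -1.0, 1.0)
    series = FPSeries(x, fp, mode,
                      tracer_conc=scenario.fp_tracer_uM if mode == "direct" else None)
    return series, truth


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def true_net_fret(scenario: SyntheticScenario, coa_uM: float, variant: str,
                  probe: str = "TAZ") -> float:
    """Ground-truth per-cell net FRET of the generator's forward model.

    The responsive probe interpolates between the closed (zero analyte) and
    open (saturating analyte) net-FRET levels along the variant's binding
    hyperbola; the open-control probe sits at the open level regardless of
    analyte.
    """
    g = scenario.image
    if probe == "Me":
        return g.netfret_open
    _, _, c50 = scenario.sensor_params[variant]
    return float(hyperbola(coa_uM, g.netfret_closed, g.netfret_open, c50))


def conc_for_normalized_fret(scenario: SyntheticScenario, target_pct: float,
                             variant: str) -> float:
    """Analyte concentration whose normalized FRET (open/probe x 100) is ``target_pct``."""
    g = scenario.image
    net_probe = 100.0 * g.netfret_open / target_pct
    if not g.netfret_open < net_probe < g.netfret_closed:
        raise ValueError("target normalized FRET unreachable for this geometry")
    _, _, c50 = scenario.sensor_params[variant]
    return c50 * ((g.netfret_closed - g.netfret_open) / (net_probe - g.netfret_open) - 1.0)


def _place_cells(geom: ImageGeometry, rng: np.random.Generator):
    """Non-overlapping random discs; bounded retries then error."""
    h, w = geom.shape
    placed: list[tuple[float, float, float]] = []
    tries = 0
    while len(placed) < geom.n_cells:
        tries += 1
        if tries > geom.max_placement_tries:
            raise RuntimeError("could not place non-overlapping cells; "
                               "reduce n_cells or radius")
        r = rng.uniform(*geom.radius_px)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 2.0) ** 2
               for y, x, rr in placed):
            placed.append((cy, cx, r))
    return placed


def gen_image_set(scenario: SyntheticScenario, condition: str = "", coa_uM: float = 75.0,
                  variant: str = "V97T", probe: str = "TAZ", fov_id: str = "fov0",
                  noise: bool = True, rng: np.random.Generator | None = None):
    """One three-channel FOV with known ground truth.

    Cells are hard discs.  Per cell, the acceptor amplitude A is drawn
    uniformly, the donor amplitude is D = R([CoA]) * A through the variant's
    emission-ratio isotherm, and the FRET channel is composed as the true
    sensitized emission netFRET * sqrt(D*A) plus bleedthrough BT_d*D +
    BT_a*A.  A constant background is added to all channels; Poisson shot
    noise is applied when ``noise`` is set.  Returns (ImageSet, truth dict).
    """
    rng = rng or scenario.rng(3)
    geom = scenario.image
    if geom.n_cells < 1:
        raise ValueError("need at least one cell")
    rmin, rmax, c50 = scenario.sensor_params[variant]
    ratio = float(hyperbola(coa_uM, rmin, rmax, c50)) if probe == "TAZ" else rmax
    nf = true_net_fret(scenario, coa_uM, variant, probe)

    h, w = geom.shape
    donor = np.full((h, w), geom.background, dtype=float)
    acceptor = np.full((h, w), geom.background, dtype=float)
    fret = np.full((h, w), geom.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    cells = _place_cells(geom, rng)
    for cy, cx, r in cells:
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        a_amp = rng.uniform(*geom.acceptor_amplitude)
        d_amp = ratio * a_amp
        donor[disc] += d_amp
        acceptor[disc] += a_amp
        fret[disc] += nf * np.sqrt(d_amp * a_amp) \
            + scenario.bt_donor * d_amp + scenario.bt_acceptor * a_amp
    if noise:
        donor = rng.poisson(donor).astype(float)
        acceptor = rng.poisson(acceptor).astype(float)
        fret = rng.poisson(fret).astype(float)
    imgs = ImageSet(donor, acceptor, fret, fov_id=fov_id, condition=condition,
                    probe=probe, pixel_size_um=0.379)
    truth = {"coa_uM": coa_uM, "variant": variant, "probe": probe,
             "net_fret": nf, "emission_ratio": ratio, "n_cells": len(cells),
             "bt_donor": scenario.bt_donor, "bt_acceptor": scenario.bt_acceptor,
             "background": geom.background}
    return imgs, truth


def gen_control_image(scenario: SyntheticScenario, channel: str = "donor",
                      fov_id: str = "ctrl0", noise: bool = True,
                      rng: np.random.Generator | None = None):
    """Single-fluorophore control FOV for bleedthrough estimation.

    Only the named fluorophore is present: its own channel carries the cells,
    the FRET channel carries only the corresponding bleedthrough fraction,
    and the other channel is background.
    """
    rng = rng or scenario.rng(4)
    geom = scenario.image
    h, w = geom.shape
    bt = scenario.bt_donor if channel == "donor" else scenario.bt_acceptor
    source = np.full((h, w), geom.background, dtype=float)
    other = np.full((h, w), geom.background, dtype=float)
    fret = np.full((h, w), geom.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, r in _place_cells(geom, rng):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        amp = rng.uniform(*geom.acceptor_amplitude)
        source[disc] += amp
        fret[disc] += bt * amp
    if noise:
        source = rng.poisson(source).astype(float)
        other = rng.poisson(other).astype(float)
        fret = rng.poisson(fret).astype(float)
    if channel == "donor":
        imgs = ImageSet(source, other, fret, fov_id=fov_id, probe="donor-only")
    elif channel == "acceptor":
        imgs = ImageSet(other, source, fret, fov_id=fov_id, probe="acceptor-only")
    else:
        raise ValueError("channel must be 'donor' or 'acceptor'")
    return imgs, {"channel": channel, "bt": bt, "background": geom.background}


# ---------------------------------------------------------------------------
# decays
# ---------------------------------------------------------------------------


def decay_components_for_conc(scenario: SyntheticScenario, coa_uM: float | None):
    """Ground-truth decay components for a given analyte concentration.

    The donor-only sample (``coa_uM=None``) is monoexponential at tau_D.  A
    FRET sample is a two-population mixture of the quenched (short-lifetime)
    and unquenched (tau_D) sensor states whose amplitude-weighted mean
    lifetime reproduces tau_D * (1 - E(c)) for the calibration hyperbola
    E(c) = E_min + (E_max - E_min)/(1 + c50/c) of the G41S variant.
    """
    d = scenario.decay
    if coa_uM is None:
        return np.array([1.0]), np.array([d.tau_donor_ns])
    _, _, c50 = scenario.sensor_params["G41S"]
    e = float(hyperbola(coa_uM, d.e_min, d.e_max, c50))
    tau_aw = d.tau_donor_ns * (1.0 - e)
    frac_short = (d.tau_donor_ns - tau_aw) / (d.tau_donor_ns - d.tau_quenched_ns)
    frac_short = float(np.clip(frac_short, 0.0, 1.0))
    return (np.array([frac_short, 1.0 - frac_short]),
            np.array([d.tau_quenched_ns, d.tau_donor_ns]))


def gen_decay(scenario: SyntheticScenario, amplitudes=None, lifetimes_ns=None,
              photons: float | None = None, coa_uM: float | None = None,
              noise: bool = True, rng: np.random.Generator | None = None):
    """TCSPC histogram sampled multinomially from a multi-exponential model.

    Components are given either explicitly (``amplitudes``/``lifetimes_ns``)
    or through ``coa_uM`` via :func:`decay_components_for_conc`.  Without
    noise the histogram carries the exact expected (fractional) counts.
    """
    rng = rng or scenario.rng(5)
    d = scenario.decay
    if amplitudes is None or lifetimes_ns is None:
        amplitudes, lifetimes_ns = decay_components_for_conc(scenario, coa_uM)
    amplitudes = np.asarray(amplitudes, dtype=float)
    lifetimes_ns = np.asarray(lifetimes_ns, dtype=float)
    photons = d.photons_per_roi if photons is None else float(photons)
    if photons < 100:
        raise ValueError("at least 100 photons are required")
    edges = np.linspace(0.0, d.window_ns, d.n_bins, endpoint=False)
    centers = edges + 0.5 * d.window_ns / d.n_bins
    weights = np.zeros_like(centers)
    for a, tau in zip(amplitudes, lifetimes_ns):
        weights += a * np.exp(-centers / tau)
    p = weights / weights.sum()
    counts = rng.multinomial(int(photons), p).astype(float) if noise else photons * p
    truth = {"amplitudes": amplitudes.tolist(), "lifetimes_ns": lifetimes_ns.tolist(),
             "photons": photons, "coa_uM": coa_uM}
    return DecayHistogram(edges, counts), truth


def gen_flim_titration(scenario: SyntheticScenario, ladder=None,
                       photons: float | None = None, noise: bool = True,
                       rng: np.random.Generator | None = None):
    """Lifetime titration (conc, decay) pairs plus a donor-only decay."""
    rng = rng or scenario.rng(6)
    ladder = np.asarray(scenario.concentration_ladder if ladder is None else ladder,
                        dtype=float)
    pairs = [(float(c), gen_decay(scenario, coa_uM=float(c), photons=photons,
                                  noise=noise, rng=rng)[0]) for c in ladder]
    donor, _ = gen_decay(scenario, coa_uM=None, photons=photons, noise=noise, rng=rng)
    d = scenario.decay
    _, _, c50 = scenario.sensor_params["G41S"]
    truth = {"tau_donor_ns": d.tau_donor_ns, "e_min": d.e_min, "e_max": d.e_max,
             "c50_uM": c50}
    return pairs, donor, truth


# ---------------------------------------------------------------------------
# gel bands
# ---------------------------------------------------------------------------


def gen_gel_quad(scenario: SyntheticScenario, efficiency_pct: float = 96.0,
                 noise_sd: float = 0.0, rng: np.random.Generator | None = None):
    """Gel-band quadruple with a constructed labeling efficiency."""
    rng = rng or scenario.rng(7)
    from .labeling import GelBandQuad
    c_a488, c_sir = 1000.0, 800.0
    s_sir = 900.0
    s_a488 = (1.0 - efficiency_pct / 100.0) * (c_a488 / c_sir) * s_sir
    if noise_sd > 0:
        s_a488 *= max(1.0 + rng.normal(0, noise_sd), 0.0)
        s_sir *= max(1.0 + rng.normal(0, noise_sd), 0.0)
    return GelBandQuad(s_a488, s_sir, c_a488, c_sir), {"efficiency_pct": efficiency_pct}


# ---------------------------------------------------------------------------
# on-disk experiment bundle
# ---------------------------------------------------------------------------


def gen_experiment(scenario: SyntheticScenario, out_dir, n_fovs: int = 2,
                   conditions=("control", "treated"),
                   coa_by_condition: dict[str, float] | None = None,
                   variant: str = "V97T") -> Path:
    """Write a directory bundle (CSV + TIFF + manifest + truth JSON).

    The layout is the one the command-line interface consumes end to end:
    a titration CSV, an FP CSV, decay CSVs, gel CSV, per-FOV channel TIFFs
    for probe and open-control samples plus single-fluorophore controls,
    an imaging manifest, and ``truth.json`` holding every generating value.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coa = coa_by_condition or {c: scenario.compartment_truth["cytosol"] * (1.0 + 0.3 * i)
                               for i, c in enumerate(conditions)}

    series, t_truth = gen_titration(scenario, variant=variant)
    pd.DataFrame({"analyte": series.analyte_name,
                  "conc_uM": series.concentrations,
                  "ratio": series.ratios,
                  "replicate": series.replicate_id}).to_csv(out / "titration.csv",
                                                            index=False)
    fp, fp_truth = gen_fp_series(scenario, mode="direct")
    pd.DataFrame({"x_uM": fp.x_values, "fp": fp.fp_values, "mode": fp.mode,
                  "tracer_uM": fp.tracer_conc}).to_csv(out / "fp_direct.csv", index=False)

    decay, d_truth = gen_decay(scenario, coa_uM=coa[conditions[0]], photons=1e5)
    pd.DataFrame({"t_ns": decay.bin_time_ns,
                  "counts": decay.counts}).to_csv(out / "decay_roi0.csv", index=False)

    quad, g_truth = gen_gel_quad(scenario)
    pd.DataFrame([{"sample_id": "lane0", "s_a488": quad.s_alexa488, "s_sir": quad.s_sir,
                   "c_a488": quad.c_alexa488, "c_sir": quad.c_sir}]).to_csv(
        out / "gel_bands.csv", index=False)

    rows = []
    rng = scenario.rng(8)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for cond in conditions:
        for i in range(n_fovs):
            for probe in ("TAZ", "Me"):
                fov = f"{cond}_{probe}_{i}"
                imgs, _ = gen_image_set(scenario, condition=cond, coa_uM=coa[cond],
                                        variant=variant, probe=probe, fov_id=fov, rng=rng)
                paths = {}
                for ch, arr in (("donor", imgs.donor_img), ("acceptor", imgs.acceptor_img),
                                ("fret", imgs.fret_img)):
                    p = img_dir / f"{fov}_{ch}.tif"
                    tifffile.imwrite(p, arr.astype(np.float32))
                    paths[ch] = p.relative_to(out).as_posix()
                rows.append({"fov_id": fov, "condition": cond, "probe": probe, **paths})
    for ch in ("donor", "acceptor"):
        ctrl, _ = gen_control_image(scenario, channel=ch, rng=rng)
        paths = {}
        for name, arr in (("donor", ctrl.donor_img), ("acceptor", ctrl.acceptor_img),
                          ("fret", ctrl.fret_img)):
            p = img_dir / f"{ch}_only_{name}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            paths[name] = p.relative_to(out).as_posix()
        rows.append({"fov_id": f"{ch}_only", "condition": "control-sample",
                     "probe": f"{ch}-only", **paths})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)

    truth = {"scenario": _scenario_dict(scenario), "titration": t_truth,
             "fp_direct": fp_truth, "decay_roi0": d_truth, "gel": g_truth,
             "coa_by_condition": coa}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def scenario_from_dict(d: dict) -> SyntheticScenario:
    """Build a scenario from a plain (JSON-loaded) dict, coercing nested blocks."""
    d = dict(d)
    if "image" in d and isinstance(d["image"], dict):
        img = dict(d["image"])
        if "shape" in img:
            img["shape"] = tuple(img["shape"])
        if "radius_px" in img:
            img["radius_px"] = tuple(img["radius_px"])
        if "acceptor_amplitude" in img:
            img["acceptor_amplitude"] = tuple(img["acceptor_amplitude"])
        d["image"] = ImageGeometry(**img)
    if "decay" in d and isinstance(d["decay"], dict):
        d["decay"] = DecayTruth(**d["decay"])
    if "concentration_ladder" in d:
        d["concentration_ladder"] = np.asarray(d["concentration_ladder"], dtype=float)
    if "sensor_params" in d:
        d["sensor_params"] = {k: tuple(v) for k, v in d["sensor_params"].items()}
    return SyntheticScenario(**d)


def _scenario_dict(scenario: SyntheticScenario) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj
    return conv(scenario)
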