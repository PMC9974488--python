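"""Readers and writers for the package's CSV/TIFF/JSON interchange formats."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .binding import FPSeries, TitrationSeries
from .flim import DecayHistogram, LifetimeCalibration
from .imaging import ImageSet
from .labeling import GelBandQuad


def read_titration_csv(path) -> TitrationSeries:
    """Columns: analyte, conc_uM, ratio, optional replicate (header required)."""
    df = pd.read_csv(path)
    required = {"analyte", "conc_uM", "ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV needs columns {sorted(required)}")
    analytes = df["analyte"].unique()
    if len(analytes) != 1:
        raise ValueError("one analyte per titration CSV")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return TitrationSeries(str(analytes[0]), df["conc_uM"].to_numpy(),
                           df["ratio"].to_numpy(), rep)


def read_fp_csv(path) -> FPSeries:
    """Columns: x_uM, fp (or i_par/i_perp/g), mode, tracer_uM."""
    df = pd.read_csv(path)
    if "mode" not in df.columns:
        raise ValueError("FP CSV needs a 'mode' column")
    mode = str(df["mode"].iloc[0])
    if "fp" in df.columns:
        fp = df["fp"].to_numpy(dtype=float)
    elif {"i_par", "i_perp", "g"}.issubset(df.columns):
        from .binding import fp_from_intensities
        fp = np.array([fp_from_intensities(r.i_par, r.i_perp, r.g)
                       for r in df.itertuples()])
    else:
        raise ValueError("FP CSV needs 'fp' or 'i_par'/'i_perp'/'g' columns")
    tracer = float(df["tracer_uM"].iloc[0]) if "tracer_uM" in df.columns else None
    return FPSeries(df["x_uM"].to_numpy(dtype=float), fp, mode, tracer)


def read_decay_csv(path) -> DecayHistogram:
    """Columns: t_ns, counts, optional irf_counts."""
    df = pd.read_csv(path)
    if not {"t_ns", "counts"}.issubset(df.columns):
        raise ValueError("decay CSV needs columns t_ns, counts")
    irf = df["irf_counts"].to_numpy(dtype=float) if "irf_counts" in df.columns else None
    return DecayHistogram(df["t_ns"].to_numpy(dtype=float),
                          df["counts"].to_numpy(dtype=float), irf)


def read_gel_csv(path) -> list[tuple[str, GelBandQuad]]:
    """Columns: sample_id, s_a488, s_sir, c_a488, c_sir (one row per lane)."""
    df = pd.read_csv(path)
    required = {"sample_id", "s_a488", "s_sir", "c_a488", "c_sir"}
    if not required.issubset(df.columns):
        raise ValueError(f"gel CSV needs columns {sorted(required)}")
    return [(str(r.sample_id), GelBandQuad(r.s_a488, r.s_sir, r.c_a488, r.c_sir))
            for r in df.itertuples()]


def read_manifest(path) -> pd.DataFrame:
    """Imaging manifest: fov_id, condition, probe, donor, acceptor, fret paths."""
    df = pd.read_csv(path)
    required = {"fov_id", "condition", "probe", "donor", "acceptor", "fret"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def load_image_set(row, base_dir) -> ImageSet:
    """Load one manifest row's three channels from TIFF files."""
    base = Path(base_dir)
    return ImageSet(
        tifffile.imread(base / row["donor"]).astype(float),
        tifffile.imread(base / row["acceptor"]).astype(float),
        tifffile.imread(base / row["fret"]).astype(float),
        fov_id=str(row["fov_id"]), condition=str(row["condition"]),
        probe=str(row["probe"]))


def write_fit_report(path, fit, extra: dict | None = None) -> None:
    """Serialize a fit dataclass to a flat JSON report."""
    rec = dataclasses.asdict(fit) if dataclasses.is_dataclass(fit) else dict(fit)
    rec = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in rec.items()}
    if extra:
        rec.update(extra)
    Path(path).write_text(json.dumps(rec, indent=2, default=float))


def write_calibration(path, calib: LifetimeCalibration) -> None:
    write_fit_report(path, calib)


def read_calibration(path) -> LifetimeCalibration:
    rec = json.loads(Path(path).read_text())
    return LifetimeCalibration(rec["tau_donor_ns"], rec["e_min"], rec["e_max"],
                               rec["c50_uM"],
                               standard_errors=rec.get("standard_errors", {}),
                               residual_sse=rec.get("residual_sse", float("nan")),
                               temperature_note=rec.get("temperature_note", ""),
                               warnings=rec.get("warnings", []))


def provenance_record(inputs: dict, seed: int | None, config: dict) -> dict:
    """Machine-readable provenance: inputs, package version, seed, config hash."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"inputs": {k: str(v) for k, v in inputs.items()},
            "version": __version__, "seed": seed,
            "config": config,
            "config_sha256": hashlib.sha256(blob).hexdigest()}
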