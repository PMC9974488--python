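# fretquant

Quantification machinery for semisynthetic ratiometric/FLIM FRET biosensors
of the Snifit type — fusions of an analyte-binding protein, a self-labeling
tag carrying a tethered fluorescent ligand, and a fluorescent protein.  The
tethered ligand and the analyte (here: free coenzyme A) compete for the
binding protein, switching the sensor between a closed high-FRET and an open
low-FRET conformation.  The package implements everything needed to turn raw
fluorescence readouts into calibrated analyte concentrations:

* **Binding calibration** — the emission-ratio isotherm
  `R(c) = R_min + (R_max − R_min)/(1 + c50/c)` fitted for
  (R_min, R_max, c50), the dynamic range ΔR = R_max/R_min, and
  fluorescence-polarization assays: the exact ligand-depletion quadratic for
  the tracer Kd and the competition hyperbola for analyte c50.
* **Sensitized-emission FRET imaging** — pixel-wise net FRET
  `(I_FRET − BT_d·I_donor − BT_a·I_acceptor)/√(I_donor·I_acceptor)` with
  bleedthrough factors measured on single-fluorophore controls, Otsu/
  connected-component cell segmentation, normalization of each cell against
  a fully-open control probe, and FOV-level condition statistics
  (percent ratio change ± s.e.m., two-tailed unpaired t-test).
* **FLIM quantification** — Poisson maximum-likelihood multi-exponential
  TCSPC decay fits, amplitude-weighted lifetimes τ = Σαᵢτᵢ/Σαᵢ, FRET
  efficiency E = 1 − τ_FRET/τ_D, a hyperbolic E(c) calibration and its
  algebraic inverse `c = c50·(E − E_min)/(E_max − E)` for absolute
  concentrations.
* **Labeling efficiency** — dual-channel gel-band arithmetic and
  time-course plateau detection.
* **Synthetic data** — seeded generators for every input class (titration
  tables, FP series, three-channel 512×512 FOVs with known bleedthrough and
  Poisson noise, multinomially sampled TCSPC histograms, gel bands) with the
  generating truth stored alongside, so recovery can be asserted end to end.

## Layout

The repository is organized as an analysis project: the numbered scripts
under `analysis/` tell the story and write their tables to `results/`, while
all computation lives in the importable package under `src/fretquant/`
(`binding`, `imaging`, `flim`, `labeling`, `synthetic`, `io`, `cli`).
A `fretquant` command-line tool exposes the same stages
(`simulate`, `fit-titration`, `fit-fp`, `fret-image`, `flim-fit`,
`flim-calibrate`, `flim-quantify`, `labeling`) for on-disk CSV/TIFF data.

## Worked example

```
$ python analysis/03_fret_imaging.py
constructed ground truth: control at 2.40 uM, treated at 4.25 uM (normalized FRET 40% vs 48%, a +20% relative change)
1320 cells segmented over 12 probe FOVs (55 per FOV)
recovered ratio change: +20.16% +- 0.09% (s.e.m., n = 6 FOVs), p = 3.86e-20 (two-tailed unpaired t-test)
```

Two imaging conditions are generated whose true analyte levels were chosen
so that normalized FRET differs by exactly +20%; the full pipeline
(bleedthrough estimation from single-fluorophore controls → pixel-wise net
FRET → segmentation → per-cell normalization → FOV statistics) recovers
+20.16 ± 0.09%, significant at p ≈ 4·10⁻²⁰.

```
$ python analysis/04_flim_quantification.py
calibration: tau_D = 2.603 ns (truth 2.6), E_min = 0.052, E_max = 0.451, c50 = 59.1 uM (truth 58.9)
 true_uM  tau_ns  efficiency  estimated_uM  chi2_reduced  rel_error_pct
  12.000   2.295       0.118        11.829         0.943          1.422
 ...
maximum per-point error 3.1% across the ladder; every fit meets the reduced chi2 < 1.2 quality bound
```

The lifetime calibration built from 10⁶-photon decays recovers the
generating hyperbola, and a fresh five-point concentration ladder inverts
back to truth within ~3% per point.

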