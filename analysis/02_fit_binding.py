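"""Fit binding calibrations for every sensor variant and the FP assays.

Titrates each sensor variant over the 12.8 nM - 1 mM ladder (1%
multiplicative readout noise, 3 replicates), fits the hyperbolic isotherm,
and reports (R_min, R_max, c50, dynamic range).  Then fits the
fluorescence-polarization direct-binding quadratic (tracer Kd) and the
competition hyperbola (analyte c50), and derives the selectivity fold of a
weaker off-target competitor.  Tables go to results/.
"""

from pathlib import Path

import pandas as pd

from fretquant import binding
from fretquant.synthetic import SENSOR_VARIANTS, SyntheticScenario, gen_fp_series, gen_titration

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sc = SyntheticScenario(seed=1)
    rows = []
    for idx, variant in enumerate(SENSOR_VARIANTS):
        series, truth = gen_titration(sc, variant=variant, rng=sc.rng(100 + idx))
        fit = binding.fit_isotherm(series)
        rows.append({"variant": variant, "true_c50_uM": truth["c50_uM"],
                     "fit_c50_uM": fit.c50, "c50_se": fit.standard_errors["c50"],
                     "r_min": fit.r_min, "r_max": fit.r_max,
                     "dynamic_range_fold": fit.dynamic_range})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "titration_fits.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    direct, dt = gen_fp_series(sc, "direct", rng=sc.rng(201))
    kd_fit = binding.fit_fp_direct(direct)
    comp_coa, _ = gen_fp_series(sc, "competition", competition_c50_uM=13.9,
                                rng=sc.rng(202))
    comp_off, _ = gen_fp_series(sc, "competition", competition_c50_uM=163.0,
                                rng=sc.rng(203))
    c50_coa = binding.fit_fp_competition(comp_coa).c50
    c50_off = binding.fit_fp_competition(comp_off).c50
    fold = binding.selectivity_fold(c50_off, c50_coa)
    fp = pd.DataFrame([
        {"quantity": "tracer_kd_uM", "value": kd_fit.kd, "truth": dt["kd_uM"]},
        {"quantity": "competition_c50_analyte_uM", "value": c50_coa, "truth": 13.9},
        {"quantity": "competition_c50_offtarget_uM", "value": c50_off, "truth": 163.0},
        {"quantity": "selectivity_fold", "value": fold, "truth": 163.0 / 13.9},
    ])
    fp.to_csv(RESULTS / "fp_fits.csv", index=False)
    print()
    print(fp.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nThe off-target competitor requires {fold:.1f}-fold more compound "
          "for half-displacement: the sensor is selective for its analyte.")


if __name__ == "__main__":
    main()
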