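"""FLIM workflow: lifetime calibration and absolute concentration recovery.

Builds the efficiency-vs-concentration calibration from a simulated lifetime
titration (10^6 photons per decay, 12 concentrations, donor-only reference),
then quantifies a fresh 5-point concentration ladder through the decay-fit ->
amplitude-weighted lifetime -> FRET efficiency -> inversion chain.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fretquant import flim
from fretquant.io import write_calibration
from fretquant.synthetic import SyntheticScenario, gen_decay, gen_flim_titration

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sc = SyntheticScenario(seed=1)
    pairs, donor, truth = gen_flim_titration(sc, photons=1e6, noise=True,
                                             rng=sc.rng(401))
    calib = flim.build_lifetime_calibration(pairs, donor, n_components=2)
    RESULTS.mkdir(exist_ok=True)
    write_calibration(RESULTS / "flim_calibration.json", calib)
    print(f"calibration: tau_D = {calib.tau_donor_ns:.3f} ns "
          f"(truth {truth['tau_donor_ns']}), E_min = {calib.e_min:.3f}, "
          f"E_max = {calib.e_max:.3f}, c50 = {calib.c50_uM:.1f} uM "
          f"(truth {truth['c50_uM']})")

    rng = sc.rng(402)
    rows = []
    for conc in np.geomspace(12.0, 300.0, 5):
        decay, _ = gen_decay(sc, coa_uM=float(conc), photons=1e6, noise=True, rng=rng)
        fit = flim.fit_multiexp(decay, n_components=2)
        tau = flim.amplitude_weighted_lifetime(fit)
        eff = flim.fret_efficiency(tau, calib.tau_donor_ns)
        est = flim.coa_concentration(eff, calib)
        rows.append({"true_uM": conc, "tau_ns": tau, "efficiency": eff,
                     "estimated_uM": est.coa_uM, "chi2_reduced": fit.chi2_reduced,
                     "rel_error_pct": 100.0 * abs(est.coa_uM - conc) / conc})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "flim_ladder.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nmaximum per-point error {df['rel_error_pct'].max():.1f}% across the "
          "ladder; every fit meets the reduced chi2 < 1.2 quality bound"
          if (df["chi2_reduced"] < 1.2).all() else "")


if __name__ == "__main__":
    main()
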