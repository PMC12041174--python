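#!/usr/bin/env python
"""Celiac-stenosis severity sweep and the replaced-RHA experiment.

Part 1: sweep the celiac-trunk area reduction 0 -> 0.95 on the Michels-I
template and record CHA/GDA flows: the gastroduodenal artery reverses
(negative flow, i.e. collateral perfusion of the liver through the
pancreaticoduodenal arcade) beyond a critical severity.

Part 2: for a replaced-right-hepatic-artery patient, clamp the GDA and show
the RHA flow from the SMA is essentially unaffected while the celiac-side
PHA flow rises.

Outputs: results/stenosis_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import hepanet as hp

OUT = Path("results")


def main() -> None:
    rows = []
    for severity in np.linspace(0.0, 0.95, 39):
        net = hp.build_template(hp.Variant.CELIAC_STENOSIS,
                                area_reduction=float(severity))
        sol = hp.solve_steady(net)
        rows.append(
            {
                "area_reduction": severity,
                "cha_ml_min": sol.flow("CHA"),
                "gda_ml_min": sol.flow("GDA"),
                "pha_ml_min": sol.flow("PHA"),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "stenosis_sweep.csv", index=False, float_format="%.4f")

    reversal = df[df.gda_ml_min < 0].area_reduction.min()
    print(f"GDA reverses at area reduction >= {reversal:.3f} "
          f"(template geometry); CHA falls monotonically "
          f"{df.cha_ml_min.iloc[0]:.0f} -> {df.cha_ml_min.iloc[-1]:.0f} ml/min")

    patient = hp.generate_patient(hp.Variant.MICHELS_VIII_REPLACED_RHA, seed=23)
    base = patient.truth_flows[hp.BASELINE]
    clamped = patient.truth_flows[hp.CLAMP_GDA]
    d_rha = 100 * (clamped.flow("RHA") - base.flow("RHA")) / base.flow("RHA")
    print(f"replaced-RHA patient: GDA clamp changes RHA flow by {d_rha:+.2f}% "
          f"({base.flow('RHA'):.1f} -> {clamped.flow('RHA'):.1f} ml/min) "
          f"while PHA rises {base.flow('PHA'):.1f} -> "
          f"{clamped.flow('PHA'):.1f} ml/min")


if __name__ == "__main__":
    main()
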