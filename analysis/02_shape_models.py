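#!/usr/bin/env python
"""Fit the per-sex PCA shape models and report their variance structure.

Builds 60 training anatomies per sex, fits point-distribution models to the
corresponding 600-landmark templates, and reports how the anatomical
variance concentrates in the leading modes (the study retained the modes
covering 99% of variance, capped at 20). Writes
results/variance_fractions.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hipsnap.anatomy import PopulationConfig, build_anatomy, sample_parameters
from hipsnap.shape_model import fit_shape_model

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = PopulationConfig()
    rows = []
    for sex, seed in (("male", 11), ("female", 12)):
        params = sample_parameters(sex, 60, seed=seed, config=config)
        landmarks = [build_anatomy(p, config).landmarks for p in params]
        model = fit_shape_model(landmarks, align=False)
        k99 = model.modes_for_fraction(0.99, cap=20)
        print(
            f"{sex}: {model.t} positive modes from 60 training shapes; "
            f"{k99} modes reach 99% of landmark variance"
        )
        for k in range(1, min(model.t, 10) + 1):
            rows.append(
                {
                    "sex": sex,
                    "mode": k,
                    "eigenvalue_mm2": model.eigenvalues[k - 1],
                    "cumulative_fraction": model.explained_variance_fraction(k),
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "variance_fractions.csv", index=False)
    print(df.round(4).to_string(index=False))
    print(
        "\nThe synthetic anatomy varies five independent measures, so the "
        "spectrum concentrates in ~5 modes; real dense-correspondence data "
        "spreads variance over many more."
    )


if __name__ == "__main__":
    main()
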