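#!/usr/bin/env python
"""Snap mechanics on contrasting phenotypes.

Simulates the provocative circumduction (120 frames, 25 deg/s) on three
female anatomies - protective (-3 SD risk direction), population mean, and
high-risk (+3 SD anteversion, -3 SD offset) - and reports the tendon
angular-velocity curves, the phase of the peak, and the warm-start vs
cold-start divergence that demonstrates the hooked local minimum. Writes
results/risk_velocity_curves.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hipsnap.anatomy import AnatomicalParameters, PopulationConfig, build_anatomy
from hipsnap.kinematics import build_circumduction_sequence
from hipsnap.wrapping import simulate_trajectory

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = PopulationConfig()
    stats = config.statistics["female"]
    mean = np.array([stats[k][0] for k in stats])
    sd = np.array([stats[k][1] for k in stats])
    phenotypes = {
        "protective": mean + np.array([-3, -3, 3, 3, 0]) * sd,
        "mean": mean,
        "high_risk": mean + np.array([0, 3, -3, 0, 0]) * sd,
    }
    seq = build_circumduction_sequence()
    frames = []
    for tag, values in phenotypes.items():
        anatomy = build_anatomy(AnatomicalParameters.from_array(values, sex="female"), config)
        warm = simulate_trajectory(anatomy, seq, warm_start=True)
        cold = simulate_trajectory(anatomy, seq, warm_start=False)
        diffs = np.array(
            [np.linalg.norm(w.nodes - c.nodes, axis=1).max() for w, c in zip(warm.paths, cold.paths)]
        )
        ret = diffs[seq.apex_index :]
        print(
            f"{tag:11s}: peak {warm.peak_velocity:6.1f} deg/s at frame {warm.peak_frame:3d} "
            f"(apex {seq.apex_index}); return-phase peak {warm.velocity[seq.apex_index:].max():6.1f}; "
            f"max warm-cold divergence in return phase {ret.max():5.1f} mm "
            f"({int((ret > 2).sum())} frames > 2 mm)"
        )
        frames.append(
            pd.DataFrame(
                {
                    "phenotype": tag,
                    "frame": np.arange(len(seq)),
                    "time_s": seq.times,
                    "velocity_deg_s": warm.velocity,
                    "warm_cold_divergence_mm": diffs,
                }
            )
        )
    OUT.mkdir(exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(OUT / "risk_velocity_curves.csv", index=False)
    print(
        "\nEvery phenotype releases in the return phase, and the high-risk "
        "shape releases latest with the most hooked frames. Case-by-case "
        "release size is not monotone in the risk direction - individual "
        "jumps depend sensitively on where the release is caught by the "
        "frame grid - but across the simulated cohorts (next script) the "
        "risk-direction trend dominates. The warm/cold divergence shows the "
        "tendon hooked in a stable local minimum during the return."
    )


if __name__ == "__main__":
    main()
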