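#!/usr/bin/env python
"""Coexistence in a fluctuating environment equals the averaged environment.

Runs the coexisting replica pair under constant dilution factors spanning
its window, then compares the alternating 10^2/10^4 regime against the
constant geometric-mean regime (10^3): the fluctuating community settles
into an oscillation around the constant regime's stable interior fraction.

Writes results/coexist_trajectories.csv and a comparison summary.
"""

import numpy as np
import pandas as pd

from lvdilution import DilutionSchedule, SimulationConfig, day0_density, run_schedule
from lvdilution.synth import example_community

OUT = "results"
IDEAL = SimulationConfig(extinction_threshold=0.0, max_cycles=400)


def main():
    pair = example_community().pair(2, 1)
    frames = []
    print("constant regimes, final fraction of the fast grower from a 50:50 start:")
    for df in (10.0, 1e2, 1e3, 1e4):
        traj = run_schedule([0.5, 0.5], day0_density(df), pair,
                            DilutionSchedule.constant(df), IDEAL)
        frame = traj.to_frame()
        frame["regime"] = f"constant_df{df:g}"
        frames.append(frame)
        print(f"  DF {df:>8g}: {traj.final_fractions[0]:.3f}")

    fluct = DilutionSchedule((1e2, 1e4))
    t_fluct = run_schedule([0.5, 0.5], day0_density(1e2), pair, fluct, IDEAL)
    frame = t_fluct.to_frame()
    frame["regime"] = "alternating_1e2_1e4"
    frames.append(frame)
    t_const = run_schedule([0.5, 0.5], day0_density(1e3), pair,
                           DilutionSchedule.constant(1e3), IDEAL)
    f_fluct = t_fluct.fractions[-2:, 0]
    f_const = t_const.fractions[-1, 0]
    print(f"alternating 1e2/1e4: fraction oscillates {f_fluct.min():.3f}-"
          f"{f_fluct.max():.3f} (period mean {f_fluct.mean():.3f})")
    print(f"constant 1e3 equivalent: stable fraction {f_const:.3f}")
    print(f"period mean vs constant: |diff| = {abs(f_fluct.mean() - f_const):.4f}")
    pd.concat(frames, ignore_index=True).to_csv(f"{OUT}/coexist_trajectories.csv",
                                                index=False, float_format="%.5g")
    pd.DataFrame([{
        "fluct_period_mean": f_fluct.mean(), "fluct_low_phase": f_fluct.min(),
        "fluct_high_phase": f_fluct.max(), "constant_equivalent": f_const,
        "abs_difference": abs(f_fluct.mean() - f_const),
    }]).to_csv(f"{OUT}/coexist_summary.csv", index=False)
    print(f"wrote {OUT}/coexist_trajectories.csv and {OUT}/coexist_summary.csv")


if __name__ == "__main__":
    main()
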