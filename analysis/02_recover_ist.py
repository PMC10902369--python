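"""Recover IST parameters from the simulated tracer traces.

Fits inspired/expired sinusoids to every trace written by
01_simulate_cohort.py, inverts the one-compartment frequency response for
(ELV, Qp, Qp_mean) at both periods and computes the ratio heterogeneity
indices ELV180/ELV60 and Qp60/Qp180.
"""

import argparse
from pathlib import Path

import pandas as pd

from istct.ist import heterogeneity_ratios, recover_ist
from istct.lung import BreathTrace


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir

    index = pd.read_csv(out / "traces_index.csv")
    warmup = {180.0: 1.0, 60.0: 2.0}
    rows = []
    for (a, s, rep), grp in index.groupby(["animal", "step", "repeat"]):
        res = {}
        meta = grp.iloc[0]
        for r in grp.itertuples():
            tr = BreathTrace.from_csv(
                out / r.file, period_T=r.period_T, VT=r.VT, RR=r.RR, V_D=r.V_D
            )
            res[r.period_T] = recover_ist(tr, warmup_periods=warmup[r.period_T])
        h = heterogeneity_ratios(res[180.0], res[60.0])
        rows.append(
            {
                "animal": a, "step": s, "peep": meta.peep, "limb": meta.limb,
                "repeat": rep,
                "elv_180": res[180.0].ELV, "qp_180": res[180.0].Qp,
                "qp_mean_180": res[180.0].Qp_mean,
                "elv_60": res[60.0].ELV, "qp_60": res[60.0].Qp,
                "qp_mean_60": res[60.0].Qp_mean,
                "h_ratio_v": h.h_ratio_v, "h_ratio_p": h.h_ratio_p,
                "vd": meta.V_D, "vt": meta.VT, "rr": meta.RR,
                "vd_over_elv": meta.V_D / res[180.0].ELV,
                "vd_over_vt": meta.V_D / meta.VT,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "ist_results.csv", index=False)
    print(f"recovered {len(df)} paired IST tests")
    print(df.groupby("peep")[["elv_180", "qp_180", "h_ratio_v", "h_ratio_p",
                              "vd_over_elv", "vd_over_vt"]].mean().round(3))


if __name__ == "__main__":
    main()
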