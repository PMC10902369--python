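"""Generate the synthetic porcine-ARDS cohort.

Writes the ground-truth table, every per-breath tracer trace (CSV) and
every end-expiratory CT volume + lung mask (NIfTI) for the default
6-animal, 7-step PEEP-ladder protocol with two paired measurements per
step.  Later stages read these artifacts, so the whole analysis can be
re-run stage by stage.
"""

import argparse
from pathlib import Path

import pandas as pd

from istct.cohort import (
    ProtocolSpec,
    generate_ct_volume,
    generate_ground_truth,
    generate_ist_measurements,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--noise", type=float, default=0.005)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    spec = ProtocolSpec(seed=args.seed, noise_sd=args.noise)
    truth = generate_ground_truth(spec)
    out = args.outdir
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "ct").mkdir(parents=True, exist_ok=True)
    truth.to_csv(out / "ground_truth.csv", index=False)

    print(f"cohort: {spec.n_animals} animals, ladder {spec.peep_ladder}, "
          f"{spec.repeats_per_step} repeats/step, noise {spec.noise_sd}")
    print(truth.groupby("peep")[["log_sd_v_true", "log_sd_p_true", "ct_param"]]
          .mean().round(3))

    measurements = generate_ist_measurements(truth, spec)
    index_rows = []
    for m in measurements:
        for T, tr in m.traces.items():
            name = f"trace_a{m.animal}_s{m.step}_r{m.repeat}_T{int(T)}.csv"
            tr.to_csv(out / "traces" / name)
            index_rows.append(
                {
                    "animal": m.animal, "step": m.step, "peep": m.peep,
                    "limb": m.limb, "repeat": m.repeat, "period_T": T,
                    "file": f"traces/{name}", "VT": tr.VT, "RR": tr.RR,
                    "V_D": tr.V_D,
                }
            )
    pd.DataFrame(index_rows).to_csv(out / "traces_index.csv", index=False)
    print(f"wrote {len(index_rows)} tracer traces")

    ct_rows = []
    truth_idx = truth.set_index(["animal", "step"])
    for (a, s), row in truth_idx.iterrows():
        row = row.copy()
        row["animal"], row["step"] = a, s
        for rep in range(spec.repeats_per_step):
            ct = generate_ct_volume(row, spec, repeat=rep)
            hu_name = f"ct_a{a}_s{s}_r{rep}_hu.nii.gz"
            mask_name = f"ct_a{a}_s{s}_r{rep}_mask.nii.gz"
            ct.to_nifti(out / "ct" / hu_name, out / "ct" / mask_name)
            ct_rows.append(
                {"animal": a, "step": s, "peep": row["peep"], "limb": row["limb"],
                 "repeat": rep, "hu_file": f"ct/{hu_name}",
                 "mask_file": f"ct/{mask_name}"}
            )
    pd.DataFrame(ct_rows).to_csv(out / "ct_index.csv", index=False)
    print(f"wrote {len(ct_rows)} CT volumes to {out / 'ct'}")


if __name__ == "__main__":
    main()
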