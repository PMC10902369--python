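"""Compare IST and CT heterogeneity: correlations, regressions,
four-quadrant trend concordance, and figures.

Merges the IST ratio indices, the LogSD fits and the CT readouts into the
long-format cohort table, then reproduces the study's statistical
machinery: the Pearson matrix over all heterogeneity variables, per-animal
and pooled OLS of each IST index on H_CT, and the four-quadrant analysis
of paired PEEP-induced changes with the 15%-of-maximum exclusion zone.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from istct.pipeline import CORR_VARS, IST_INDICES
from istct.stats import delta_pairs, four_quadrant, pearson_matrix, per_animal_regression


def quadrant_figure(qa, yname, path):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    mx = qa.pairs.dx.abs().max()
    my = qa.pairs.dy.abs().max()
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.add_patch(
        plt.Rectangle(
            (-0.15 * mx, -0.15 * my), 0.3 * mx, 0.3 * my,
            fill=False, edgecolor="black", lw=1.2,
        )
    )
    ax.scatter(qa.pairs.dx, qa.pairs.dy, s=18, c=qa.pairs.animal, cmap="tab10")
    ax.set_xlabel("change in H_CT")
    ax.set_ylabel(f"change in {yname}")
    ax.set_title(
        f"concordance {qa.concordance:.0f}%  slope {qa.slope:.2f}  "
        f"R$^2$ {qa.r_squared:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    keys = ["animal", "step", "peep", "limb", "repeat"]
    ist = pd.read_csv(out / "ist_results.csv")
    logsd = pd.read_csv(out / "logsd_estimates.csv")
    ct = pd.read_csv(out / "ct_results.csv")
    table = (
        ist.merge(logsd[keys + ["log_sd_v", "log_sd_p"]], on=keys)
        .merge(ct[keys + ["h_ct", "a_n", "o_n"]], on=keys)
    )
    table.to_csv(out / "cohort.csv", index=False)

    per_step = (
        table.groupby(["animal", "step"])
        .agg({**{v: "mean" for v in CORR_VARS}, "peep": "first", "limb": "first"})
        .reset_index()
    )
    r, p = pearson_matrix(per_step, list(CORR_VARS))
    r.to_csv(out / "pearson_r.csv")
    p.to_csv(out / "pearson_p.csv")
    print("Pearson r (per-step averages):")
    print(r.round(2).to_string())

    qrows = []
    for yvar in IST_INDICES:
        reg = per_animal_regression(per_step, x="h_ct", y=yvar)
        reg.to_csv(out / f"regression_{yvar}.csv", index=False)
        qa = four_quadrant(delta_pairs(table, x="h_ct", y=yvar))
        qrows.append(
            {"index": yvar, "concordance_pct": qa.concordance, "slope": qa.slope,
             "r_squared": qa.r_squared, "n_included": qa.n_included,
             "n_excluded": qa.n_excluded}
        )
        quadrant_figure(qa, yvar, figdir / f"quadrant_{yvar}.png")
    qdf = pd.DataFrame(qrows)
    qdf.to_csv(out / "quadrant_summary.csv", index=False)
    print("\nFour-quadrant trend concordance vs H_CT:")
    print(qdf.round(2).to_string(index=False))

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5), sharex=True)
    order = [5, 10, 15, 20]
    for ax, var, label in zip(
        axes, ["h_ct", "log_sd_v", "h_ratio_v"],
        ["H_CT", "LogSDv", "ELV180/ELV60"],
    ):
        g = table.groupby(["limb", "peep"])[var].agg(["mean", "std"])
        for limb, style in (("incremental", "-o"), ("decremental", "--s")):
            sub = g.loc[limb].reindex(order).dropna()
            ax.errorbar(sub.index, sub["mean"], yerr=sub["std"], fmt=style, label=limb)
        ax.set_xlabel("PEEP (cmH$_2$O)")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "peep_trends.png", dpi=120)
    print(f"\nfigures in {figdir}")


if __name__ == "__main__":
    main()
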