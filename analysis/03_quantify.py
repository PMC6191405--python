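"""Assemble the quantification tables and figures from persisted studies.

Reads the per-study reports written by ``02_run_studies.py`` and produces:
regression/offset/R²/RMSE tables per image (one row block per study),
cross-contamination RMSE tables, per-agent CNR slopes, the across-study
intraclass correlation of each agent, and the figure panels (regression,
Bland-Altman, CNR bars, image montages).
"""

import argparse
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd
import tifffile

from spcct.phantom import STUDY_IDS
from spcct.pipeline import _icc_block, report_to_json
from spcct.recon import ImageGrid
from spcct import plots


def load_report(outdir, sid):
    return json.loads((outdir / "studies" / sid / "report.json").read_text())


def load_image(outdir, sid, name):
    d = outdir / "studies" / sid
    side = json.loads((d / f"{name}.json").read_text())
    return ImageGrid(
        tifffile.imread(d / f"{name}.tif").astype(float),
        side["pixel_size_cm"],
        side["kind"],
        side["units"],
        side["material"],
    )


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    out = args.outdir
    figdir = out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    reports = {}
    for sid in STUDY_IDS:
        path = out / "studies" / sid / "report.json"
        if path.exists():
            reports[sid] = load_report(out, sid)
    if not reports:
        raise SystemExit("no study reports found; run 02_run_studies.py first")

    # regression table (slope / offset / R² / RMSE / 95% CI per image)
    rows = []
    for sid, rep in reports.items():
        for agent, blk in rep["per_agent"].items():
            r = blk["regression"]
            rows.append(
                {
                    "study": sid,
                    "image": agent,
                    "slope": round(r["slope"], 3),
                    "offset_mg_per_ml": round(r["offset"], 3),
                    "r_squared": round(r["r_squared"], 4),
                    "rmse_mg_per_ml": round(r["rmse"], 3),
                    "ci95_slope_low": round(r["ci95_slope"][0], 3),
                    "ci95_slope_high": round(r["ci95_slope"][1], 3),
                    "cnr_slope_per_mg_per_ml": round(blk["cnr_slope"], 3),
                }
            )
    reg_df = pd.DataFrame(rows)
    reg_df.to_csv(out / "regression_table.csv", index=False)

    # cross-contamination RMSE of the off-target images
    rows = []
    for sid, rep in reports.items():
        for mat, blk in rep["off_target"].items():
            rows.append(
                {
                    "study": sid,
                    "image": mat,
                    "expected_mg_per_ml": blk["expected_mg_per_ml"],
                    "rmse_mg_per_ml": round(blk["rmse"], 3),
                }
            )
        rows.append(
            {
                "study": sid,
                "image": "water (PBS tube)",
                "expected_mg_per_ml": 1000.0,
                "rmse_mg_per_ml": round(
                    abs(rep["water_pbs_roi"]["mean"] - 1000.0), 3
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "cross_contamination_table.csv", index=False)

    # reliability of each agent across its unmixed and mixed series
    icc = _icc_block(reports)
    (out / "icc.json").write_text(report_to_json(icc))

    # conventional-image summary
    conv = pd.DataFrame(
        {
            "study": sid,
            "mean_hu_tubes": round(rep["conventional"]["mean_hu_tubes"], 1),
            "sd_hu_across_tubes": round(rep["conventional"]["sd_hu_across_tubes"], 1),
        }
        for sid, rep in reports.items()
    )
    conv.to_csv(out / "conventional_hu_table.csv", index=False)

    for sid, rep in reports.items():
        plots.regression_panel(rep, figdir / f"{sid}_regression.png")
        plots.bland_altman_panel(rep, figdir / f"{sid}_bland_altman.png")
        plots.cnr_bars(rep, figdir / f"{sid}_cnr.png")
        conventional = load_image(out, sid, "conventional")
        images = {
            m: load_image(out, sid, m)
            for m in rep["basis"]
            if (out / "studies" / sid / f"{m}.tif").exists()
        }
        plots.image_montage(conventional, images, figdir / f"{sid}_maps.png")

    print("Regression (measured vs prepared concentration):")
    print(reg_df.to_string(index=False))
    print("\nConventional image:")
    print(conv.to_string(index=False))
    print("\nICC (consistency, mean of k series):")
    for agent, blk in icc.items():
        print(
            f"  {agent}: ICC={blk['icc']:.3f} "
            f"(95% CI {blk['ci95'][0]:.2f}-{blk['ci95'][1]:.2f}, k={blk['k']})"
        )
    print(f"\ntables under {out}, figures under {figdir}")


if __name__ == "__main__":
    main()
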