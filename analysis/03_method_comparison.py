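"""Statistical agreement of the three flow-determination methods.

Computes per-model Pearson correlations between the benchtop-derived,
invasive-derived and Windkessel site flows (table3.csv), Bland-Altman
limits of agreement (bland_altman.csv), and scatter/Bland-Altman figures
under results/figures/.

Run:  python analysis/03_method_comparison.py [--tables-dir results/tables]
"""

import argparse
from pathlib import Path

import pandas as pd

from coroflow import SiteFlowReport, bland_altman_table, table3
from coroflow.plots import comparison_plots


def reports_from_frame(df):
    return [
        SiteFlowReport(
            model_id=str(r["model"]),
            segment_id=str(r["site"]),
            activity=str(r["activity"]),
            I_windkessel_cc_s=float(r["I_windkessel_cc_s"]),
            model_ffr=float(r["model_ffr"]),
            I_invasive_cc_s=None if pd.isna(r["I_invasive_cc_s"])
            else float(r["I_invasive_cc_s"]),
            I_benchtop_cc_s=None if pd.isna(r["I_benchtop_cc_s"])
            else float(r["I_benchtop_cc_s"]),
            total_coronary_inflow_cc_s=float(r["total_coronary_inflow_cc_s"]),
            aortic_outlet_flow_cc_s=float(r["aortic_outlet_flow_cc_s"]),
        )
        for r in df.to_dict("records")
    ]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables-dir", type=Path, default=Path("results/tables"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.tables_dir / "site_report.csv")
    reports = reports_from_frame(df)

    t3 = table3(reports)
    ba = bland_altman_table(reports, grouping="pooled")
    (args.out_dir / "tables").mkdir(parents=True, exist_ok=True)
    t3.to_csv(args.out_dir / "tables" / "table3.csv", index=False)
    ba.to_csv(args.out_dir / "tables" / "bland_altman.csv", index=False)
    figures = comparison_plots(reports, args.out_dir / "figures")

    print("Per-model Pearson correlation of site flows:")
    print(t3.round(3).to_string(index=False))
    print("\nBland-Altman limits of agreement (pooled site x state points):")
    print(ba.round(3).to_string(index=False))
    print(f"\nwrote {len(figures)} figures to {args.out_dir / 'figures'}")


if __name__ == "__main__":
    main()
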