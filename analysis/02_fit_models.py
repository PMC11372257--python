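"""Fit compartment models to the simulated cohort and derive macroparameters.

For every region of every scan: fit 1T4P/2T5P/2T6P with joint delay
estimation, select by AICc, and compute SUV, SUVR(60-90), Logan K_Logan
(t*=30), K_i, V_T and V_T(v_b).  Writes results/fits.csv and
results/macro.csv and reports V_T recovery against the ground truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from petkin.pipeline import fit_scan
from petkin.tac_io import RunConfig, read_tac_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--scans", nargs="*", help="subset of scan CSVs (default: all)")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [Path(p) for p in args.scans] if args.scans else sorted(
        p for p in cohort.glob("*.csv") if p.name != "ground_truth.csv"
    )
    config = RunConfig()
    fits, macros = [], []
    for path in paths:
        scan = read_tac_table(path)
        f, m = fit_scan(scan, config)
        fits.append(f)
        macros.append(m)
        print(f"fitted {scan.subject_id}/{scan.scan_id}: {len(m)} regions")
    fits = pd.concat(fits, ignore_index=True)
    macro = pd.concat(macros, ignore_index=True)
    fits.to_csv(outdir / "fits.csv", index=False)
    macro.to_csv(outdir / "macro.csv", index=False)

    truth_path = cohort / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        j = macro.merge(truth, on=["subject", "scan", "region"], suffixes=("", "_true"))
        ok = j.dropna(subset=["V_T", "V_T_true"])
        err = 100 * (ok.V_T - ok.V_T_true) / ok.V_T_true
        print(f"V_T recovery over {len(ok)} regions: "
              f"median {np.median(err):+.1f}%, IQR [{np.percentile(err, 25):+.1f}, "
              f"{np.percentile(err, 75):+.1f}]%")
    sel = fits[fits.selected]
    print("AICc selection:", sel.model.value_counts().to_dict())


if __name__ == "__main__":
    main()
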