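"""Surrogacy correlations and paired pre/post-therapy tests.

From the fitted macro table: Spearman correlations of SUV, SUVR and
K_Logan against V_T and V_T(v_b) over the healthy-organ regions, and exact
paired Wilcoxon signed-rank tests of the therapy-induced changes in the 7
tumor subregions (SUVR, K_Logan, V_T and the rate constants k_3, k_4).
"""

import argparse
from pathlib import Path

import pandas as pd

from petkin.pipeline import paired_prepost_tests, surrogacy_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--macro", default="results/macro.csv")
    ap.add_argument("--fits", default="results/fits.csv")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    macro = pd.read_csv(args.macro)
    fits = pd.read_csv(args.fits)

    healthy = macro[macro.subject.str.startswith("healthy")]
    surr = surrogacy_table(healthy)
    surr.to_csv(outdir / "surrogacy.csv", index=False)
    print("surrogacy (healthy organs, all subjects):")
    for _, r in surr.iterrows():
        print(f"  {r['pair']:24s} rho={r.rho:+.3f}  p={r.p:.2g}  n={r.n}")

    pre = macro[(macro.subject == "patient") & (macro.scan == "pre")]
    post = macro[(macro.subject == "patient") & (macro.scan == "post")]
    fp = fits[(fits.subject == "patient") & (fits.scan == "pre")]
    fq = fits[(fits.subject == "patient") & (fits.scan == "post")]
    tests = paired_prepost_tests(pre, post, fp, fq)
    tests.to_csv(outdir / "paired_tests.csv", index=False)
    print("paired pre/post tests (7 tumor subregions, exact Wilcoxon):")
    for _, r in tests.iterrows():
        print(f"  {r.measure:8s} n={r.n}  W={r.statistic:.1f}  p={r.p:.6g}  "
              f"median change {r.median_change:+.3g}")


if __name__ == "__main__":
    main()
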