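"""Sensitivity diagnostics for the univariable MR fits.

For each exposure→outcome analysis: Cochran's Q heterogeneity against the
IVW and Egger references, the MR-Egger intercept test for directional
pleiotropy, leave-one-out influence refits, and funnel-plot data.  Tables go
to results/sensitivity/.
"""

import pandas as pd

from _common import parse_args, simulated_tables
from mrmediate import (
    cochran_q,
    egger_intercept_test,
    funnel_data,
    harmonize,
    leave_one_out,
    select_instruments,
)


def main() -> None:
    args = parse_args(__doc__)
    exposure, mediator, outcome = simulated_tables(args.results, args.seed)
    outdir = args.results / "sensitivity"
    outdir.mkdir(parents=True, exist_ok=True)

    het_rows = []
    for exp in (exposure, mediator):
        inst = select_instruments(exp, one_per_block=True)
        h = harmonize(inst, outcome)
        print(f"\n{exp.trait_name} -> {outcome.trait_name} (k = {h.k})")
        for ref in ("ivw", "egger"):
            het = cochran_q(h, ref)
            print(f"  Q ({ref}): {het.q:.2f} on {het.df} df, p = {het.pval:.3g}")
            het_rows.append({"exposure": exp.trait_name, "reference": ref,
                             "q": het.q, "df": het.df, "pval": het.pval})
        pleio = egger_intercept_test(h)
        print(f"  Egger intercept: {pleio.intercept:.5f} (se {pleio.se:.5f}), "
              f"p = {pleio.pval:.3g}")
        het_rows.append({"exposure": exp.trait_name, "reference": "egger_intercept",
                         "q": pleio.intercept, "df": 0, "pval": pleio.pval})

        loo = leave_one_out(h)
        drivers = [snp for snp, _, flag in loo.rows if flag]
        print(f"  leave-one-out: {len(loo.rows)} refits, "
              f"{'drivers: ' + ', '.join(drivers) if drivers else 'no driver SNPs'}")
        loo.to_frame().to_csv(outdir / f"leave_one_out_{exp.trait_name}.tsv",
                              sep="\t", index=False, float_format="%.6g")
        funnel_data(h).to_frame().to_csv(outdir / f"funnel_{exp.trait_name}.tsv",
                                         sep="\t", index=False, float_format="%.6g")

    pd.DataFrame(het_rows).to_csv(outdir / "heterogeneity.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    print(f"\nwrote {outdir}")


if __name__ == "__main__":
    main()
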