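#!/usr/bin/env python
"""Cohort distributions, group comparison and outlier taxonomy.

On the simulated cohort from 01: per-individual summaries, Gaussian fits
(moment and binned least-squares), normality tests, patient-vs-healthy
t-tests with relative increases, the SD-exceedance table against both
reference distributions, and the four-class outlier taxonomy compared to
the planted truth.

Run after 01:  python analysis/04_cohort_stats.py
"""

import json
from pathlib import Path

import pandas as pd

from fociscreen.cohortstats import (
    classify_outliers,
    compare_groups,
    exceedance_table,
    fit_all,
    outlier_taxonomy,
    summarize,
    test_normality,
)

COHORT = Path("results/cohort")
OUT = Path("results/stats")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if not (COHORT / "records.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    records = pd.read_csv(COHORT / "records.csv")
    truth = pd.read_csv(COHORT / "cohort.truth.csv")

    summaries = summarize(records)
    summaries.to_csv(OUT / "summaries.csv", index=False)

    fits = fit_all(summaries, method="moment")
    fits_json = {
        f"{g}:{c}": {"mu": round(f.mu, 4), "sigma": round(f.sigma, 4), "n": f.n}
        for (g, c), f in fits.items()
    }
    (OUT / "fits.json").write_text(json.dumps(fits_json, indent=2))
    print("moment fits (mu, sigma):")
    for k, v in fits_json.items():
        print(f"  {k:16s} mu={v['mu']:.3f} sigma={v['sigma']:.3f} n={v['n']}")

    print("normality (KS / Monte-Carlo Lilliefors p):")
    for (g, c), f in fits.items():
        vals = summaries.query("group == @g and condition == @c")["mean_foci"]
        r = test_normality(vals.to_numpy(), seed=SEED)
        print(f"  {g}:{c:12s} ks_p={r['ks_p']:.3f} lilliefors_p={r['lilliefors_p']:.3f}")

    print("patient vs healthy (two-sample t-test):")
    comps = {}
    for cond in ("preexisting", "initial", "remaining"):
        sub = summaries[summaries["condition"] == cond]
        r = compare_groups(
            sub[sub["group"] == "HI"]["mean_foci"],
            sub[sub["group"] == "RC"]["mean_foci"],
        )
        comps[cond] = r
        print(f"  {cond:12s} t={r['t']:.2f} p={r['p']:.2e} "
              f"increase={r['relative_increase_pct']:.1f}%")
    (OUT / "comparisons.json").write_text(json.dumps(comps, indent=2))

    exc = exceedance_table(summaries, fits)
    exc.to_csv(OUT / "exceedance.csv", index=False)
    print("exceedance beyond k SD (percent of group, vs reference fit):")
    print(
        exc.pivot_table(index="k", values="pct",
                        columns=["group", "reference", "condition"])
        .round(1).to_string()
    )

    # taxonomy against the binned patient reference, compared to truth
    rc = summaries[summaries["group"] == "RC"]
    tax_fits = fit_all(rc, method="binned-least-squares")
    calls = {
        cond: classify_outliers(rc, tax_fits[("RC", cond)], cond)
        for cond in ("preexisting", "remaining")
    }
    tax = outlier_taxonomy(calls["preexisting"], calls["remaining"])
    tax.to_csv(OUT / "taxonomy.csv", index=False)
    merged = tax.merge(
        truth.drop_duplicates("individual_id")[["individual_id", "outlier_class"]],
        on="individual_id", suffixes=("_called", "_planted"),
    )
    confusion = pd.crosstab(
        merged["outlier_class_planted"], merged["outlier_class_called"]
    )
    confusion.to_csv(OUT / "taxonomy_confusion.csv")
    print("taxonomy confusion matrix (rows = planted, cols = called):")
    print(confusion.to_string())
    print(f"tables written under {OUT}/")


if __name__ == "__main__":
    main()
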