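"""Cohort-level statistics and radiosensitivity-outlier classification.

Per-individual mean foci rates are summarised per group and condition,
fitted by Gaussian distributions (either moment fit — sample mean and SD —
or a least-squares Gaussian fit to the binned frequency distribution),
tested for normality (Kolmogorov-Smirnov against the fitted Gaussian, and
a Lilliefors test whose null distribution is obtained by seeded
Monte-Carlo simulation, since parameters are estimated from the data).
Groups are compared with the two-sample t-test and the relative increase
of the patient mean over the healthy mean.  Individuals are classified as
outliers by one-sided exceedance of 1, 2 or 3 fitted standard deviations
above a reference mean — the 2 and 3 SD cut-offs correspond to the upper
tails beyond the 95% and 99% two-sided confidence ranges — and the
2-SD calls in the unirradiated and 24-h conditions combine into the
four-class taxonomy: elevated preexisting only, elevated in both,
elevated remaining only, or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Conditions entering the outlier taxonomy (the initial 0.5 Gy/30 min
#: condition participates in fits and group comparison but not here).
TAXONOMY_CONDITIONS = ("preexisting", "remaining")
TAXONOMY_CLASSES = ("preexisting_only", "both", "remaining_only", "none")


@dataclass
class CohortDistribution:
    """A fitted Gaussian for one group x condition."""

    group: str
    condition: str
    mu: float
    sigma: float
    n: int
    method: str  # "moment" or "binned-least-squares"
    bin_width: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n < 3:
            raise ValueError("need at least 3 individuals")


@dataclass
class OutlierCall:
    """SD-multiple exceedance of one individual against one reference."""

    individual_id: str
    condition: str
    reference: str  # "<group>:<condition>" of the reference distribution
    value: float
    k: int  # largest j in {1,2,3} with value > mu + j*sigma, else 0
    direction: str = "above"


def summarize(records: pd.DataFrame, min_cells: int = 600) -> pd.DataFrame:
    """Per-individual, per-condition mean foci/cell with cell counts.

    Individuals scoring fewer than ``min_cells`` cells in a condition are
    kept but flagged ``sufficient=False`` (the assay's default minimum is
    600 cells, from the sufficiency analysis).  Empty groups simply do not
    appear.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    out = (
        records.groupby(["individual_id", "group", "condition"], sort=True)[
            "foci_count"
        ]
        .agg(mean_foci="mean", n_cells="size")
        .reset_index()
    )
    out["sufficient"] = out["n_cells"] >= min_cells
    return out


def fit_distribution(
    values,
    group: str = "",
    condition: str = "",
    method: str = "moment",
    bin_width: float | None = None,
) -> CohortDistribution:
    """Fit a Gaussian to per-individual mean foci rates.

    ``method="moment"`` uses the sample mean and SD (denominator n-1) and
    is the deterministic default.  ``method="binned-least-squares"``
    reproduces the histogram-fit procedure: values are binned (bin width
    defaults to the Freedman-Diaconis rule) and amplitude, mu and sigma of
    a Gaussian are fitted by least squares to the bin counts.  The binned
    fit locks onto the main mode of the distribution and is therefore
    robust to a heavy upper tail of outliers.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 values to fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: Gaussian fit undefined")
    if method == "moment":
        return CohortDistribution(
            group, condition, float(x.mean()), float(x.std(ddof=1)), x.size, method
        )
    if method != "binned-least-squares":
        raise ValueError(f"unknown fit method {method!r}")

    if bin_width is None:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        bin_width = 2 * iqr * x.size ** (-1 / 3) if iqr > 0 else np.ptp(x) / 10
    edges = np.arange(x.min(), x.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    med = np.median(x)
    mad_sd = max(1.4826 * np.median(np.abs(x - med)), bin_width / 2)
    p0 = (x.size * bin_width / (mad_sd * np.sqrt(2 * np.pi)), med, mad_sd)

    def gauss(c, a, mu, sigma):
        return a * np.exp(-((c - mu) ** 2) / (2 * sigma**2))

    popt, _ = optimize.curve_fit(
        gauss, centers, counts, p0=p0,
        bounds=([0, x.min() - mad_sd, bin_width / 10],
                [np.inf, x.max() + mad_sd, np.ptp(x) + bin_width]),
        maxfev=20000,
    )
    return CohortDistribution(
        group, condition, float(popt[1]), float(abs(popt[2])), x.size,
        method, bin_width=float(bin_width),
    )


# ---------------------------------------------------------------------------
# Normality tests
# ---------------------------------------------------------------------------


def _ks_statistics(samples: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of standardised samples from N(0, 1).

    Each row is standardised by its own mean and SD (ddof=1) — the
    Lilliefors situation of estimated parameters — before the one-sample
    KS distance against the standard normal CDF is computed.
    """
    X = np.sort(samples, axis=1)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    z = stats.norm.cdf((X - mu) / sd)
    n = X.shape[1]
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=1)
    d_minus = (z - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_null_statistics(n: int, n_replicates: int, rng) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors KS statistic."""
    draws = rng.standard_normal((n_replicates, n))
    return _ks_statistics(draws)


def test_normality(
    values,
    seed: int = 0,
    n_mc: int = 10_000,
) -> dict[str, float]:
    """KS and Monte-Carlo Lilliefors p-values for a Gaussian fit.

    The KS p-value treats the fitted mu/sigma as known (the classical
    test, anticonservative with estimated parameters); the Lilliefors
    p-value corrects for estimation via ``n_mc`` seeded null replicates,
    with the add-one estimator ``p = (1 + #{D_null >= D_obs}) / (n_mc + 1)``.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 values")
    if np.ptp(x) == 0:
        raise ValueError("ties-only data: normality test undefined")
    d_obs = float(_ks_statistics(x[None, :])[0])
    ks_p = float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    rng = np.random.default_rng(seed)
    null = lilliefors_null_statistics(x.size, n_mc, rng)
    lf_p = (1 + int(np.sum(null >= d_obs))) / (n_mc + 1)
    return {"ks_stat": d_obs, "ks_p": ks_p, "lilliefors_p": float(lf_p)}


def relative_increase_pct(mean_reference: float, mean_test: float) -> float:
    """Relative increase of ``mean_test`` over ``mean_reference``, in %.

    Reported at one decimal, as in the assay report (e.g. healthy 0.49 vs
    patient 0.59 preexisting foci/cell gives 20.4%).  NaN when the
    reference mean is zero.
    """
    if mean_reference == 0:
        return float("nan")
    return round(100.0 * (mean_test - mean_reference) / mean_reference, 1)


def compare_groups(hi_values, rc_values) -> dict[str, float]:
    """Two-sample t-test plus the patient-over-healthy relative increase.

    ``relative_increase_pct`` is ``100 * (mean_RC - mean_HI) / mean_HI``
    reported at one decimal; it is NaN (and flagged) when the healthy mean
    is zero.
    """
    hi = np.asarray(hi_values, dtype=np.float64)
    rc = np.asarray(rc_values, dtype=np.float64)
    if hi.size < 2 or rc.size < 2:
        raise ValueError("both groups need at least 2 values")
    t, p = stats.ttest_ind(rc, hi, equal_var=True)
    mean_hi, mean_rc = float(hi.mean()), float(rc.mean())
    rel = relative_increase_pct(mean_hi, mean_rc)
    return {
        "t": float(t),
        "p": float(p),
        "mean_HI": mean_hi,
        "mean_RC": mean_rc,
        "relative_increase_pct": rel,
        "relative_increase_defined": mean_hi != 0,
    }


# ---------------------------------------------------------------------------
# Outlier classification
# ---------------------------------------------------------------------------


def _k_exceeded(value: float, mu: float, sigma: float) -> int:
    k = 0
    for j in (1, 2, 3):
        if value > mu + j * sigma:
            k = j
    return k


def classify_outliers(
    summaries: pd.DataFrame,
    reference: CohortDistribution,
    condition: str | None = None,
) -> list[OutlierCall]:
    """One-sided SD-multiple exceedance calls against a reference fit.

    For each individual's mean in ``condition`` (defaulting to the
    reference's condition), ``k`` is the largest j in {1, 2, 3} with
    ``value > mu + j * sigma``; 0 means within 1 SD above the mean (or
    below it).  Calls can be made against the individuals' own group fit
    or the other group's.
    """
    cond = condition or reference.condition
    sub = summaries[summaries["condition"] == cond]
    ref_id = f"{reference.group}:{reference.condition}"
    return [
        OutlierCall(
            individual_id=row.individual_id,
            condition=cond,
            reference=ref_id,
            value=float(row.mean_foci),
            k=_k_exceeded(float(row.mean_foci), reference.mu, reference.sigma),
        )
        for row in sub.itertuples()
    ]


def exceedance_table(
    summaries: pd.DataFrame,
    fits: dict[tuple[str, str], CohortDistribution],
    groups_and_refs: list[tuple[str, str]] | None = None,
    conditions: tuple[str, ...] = ("preexisting", "remaining"),
) -> pd.DataFrame:
    """Percentage of each group beyond 1-3 SD of each reference fit.

    ``groups_and_refs`` lists (group under evaluation, reference group)
    pairs; the default mirrors the assay report's layout — each group
    against its own fit, plus patients against the healthy fit.  An empty
    group/condition intersection produces a row of NaN percentages rather
    than an error.
    """
    if groups_and_refs is None:
        groups_and_refs = [("HI", "HI"), ("RC", "RC"), ("RC", "HI")]
    rows = []
    for group, ref_group in groups_and_refs:
        for cond in conditions:
            ref = fits[(ref_group, cond)]
            sub = summaries[
                (summaries["group"] == group) & (summaries["condition"] == cond)
            ]
            calls = classify_outliers(sub, ref, cond)
            ks = np.array([c.k for c in calls])
            for j in (1, 2, 3):
                rows.append(
                    {
                        "group": group,
                        "reference": ref_group,
                        "condition": cond,
                        "k": j,
                        "pct": 100.0 * np.mean(ks >= j) if ks.size else np.nan,
                        "n": int(ks.size),
                    }
                )
    return pd.DataFrame(rows, columns=["group", "reference", "condition", "k", "pct", "n"])


def outlier_taxonomy(
    calls_preexisting: list[OutlierCall],
    calls_remaining: list[OutlierCall],
    k_threshold: int = 2,
) -> pd.DataFrame:
    """Combine per-condition calls into the four-class outlier taxonomy.

    ``both`` when k >= threshold in both the unirradiated and the 24-h
    condition, ``preexisting_only`` / ``remaining_only`` when in exactly
    one, ``none`` otherwise.  The classes partition the cohort.  Raises
    if the two call sets cover different individuals.
    """
    pre = {c.individual_id: c.k for c in calls_preexisting}
    rem = {c.individual_id: c.k for c in calls_remaining}
    if set(pre) != set(rem):
        raise ValueError("call sets cover different individuals")
    rows = []
    for ind in sorted(pre):
        hit_pre = pre[ind] >= k_threshold
        hit_rem = rem[ind] >= k_threshold
        if hit_pre and hit_rem:
            cls = "both"
        elif hit_pre:
            cls = "preexisting_only"
        elif hit_rem:
            cls = "remaining_only"
        else:
            cls = "none"
        rows.append(
            {
                "individual_id": ind,
                "k_preexisting": pre[ind],
                "k_remaining": rem[ind],
                "outlier_class": cls,
                "k_threshold": k_threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "k_preexisting", "k_remaining",
                 "outlier_class", "k_threshold"],
    )


def fit_all(
    summaries: pd.DataFrame,
    method: str = "moment",
    bin_width: float | None = None,
) -> dict[tuple[str, str], CohortDistribution]:
    """Fit every (group, condition) present in the summaries."""
    fits = {}
    for (group, cond), g in summaries.groupby(["group", "condition"], sort=True):
        fits[(group, cond)] = fit_distribution(
            g["mean_foci"].to_numpy(), group, cond, method=method, bin_width=bin_width
        )
    return fits
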