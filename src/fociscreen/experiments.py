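"""End-to-end experiments on synthetic cohorts with known ground truth.

Each function here runs one self-contained study on data produced by the
package's own generators and measures how well the pipeline recovers the
planted truth: group-mean relative increases, the cumulative-mean
sufficiency statistic, Gaussian-tail exceedance fractions, image-based
foci-count recovery, planted-outlier recovery, and the type-I error of the
Monte-Carlo Lilliefors test.  The analysis drivers, the test suite and the
acceptance script all call these routines.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from fociscreen.cohortstats import (
    classify_outliers,
    fit_distribution,
    lilliefors_null_statistics,
    outlier_taxonomy,
    relative_increase_pct,
    summarize,
    _ks_statistics,
)
from fociscreen.imaging import FociDetectionConfig, quantify_field
from fociscreen.sufficiency import (
    SufficiencyConfig,
    cumulative_agreement,
    fraction_within_tolerance,
)
from fociscreen.synthgen import (
    CohortParams,
    generate_cohort,
    generate_image_truth,
    generate_zstack,
)

#: Group-mean foci/cell reported for the study cohort (healthy vs patient,
#: preexisting and remaining conditions).
REPORTED_MEANS = {
    ("HI", "preexisting"): 0.49,
    ("RC", "preexisting"): 0.59,
    ("HI", "remaining"): 2.63,
    ("RC", "remaining"): 2.97,
}


def reported_mean_increases() -> dict[str, float]:
    """Relative patient-over-healthy increases from the reported means."""
    return {
        "preexisting": relative_increase_pct(
            REPORTED_MEANS[("HI", "preexisting")],
            REPORTED_MEANS[("RC", "preexisting")],
        ),
        "remaining": relative_increase_pct(
            REPORTED_MEANS[("HI", "remaining")],
            REPORTED_MEANS[("RC", "remaining")],
        ),
    }


def sufficiency_worked_example() -> list[float]:
    """Agreement curve of the six-cell worked example at interval 2."""
    cfg = SufficiencyConfig(checkpoint_interval=2, reference_cells=6)
    curve = cumulative_agreement([1, 0, 2, 0, 1, 2], cfg, "example", "preexisting")
    return [float(a) for a in curve.agreement_pct]


def analytic_tail_experiment(
    n: int = 100_000, seed: int = 0
) -> dict[str, float]:
    """Self-referenced exceedance fractions of a pure-Gaussian cohort.

    Draws ``n`` individual means from one Gaussian, fits it by moments and
    measures the fraction beyond 1, 2 and 3 fitted SD above the fitted
    mean.  As n grows these converge to the one-sided normal tails
    15.87% / 2.28% / 0.13%.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(2.97, 0.6, size=n)
    fit = fit_distribution(values, "RC", "remaining", method="moment")
    out = {}
    for j in (1, 2, 3):
        out[f"pct_gt_{j}sd"] = float(
            100.0 * np.mean(values > fit.mu + j * fit.sigma)
        )
    return out


def image_recovery_experiment(
    n_fields: int = 10,
    nuclei_per_field: int = 52,
    mean_foci: float = 2.0,
    seed: int = 0,
    config: FociDetectionConfig | None = None,
) -> dict[str, float]:
    """Render synthetic fields and measure foci-count recovery.

    Builds ``n_fields`` two-channel z-stacks at default (high) SNR with
    well-separated nuclei and Poisson-planted foci, runs the full imaging
    pipeline, matches each kept nucleus to the nearest planted nucleus,
    and reports the per-nucleus exact-count agreement, the relative error
    of the recovered cohort mean, and bookkeeping counts.
    """
    config = config or FociDetectionConfig()
    rng = np.random.default_rng(seed)
    matched_true: list[int] = []
    matched_det: list[int] = []
    n_unmatched = 0
    for f in range(n_fields):
        field_seed = int(rng.integers(0, 2**31 - 1))
        truth = generate_image_truth(
            n_nuclei=nuclei_per_field, mean_foci=mean_foci, seed=field_seed
        )
        stack, table = generate_zstack(truth)
        records, qc = quantify_field(stack, config, individual_id=f"field-{f}")
        kept = qc[~qc["apoptotic"]]
        centers = table[["center_y", "center_x"]].to_numpy()
        for rec, (_, row) in zip(records.itertuples(), kept.iterrows()):
            d = np.hypot(
                centers[:, 0] - row["centroid_y"], centers[:, 1] - row["centroid_x"]
            )
            i = int(np.argmin(d))
            if d[i] <= table["radius_px"].iloc[i]:
                matched_true.append(int(table["n_foci"].iloc[i]))
                matched_det.append(int(rec.foci_count))
            else:
                n_unmatched += 1
    matched_true = np.array(matched_true)
    matched_det = np.array(matched_det)
    exact = float(100.0 * np.mean(matched_true == matched_det))
    true_mean = matched_true.mean()
    rel_err = float(100.0 * abs(matched_det.mean() - true_mean) / true_mean)
    return {
        "n_nuclei": int(matched_true.size),
        "n_unmatched": int(n_unmatched),
        "exact_agreement_pct": exact,
        "mean_rel_error_pct": rel_err,
        "planted_mean": float(true_mean),
        "recovered_mean": float(matched_det.mean()),
    }


def planted_outlier_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    outlier_fraction: float = 0.12,
    outlier_effect: float = 2.5,
    n_patients: int = 136,
    k_threshold: int = 2,
) -> dict[str, float]:
    """Recovery of planted radiosensitivity outliers over seeded cohorts.

    Each replicate simulates one patient cohort (counts only), summarises
    per-individual means, fits the patient reference Gaussians by binned
    least squares (robust to the planted heavy upper tail), classifies
    2-SD exceedance in the unirradiated and 24-h conditions, and assigns
    the taxonomy.  The planted-fraction estimate subtracts the exceedance
    rule's intrinsic Gaussian-tail background — under a perfect fit a
    fraction ``1 - (1 - phi_bar(k))**2`` of ordinary individuals exceeds
    k SD in at least one of the two conditions — and each replicate is
    scored by whether the realised planted fraction lies inside the
    estimate's binomial 95% CI.  Per-class recall against the planted
    classes is pooled over replicates.
    """
    rng = np.random.default_rng(seed)
    tail = stats.norm.sf(k_threshold)
    p_bg = 1.0 - (1.0 - tail) ** 2
    in_ci = 0
    est_fracs = []
    raw_fracs = []
    per_class = {c: [0, 0] for c in ("preexisting_only", "both", "remaining_only")}
    for _ in range(n_replicates):
        params = CohortParams(
            n_individuals={"HI": 0, "RC": n_patients},
            outlier_fraction={"HI": 0.0, "RC": outlier_fraction},
            outlier_effect=outlier_effect,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records, truth = generate_cohort(params)
        summaries = summarize(records)
        calls = {}
        for cond in ("preexisting", "remaining"):
            sub = summaries[summaries["condition"] == cond]
            fit = fit_distribution(
                sub["mean_foci"].to_numpy(), "RC", cond,
                method="binned-least-squares",
            )
            calls[cond] = classify_outliers(sub, fit, cond)
        tax = outlier_taxonomy(
            calls["preexisting"], calls["remaining"], k_threshold=k_threshold
        )
        raw = int((tax["outlier_class"] != "none").sum()) / n_patients
        est = max(0.0, (raw - p_bg) / (1.0 - p_bg))
        raw_fracs.append(raw)
        est_fracs.append(est)
        half = 1.96 * np.sqrt(max(est * (1 - est), 1e-12) / n_patients)
        planted_frac = float(
            (truth.drop_duplicates("individual_id")["outlier_class"] != "none").mean()
        )
        if est - half <= planted_frac <= est + half:
            in_ci += 1
        planted = (
            truth.drop_duplicates("individual_id")
            .set_index("individual_id")["outlier_class"]
        )
        called = tax.set_index("individual_id")["outlier_class"]
        for cls in per_class:
            idx = planted.index[planted == cls]
            per_class[cls][1] += len(idx)
            per_class[cls][0] += int((called.loc[idx] == cls).sum())
    out = {
        "ci_coverage_pct": 100.0 * in_ci / n_replicates,
        "mean_estimated_outlier_pct": float(100.0 * np.mean(est_fracs)),
        "mean_raw_exceedance_pct": float(100.0 * np.mean(raw_fracs)),
        "planted_outlier_pct": 100.0 * outlier_fraction,
    }
    for cls, (hit, tot) in per_class.items():
        out[f"recall_{cls}_pct"] = 100.0 * hit / tot if tot else float("nan")
    return out


def lilliefors_type1_experiment(
    n: int = 59,
    alpha: float = 0.05,
    n_replicates: int = 10_000,
    n_null: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error of the Monte-Carlo Lilliefors test under the null.

    Draws ``n_replicates`` Gaussian samples of size ``n``, computes each
    sample's Lilliefors statistic, converts to p-values against an
    independently simulated null table of ``n_null`` statistics, and
    reports the rejection rate at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    null = np.sort(lilliefors_null_statistics(n, n_null, rng))
    obs = _ks_statistics(rng.standard_normal((n_replicates, n)))
    # p = (1 + #{null >= d}) / (n_null + 1), vectorised via searchsorted
    n_ge = n_null - np.searchsorted(null, obs, side="left")
    p = (1 + n_ge) / (n_null + 1)
    return {
        "type1_error": float(np.mean(p <= alpha)),
        "alpha": alpha,
        "n": n,
        "n_replicates": n_replicates,
    }


def sufficiency_heterogeneity_experiment(
    seed: int = 0,
    n_individuals: int = 59,
    mean: float = 0.49,
    phi_overdispersed: float = 20.0,
    checkpoint: int = 600,
) -> dict[str, float]:
    """Within-tolerance fractions at 600 cells: Poisson vs overdispersed.

    Under pure Poisson counts the cumulative mean stabilises so fast that
    essentially all individuals sit inside the +/-15% band by 600 cells;
    only strong within-individual heterogeneity (negative-binomial with
    large phi, emulating scoring drift in real acquisitions) reproduces
    sub-100% fractions at 600 cells such as the 75% observed on real data.
    """
    cfg = SufficiencyConfig()
    out = {}
    for label, phi in (("poisson", 0.0), ("overdispersed", phi_overdispersed)):
        params = CohortParams(
            n_individuals={"HI": n_individuals, "RC": 0},
            means={
                "HI": {"preexisting": mean, "initial": 5.0, "remaining": 2.63},
                "RC": {"preexisting": 0.59, "initial": 5.0, "remaining": 2.97},
            },
            tau={"preexisting": 0.0, "initial": 0.0, "remaining": 0.0},
            phi=phi,
            outlier_fraction={"HI": 0.0, "RC": 0.0},
            seed=seed,
        )
        records, _ = generate_cohort(params)
        curves = []
        sub = records[records["condition"] == "preexisting"]
        for ind, g in sub.groupby("individual_id", sort=True):
            counts = g.sort_values("cell_index")["foci_count"].to_numpy()
            curves.append(cumulative_agreement(counts, cfg, ind, "preexisting"))
        table = fraction_within_tolerance(curves, cfg)
        row = table[table["n_cells"] == checkpoint]
        out[f"pct_within_at_{checkpoint}_{label}"] = float(row["pct_within"].iloc[0])
    return out
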