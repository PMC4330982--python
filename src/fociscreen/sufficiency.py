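"""How many cells must be scored for a stable per-individual foci rate.

The agreement statistic is Bland-Altman-style: at each checkpoint (every
200 cells by default) the cumulative mean foci rate over the first *n*
cells is expressed as a percentage of the final reference mean (all scored
cells, capped at 1000).  100% is exact agreement; deviations up- and
downward give higher and lower percentages.  A cohort is then summarised
by the fraction of individuals whose agreement lies within a +/-15%
tolerance band at each checkpoint, and the minimum sufficient cell count
is the smallest checkpoint at which a required fraction (e.g. 75% or 95%)
of individuals is within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SufficiencyConfig:
    checkpoint_interval: int = 200
    tolerance: float = 0.15
    reference_cells: int = 1000
    required_fraction: float = 0.75

    def __post_init__(self):
        if self.checkpoint_interval < 1:
            raise ValueError("checkpoint_interval must be >= 1")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if self.reference_cells < self.checkpoint_interval:
            raise ValueError("reference_cells must be >= checkpoint_interval")
        if not 0 < self.required_fraction <= 1:
            raise ValueError("required_fraction must be in (0, 1]")


@dataclass
class SufficiencyCurve:
    """Per-checkpoint agreement of one individual x condition."""

    individual_id: str
    condition: str
    n_cells: np.ndarray          # checkpoint cell counts, ascending
    agreement_pct: np.ndarray    # 100 * cumulative mean / reference mean
    final_n: int
    valid: bool = True           # False when the reference mean is zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "condition": self.condition,
                "n_cells": self.n_cells,
                "agreement_pct": self.agreement_pct,
            }
        )


def cumulative_agreement(
    counts,
    config: SufficiencyConfig,
    individual_id: str = "",
    condition: str = "",
) -> SufficiencyCurve:
    """Agreement of cumulative means with the reference mean.

    ``counts`` must be in the original scoring order.  The reference mean
    is taken over the first ``min(reference_cells, len(counts))`` cells;
    the final checkpoint always sits at that count, so its agreement is
    exactly 100%.  An all-zero reference mean makes agreement undefined:
    the curve is returned with ``valid=False`` and is excluded from cohort
    aggregation.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    n_ref = min(config.reference_cells, counts.size)
    if n_ref < config.checkpoint_interval:
        raise ValueError(
            f"need at least {config.checkpoint_interval} cells, got {counts.size}"
        )
    checkpoints = np.arange(config.checkpoint_interval, n_ref + 1,
                            config.checkpoint_interval)
    if checkpoints[-1] != n_ref:
        checkpoints = np.append(checkpoints, n_ref)
    cum = np.cumsum(counts[:n_ref])
    ref_mean = cum[-1] / n_ref
    if ref_mean == 0:
        return SufficiencyCurve(
            individual_id, condition, checkpoints,
            np.full(checkpoints.shape, np.nan), int(n_ref), valid=False,
        )
    # ratio first, then scale: keeps the final self-ratio exactly 100.0
    agreement = 100.0 * ((cum[checkpoints - 1] / checkpoints) / ref_mean)
    return SufficiencyCurve(
        individual_id, condition, checkpoints, agreement, int(n_ref)
    )


def fraction_within_tolerance(
    curves: list[SufficiencyCurve],
    config: SufficiencyConfig,
) -> pd.DataFrame:
    """Per checkpoint, the percentage of individuals within tolerance.

    Only valid curves contribute.  Checkpoints are pooled across curves;
    each checkpoint's percentage is computed over the curves that reach it.
    Raises on an empty (or all-invalid) cohort.
    """
    valid = [c for c in curves if c.valid]
    if not valid:
        raise ValueError("no valid curves in cohort")
    band = 100.0 * config.tolerance
    rows: dict[int, list[bool]] = {}
    for c in valid:
        for n, a in zip(c.n_cells, c.agreement_pct):
            rows.setdefault(int(n), []).append(abs(a - 100.0) <= band)
    table = pd.DataFrame(
        {
            "n_cells": sorted(rows),
            "pct_within": [100.0 * np.mean(rows[n]) for n in sorted(rows)],
            "n_individuals": [len(rows[n]) for n in sorted(rows)],
        }
    )
    return table


def minimum_cells(table: pd.DataFrame, required_fraction: float) -> int | None:
    """Smallest checkpoint where the within-tolerance fraction qualifies.

    Returns ``None`` when no checkpoint reaches ``required_fraction``.
    """
    if table.empty:
        raise ValueError("empty tolerance table")
    ok = table[table["pct_within"] >= 100.0 * required_fraction]
    if ok.empty:
        return None
    return int(ok["n_cells"].min())


def cohort_sufficiency(
    records: pd.DataFrame,
    config: SufficiencyConfig | None = None,
    condition: str | None = None,
    permutation_seed: int | None = None,
) -> tuple[list[SufficiencyCurve], pd.DataFrame, int | None]:
    """Convenience wrapper: curves, tolerance table and minimum cell count.

    ``records`` follows the shared per-cell schema; rows are ordered by
    ``cell_index`` (the acquisition order) within each individual.
    ``permutation_seed`` optionally reshuffles each individual's scoring
    order (seeded) for robustness analysis; the default keeps acquisition
    order, which is how cells are scored in practice.
    """
    config = config or SufficiencyConfig()
    df = records if condition is None else records[records["condition"] == condition]
    rng = (
        np.random.default_rng(permutation_seed)
        if permutation_seed is not None
        else None
    )
    curves = []
    for (ind, cond), g in df.groupby(["individual_id", "condition"], sort=True):
        counts = g.sort_values("cell_index")["foci_count"].to_numpy()
        if rng is not None:
            counts = rng.permutation(counts)
        curves.append(cumulative_agreement(counts, config, ind, cond))
    table = fraction_within_tolerance(curves, config)
    return curves, table, minimum_cells(table, config.required_fraction)
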