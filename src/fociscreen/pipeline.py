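"""Reproducible end-to-end pipeline: simulate/ingest -> quantify -> stats.

``run_pipeline`` drives the stages on one of three input modes — a
simulated cohort, an existing per-cell count table, or a directory of
two-channel z-stacks — and writes all tables, fit reports and a run
manifest (config hash, seed, package and library versions) into the
output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

import fociscreen
from fociscreen import io as fio
from fociscreen.cohortstats import (
    classify_outliers,
    compare_groups,
    exceedance_table,
    fit_all,
    outlier_taxonomy,
    summarize,
    test_normality,
)
from fociscreen.imaging import FociDetectionConfig, quantify_field
from fociscreen.sufficiency import SufficiencyConfig, cohort_sufficiency
from fociscreen.synthgen import CohortParams, generate_cohort

log = logging.getLogger("fociscreen")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode is active: ``simulate`` (synthetic cohort from
    ``cohort`` parameters), ``counts`` (read ``counts_path``), or
    ``images`` (quantify every ``*.tif`` under ``images_dir``; file names
    are parsed as ``<individual>_<group>_<condition>.tif``).
    """

    mode: str = "simulate"
    counts_path: str | None = None
    images_dir: str | None = None
    out_dir: str = "results"
    seed: int = 0
    min_cells: int = 600
    fit_method: str = "moment"
    taxonomy_fit_method: str = "binned-least-squares"
    taxonomy_reference_group: str = "RC"
    k_threshold: int = 2
    cohort: CohortParams = field(default_factory=CohortParams)
    detection: FociDetectionConfig = field(default_factory=FociDetectionConfig)
    sufficiency: SufficiencyConfig = field(default_factory=SufficiencyConfig)

    def validate(self) -> None:
        if self.mode not in ("simulate", "counts", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "counts" and not self.counts_path:
            raise ValueError("counts mode requires counts_path")
        if self.mode == "images" and not self.images_dir:
            raise ValueError("images mode requires images_dir")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("cohort", CohortParams),
            ("detection", FociDetectionConfig),
            ("sufficiency", SufficiencyConfig),
        ):
            if key in raw:
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ingest(config: PipelineConfig) -> pd.DataFrame:
    if config.mode == "simulate":
        params = config.cohort.replace(seed=config.seed)
        records, truth = generate_cohort(params)
        truth.to_csv(Path(config.out_dir) / "cohort.truth.csv", index=False)
        return records
    if config.mode == "counts":
        return fio.read_records(config.counts_path)
    frames = []
    for tif in sorted(Path(config.images_dir).glob("*.tif")):
        parts = tif.stem.split("_")
        if len(parts) != 3:
            raise ValueError(
                f"cannot parse {tif.name}: expected <individual>_<group>_<condition>.tif"
            )
        stack = fio.read_zstack(tif)
        rec, qc = quantify_field(stack, config.detection, *parts)
        qc.to_csv(Path(config.out_dir) / f"{tif.stem}.qc.csv", index=False)
        frames.append(rec)
    if not frames:
        raise ValueError(f"no *.tif stacks under {config.images_dir}")
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: mode=%s seed=%d", config.mode, config.seed)

    records = _ingest(config)
    fio.write_records(records, out / "records.csv")
    summaries = summarize(records, min_cells=config.min_cells)
    summaries.to_csv(out / "summaries.csv", index=False)

    report: dict = {"seed": config.seed, "mode": config.mode}

    # sufficiency (needs at least one full checkpoint per individual)
    n_per = records.groupby(["individual_id", "condition"])["cell_index"].size()
    eligible = n_per[n_per >= config.sufficiency.checkpoint_interval]
    if not eligible.empty:
        keep = records.set_index(["individual_id", "condition"]).index.isin(
            eligible.index
        )
        curves, table, min_n = cohort_sufficiency(
            records[keep], config.sufficiency
        )
        pd.concat([c.to_frame() for c in curves]).to_csv(
            out / "sufficiency_curves.csv", index=False
        )
        table.to_csv(out / "sufficiency_tolerance.csv", index=False)
        report["minimum_cells"] = min_n
    else:
        log.warning("no individual reaches one sufficiency checkpoint; stage skipped")

    # cohort statistics
    fits = fit_all(summaries, method=config.fit_method)
    report["fits"] = {
        f"{g}:{c}": {"mu": f.mu, "sigma": f.sigma, "n": f.n, "method": f.method}
        for (g, c), f in fits.items()
    }
    report["normality"] = {}
    report["comparisons"] = {}
    for cond in sorted(summaries["condition"].unique()):
        sub = summaries[summaries["condition"] == cond]
        for grp in sorted(sub["group"].unique()):
            vals = sub[sub["group"] == grp]["mean_foci"].to_numpy()
            if vals.size >= 5 and np.ptp(vals) > 0:
                report["normality"][f"{grp}:{cond}"] = test_normality(
                    vals, seed=config.seed
                )
        hi = sub[sub["group"] == "HI"]["mean_foci"].to_numpy()
        rc = sub[sub["group"] == "RC"]["mean_foci"].to_numpy()
        if hi.size >= 2 and rc.size >= 2:
            report["comparisons"][cond] = compare_groups(hi, rc)

    present = {(g, c) for (g, c) in fits}
    pairs = [(g, r) for g, r in (("HI", "HI"), ("RC", "RC"), ("RC", "HI"))
             if any(gr == g for gr, _ in present) and any(gr == r for gr, _ in present)]
    tax_conditions = [c for c in ("preexisting", "remaining")
                      if any(cc == c for _, cc in present)]
    if pairs and tax_conditions:
        exc = exceedance_table(
            summaries, fits, groups_and_refs=pairs,
            conditions=tuple(tax_conditions),
        )
        exc.to_csv(out / "exceedance.csv", index=False)

    ref_grp = config.taxonomy_reference_group
    if len(tax_conditions) == 2 and all((ref_grp, c) in present for c in tax_conditions):
        try:
            tax_fits = fit_all(
                summaries[summaries["group"] == ref_grp],
                method=config.taxonomy_fit_method,
            )
        except (RuntimeError, ValueError):
            # histogram fit can fail on very small cohorts; fall back
            log.warning("taxonomy %s fit failed; falling back to moment fit",
                        config.taxonomy_fit_method)
            tax_fits = fit_all(
                summaries[summaries["group"] == ref_grp], method="moment"
            )
        calls = {
            cond: classify_outliers(
                summaries[summaries["group"] == ref_grp], tax_fits[(ref_grp, cond)], cond
            )
            for cond in tax_conditions
        }
        tax = outlier_taxonomy(
            calls["preexisting"], calls["remaining"], k_threshold=config.k_threshold
        )
        tax.to_csv(out / "taxonomy.csv", index=False)
        report["taxonomy_counts"] = (
            tax["outlier_class"].value_counts().to_dict()
        )

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "fociscreen": fociscreen.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    log.info("pipeline done: outputs under %s", out)
    return report


def setup_logging(out_dir: str | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "pipeline.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
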