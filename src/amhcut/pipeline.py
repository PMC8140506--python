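"""End-to-end analysis pipeline and report I/O.

Orchestrates the full cut-off analysis on a subject-level CSV: per-group
Tukey outlier filtering on the biomarker, descriptive summaries,
GAM/AUC-based age categorization, per-band and overall Bayesian and PSI
cut-off estimation, and a combined JSON + CSV report mirroring the
band-by-method layout of the reference analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from amhcut.age_partition import AgePartition, optimal_cutpoints
from amhcut.bayes import McmcConfig, PriorSpec, sample_posterior, summarize_posterior
from amhcut.preprocess import FilterResult, describe, filter_outliers
from amhcut.psi import bootstrap_ci

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_cohort_csv",
    "run_full_analysis",
    "write_report",
    "sample_accounting",
]

REQUIRED_COLUMNS = ("age", "amh", "group")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the full analysis run."""

    input_path: Optional[str] = None
    value_col: str = "amh"
    group_col: str = "group"
    age_col: str = "age"
    k: int = 2
    grid_step: float = 0.5
    prior: PriorSpec = field(default_factory=PriorSpec.uninformative)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    n_boot: int = 1000
    master_seed: int = 0
    output_dir: Optional[str] = None


@dataclass
class AnalysisReport:
    """Results of the full analysis: per-band and overall estimates."""

    partition: AgePartition
    bands: pd.DataFrame          # band x method x (cutoff, ppv, npv + CIs)
    descriptives: pd.DataFrame
    accounting: Dict[str, float]
    band_counts: pd.DataFrame    # band x group subject counts
    excluded_ids: Tuple

    def to_dict(self) -> Dict:
        def records(frame: pd.DataFrame) -> list:
            # NaN -> None so the payload is valid JSON and round-trips
            return [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
                for row in frame.to_dict(orient="records")
            ]

        return {
            "partition": {
                "cutpoints": list(self.partition.cutpoints),
                "auc": self.partition.auc,
                "intervals": list(self.partition.intervals),
            },
            "bands": records(self.bands),
            "descriptives": records(self.descriptives),
            "accounting": self.accounting,
            "band_counts": records(self.band_counts),
            "excluded_ids": [str(i) for i in self.excluded_ids],
        }


def sample_accounting(
    n_enrolled: Dict[str, int], n_excluded: Dict[str, int]
) -> Dict[str, float]:
    """Post-exclusion sample accounting.

    Given enrolled and excluded counts per group, returns final counts
    and the case percentage (one decimal, as conventionally reported).
    Survivors + exclusions must reconcile with enrolment.
    """
    final = {}
    for g, n in n_enrolled.items():
        e = n_excluded.get(g, 0)
        if e < 0 or e > n:
            raise ValueError(f"exclusions for {g!r} ({e}) exceed enrolment ({n})")
        final[g] = n - e
    total = sum(final.values())
    if total <= 0:
        raise ValueError("no subjects remain after exclusion")
    out: Dict[str, float] = {f"final_n_{g}": int(v) for g, v in final.items()}
    out["final_n_total"] = int(total)
    for g, v in final.items():
        out[f"percent_{g}"] = round(100.0 * v / total, 1)
    return out


def read_cohort_csv(
    path: str | Path, column_map: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Read and validate a subject-level cohort CSV.

    ``column_map`` renames input columns onto the canonical
    ``id, age, amh, group, bmi`` schema.  Rows with missing age, AMH or
    group are rejected and logged by id; group labels are normalized to
    lower case.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty cohort file {path}")
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing} in {path}")
    if "id" not in frame.columns:
        frame.insert(0, "id", np.arange(1, len(frame) + 1))
    for col in ("age", "amh"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame["group"] = frame["group"].astype(str).str.strip().str.lower()
    bad = frame["age"].isna() | frame["amh"].isna() | ~frame["group"].isin(["case", "control"])
    if bad.any():
        logger.warning(
            "rejected %d unparseable row(s): ids %s",
            int(bad.sum()), list(frame.loc[bad, "id"]),
        )
        frame = frame.loc[~bad]
    if frame.empty:
        raise ValueError(f"no valid rows in {path}")
    return frame.reset_index(drop=True)


def _band_estimates(
    x: np.ndarray,
    d: np.ndarray,
    band_label: str,
    config: AnalysisConfig,
    seed_offset: int,
) -> list[dict]:
    """Bayesian and PSI estimates for one subject subset."""
    mcmc_seed = int(np.random.default_rng([config.master_seed, seed_offset, 1]).integers(2**31))
    boot_seed = int(np.random.default_rng([config.master_seed, seed_offset, 2]).integers(2**31))
    chains = sample_posterior(x, d, config.prior, replace(config.mcmc, seed=mcmc_seed))
    post = summarize_posterior(chains)
    psi = bootstrap_ci(x, d, n_boot=config.n_boot, seed=boot_seed)
    rows = []
    for param, s in (("cutoff", post.cutoff), ("ppv", post.ppv), ("npv", post.npv)):
        rows.append(
            dict(band=band_label, method="bayes", parameter=param,
                 estimate=s.mean, median=s.median,
                 ci_lower=s.ci_lower, ci_upper=s.ci_upper, rhat=s.rhat)
        )
    for param, est, ci in (
        ("cutoff", psi.cutoff, psi.ci_cutoff),
        ("ppv", psi.ppv, psi.ci_ppv),
        ("npv", psi.npv, psi.ci_npv),
    ):
        rows.append(
            dict(band=band_label, method="psi", parameter=param,
                 estimate=est, median=np.nan, ci_lower=ci[0], ci_upper=ci[1],
                 rhat=np.nan)
        )
    return rows


def run_full_analysis(
    config: AnalysisConfig, cohort: Optional[pd.DataFrame] = None
) -> AnalysisReport:
    """Run the full pipeline: filter, describe, partition ages, estimate.

    ``cohort`` may be passed directly (e.g. a synthetic cohort); else it
    is read from ``config.input_path``.  Every random stage is seeded
    from ``config.master_seed``, so identical inputs give identical
    reports.
    """
    if cohort is None:
        if config.input_path is None:
            raise ValueError("either a cohort frame or config.input_path is required")
        cohort = read_cohort_csv(config.input_path)

    logger.info("stage filter: per-group Tukey fences on %s", config.value_col)
    enrolled = cohort[config.group_col].value_counts().to_dict()
    try:
        filt: FilterResult = filter_outliers(cohort, config.value_col, config.group_col)
    except Exception as err:
        raise RuntimeError(f"stage 'filter' failed: {err}") from err
    excluded_per_group = (
        filt.excluded[config.group_col].value_counts().to_dict() if len(filt.excluded) else {}
    )
    accounting = sample_accounting(enrolled, excluded_per_group)
    data = filt.cohort

    logger.info("stage describe")
    try:
        desc = describe(data, [c for c in ("age", config.value_col, "bmi") if c in data],
                        config.group_col)
    except Exception as err:
        raise RuntimeError(f"stage 'describe' failed: {err}") from err

    logger.info("stage partition: k=%d grid_step=%.2f", config.k, config.grid_step)
    labels = (data[config.group_col] == "case").astype(int)
    work = data.assign(label=labels)
    try:
        partition = optimal_cutpoints(
            work, k=config.k, grid_step=config.grid_step, age_col=config.age_col,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'partition' failed: {err}") from err

    band_idx = partition.assign_bands(work[config.age_col])
    x_all = work[config.value_col].to_numpy(dtype=float)
    d_all = work["label"].to_numpy(dtype=int)

    rows: list[dict] = []
    counts_rows = []
    for b, label in enumerate(partition.intervals):
        mask = band_idx == b
        counts_rows.append(
            dict(band=label,
                 n_case=int(d_all[mask].sum()),
                 n_control=int((1 - d_all[mask]).sum()))
        )
        logger.info("stage estimate: band %s (n=%d)", label, int(mask.sum()))
        try:
            rows.extend(
                _band_estimates(x_all[mask], d_all[mask], label, config, seed_offset=b)
            )
        except Exception as err:
            raise RuntimeError(f"stage 'estimate band {label}' failed: {err}") from err
    logger.info("stage estimate: overall (n=%d)", len(work))
    try:
        rows.extend(_band_estimates(x_all, d_all, "total", config, seed_offset=99))
    except Exception as err:
        raise RuntimeError(f"stage 'estimate total' failed: {err}") from err

    report = AnalysisReport(
        partition=partition,
        bands=pd.DataFrame(rows),
        descriptives=desc,
        accounting=accounting,
        band_counts=pd.DataFrame(counts_rows),
        excluded_ids=tuple(filt.excluded["id"]) if "id" in filt.excluded else (),
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> Dict[str, Path]:
    """Write report.json, table3.csv and exclusions.csv (idempotent)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "report.json",
        "table": out / "table3.csv",
        "exclusions": out / "exclusions.csv",
    }
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    report.bands.to_csv(paths["table"], index=False)
    pd.DataFrame({"id": list(report.excluded_ids)}).to_csv(paths["exclusions"], index=False)
    logger.info("report written to %s", out)
    return paths
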