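"""One-call pipeline: folders in, index table and statistics out.

``run_easyhrv`` loads every recording from the given per-group folders,
filters artifacts, computes the requested index families per recording
(parallelisable per recording), and runs the group comparison.  A
recording whose non-linear stage fails contributes NaNs for the affected
columns but keeps its valid time/frequency values; no single recording
can abort the cohort run.  Results are identical for any ``n_jobs``.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .freq_domain import FREQ_INDEX_NAMES, SpectralParams, compute_freq_indices
from .io import Cohort, Recording, discover_cohort
from .nonlinear import (
    NONLINEAR_INDEX_NAMES,
    RQA_INDEX_NAMES,
    EmbeddingParams,
    compute_nonlinear_indices,
)
from .preprocess import FilterParams, filter_beats
from .stats import StatsConfig, StatsReport, run_stats
from .time_domain import TIME_INDEX_NAMES, compute_time_indices

__all__ = ["RunConfig", "EasyHRVResult", "run_easyhrv", "export_indices",
           "render_summary", "indices_for_recording"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; mirrors the single-call prototype."""

    folders: tuple = ()
    dialect: str = "rr"
    non_linear: bool = False
    do_rqa: bool = False
    type_analysis: str = "fourier"
    correction: str = "bonferroni"
    significance: float = 0.05
    n_jobs: int = 1
    save_indices_path: str | None = None
    verbose: bool = False
    seed: int = 0
    filtering: bool = True
    window_s: float = 300.0
    filter_params: FilterParams = field(default_factory=FilterParams)
    spectral_params: SpectralParams | None = None
    embedding_params: EmbeddingParams | None = None

    def __post_init__(self) -> None:
        if self.do_rqa and not self.non_linear:
            raise ValueError("do_rqa requires non_linear")
        if self.n_jobs < 1:
            raise ValueError("n_jobs must be >= 1")


@dataclass
class EasyHRVResult:
    hrv_indices: pd.DataFrame
    stats: StatsReport
    run_log: list[dict]

    def __str__(self) -> str:
        return render_summary(self)


def _recording_seed(base_seed: int, group: str, rec_id: str) -> int:
    return (base_seed * 1000003 + zlib.crc32(f"{group}/{rec_id}".encode())) % 2**31


def indices_for_recording(
    rec: Recording, config: RunConfig
) -> tuple[dict[str, float], list[dict]]:
    """Compute one index row; failures become NaNs plus log entries."""
    log: list[dict] = []
    row: dict[str, float] = {"id": rec.id, "group": rec.group}

    def note(stage: str, message: str) -> None:
        log.append({"id": rec.id, "group": rec.group, "stage": stage,
                    "message": message})

    series = rec.series
    if config.filtering:
        try:
            series, removal = filter_beats(series, config.filter_params)
            if len(removal):
                note("filter", f"{len(removal)} beats rejected")
        except ValueError as err:
            note("filter", str(err))
            for name in TIME_INDEX_NAMES + FREQ_INDEX_NAMES:
                row[name] = np.nan
            if config.non_linear:
                for name in NONLINEAR_INDEX_NAMES:
                    row[name] = np.nan
            return row, log

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            row.update(compute_time_indices(series, window_s=config.window_s).as_dict())
        except ValueError as err:
            note("time_domain", str(err))
            row.update(dict.fromkeys(TIME_INDEX_NAMES, np.nan))
        try:
            sp = config.spectral_params or SpectralParams(method=config.type_analysis)
            if sp.method != config.type_analysis:
                sp = replace(sp, method=config.type_analysis)
            row.update(compute_freq_indices(series, sp).as_dict())
        except ValueError as err:
            note("freq_domain", str(err))
            row.update(dict.fromkeys(FREQ_INDEX_NAMES, np.nan))
        for w in caught:
            note("warning", str(w.message))

    if config.non_linear:
        ep = config.embedding_params or EmbeddingParams()
        ep = replace(ep, seed=_recording_seed(config.seed, rec.group, rec.id))
        nl_log: list[str] = []
        nl = compute_nonlinear_indices(series, ep, do_rqa=config.do_rqa, log=nl_log)
        values = nl.as_dict()
        if not config.do_rqa:
            for name in RQA_INDEX_NAMES:
                values.pop(name)
        row.update(values)
        for msg in nl_log:
            note("nonlinear", msg)
    return row, log


def run_easyhrv(config: RunConfig, cohort: Cohort | None = None) -> EasyHRVResult:
    """Run the complete pipeline for a cohort of per-group folders."""
    if cohort is None:
        cohort = discover_cohort(config.folders, dialect=config.dialect)
    if len(cohort.groups) < 2:
        raise ValueError("need at least two groups for a comparison")

    results = Parallel(n_jobs=config.n_jobs)(
        delayed(indices_for_recording)(rec, config) for rec in cohort.recordings
    )
    rows = [row for row, _ in results]
    run_log = [entry for _, log in results for entry in log]

    table = pd.DataFrame(rows)
    stats_config = StatsConfig(
        significance=config.significance,
        correction=config.correction,
        seed=config.seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        stats = run_stats(table, stats_config)
    for w in caught:
        run_log.append({"id": "", "group": "", "stage": "stats",
                        "message": str(w.message)})

    result = EasyHRVResult(hrv_indices=table, stats=stats, run_log=run_log)
    if config.save_indices_path:
        export_indices(result, config.save_indices_path)
    if config.verbose:
        print(render_summary(result))
    return result


def export_indices(result: EasyHRVResult, path: str | Path) -> tuple[Path, Path]:
    """Write the index table as an Excel spreadsheet plus a CSV twin.

    NA cells are left empty in both files.
    """
    path = Path(path)
    if path.suffix.lower() != ".xlsx":
        path = path.with_suffix(".xlsx")
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    df = result.hrv_indices
    df.to_excel(path, index=False)
    df.to_csv(csv_path, index=False)
    return path, csv_path


def export_run_log(result: EasyHRVResult, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(result.run_log, fh, indent=1)
    return path


def render_summary(result: EasyHRVResult) -> str:
    """Console summary: significant indices with p-values and group CIs."""
    stats = result.stats
    lines = []
    sig = [o for o in stats.omnibus if o.significant]
    n_idx = len(stats.omnibus)
    lines.append(
        f"Analysed {len(result.hrv_indices)} recordings in "
        f"{result.hrv_indices['group'].nunique()} groups; {n_idx} indices tested "
        f"({stats.config.correction} correction, alpha={stats.config.significance:g})."
    )
    if not sig:
        lines.append("No statistically significant differences were found.")
        return "\n".join(lines)

    ci_by_index: dict[str, list] = {}
    for ci in stats.cis:
        ci_by_index.setdefault(ci.index_name, []).append(ci)
    ph_by_index: dict[str, list] = {}
    for ph in stats.posthoc:
        ph_by_index.setdefault(ph.index_name, []).append(ph)

    for o in sorted(sig, key=lambda o: o.index_name):
        test = "ANOVA" if o.method == "anova" else "Kruskal-Wallis"
        lines.append(f"\n{o.index_name}: {test}, adjusted p = {o.p_adj:.4g}")
        for ci in ci_by_index.get(o.index_name, []):
            lines.append(
                f"  {ci.group}: {100 * ci.level:.0f}% CI "
                f"[{ci.lo:.4g}, {ci.hi:.4g}] ({ci.method})"
            )
        for ph in ph_by_index.get(o.index_name, []):
            marker = "*" if ph.p_adj < stats.config.significance else " "
            lines.append(
                f"  {ph.group_a} vs {ph.group_b}: adjusted p = {ph.p_adj:.4g} {marker}"
            )
    return "\n".join(lines)
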