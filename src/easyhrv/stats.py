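"""Normality-gated multi-group comparison of HRV indices.

For each index, a one-way ANOVA is fitted and the normality of its
residuals checked with the Shapiro-Wilk test.  If normality is rejected
at the significance level the ANOVA is discarded in favour of a
(tie-corrected) Kruskal-Wallis test.  Raw omnibus p-values are corrected
across the whole family of computed indices.  For significant indices
with three or more groups, pairwise post-hocs follow the omnibus choice:
two-sample t-tests after ANOVA, Dunn rank tests after Kruskal-Wallis,
each family corrected with the same method.  Per-group confidence
intervals use the t distribution when the index passed the normality
gate and a seeded percentile bootstrap of the mean otherwise.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "OmnibusResult",
    "PosthocEntry",
    "GroupCI",
    "StatsReport",
    "omnibus_test",
    "adjust_pvalues",
    "posthoc_tests",
    "group_confidence_intervals",
    "run_stats",
]

_CORRECTIONS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "BH": "fdr_bh",
    "fdr": "fdr_bh",
    "BY": "fdr_by",
}


@dataclass(frozen=True)
class StatsConfig:
    significance: float = 0.05
    correction: str = "bonferroni"
    bootstrap_B: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")
        if self.correction not in _CORRECTIONS and self.correction != "none":
            raise ValueError(
                f"unknown correction {self.correction!r}; "
                f"choose from {sorted(_CORRECTIONS) + ['none']}"
            )


@dataclass
class OmnibusResult:
    index_name: str
    method: str          # "anova" | "kruskal"
    shapiro_p: float
    p_raw: float
    p_adj: float = np.nan
    significant: bool = False


@dataclass
class PosthocEntry:
    index_name: str
    group_a: str
    group_b: str
    method: str          # "pairwise_t" | "dunn"
    p_raw: float
    p_adj: float


@dataclass
class GroupCI:
    index_name: str
    group: str
    level: float
    lo: float
    hi: float
    method: str          # "t" | "bootstrap"


@dataclass
class StatsReport:
    omnibus: list[OmnibusResult] = field(default_factory=list)
    posthoc: list[PosthocEntry] = field(default_factory=list)
    cis: list[GroupCI] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    config: StatsConfig = field(default_factory=StatsConfig)

    def omnibus_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(o) for o in self.omnibus])

    def posthoc_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.posthoc])

    def ci_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cis])

    def significant_indices(self) -> list[str]:
        return [o.index_name for o in self.omnibus if o.significant]

    def to_csv(self, path) -> None:
        """Write omnibus, post-hoc and CI tables into one long CSV."""
        frames = []
        for label, df in [
            ("omnibus", self.omnibus_frame()),
            ("posthoc", self.posthoc_frame()),
            ("ci", self.ci_frame()),
        ]:
            if not df.empty:
                df = df.copy()
                df.insert(0, "table", label)
                frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def omnibus_test(
    values_by_group: dict[str, np.ndarray],
    config: StatsConfig | None = None,
    index_name: str = "",
) -> OmnibusResult:
    """ANOVA with a Shapiro-Wilk gate, falling back to Kruskal-Wallis.

    NA values must already be excluded; each group needs >= 3 values.
    Degenerate inputs (constant residuals, all-tied ranks) fall back to
    Kruskal-Wallis, and a fully tied Kruskal-Wallis reports p = 1.
    """
    config = config or StatsConfig()
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs at least three non-NA values")

    residuals = np.concatenate([g - g.mean() for g in groups])
    alpha = config.significance
    try:
        if np.ptp(residuals) == 0:
            raise ValueError("constant residuals")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if residuals.size > 5000:
                rng = np.random.default_rng(config.seed)
                residuals = rng.choice(residuals, 5000, replace=False)
            shapiro_p = float(sps.shapiro(residuals).pvalue)
        normal = shapiro_p >= alpha
    except ValueError as err:
        warnings.warn(f"Shapiro-Wilk undefined ({err}); falling back to Kruskal-Wallis")
        shapiro_p, normal = np.nan, False

    if normal:
        p_raw = float(sps.f_oneway(*groups).pvalue)
        method = "anova"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_raw = float(sps.kruskal(*groups).pvalue)
            if np.isnan(p_raw):  # fully tied ranks carry no evidence
                p_raw = 1.0
        except ValueError:  # all values identical
            p_raw = 1.0
        method = "kruskal"
    return OmnibusResult(index_name=index_name, method=method,
                         shapiro_p=shapiro_p, p_raw=p_raw)


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity-corrected p-values, order-preserving.

    Methods: bonferroni, holm, hochberg, hommel (family-wise error),
    BH / fdr, BY (false discovery rate), none.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in _CORRECTIONS:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, alpha=0.05, method=_CORRECTIONS[method])[1]


def _dunn_pvalues(
    values_by_group: dict[str, np.ndarray]
) -> list[tuple[str, str, float]]:
    """Dunn z-tests on mean ranks with tie correction, uncorrected p."""
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction T = sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    pos = 0
    for g in names:
        n_g = values_by_group[g].size
        mean_ranks[g] = float(ranks[pos: pos + n_g].mean())
        sizes[g] = n_g
        pos += n_g

    out = []
    var_base = n_total * (n_total + 1) / 12.0 - T
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
            out.append((a, b, p))
    return out


def posthoc_tests(
    values_by_group: dict[str, np.ndarray],
    omnibus: OmnibusResult,
    config: StatsConfig | None = None,
) -> list[PosthocEntry]:
    """Pairwise comparisons after a significant omnibus (>= 3 groups).

    t-tests after ANOVA, Dunn rank z-tests after Kruskal-Wallis; the
    pairwise family is corrected with the configured method.
    """
    config = config or StatsConfig()
    usable = {g: np.asarray(v, float) for g, v in values_by_group.items()
              if np.asarray(v).size >= 2}
    skipped = set(values_by_group) - set(usable)
    if skipped:
        warnings.warn(f"groups with <2 values skipped in post-hoc: {sorted(skipped)}")
    if len(usable) < 3:
        return []

    if omnibus.method == "anova":
        method = "pairwise_t"
        names = list(usable)
        raw = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = float(sps.ttest_ind(usable[a], usable[b]).pvalue)
                raw.append((a, b, p))
    else:
        method = "dunn"
        raw = _dunn_pvalues(usable)

    adj = adjust_pvalues([p for _, _, p in raw], config.correction)
    return [
        PosthocEntry(index_name=omnibus.index_name, group_a=a, group_b=b,
                     method=method, p_raw=p, p_adj=float(q))
        for (a, b, p), q in zip(raw, adj)
    ]


def group_confidence_intervals(
    values_by_group: dict[str, np.ndarray],
    normal: bool,
    config: StatsConfig | None = None,
    index_name: str = "",
) -> list[GroupCI]:
    """Unadjusted CIs of the group means (t-based or percentile bootstrap)."""
    config = config or StatsConfig()
    level = 1.0 - config.significance
    out = []
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values for a CI")
        if normal or np.ptp(v) == 0:
            m, s = v.mean(), v.std(ddof=1)
            half = sps.t.ppf(1 - config.significance / 2, v.size - 1) * s / np.sqrt(v.size)
            lo, hi = m - half, m + half
            method = "t"
        else:
            # per-group seed stable across index/group orderings
            sub = zlib.crc32(f"{index_name}/{g}".encode()) % 2**31
            rng = np.random.default_rng((config.seed, sub))
            idx = rng.integers(0, v.size, size=(config.bootstrap_B, v.size))
            means = v[idx].mean(axis=1)
            lo, hi = np.percentile(
                means, [100 * config.significance / 2, 100 * (1 - config.significance / 2)]
            )
            method = "bootstrap"
        out.append(GroupCI(index_name=index_name, group=g, level=level,
                           lo=float(lo), hi=float(hi), method=method))
    return out


def run_stats(
    indices: pd.DataFrame, config: StatsConfig | None = None
) -> StatsReport:
    """Full statistical comparison of an index table.

    ``indices`` has one row per recording with at least columns ``id``
    and ``group``; every other numeric column is treated as an HRV index.
    All-NA columns (and columns leaving any group with < 3 values) are
    excluded with a warning.  Re-runnable on an externally edited table.
    """
    config = config or StatsConfig()
    if "group" not in indices.columns:
        raise ValueError("index table needs a 'group' column")
    group_labels = sorted(indices["group"].unique())
    if len(group_labels) < 2:
        raise ValueError("statistical comparison needs at least two groups")

    index_cols = [c for c in indices.columns if c not in ("id", "group")]
    report = StatsReport(config=config)
    per_index_values: dict[str, dict[str, np.ndarray]] = {}

    for col in index_cols:
        values = {}
        ok = True
        for g in group_labels:
            v = pd.to_numeric(indices.loc[indices["group"] == g, col], errors="coerce")
            v = v.dropna().to_numpy(dtype=float)
            if v.size < 3:
                ok = False
            values[g] = v
        if not ok:
            warnings.warn(
                f"index {col!r} skipped: a group has fewer than 3 non-NA values"
            )
            report.skipped.append(col)
            continue
        per_index_values[col] = values
        report.omnibus.append(omnibus_test(values, config, index_name=col))

    if not report.omnibus:
        return report

    adj = adjust_pvalues([o.p_raw for o in report.omnibus], config.correction)
    for o, q in zip(report.omnibus, adj):
        o.p_adj = float(q)
        o.significant = bool(q < config.significance)

    for o in report.omnibus:
        if not o.significant:
            continue
        values = per_index_values[o.index_name]
        if len(group_labels) >= 3:
            report.posthoc.extend(posthoc_tests(values, o, config))
        report.cis.extend(
            group_confidence_intervals(
                values, normal=o.method == "anova", config=config,
                index_name=o.index_name,
            )
        )
    return report
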