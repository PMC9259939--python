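"""Population-level statistics: percent positive, frequency histograms,
and the two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

The rank-sum test uses midranks for ties. For small samples
(n1 + n2 <= exact_limit) the two-sided p-value is exact: the null
distribution of the rank sum is enumerated over all C(n1+n2, n1)
assignments of the observed (mid)ranks to the first sample, and
p = min(1, 2 * min(P(W <= w), P(W >= w))). Larger samples use the
tie-corrected normal approximation with a continuity correction.

Percent positive follows the section-as-data-point convention: the
percentage is computed per section, then summarised as mean +- SEM across
sections (a pooled percentage over all cells is also reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PositivityOptions, SimConfig
from .errors import ConfigError, EmptyPopulationError


# ---------------------------------------------------------------------------
# frequency histogram

@dataclass
class FrequencyHistogram:
    """Relative-frequency histogram on left-closed right-open bins from 0."""

    bin_width: float
    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray
    relative_frequency: np.ndarray
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.counts,
            "relative_frequency": self.relative_frequency,
        })


def frequency_distribution(scores, bin_width: float = 1.0) -> FrequencyHistogram:
    """Bin non-negative scores into [0,w), [w,2w), ... and normalise to 1."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise EmptyPopulationError("frequency_distribution needs at least one score")
    if bin_width <= 0:
        raise ConfigError(f"bin_width must be > 0, got {bin_width}")
    if scores.min() < 0:
        raise ConfigError("scores must be non-negative")
    n_bins = int(math.floor(scores.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(scores, bins=edges)
    return FrequencyHistogram(
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts,
        relative_frequency=counts / scores.size,
        n=int(scores.size),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

@dataclass
class RankSumResult:
    statistic_U: float
    rank_sum_W: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"

    def __str__(self) -> str:
        return (f"RankSum(U={self.statistic_U:g}, n1={self.n1}, n2={self.n2}, "
                f"p={self.p_two_sided:.4g}, {self.method})")


def _exact_two_sided(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for comb in itertools.combinations(range(ranks.size), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(x, y, exact_limit: int = 16) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Exact by full enumeration of rank assignments when n1 + n2 <= exact_limit
    (ties handled by enumerating the observed midranks); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyPopulationError(
            f"rank_sum_test needs non-empty samples (n1={x.size}, n2={y.size})"
        )
    n1, n2 = int(x.size), int(y.size)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))  # midranks
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    if n <= exact_limit:
        p = _exact_two_sided(ranks, n1, w)
        return RankSumResult(statistic_U=u, rank_sum_W=w, n1=n1, n2=n2,
                             p_two_sided=p, method="exact")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        p = 1.0
    else:
        diff = u - mu
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var) if diff != 0 else 0.0
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return RankSumResult(statistic_U=u, rank_sum_W=w, n1=n1, n2=n2,
                         p_two_sided=p, method="normal_approx")


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment across regions (off by default upstream).

    ``method`` is ``bonferroni`` or ``bh`` (Benjamini-Hochberg), delegated to
    statsmodels.
    """
    from statsmodels.stats.multitest import multipletests

    mapped = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    if method not in mapped:
        raise ConfigError(f"unknown adjustment method {method!r}")
    return multipletests(np.asarray(list(pvalues), dtype=float),
                         method=mapped[method])[1]


# ---------------------------------------------------------------------------
# percent positive

@dataclass
class PercentPositive:
    """Percent positive of one population: per-section, mean +- SEM, pooled."""

    mean: float
    sem: float
    n_sections: int
    pooled: float
    n_cells: int
    per_section: dict[str, float] = field(default_factory=dict)


def percent_positive(records: pd.DataFrame, population: str, positive_col: str,
                     section_col: str = "section_id") -> PercentPositive:
    """Mean +- SEM across sections of the per-section percent positive.

    ``records`` is a typed cell table with ``type_label``, a boolean
    positivity column and a section identifier column.
    """
    sub = records[records["type_label"] == population]
    if sub.empty:
        raise EmptyPopulationError(f"no cells of population {population!r}")
    if section_col in sub.columns:
        per = (sub.groupby(section_col, sort=True)[positive_col].mean() * 100.0)
    else:  # single unlabelled section
        per = pd.Series({"all": sub[positive_col].mean() * 100.0})
    vals = per.to_numpy(dtype=float)
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return PercentPositive(
        mean=float(vals.mean()),
        sem=sem,
        n_sections=int(vals.size),
        pooled=float(sub[positive_col].mean() * 100.0),
        n_cells=int(sub.shape[0]),
        per_section={str(k): float(v) for k, v in per.items()},
    )


# ---------------------------------------------------------------------------
# population comparison

@dataclass
class PopulationStats:
    label: str
    n_cells: int
    percent_positive: PercentPositive
    histogram: FrequencyHistogram
    median_score: float
    scores: np.ndarray


@dataclass
class PopulationSummary:
    """Two-population comparison for one region: percent positive,
    relative-frequency histograms of the expression score, and the
    rank-sum test on the pooled per-cell scores."""

    region_label: str
    target_channel: str
    score_mode: str  # "density" (dots / 100 um^2) | "count"
    populations: dict[str, PopulationStats]
    rank_sum: RankSumResult
    pop_a: str
    pop_b: str

    def to_dict(self) -> dict:
        def popd(p: PopulationStats) -> dict:
            return {
                "n_cells": p.n_cells,
                "percent_positive_mean": p.percent_positive.mean,
                "percent_positive_sem": p.percent_positive.sem,
                "percent_positive_pooled": p.percent_positive.pooled,
                "n_sections": p.percent_positive.n_sections,
                "per_section_percent": p.percent_positive.per_section,
                "median_score": p.median_score,
                "histogram": {
                    "bin_width": p.histogram.bin_width,
                    "bin_edges": p.histogram.bin_edges.tolist(),
                    "relative_frequency": p.histogram.relative_frequency.tolist(),
                    "n": p.histogram.n,
                },
            }

        return {
            "region_label": self.region_label,
            "target_channel": self.target_channel,
            "score_mode": self.score_mode,
            "population_a": self.pop_a,
            "population_b": self.pop_b,
            "populations": {k: popd(v) for k, v in self.populations.items()},
            "rank_sum": {
                "statistic_U": self.rank_sum.statistic_U,
                "n1": self.rank_sum.n1,
                "n2": self.rank_sum.n2,
                "p_two_sided": self.rank_sum.p_two_sided,
                "method": self.rank_sum.method,
            },
        }


def compare_populations(records: pd.DataFrame, region_label: str, pop_a: str, pop_b: str,
                        target_channel: str = "Gprc5b", score_mode: str = "density",
                        bin_width: float = 1.0, exact_limit: int = 16,
                        positivity_min_dots: int = 1,
                        section_col: str = "section_id") -> PopulationSummary:
    """Assemble the full two-population comparison for one region.

    Cells are pooled across sections for the histogram and the rank-sum test;
    percent positive keeps the section-as-data-point convention.
    """
    if score_mode == "density":
        score_col = f"{target_channel}_dot_density"
    elif score_mode == "count":
        score_col = f"{target_channel}_dot_count"
    else:
        raise ConfigError(f"unknown score_mode {score_mode!r}")
    for col in (score_col, "type_label"):
        if col not in records.columns:
            raise ConfigError(f"cell table lacks column {col!r}")
    pos_col = f"positive_{target_channel}"
    if pos_col not in records.columns:
        records = records.copy()
        records[pos_col] = records[f"{target_channel}_dot_count"] >= positivity_min_dots

    missing = [p for p in (pop_a, pop_b)
               if records[records["type_label"] == p].empty]
    if missing:
        raise EmptyPopulationError(f"empty population(s): {missing}")

    pops: dict[str, PopulationStats] = {}
    for p in (pop_a, pop_b):
        sub = records[records["type_label"] == p]
        scores = sub[score_col].to_numpy(dtype=float)
        pops[p] = PopulationStats(
            label=p,
            n_cells=int(sub.shape[0]),
            percent_positive=percent_positive(records, p, pos_col, section_col=section_col),
            histogram=frequency_distribution(scores, bin_width=bin_width),
            median_score=float(np.median(scores)),
            scores=scores,
        )
    rs = rank_sum_test(pops[pop_a].scores, pops[pop_b].scores, exact_limit=exact_limit)
    return PopulationSummary(
        region_label=region_label,
        target_channel=target_channel,
        score_mode=score_mode,
        populations=pops,
        rank_sum=rs,
        pop_a=pop_a,
        pop_b=pop_b,
    )


# ---------------------------------------------------------------------------
# recovery against the generating model

@dataclass
class PopulationRecovery:
    true_percent_positive: float
    estimated_percent_positive: float
    true_median_count: float
    estimated_median_score: float


@dataclass
class RecoveryReport:
    """Estimated vs generating-model quantities for a simulated comparison."""

    per_population: dict[str, PopulationRecovery]
    direction_correct: bool
    p_two_sided: float


def true_percent_positive(config: SimConfig, type_label: str, target_channel: str,
                          min_dots: int = 1) -> float:
    """Closed-form percent of cells with count >= min_dots under the generator."""
    model = config.count_model[type_label][target_channel]
    return 100.0 * model.prob_at_least(min_dots)


def evaluate_recovery(summary: PopulationSummary, config: SimConfig,
                      positivity: PositivityOptions | None = None) -> RecoveryReport:
    """Score a simulated-field summary against its generating model.

    The true percent positive is P(count >= min_dots) in closed form from
    the configured Poisson / negative-binomial model; the direction check
    compares the sign of the estimated median-score difference with the sign
    of the generating mean difference.
    """
    if positivity is None:
        positivity = PositivityOptions(target_channel=summary.target_channel)
    ch = positivity.target_channel
    per: dict[str, PopulationRecovery] = {}
    for p, stats_p in summary.populations.items():
        if p not in config.count_model:
            raise ConfigError(f"population {p!r} absent from the generator's count model")
        model = config.count_model[p][ch]
        per[p] = PopulationRecovery(
            true_percent_positive=true_percent_positive(config, p, ch, positivity.min_dots),
            estimated_percent_positive=stats_p.percent_positive.pooled,
            true_median_count=float(model.frozen().median()),
            estimated_median_score=stats_p.median_score,
        )
    a, b = summary.pop_a, summary.pop_b
    true_diff = (config.count_model[a][ch].mean - config.count_model[b][ch].mean)
    est_diff = (summary.populations[a].median_score - summary.populations[b].median_score)
    direction = bool(np.sign(true_diff) == np.sign(est_diff)) if true_diff != 0 else True
    return RecoveryReport(per_population=per, direction_correct=direction,
                          p_two_sided=summary.rank_sum.p_two_sided)
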