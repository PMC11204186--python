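"""Top-k projected-distance estimator and cross-condition comparisons.

The measurement rule: from at least ``n`` (default 200) 2D projected
inter-probe distances per condition, keep the ``k`` (default 40) largest and
report their mean. Because segment orientation is uniform, the projected /
true length ratio has density ``x / sqrt(1 - x^2)`` on (0, 1); its mean is
pi/4, but the mean of the top quintile is ~0.9933, so the top-40-of-200 mean
recovers the true 3D separation to within a percent in the noiseless limit.
Conditions are compared with two-sided pooled-variance Student's t-tests on
the two top-k subsets, with the usual significance-star ladder.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .fish_sim import GENOTYPES, PAIRS, pair_distances, pair_tag

__all__ = [
    "TopKResult",
    "ComparisonResult",
    "topk_distances",
    "students_t",
    "significance_tier",
    "compare_conditions",
    "estimator_bias_oracle",
    "plot_comparison",
]

#: (threshold, tier) ladder for two-sided p-values, checked in order.
TIER_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TopKResult:
    """The k largest of n distances and their summary statistics (um)."""

    k: int
    n_total: int
    values: tuple[float, ...]  # sorted descending
    mean: float
    sd: float


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample Student's t comparison with a significance tier."""

    t: float
    df: int
    p: float
    tier: str


def topk_distances(distances, k: int = 40) -> TopKResult:
    """Mean (and SD) of the ``k`` largest distances.

    Selection is by value, ties broken by input order; deterministic.
    """
    d = np.asarray(list(distances), dtype=float)
    n = d.size
    if n < k:
        raise ValueError(
            f"need at least k={k} measurements but got {n}; lower k or collect more nuclei"
        )
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    # stable selection: sort by (-value, input order)
    order = np.argsort(-d, kind="stable")[:k]
    vals = tuple(sorted((float(v) for v in d[order]), reverse=True))
    return TopKResult(
        k=k,
        n_total=n,
        values=vals,
        mean=float(np.mean(d[order])),
        sd=float(np.std(d[order], ddof=1)) if k > 1 else 0.0,
    )


def significance_tier(p: float) -> str:
    for threshold, tier in TIER_LADDER:
        if p < threshold:
            return tier
    return "ns"


def students_t(a, b) -> ComparisonResult:
    """Two-sided pooled-variance (equal-variance) two-sample Student's t-test."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        # degenerate: all observations identical within each group
        if diff == 0.0:
            return ComparisonResult(t=0.0, df=df, p=1.0, tier="ns")
        t = np.inf if diff > 0 else -np.inf
        return ComparisonResult(t=float(t), df=df, p=0.0, tier="****")
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return ComparisonResult(t=float(t), df=df, p=float(p), tier=significance_tier(p))


def _condition_key(pair: tuple[int, int], genotype: str) -> tuple[str, str]:
    return pair_tag(pair), genotype


def compare_conditions(
    tables: dict,
    k: int = 40,
    homologs_per_nucleus: int = 1,
) -> dict[str, pd.DataFrame]:
    """Full cross-comparison of (probe pair x genotype) conditions.

    Parameters
    ----------
    tables : mapping (pair, genotype) -> spot table (or -> 1D distance array).
    k : top-k count for the distance statistic.
    homologs_per_nucleus : how many homolog measurements per nucleus to pool.

    Returns a dict of three data frames:

    ``summary`` — per-condition top-k mean/SD and measurement counts;
    ``within_genotype`` — pairwise probe-pair contrasts at fixed genotype,
    plus a per-genotype flag ``loop_signature`` in ``summary`` marking whether
    the 1.3 Mb interior pair (#2-#3) lies farther apart in the nucleus than
    the 2.6 Mb anchor pair (#1-#4);
    ``within_pair`` — pairwise genotype contrasts at fixed probe pair.
    """
    conditions = [(p, g) for p in PAIRS for g in GENOTYPES]
    missing = [
        f"pair {pair_tag(p)} / genotype {g}"
        for (p, g) in conditions
        if (p, g) not in tables and (pair_tag(p), g) not in tables
    ]
    if missing:
        raise KeyError("missing condition(s): " + ", ".join(missing))

    topk: dict[tuple, TopKResult] = {}
    for p, g in conditions:
        tab = tables.get((p, g), tables.get((pair_tag(p), g)))
        if isinstance(tab, pd.DataFrame):
            d = pair_distances(tab, homologs_per_nucleus=homologs_per_nucleus)
        else:
            d = np.asarray(tab, dtype=float)
        topk[(p, g)] = topk_distances(d, k=k)

    summary = pd.DataFrame(
        [
            {
                "pair": pair_tag(p),
                "genotype": g,
                "n_measurements": topk[(p, g)].n_total,
                "k": k,
                "topk_mean_um": topk[(p, g)].mean,
                "topk_sd_um": topk[(p, g)].sd,
            }
            for p, g in conditions
        ]
    )
    # per-genotype loop signature: interior 1.3 Mb pair farther than anchor 2.6 Mb pair
    sig = {
        g: topk[((2, 3), g)].mean > topk[((1, 4), g)].mean for g in GENOTYPES
    }
    summary["loop_signature"] = summary["genotype"].map(sig)

    rows = []
    for g in GENOTYPES:
        for pa, pb in itertools.combinations(PAIRS, 2):
            res = students_t(topk[(pa, g)].values, topk[(pb, g)].values)
            rows.append(
                {
                    "genotype": g,
                    "pair_a": pair_tag(pa),
                    "pair_b": pair_tag(pb),
                    "mean_a_um": topk[(pa, g)].mean,
                    "mean_b_um": topk[(pb, g)].mean,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "tier": res.tier,
                }
            )
    within_genotype = pd.DataFrame(rows)

    rows = []
    for p in PAIRS:
        for ga, gb in itertools.combinations(GENOTYPES, 2):
            res = students_t(topk[(p, ga)].values, topk[(p, gb)].values)
            rows.append(
                {
                    "pair": pair_tag(p),
                    "genotype_a": ga,
                    "genotype_b": gb,
                    "mean_a_um": topk[(p, ga)].mean,
                    "mean_b_um": topk[(p, gb)].mean,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "tier": res.tier,
                }
            )
    within_pair = pd.DataFrame(rows)

    return {
        "summary": summary,
        "within_genotype": within_genotype,
        "within_pair": within_pair,
    }


def estimator_bias_oracle(
    n: int = 200, k: int = 40, reps: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo expectation of (top-k mean projected length) / (true length).

    Rigid segments of unit length with uniform orientation and no noise: each
    projected length is ``sqrt(1 - u^2)`` with ``u = cos(polar angle)``
    uniform on (0, 1). Returns (mean ratio, standard error over reps).
    For k = n the expectation is pi/4; for k/n = 0.2 it is ~0.9933.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((reps, n))
    proj = np.sqrt(1.0 - u * u)
    part = np.partition(proj, n - k, axis=1)[:, n - k:]
    ratios = part.mean(axis=1)
    se = ratios.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
    return float(ratios.mean()), float(se)


def plot_comparison(tables: dict, k: int = 40, homologs_per_nucleus: int = 1, ax=None):
    """Strip plot of the top-k distances per condition (one dot per value)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    rng = np.random.default_rng(0)  # jitter only
    xticks, labels = [], []
    x = 0
    for p in PAIRS:
        for g in GENOTYPES:
            tab = tables.get((p, g), tables.get((pair_tag(p), g)))
            if tab is None:
                continue
            d = (
                pair_distances(tab, homologs_per_nucleus=homologs_per_nucleus)
                if isinstance(tab, pd.DataFrame)
                else np.asarray(tab, dtype=float)
            )
            res = topk_distances(d, k=k)
            jitter = rng.uniform(-0.18, 0.18, size=len(res.values))
            ax.scatter(x + jitter, res.values, s=8, alpha=0.7)
            ax.hlines(res.mean, x - 0.3, x + 0.3, color="k", lw=1.5)
            xticks.append(x)
            labels.append(f"#{p[0]}#{p[1]}\n{g}")
            x += 1
        x += 0.5
    ax.set_xticks(xticks)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_ylabel("top-k projected distance (µm)")
    return ax
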