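"""Non-parametric comparison battery used on upstream statistics.

Wraps the standard tests (Wilcoxon rank-sum / signed-rank,
Kruskal-Wallis with Benjamini-Hochberg-adjusted post hocs, exact
binomial sign-bias) with explicit handling of the degenerate cases that
windowed genomic data produces: zero paired differences, tiny groups,
and tied ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "bh_adjust",
    "compare_two",
    "compare_many",
    "diversity_bias_binomial",
]


@dataclass
class ComparisonResult:
    statistic_name: str
    groups: tuple[str, ...]
    test: str
    raw_p: float
    adjusted_p: float | None = None
    adjustment: str = "none"
    statistic: float | None = None
    medians: dict[str, float] = field(default_factory=dict)
    quartiles: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def _summaries(res: ComparisonResult, named: dict[str, np.ndarray]) -> None:
    for k, v in named.items():
        res.n[k] = int(len(v))
        if len(v):
            res.medians[k] = float(np.median(v))
            res.quartiles[k] = (
                float(np.quantile(v, 0.25)),
                float(np.quantile(v, 0.75)),
            )


def compare_two(
    a,
    b,
    paired: bool = False,
    names: tuple[str, str] = ("A", "B"),
    statistic_name: str = "",
) -> ComparisonResult:
    """Two-group comparison: rank-sum (unpaired) or signed-rank (paired).

    Exact null distributions are used for n <= 25 without ties, the
    normal approximation with continuity and tie correction otherwise.
    Paired input must be coordinate-aligned and of equal length; all-zero
    paired differences yield a degenerate result with p = 1 flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires aligned vectors")
        diffs = a - b
        nz = diffs[diffs != 0]
        res = ComparisonResult(
            statistic_name, names, "wilcoxon_signed_rank", 1.0
        )
        res.note = f"{len(diffs) - len(nz)} zero differences dropped"
        if len(nz) == 0:
            res.degenerate = True
            _summaries(res, {names[0]: a, names[1]: b})
            return res
        has_ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
        w = stats.wilcoxon(
            nz, alternative="two-sided", method=method, correction=True,
            zero_method="wilcox",
        )
        res.raw_p = float(w.pvalue)
        res.statistic = float(w.statistic)
        _summaries(res, {names[0]: a, names[1]: b})
        return res

    res = ComparisonResult(statistic_name, names, "wilcoxon_rank_sum", 1.0)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else
        "asymptotic"
    )
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    res.raw_p = float(u.pvalue)
    res.statistic = float(u.statistic)
    _summaries(res, {names[0]: a, names[1]: b})
    return res


def compare_many(
    groups: dict[str, np.ndarray],
    posthoc: bool = True,
) -> list[ComparisonResult]:
    """Kruskal-Wallis across >= 3 groups, with BH-adjusted post hocs.

    Returns the omnibus result first, followed (when ``posthoc``) by all
    pairwise rank-sum comparisons carrying BH-adjusted p-values.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("compare_many needs >= 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {k!r} is empty")
    if all((v == next(iter(arrays.values()))[0]).all() for v in arrays.values()):
        omnibus = ComparisonResult(
            "omnibus", tuple(names), "kruskal_wallis", 1.0,
            statistic=0.0, degenerate=True,
        )
    else:
        h = stats.kruskal(*arrays.values())
        omnibus = ComparisonResult(
            "omnibus", tuple(names), "kruskal_wallis",
            float(h.pvalue), statistic=float(h.statistic),
        )
    _summaries(omnibus, arrays)
    results = [omnibus]
    if posthoc:
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        posts = [
            compare_two(
                arrays[x], arrays[y], names=(x, y),
                statistic_name=f"{x}_vs_{y}",
            )
            for x, y in pairs
        ]
        adj = bh_adjust([r.raw_p for r in posts])
        for r, q in zip(posts, adj):
            r.adjusted_p = float(q)
            r.adjustment = "BH"
        results.extend(posts)
    return results


def diversity_bias_binomial(per_gene_diffs) -> ComparisonResult:
    """Exact binomial test for a sign bias in per-gene diversity.

    ``per_gene_diffs`` are signed per-gene differences (group A minus
    group B); zeros are excluded, then k = number of positive genes out
    of m is tested against p0 = 0.5.  Both the two-sided exact p and the
    one-sided tail are reported (the one-sided tail lives in ``note``).
    """
    d = np.asarray(per_gene_diffs, dtype=float)
    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        raise ValueError("no nonzero per-gene differences")
    k = int((nz > 0).sum())
    two = stats.binomtest(k, m, 0.5, alternative="two-sided")
    alt = "greater" if k >= m / 2 else "less"
    one = stats.binomtest(k, m, 0.5, alternative=alt)
    res = ComparisonResult(
        "diversity_bias",
        ("positive", "negative"),
        "binomial",
        float(two.pvalue),
        statistic=float(k),
    )
    res.n = {"positive": k, "negative": m - k, "excluded_zero": len(d) - m}
    res.note = f"one_sided_p={float(one.pvalue):.6g} ({alt})"
    return res
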