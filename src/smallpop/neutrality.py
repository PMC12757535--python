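"""Tajima's D over a pooled site set, with delete-one jackknife CIs.

The statistic contrasts two estimators of the population mutation rate:
mean pairwise differences (pi-hat, summed over sites) and Watterson's
S/a1.  An excess of intermediate-frequency variants (balancing
selection, contraction) drives D positive; an excess of rare variants
(sweep, expansion) drives it negative.  Because D is frequency-based it
needs no phase information.

Missing genotypes make the number of sampled allele copies vary across
sites; pi-hat and S use each site's own called copies, while the
variance constants require a single n, taken as the mode of the
per-site copy counts (heterogeneous inputs are flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .matrix import GenotypeMatrix

__all__ = ["NeutralityResult", "tajima_constants", "tajimas_d", "jackknife_ci"]


@dataclass
class NeutralityResult:
    """Point estimate and (optionally) jackknife CI for Tajima's D."""

    group: str
    n_samples: int
    n_haplotypes: int
    S: int
    pi_hat: float
    theta_w: float
    D: float | None  # None when undefined (S == 0)
    heterogeneous_n: bool = False
    jackknife_mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    replicates: np.ndarray | None = None
    n_dropped_replicates: int = 0
    ci_flagged: bool = False

    @property
    def defined(self) -> bool:
        return self.D is not None


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants a1..e2 for sample size n (haplotypes)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _pooled_stats(
    g: GenotypeMatrix, sample_idx: np.ndarray, site_idx: np.ndarray
) -> tuple[int, float, np.ndarray]:
    """(S, pi_hat, per-site copy counts) over the pooled site set."""
    sub = g.take_variants(site_idx)
    n_alleles = int(max((len(a) for a in sub.alt), default=0) + 1)
    counts = sub.allele_counts(sample_idx=sample_idx, n_alleles=n_alleles)
    n = counts.sum(axis=1).astype(float)
    seg = ((counts > 0).sum(axis=1) > 1) & (n >= 2)
    S = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_p2 = (counts**2).sum(axis=1) / n**2
        pi_site = n / (n - 1) * (1 - sum_p2)
    pi_hat = float(np.sum(pi_site[seg])) if S else 0.0
    return S, pi_hat, n[seg]


def tajimas_d(
    g: GenotypeMatrix,
    group: list[str] | None = None,
    site_idx: np.ndarray | None = None,
    label: str = "all",
) -> NeutralityResult:
    """Tajima's D pooled over ``site_idx`` for the given sample group.

    Returns a flagged-undefined result (``D is None``) when no site
    segregates; a silent zero would be indistinguishable from perfect
    neutrality.
    """
    idx = (
        np.arange(g.n_samples) if group is None else g.sample_index(group)
    )
    sidx = np.arange(g.n_variants) if site_idx is None else np.asarray(site_idx)
    S, pi_hat, copies = _pooled_stats(g, idx, sidx)
    if S == 0:
        return NeutralityResult(
            group=label, n_samples=len(idx), n_haplotypes=2 * len(idx),
            S=0, pi_hat=0.0, theta_w=0.0, D=None,
        )
    vals, freqs = np.unique(copies.astype(int), return_counts=True)
    n_hap = int(vals[np.argmax(freqs)])  # mode of per-site copy counts
    heterogeneous = len(vals) > 1
    k = tajima_constants(n_hap)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = float((pi_hat - theta_w) / np.sqrt(var))
    return NeutralityResult(
        group=label, n_samples=len(idx), n_haplotypes=n_hap,
        S=S, pi_hat=pi_hat, theta_w=float(theta_w), D=D,
        heterogeneous_n=heterogeneous,
    )


def jackknife_ci(
    g: GenotypeMatrix,
    group: list[str] | None = None,
    site_idx: np.ndarray | None = None,
    alpha: float = 0.05,
    method: str = "normal",
    label: str = "all",
) -> NeutralityResult:
    """Delete-one-individual jackknife CI around Tajima's D.

    Each replicate removes one individual from the group and recomputes
    D over the same site set.  The default CI is the normal-theory one,
    jackknife mean +/- z * SE_jack with
    SE_jack = sqrt((n-1)/n * sum (D_i - D_bar)^2); ``method="percentile"``
    uses the replicate 2.5/97.5 percentiles instead.  Replicates with no
    segregating site are dropped and counted; the CI is flagged when
    more than 10% drop.
    """
    names = list(g.sample_ids) if group is None else list(group)
    if len(names) < 3:
        raise ValueError("jackknife needs at least 3 individuals")
    full = tajimas_d(g, group=names, site_idx=site_idx, label=label)
    reps = []
    dropped = 0
    for i in range(len(names)):
        sub = names[:i] + names[i + 1 :]
        r = tajimas_d(g, group=sub, site_idx=site_idx, label=label)
        if r.D is None:
            dropped += 1
        else:
            reps.append(r.D)
    reps_arr = np.array(reps)
    n = len(reps_arr)
    if n < 2:
        raise ValueError("fewer than 2 defined jackknife replicates")
    mean = float(reps_arr.mean())
    if method == "normal":
        se = float(np.sqrt((n - 1) / n * np.sum((reps_arr - mean) ** 2)))
        z = norm.ppf(1 - alpha / 2)
        lo, hi = mean - z * se, mean + z * se
    elif method == "percentile":
        lo = float(np.quantile(reps_arr, alpha / 2))
        hi = float(np.quantile(reps_arr, 1 - alpha / 2))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    full.jackknife_mean = mean
    full.ci_low = float(lo)
    full.ci_high = float(hi)
    full.replicates = reps_arr
    full.n_dropped_replicates = dropped
    full.ci_flagged = dropped > 0.10 * len(names)
    return full
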