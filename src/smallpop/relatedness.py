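"""Relatedness screening and population-structure summaries.

Kinship uses the KING-robust between-family estimator, which stays
unbiased under population structure because it conditions on the pair's
own heterozygosity rather than on cohort allele frequencies.  Structure
is summarised by 1-IBS distances (with a neighbor-joining tree) and by
PCA of scaled genotype dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "KINSHIP_BANDS",
    "kinship_category",
    "king_kinship",
    "ibs_distance",
    "nj_tree",
    "pca",
]

# Lower kinship bound per relationship category (KING convention:
# cutoffs at 1/2^(k+3/2) for degree k).
KINSHIP_BANDS = (
    ("monozygotic", 0.354),
    ("first", 0.177),
    ("second", 0.0884),
    ("third", 0.0442),
)


def kinship_category(phi: float) -> str:
    for name, lo in KINSHIP_BANDS:
        if phi > lo:
            return name
    return "unrelated"


def king_kinship(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise KING-robust kinship coefficients.

    phi_ij = (N_het,het - 2 * N_opposite_hom) / (N_het_i + N_het_j),
    counted over sites called in both individuals.  A pair with no
    informative site (both heterozygosity counts zero) is flagged with
    NaN.  Category labels follow the standard degree bands.
    """
    if g.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    d = g.dosage()  # sites x samples, NaN missing
    n = g.n_samples
    rows = []
    for i in range(n):
        di = d[:, i]
        for j in range(i + 1, n):
            dj = d[:, j]
            ok = ~np.isnan(di) & ~np.isnan(dj)
            het_i = int(np.sum(di[ok] == 1))
            het_j = int(np.sum(dj[ok] == 1))
            het_het = int(np.sum((di[ok] == 1) & (dj[ok] == 1)))
            opp_hom = int(np.sum(np.abs(di[ok] - dj[ok]) == 2))
            denom = het_i + het_j
            if denom == 0:
                phi, cat = np.nan, "undefined"
            else:
                phi = (het_het - 2.0 * opp_hom) / denom
                cat = kinship_category(phi)
            rows.append(
                (g.sample_ids[i], g.sample_ids[j], phi, cat,
                 int(ok.sum()), het_het, opp_hom)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample1", "sample2", "phi", "category", "n_sites",
            "n_het_het", "n_opp_hom",
        ],
    )


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS distance matrix (PLINK per-site share in {0, 1/2, 1}).

    Share at a site is 1 for identical genotypes, 1/2 when they share
    exactly one allele (|dosage difference| == 1), 0 for opposite
    homozygotes.  Distance is 1 minus the mean share over co-called
    sites; a pair with no co-called site gets NaN.
    """
    if g.n_samples < 2:
        raise ValueError("distance needs at least 2 samples")
    d = g.dosage()
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            share = 1.0 - np.abs(d[ok, i] - d[ok, j]) / 2.0
            out[i, j] = out[j, i] = 1.0 - share.mean()
    return pd.DataFrame(out, index=g.sample_ids, columns=g.sample_ids)


# ----------------------------------------------------------------------
# Neighbor joining
# ----------------------------------------------------------------------
def nj_tree(dist: pd.DataFrame) -> str:
    """Canonical neighbor-joining tree from a distance matrix.

    Returns the unrooted tree as a Newick string (trifurcating root).
    Q-matrix ties break to the lowest-index pair so the output is
    deterministic.  Negative branch lengths, which NJ can legitimately
    produce on non-additive matrices, are retained.
    """
    if dist.isna().any().any():
        raise ValueError("distance matrix has missing entries")
    labels = [str(x) for x in dist.index]
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = dist.to_numpy().astype(float).copy()
    nodes = list(labels)  # newick fragment per active node

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: flatten scan order is row-major
        k = int(np.argmin(Q))
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        new_frag = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(new_frag)
        new_idx = D.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [new_idx]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return (
        f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    )


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
@dataclass
class PCAResult:
    coords: pd.DataFrame  # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(
    g: GenotypeMatrix,
    n_components: int = 2,
    scaling: str = "patterson",
) -> PCAResult:
    """PCA of genotype dosages.

    ``scaling="patterson"`` centers each site by 2*p-hat and divides by
    sqrt(2*p-hat*(1-p-hat)), the drift-variance normalization;
    ``scaling="center"`` only centers (PLINK-like covariance PCA).
    Missing calls are imputed to the site mean (zero after centering).
    Sign convention: each component's largest-magnitude coordinate is
    made positive, so results are deterministic.
    """
    if n_components > min(g.n_samples, g.n_variants):
        raise ValueError("more components than min(samples, sites)")
    d = g.dosage()  # sites x samples
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=1) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    d = d[poly]
    p = p[poly]
    x = d - 2 * p[:, None]
    if scaling == "patterson":
        x /= np.sqrt(2 * p * (1 - p))[:, None]
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")
    x = np.nan_to_num(x, nan=0.0)
    # samples are observations: SVD of (samples x sites)
    xt = x.T / np.sqrt(max(x.shape[0] - 1, 1))
    u, s, _ = np.linalg.svd(xt, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    for k in range(coords.shape[1]):
        imax = int(np.argmax(np.abs(coords[:, k])))
        if coords[imax, k] < 0:
            coords[:, k] = -coords[:, k]
    var = s**2
    return PCAResult(
        coords=pd.DataFrame(
            coords,
            index=g.sample_ids,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        explained_variance=var[:n_components],
        explained_variance_ratio=var[:n_components] / var.sum(),
    )
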