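"""Variant input/output, site and individual filtering, LD pruning and
region stratification.

The filtering protocol mirrors common practice for conservation-genomic
cohorts genotyped from whole-genome resequencing: keep biallelic SNPs
within a site-depth band, drop sites failing a deep-tail Hardy-Weinberg
exact test, mask low-GQ calls, then remove high-missingness sites and
individuals.  All interval arithmetic is 0-based half-open internally;
VCF positions stay 1-based.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "FilterConfig",
    "RegionAnnotation",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "filter_sites",
    "filter_individuals",
    "apply_filters",
    "hwe_exact_test",
    "ld_prune",
    "stratify",
]


# ----------------------------------------------------------------------
# VCF reading / writing
# ----------------------------------------------------------------------
def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes, phase and missingness are preserved losslessly; per-call
    DP and GQ are loaded when present in FORMAT.  Multi-allelic records
    are kept (flagged through ``is_biallelic``).  Raises ``ValueError``
    for files without GT or with unsorted records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, gts, phases, dps, gqs = (
        [], [], [], [], [], [], [], [],
    )
    has_dp = has_gq = False
    for v in vcf:
        g = v.genotypes  # list of [a0, a1, phased] per sample
        if g is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks GT")
        arr = np.array(g, dtype=np.int16)
        if arr.shape[1] == 2:  # haploid call: treat as missing second allele
            arr = np.column_stack([arr[:, 0], arr[:, 0], arr[:, 1]])
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(tuple(v.ALT))
        gts.append(arr[:, :2].astype(np.int8))
        phases.append(arr[:, 2].astype(bool))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_dp = True
            dps.append(np.where(dp < 0, -1, dp).reshape(-1).astype(np.int32))
        else:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            has_gq = True
            gqs.append(np.where(gq < 0, -1, gq).reshape(-1).astype(np.int32))
        else:
            gqs.append(np.full(len(samples), -1, dtype=np.int32))
    if not poss:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=np.stack(gts),
        phased=np.stack(phases),
        depth=np.stack(dps) if has_dp else None,
        gq=np.stack(gqs) if has_gq else None,
    )


def write_vcf(
    g: GenotypeMatrix,
    path: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a VCFv4.2 text file with contig headers and GT (+DP/GQ)."""
    if contig_lengths is None:
        contig_lengths = {}
        for c in dict.fromkeys(g.chrom.tolist()):
            contig_lengths[c] = int(g.pos[g.chrom == c].max())
    fmt_keys = ["GT"]
    if g.depth is not None:
        fmt_keys.append("DP")
    if g.gq is not None:
        fmt_keys.append("GQ")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=smallpop\n")
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if g.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for i in range(g.n_variants):
            alt = ",".join(g.alt[i]) if g.alt[i] else "."
            cols = [
                str(g.chrom[i]),
                str(g.pos[i]),
                ".",
                str(g.ref[i]),
                alt,
                ".",
                "PASS",
                ".",
                ":".join(fmt_keys),
            ]
            for j in range(g.n_samples):
                a0, a1 = g.gt[i, j]
                sep = "|" if g.phased[i, j] else "/"
                gt = (
                    "." + sep + "."
                    if a0 < 0 or a1 < 0
                    else f"{a0}{sep}{a1}"
                )
                parts = [gt]
                if g.depth is not None:
                    d = g.depth[i, j]
                    parts.append("." if d < 0 else str(d))
                if g.gq is not None:
                    q = g.gq[i, j]
                    parts.append("." if q < 0 else str(q))
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")


def read_popmap(path: str) -> dict[str, str]:
    """Read a two-column sample-to-population TSV (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample", "population"], dtype=str
    )
    return dict(zip(df["sample"], df["population"]))


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------
@dataclass
class FilterConfig:
    """Site and individual retention thresholds.

    Defaults follow a stringent resequencing protocol: biallelic SNPs
    with site depth in [5, 600], MAF above ``maf_min``, HWE exact-test p
    at or above 1e-50, per-call GQ > 30 (failing calls masked to missing
    before the missingness test), at most 10% missing genotypes per site
    and 30% per individual.  ``maf_min`` defaults to the site-discovery
    floor 1e-7; use 0.05 for structure/diversity analyses.
    """

    biallelic_only: bool = True
    depth_min: int = 5
    depth_max: int = 600
    maf_min: float = 1e-7
    hwe_p_floor: float = 1e-50
    gq_min: int = 30
    site_missing_max: float = 0.10
    individual_missing_max: float = 0.30

    def __post_init__(self) -> None:
        if not (0 <= self.site_missing_max <= 1):
            raise ValueError("site_missing_max must be in [0,1]")
        if not (0 <= self.individual_missing_max <= 1):
            raise ValueError("individual_missing_max must be in [0,1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min > depth_max")


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic site.

    Conditional on allele counts, sums the probabilities of all genotype
    configurations no more probable than the observed one (two-sided,
    mid-p off).  Accurate deep into the tail, which a chi-squared
    approximation is not; p-value floors of 1e-50 live there.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # unnormalized probabilities over possible het counts (same parity as rare)
    het_probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence
    curr = mid
    while curr > 1:
        h = curr
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        het_probs[h - 2] = (
            het_probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        )
        curr -= 2
    curr = mid
    while curr <= rare - 2:
        h = curr
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        het_probs[h + 2] = (
            het_probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        )
        curr += 2
    total = het_probs.sum()
    obs_p = het_probs[n_het]
    return float(min(1.0, het_probs[het_probs <= obs_p + 1e-12 * obs_p].sum() / total))


def _site_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency over called copies (any-alt pooled)."""
    d = g.dosage()
    called = 2 * np.sum(~np.isnan(d), axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=1) / called
    p = np.where(called == 0, np.nan, p)
    return np.fmin(p, 1 - p)


def filter_sites(
    g: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply site-level filters; returns the retained matrix and a log.

    Order: biallelic -> site depth band -> per-call GQ masking ->
    MAF -> HWE exact test -> site missingness.  The log records the
    number of sites surviving after each criterion.
    """
    log: list[tuple[str, int]] = [("input", g.n_variants)]
    if cfg.biallelic_only:
        g = g.take_variants(g.is_biallelic)
    log.append(("biallelic", g.n_variants))

    if g.depth is not None:
        dp = np.where(g.depth < 0, 0, g.depth)
        site_dp = dp.sum(axis=1)
        g = g.take_variants(
            (site_dp >= cfg.depth_min) & (site_dp <= cfg.depth_max)
        )
    log.append(("depth", g.n_variants))

    if g.gq is not None:
        g = g.copy()
        fail = (g.gq >= 0) & (g.gq < cfg.gq_min)
        g.gt[fail] = -1
    log.append(("gq_masked", g.n_variants))

    maf = _site_maf(g)
    with np.errstate(invalid="ignore"):
        keep = np.where(np.isnan(maf), False, maf > cfg.maf_min)
    g = g.take_variants(keep)
    log.append(("maf", g.n_variants))

    if cfg.hwe_p_floor > 0:
        het = g.is_het.sum(axis=1)
        miss = g.is_missing
        hom_alt = ((g.gt[:, :, 0] > 0) & (g.gt[:, :, 1] > 0) & ~miss).sum(axis=1)
        hom_ref = ((g.gt[:, :, 0] == 0) & (g.gt[:, :, 1] == 0) & ~miss).sum(axis=1)
        pvals = np.array(
            [hwe_exact_test(h, a, r) for h, a, r in zip(het, hom_alt, hom_ref)]
        )
        g = g.take_variants(pvals >= cfg.hwe_p_floor)
    log.append(("hwe", g.n_variants))

    miss_frac = g.is_missing.mean(axis=1)
    g = g.take_variants(miss_frac <= cfg.site_missing_max)
    log.append(("site_missing", g.n_variants))

    return g, pd.DataFrame(log, columns=["criterion", "sites_remaining"])


def filter_individuals(
    g: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove individuals with missing fraction strictly above the cap."""
    miss = g.is_missing.mean(axis=0)
    keep = miss <= cfg.individual_missing_max
    if not keep.any():
        raise ValueError("all individuals removed by missingness filter")
    log = pd.DataFrame(
        {
            "sample": g.sample_ids,
            "missing_fraction": miss,
            "retained": keep,
        }
    )
    return g.take_samples(keep), log


def apply_filters(
    g: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Full protocol: sites -> individuals -> one site re-pass."""
    g, log1 = filter_sites(g, cfg)
    g, _ = filter_individuals(g, cfg)
    log1.loc[len(log1)] = ("individuals", g.n_variants)
    # site missingness can change after individual removal
    miss_frac = g.is_missing.mean(axis=1)
    g = g.take_variants(miss_frac <= cfg.site_missing_max)
    log1.loc[len(log1)] = ("site_repass", g.n_variants)
    return g, log1


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------
def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage rows.

    Missing calls (NaN) are handled by pairwise-complete observations.
    """
    m = dos.shape[0]
    if not np.isnan(dos).any():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(dos)
        return np.nan_to_num(r, nan=0.0) ** 2
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            if ok.sum() < 2:
                continue
            x, y = dos[i, ok], dos[j, ok]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
    seed: int = 0,
) -> GenotypeMatrix:
    """Sliding-window LD pruning, removing one random SNP per linked pair.

    Windows of ``window_snps`` sites advance by ``step_snps``; within a
    window every retained pair with genotype-dosage r^2 above ``r2_max``
    loses one member, chosen uniformly at random.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    dos = g.dosage()
    n = g.n_variants
    keep = np.ones(n, dtype=bool)
    # windows never span chromosomes
    chrom_starts: list[tuple[int, int]] = []
    start = 0
    for c in dict.fromkeys(g.chrom.tolist()):
        cnt = int((g.chrom == c).sum())
        chrom_starts.append((start, start + cnt))
        start += cnt
    for lo, hi in chrom_starts:
        w0 = lo
        while True:
            w1 = min(w0 + window_snps, hi)
            idx = np.nonzero(keep[w0:w1])[0] + w0
            if len(idx) > 1:
                r2 = _r2_matrix(dos[idx])
                for a in range(len(idx)):
                    for b in range(a + 1, len(idx)):
                        ia, ib = idx[a], idx[b]
                        if keep[ia] and keep[ib] and r2[a, b] > r2_max:
                            drop = ia if rng.random() < 0.5 else ib
                            keep[drop] = False
            if w1 >= hi:
                break
            w0 += step_snps
    return g.take_variants(keep)


# ----------------------------------------------------------------------
# Region annotation and stratification
# ----------------------------------------------------------------------
@dataclass
class RegionAnnotation:
    """Genomic intervals labelling CDS and the MHC subset of CDS.

    ``intervals`` is a DataFrame with columns chrom, start, end, cls
    (0-based half-open; cls in {"CDS", "MHC_CDS"}).  MHC_CDS intervals
    are also CDS by construction.
    """

    intervals: pd.DataFrame
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "cls"}
        if not req.issubset(self.intervals.columns):
            raise ValueError(f"intervals must have columns {req}")
        bad = set(self.intervals["cls"]) - {"CDS", "MHC_CDS"}
        if bad:
            raise ValueError(f"unknown interval classes: {bad}")
        self.intervals = self.intervals.sort_values(
            ["chrom", "start", "end"]
        ).reset_index(drop=True)

    @classmethod
    def from_bed(
        cls,
        cds_bed: str,
        mhc_bed: str | None = None,
        contig_lengths: dict[str, int] | None = None,
    ) -> "RegionAnnotation":
        """Build from BED files (0-based half-open, as BED natively is)."""
        frames = []
        cds = pd.read_csv(
            cds_bed, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        cds["cls"] = "CDS"
        frames.append(cds)
        if mhc_bed is not None:
            mhc = pd.read_csv(
                mhc_bed, sep="\t", header=None, comment="#",
                usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
            )
            mhc["cls"] = "MHC_CDS"
            frames.append(mhc)
        return cls(pd.concat(frames, ignore_index=True), contig_lengths or {})

    @classmethod
    def from_gff3(
        cls,
        path: str,
        mhc_genes: set[str] | None = None,
        contig_lengths: dict[str, int] | None = None,
    ) -> "RegionAnnotation":
        """Build from GFF3 CDS features (1-based closed -> half-open).

        ``mhc_genes`` names (matched against Parent/gene attributes) mark
        the MHC subset.
        """
        rows = []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "rt") as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "CDS":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene = attrs.get("gene", attrs.get("Parent", attrs.get("ID", "")))
                start0, end = int(f[3]) - 1, int(f[4])
                rows.append((f[0], start0, end, "CDS"))
                if mhc_genes and gene in mhc_genes:
                    rows.append((f[0], start0, end, "MHC_CDS"))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])
        return cls(df, contig_lengths or {})

    def merged(self, cls_name: str, flank_bp: int = 0) -> dict[str, np.ndarray]:
        """Merged, flank-extended intervals per chromosome.

        Returns {chrom: array of shape (k, 2)} of half-open intervals,
        flanks truncated at [0, contig_length).
        """
        sel = self.intervals[self.intervals["cls"] == cls_name]
        out: dict[str, np.ndarray] = {}
        for c, sub in sel.groupby("chrom"):
            s = np.maximum(sub["start"].to_numpy() - flank_bp, 0)
            e = sub["end"].to_numpy() + flank_bp
            if c in self.contig_lengths:
                e = np.minimum(e, self.contig_lengths[c])
            order = np.argsort(s)
            s, e = s[order], e[order]
            merged: list[list[int]] = []
            for a, b in zip(s, e):
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([int(a), int(b)])
            out[str(c)] = np.array(merged, dtype=np.int64).reshape(-1, 2)
        return out

    def contains(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        cls_name: str,
        flank_bp: int = 0,
    ) -> np.ndarray:
        """Bool mask: 1-based positions falling inside class intervals."""
        iv = self.merged(cls_name, flank_bp)
        p0 = np.asarray(pos) - 1  # to 0-based
        mask = np.zeros(len(p0), dtype=bool)
        for c, arr in iv.items():
            on = np.asarray(chrom) == c
            if not on.any() or arr.size == 0:
                continue
            starts, ends = arr[:, 0], arr[:, 1]
            k = np.searchsorted(starts, p0[on], side="right") - 1
            inside = (k >= 0) & (p0[on] < ends[np.clip(k, 0, len(ends) - 1)])
            mask[np.nonzero(on)[0][inside]] = True
        return mask


def stratify(
    g: GenotypeMatrix, ann: RegionAnnotation, flank_bp: int = 1000
) -> dict[str, np.ndarray]:
    """Partition variant indices into non-CDS / CDS / MHC-CDS site sets.

    The non-CDS set excludes CDS plus ``flank_bp`` on each side; the MHC
    set is the CDS of annotated MHC genes (a subset of CDS).
    """
    ann_chroms = set(ann.intervals["chrom"].astype(str))
    g_chroms = set(map(str, dict.fromkeys(g.chrom.tolist())))
    if not ann_chroms & g_chroms:
        raise ValueError(
            "no shared chromosome names between genotypes and annotation: "
            f"genotypes={sorted(g_chroms)} annotation={sorted(ann_chroms)}"
        )
    in_cds = ann.contains(g.chrom, g.pos, "CDS")
    in_cds_flank = ann.contains(g.chrom, g.pos, "CDS", flank_bp=flank_bp)
    in_mhc = ann.contains(g.chrom, g.pos, "MHC_CDS")
    return {
        "non_CDS": np.nonzero(~in_cds_flank)[0],
        "CDS": np.nonzero(in_cds)[0],
        "MHC_CDS": np.nonzero(in_mhc & in_cds)[0],
    }
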