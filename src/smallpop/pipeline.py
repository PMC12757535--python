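"""Config-driven orchestration of the full analysis flow.

One call runs: filtering -> kinship screen -> structure (IBS / NJ /
PCA) -> diversity summaries -> ROH / F_ROH -> region stratification ->
windowed pi and F_ST -> pooled MHC Tajima's D with jackknife CI ->
XP-EHH scan -> the comparison battery.  Every table is written as TSV
with a provenance header (config hash, root seed, package version);
randomness flows from one root seed through named per-stage substreams,
so toggling one stage never shifts another's draws.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .comparison import compare_many, compare_two, diversity_bias_binomial
from .diversity import (
    allelic_richness,
    per_site_pi,
    site_heterozygosity,
    windowed_fst,
    windowed_pi,
)
from .matrix import GenotypeMatrix
from .neutrality import jackknife_ci
from .relatedness import ibs_distance, king_kinship, nj_tree, pca
from .roh import (
    DEFAULT_THRESHOLDS_MB,
    ROHParams,
    compare_froh,
    detect_roh,
    f_roh,
    genome_covered_bp,
)
from .selection import XPEHHParams, xpehh_scan
from .simulate import SimulationScenario, simulate_cohort
from .variant_io import (
    FilterConfig,
    RegionAnnotation,
    apply_filters,
    ld_prune,
    read_popmap,
    read_vcf,
    stratify,
    write_vcf,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, parameters and stage toggles for one pipeline run.

    Either ``scenario`` (simulate a cohort) or ``vcf`` plus ``popmap``
    (analyse existing data) must be given.  ``stages`` toggles
    individual stages off; filtering always runs.
    """

    outdir: str = "smallpop_out"
    seed: int = 0
    scenario: SimulationScenario | None = None
    vcf: str | None = None
    popmap: str | None = None
    cds_bed: str | None = None
    mhc_bed: str | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    structure_maf: float = 0.05
    roh_params: ROHParams = field(default_factory=ROHParams)
    xpehh_params: XPEHHParams = field(default_factory=XPEHHParams)
    ld_window: int = 50
    ld_step: int = 10
    ld_r2_max: float = 0.2
    window_sites: int = 20
    step_sites: int = 5
    flank_bp: int = 1000
    froh_thresholds: tuple = DEFAULT_THRESHOLDS_MB
    stages: dict[str, bool] = field(default_factory=dict)

    def stage_on(self, name: str) -> bool:
        return self.stages.get(name, True)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        d = asdict(self)
        d.pop("outdir", None)  # results, not their location
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write(df: pd.DataFrame, path: str, cfg: PipelineConfig,
           extra: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# smallpop {__version__}\n")
        fh.write(f"# config_hash {cfg.config_hash()}\n")
        fh.write(f"# seed {cfg.seed}\n")
        for k, v in (extra or {}).items():
            fh.write(f"# {k} {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def _results_to_df(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "statistic": r.statistic_name,
                "groups": "|".join(r.groups),
                "test": r.test,
                "raw_p": r.raw_p,
                "adjusted_p": r.adjusted_p,
                "adjustment": r.adjustment,
                "degenerate": r.degenerate,
                "note": r.note,
                **{f"median_{k}": v for k, v in r.medians.items()},
                **{f"n_{k}": v for k, v in r.n.items()},
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns a dict of in-memory results.

    On stage failure, partial outputs stay on disk and
    ``status.json`` records the failed stage and the error message
    before the exception propagates.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    status = {"completed": [], "failed": None, "config_hash":
              cfg.config_hash(), "seed": cfg.seed}
    out: dict = {}

    def mark(stage: str) -> None:
        status["completed"].append(stage)
        with open(os.path.join(cfg.outdir, "status.json"), "w") as fh:
            json.dump(status, fh, indent=2)

    try:
        _run_stages(cfg, out, mark)
    except Exception as exc:  # preserve partial outputs + status
        status["failed"] = {
            "stage": (out.get("_current_stage") or "unknown"),
            "error": str(exc),
        }
        with open(os.path.join(cfg.outdir, "status.json"), "w") as fh:
            json.dump(status, fh, indent=2)
        raise
    return out


def _run_stages(cfg: PipelineConfig, out: dict, mark) -> None:
    o = cfg.outdir

    # ------------------------------------------------------ input
    out["_current_stage"] = "input"
    if cfg.scenario is not None:
        scn = cfg.scenario
        g, ann, truth = simulate_cohort(scn)
        pops: dict[str, list[str]] = {}
        for s in g.sample_ids:
            pops.setdefault(s.split("_")[0], []).append(s)
        write_vcf(g, os.path.join(o, "cohort.vcf"),
                  {c: scn.chrom_length_bp
                   for c in dict.fromkeys(g.chrom.tolist())})
        truth.to_tsvs(o)
        out["truth"] = truth
    else:
        if cfg.vcf is None or cfg.popmap is None:
            raise ValueError("need either a scenario or vcf + popmap")
        g = read_vcf(cfg.vcf)
        pm = read_popmap(cfg.popmap)
        pops = {}
        for s in g.sample_ids:
            pops.setdefault(pm.get(s, "unknown"), []).append(s)
        ann = None
        if cfg.cds_bed is not None:
            ann = RegionAnnotation.from_bed(cfg.cds_bed, cfg.mhc_bed)
    if len(pops) != 2:
        raise ValueError(f"expected 2 populations, found {sorted(pops)}")
    (nameA, samplesA), (nameB, samplesB) = sorted(pops.items())
    out["genotypes_raw"] = g
    out["populations"] = {nameA: samplesA, nameB: samplesB}
    mark("input")

    # ------------------------------------------------------ filter
    out["_current_stage"] = "filter"
    g, flog = apply_filters(g, cfg.filter_cfg)
    pops = {k: [s for s in v if s in g.sample_ids]
            for k, v in out["populations"].items()}
    out["populations"] = pops
    samplesA, samplesB = pops[nameA], pops[nameB]
    _write(flog, os.path.join(o, "filter_log.tsv"), cfg)
    out["genotypes"] = g
    write_vcf(g, os.path.join(o, "filtered.vcf"))
    mark("filter")

    # ------------------------------------------------------ kinship
    if cfg.stage_on("kinship"):
        out["_current_stage"] = "kinship"
        kin = king_kinship(g)
        _write(kin, os.path.join(o, "kinship.tsv"), cfg)
        out["kinship"] = kin
        mark("kinship")

    # ------------------------------------------------------ structure
    if cfg.stage_on("structure"):
        out["_current_stage"] = "structure"
        # structure analyses use the common-variant, LD-pruned set
        from .variant_io import _site_maf

        common = g.take_variants(
            np.nan_to_num(_site_maf(g)) > cfg.structure_maf
        )
        pruned = ld_prune(
            common, cfg.ld_window, cfg.ld_step, cfg.ld_r2_max,
            seed=_stage_seed(cfg.seed, "ld_prune"),
        )
        out["genotypes_pruned"] = pruned
        dist = ibs_distance(pruned)
        _write(dist, os.path.join(o, "ibs_distance.tsv"), cfg, index=True)
        newick = nj_tree(dist)
        with open(os.path.join(o, "nj_tree.nwk"), "w") as fh:
            fh.write(newick + "\n")
        pc = pca(pruned, n_components=min(5, pruned.n_samples - 1))
        _write(pc.coords, os.path.join(o, "pca.tsv"), cfg,
               {"explained_variance_ratio":
                ",".join(f"{x:.4f}" for x in pc.explained_variance_ratio)},
               index=True)
        out["ibs"] = dist
        out["nj_newick"] = newick
        out["pca"] = pc
        mark("structure")

    # ------------------------------------------------------ diversity
    if cfg.stage_on("diversity"):
        out["_current_stage"] = "diversity"
        groups = {nameA: samplesA, nameB: samplesB,
                  "all": samplesA + samplesB}
        het = site_heterozygosity(g, groups)
        ar = allelic_richness(g, groups)
        rows = []
        for name in groups:
            h = het[name]
            a = ar[name]
            rows.append({
                "group": name, "n": len(groups[name]),
                "Ho_median": h.medians["Ho"],
                "Ho_lo": h.ci_low["Ho"], "Ho_hi": h.ci_high["Ho"],
                "He_median": h.medians["He"],
                "He_lo": h.ci_low["He"], "He_hi": h.ci_high["He"],
                "AR_median": a.medians["AR"],
                "AR_lo": a.ci_low["AR"], "AR_hi": a.ci_high["AR"],
            })
        tab = pd.DataFrame(rows)
        _write(tab, os.path.join(o, "diversity_summary.tsv"), cfg)
        out["diversity_summary"] = tab
        out["het"] = het
        ho_cmp = compare_two(
            het[nameA].values["Ho"].to_numpy(),
            het[nameB].values["Ho"].to_numpy(),
            names=(nameA, nameB), statistic_name="Ho",
        )
        out["ho_comparison"] = ho_cmp
        mark("diversity")

    # ------------------------------------------------------ roh
    if cfg.stage_on("roh"):
        out["_current_stage"] = "roh"
        segs = detect_roh(g, cfg.roh_params)
        _write(segs, os.path.join(o, "roh_segments.tsv"), cfg)
        gbp = genome_covered_bp(g)
        froh = f_roh(segs, gbp, cfg.froh_thresholds,
                     samples=list(g.sample_ids))
        _write(froh, os.path.join(o, "froh.tsv"), cfg,
               {"genome_covered_bp": gbp})
        cmp_froh = compare_froh(froh, {nameA: samplesA, nameB: samplesB})
        _write(cmp_froh, os.path.join(o, "froh_comparison.tsv"), cfg)
        out["roh_segments"] = segs
        out["froh"] = froh
        out["froh_comparison"] = cmp_froh
        mark("roh")

    # ------------------------------------------------------ stratify
    region_sets = None
    if ann is not None and cfg.stage_on("stratify"):
        out["_current_stage"] = "stratify"
        region_sets = stratify(g, ann, cfg.flank_bp)
        df = pd.DataFrame(
            [(k, len(v)) for k, v in region_sets.items()],
            columns=["region", "n_sites"],
        )
        _write(df, os.path.join(o, "region_counts.tsv"), cfg)
        out["region_sets"] = region_sets
        out["annotation"] = ann
        mark("stratify")

    # ------------------------------------------------------ windows
    if cfg.stage_on("windows"):
        out["_current_stage"] = "windows"
        sets = region_sets or {"all": np.arange(g.n_variants)}
        win_pi = {}
        win_fst = {}
        for region, sidx in sets.items():
            if len(sidx) == 0:
                continue
            pa = windowed_pi(g, samplesA, cfg.window_sites, cfg.step_sites,
                             site_idx=sidx)
            pb = windowed_pi(g, samplesB, cfg.window_sites, cfg.step_sites,
                             site_idx=sidx)
            fs = windowed_fst(g, {nameA: samplesA, nameB: samplesB},
                              cfg.window_sites, cfg.step_sites,
                              site_idx=sidx)
            merged = fs.copy()
            merged[f"pi_{nameA}"] = pa["pi"]
            merged[f"pi_{nameB}"] = pb["pi"]
            _write(merged, os.path.join(o, f"windows_{region}.tsv"), cfg,
                   {"region": region})
            win_pi[region] = (pa, pb)
            win_fst[region] = fs
        out["windowed_pi"] = win_pi
        out["windowed_fst"] = win_fst
        mark("windows")

    # ------------------------------------------------------ tajima
    if cfg.stage_on("tajima") and region_sets is not None:
        out["_current_stage"] = "tajima"
        mhc = region_sets["MHC_CDS"]
        rows = []
        taj = {}
        for name, samples in ((nameA, samplesA), (nameB, samplesB)):
            if len(mhc) == 0 or len(samples) < 3:
                continue
            r = jackknife_ci(g, samples, site_idx=mhc, label=name)
            taj[name] = r
            rows.append({
                "group": name, "n_samples": r.n_samples, "S": r.S,
                "pi_hat": r.pi_hat, "theta_w": r.theta_w, "D": r.D,
                "jackknife_mean": r.jackknife_mean,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "n_dropped": r.n_dropped_replicates,
            })
        if rows:
            _write(pd.DataFrame(rows), os.path.join(o, "tajima_mhc.tsv"),
                   cfg)
        out["tajima_mhc"] = taj
        mark("tajima")

    # ------------------------------------------------------ xpehh
    if cfg.stage_on("xpehh"):
        out["_current_stage"] = "xpehh"
        scores = xpehh_scan(g, samplesA, samplesB, cfg.xpehh_params)
        _write(scores, os.path.join(o, "xpehh.tsv"), cfg,
               {"popA": nameA, "popB": nameB,
                "threshold_low": scores.attrs.get("threshold_low"),
                "threshold_high": scores.attrs.get("threshold_high")})
        out["xpehh"] = scores
        mark("xpehh")

    # ------------------------------------------------------ comparisons
    if cfg.stage_on("compare") and out.get("windowed_pi"):
        out["_current_stage"] = "compare"
        results = []
        win_pi = out["windowed_pi"]
        for region, (pa, pb) in win_pi.items():
            if len(pa) and len(pb):
                results.append(
                    compare_two(pa["pi"].to_numpy(), pb["pi"].to_numpy(),
                                names=(nameA, nameB),
                                statistic_name=f"pi_{region}")
                )
        fst_groups = {
            region: fs["fst"].dropna().to_numpy()
            for region, fs in out.get("windowed_fst", {}).items()
            if len(fs)
        }
        if len(fst_groups) >= 3:
            results.extend(compare_many(fst_groups))
        # per-MHC-gene diversity bias
        if ann is not None and "name" in ann.intervals.columns:
            mhc_genes = ann.intervals[ann.intervals["cls"] == "MHC_CDS"]
            diffs = []
            pi_a = per_site_pi(g, g.sample_index(samplesA))
            pi_b = per_site_pi(g, g.sample_index(samplesB))
            for _, row in mhc_genes.iterrows():
                on = (
                    (g.chrom == row["chrom"])
                    & (g.pos >= row["start"] + 1)
                    & (g.pos <= row["end"])
                )
                if not on.any():
                    continue
                diffs.append(np.nanmean(pi_a[on]) - np.nanmean(pi_b[on]))
            if diffs and any(d != 0 for d in diffs):
                results.append(diversity_bias_binomial(diffs))
        df = _results_to_df(results)
        _write(df, os.path.join(o, "comparisons.tsv"), cfg)
        out["comparisons"] = results
        mark("compare")

    out.pop("_current_stage", None)
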