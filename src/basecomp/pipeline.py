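"""End-to-end orchestration: extraction -> binning -> ancestral inference ->
substitution and SFS statistics -> selection-model fits -> report tables.

Every run resolves its configuration up front, funnels all randomness
through per-stage seeds derived from one base seed, writes each stage's
output as TSV/JSON under the run directory, and records a manifest with
checksums so that reruns with the same configuration are bit-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from basecomp import ancestry, extraction, sfs as sfs_mod, substitution
from basecomp.containers import SpectrumSet
from basecomp.glemin import fit_glemin, glemin_model_selection
from basecomp.zc import FrequencyGrid, fit_zc, zc_model_tests

__all__ = ["PipelineConfig", "run_pipeline", "report"]

log = logging.getLogger("basecomp.pipeline")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    genomes: dict = field(default_factory=dict)       # name -> FASTA path
    annotation: str = ""
    samples: dict = field(default_factory=dict)       # name -> FASTA path
    reference_names: tuple = ("mel", "sim", "yak")
    n_auto_bins: int = 20
    n_x_bins: int = 4
    n_si_bins: int = 1
    method: str = "AWP"                               # parsimony | SBR | AWP
    lineages: tuple = ("mel", "sim")
    min_gene_sites: int = 10
    min_bin_sites: int = 1000
    gtr_restarts: int = 3
    fit_glemin: bool = False
    fit_zc: bool = False
    glemin_variants: tuple = ("M0", "M1")
    zc_variants: tuple = ("ZC0", "ZC1")
    estimator_restarts: int = 5
    zc_grid: int = 100
    seed: int = 0
    out_dir: str = "run"

    def validate(self) -> None:
        if self.n_auto_bins < 1 or self.n_x_bins < 0:
            raise ValueError("bin counts must be positive")
        if self.method not in ("parsimony", "SBR", "AWP"):
            raise ValueError(f"unknown reconstruction method {self.method!r}")
        for name in self.reference_names:
            if name not in self.genomes:
                raise ValueError(f"no genome path for reference {name!r}")
        if not self.samples:
            raise ValueError("no sample sequences configured")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _posterior_for(method: str, counts, fit_cache: dict, cfg: PipelineConfig,
                   seed: int):
    if method == "parsimony":
        return ancestry.parsimony_ancestor(), None, None
    key = id(counts)
    if key not in fit_cache:
        st = ancestry.fit_stationary_gtr(counts, restarts=cfg.gtr_restarts,
                                         seed=seed, min_sites=cfg.min_bin_sites)
        nh = ancestry.fit_nh_gtr(counts, restarts=cfg.gtr_restarts, seed=seed,
                                 min_sites=cfg.min_bin_sites, stationary_fit=st)
        fit_cache[key] = (st, nh)
    st, nh = fit_cache[key]
    return ancestry.ancestral_posteriors(nh, method=method), st, nh


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {name: int(rng.integers(2**31))
                   for name in ("gtr", "glemin", "zc")}
    (out / "config.json").write_text(json.dumps(
        {**asdict(cfg), "stage_seeds": stage_seeds}, indent=1, default=str))

    bundle = _stage("load")(extraction.load_bundle)(
        cfg.genomes, cfg.annotation, cfg.samples, cfg.reference_names)

    table4 = _stage("extract-4fold")(extraction.extract_fourfold_sites)(
        bundle, min_sites=cfg.min_gene_sites)
    table_si = _stage("extract-si")(extraction.extract_si_sites)(bundle)
    sites = pd.concat([table4, table_si], ignore_index=True)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)

    bins = []
    if not table4.empty:
        bins += _stage("bin-4fold")(extraction.assign_gc_bins)(
            table4, n_auto=cfg.n_auto_bins, n_x=cfg.n_x_bins)
    if not table_si.empty:
        si_bins = _stage("bin-si")(extraction.assign_gc_bins)(
            table_si, n_auto=cfg.n_si_bins, n_x=min(cfg.n_si_bins, 1))
        for b in si_bins:
            b.bin_id = "SI" + b.bin_id
        bins += si_bins
    bin_rows = [{"bin_id": b.bin_id, "chromosome_set": b.chromosome_set,
                 "gc": b.gc_content, "genes": ",".join(b.gene_ids)}
                for b in bins]
    pd.DataFrame(bin_rows).to_csv(out / "bins.tsv", sep="\t", index=False)

    fit_cache: dict = {}
    subst_rows, report_rows = [], []
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for b in bins:
        site_class = "SI" if b.bin_id.startswith("SI") else "4fold"
        sub = sites[(sites["gene_id"].isin(set(b.gene_ids)))
                    & (sites["site_class"] == site_class)]
        if sub.empty:
            continue
        counts = ancestry.TripletPatternCounts.from_site_bases(
            "".join(sub["ref_focal"]), "".join(sub["ref_second"]),
            "".join(sub["ref_outgroup"]))
        try:
            post, st, nh = _posterior_for(cfg.method, counts, fit_cache, cfg,
                                          stage_seeds["gtr"])
        except ValueError as exc:
            log.warning("bin %s: reconstruction skipped (%s)", b.bin_id, exc)
            continue
        row = {"bin_id": b.bin_id, "chromosome_set": b.chromosome_set,
               "gc": b.gc_content, "n_sites": counts.total}
        if nh is not None:
            chi2, df, p = ancestry.lrt_nonstationarity(nh, st)
            row.update({"lrt_chi2": chi2, "lrt_df": df, "lrt_p": p})
        for lineage in cfg.lineages:
            sc = substitution.count_substitutions_patterns(post, counts, lineage)
            rws, rsw = substitution.substitution_rates(sc)
            subst_rows.append({
                "bin_id": b.bin_id, "lineage": lineage, "method": cfg.method,
                "nws": sc.nws, "nsw": sc.nsw, "nneu": sc.nneu,
                "lw": sc.lw, "ls": sc.ls, "rws": rws, "rsw": rsw,
                "ratio": sc.ratio,
            })
            if lineage == cfg.lineages[0]:
                row.update({"nws": sc.nws, "nsw": sc.nsw, "rws": rws,
                            "rsw": rsw, "ratio": sc.ratio})

        spectra = sfs_mod.build_spectra(sub, post)
        spec = spectra["all"]
        spec.to_tsv(spectra_dir / f"{b.bin_id}.tsv")
        for cat in ("WS", "SW", "neu"):
            try:
                row[f"daf_{cat}"] = sfs_mod.mean_daf(spec, cat)
            except ValueError:
                row[f"daf_{cat}"] = np.nan
        taj = sfs_mod.tajima_d_per_gene(sub)["tajima_d"].dropna()
        dpi = sfs_mod.delta_pi_per_gene(sub)["delta_pi"].dropna()
        row["tajima_d"] = float(taj.mean()) if len(taj) else np.nan
        row["delta_pi"] = float(dpi.mean()) if len(dpi) else np.nan

        if cfg.fit_glemin and spec.total_segregating() > 0:
            fits = {v: fit_glemin(spec, v, restarts=cfg.estimator_restarts,
                                  seed=stage_seeds["glemin"])
                    for v in cfg.glemin_variants}
            sel = glemin_model_selection(fits)
            row["gamma_glemin"] = fits.get("M1", fits.get("M1*")).params["gamma"] \
                if ("M1" in fits or "M1*" in fits) else np.nan
            (out / f"glemin_{b.bin_id}.json").write_text(json.dumps(
                {v: f.to_dict() for v, f in fits.items()} | {"selection": sel},
                indent=1, default=float))
        if cfg.fit_zc and spec.s_allele_counts().sum() > 0:
            grid = FrequencyGrid(cfg.zc_grid)
            fits = {v: fit_zc(spec, v, restarts=cfg.estimator_restarts,
                              seed=stage_seeds["zc"], grid=grid)
                    for v in cfg.zc_variants}
            tests = zc_model_tests(fits)
            if "ZC1" in fits:
                row["gamma_zc"] = fits["ZC1"].params["gamma"]
            (out / f"zc_{b.bin_id}.json").write_text(json.dumps(
                {v: f.to_dict() for v, f in fits.items()} | {"tests": tests},
                indent=1, default=float))
        report_rows.append(row)

    pd.DataFrame(subst_rows).to_csv(out / "substitutions.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(report_rows).to_csv(out / "per_bin.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "files": {p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report(run_dir: str | Path) -> dict:
    """Summary tables regenerated from stored stage outputs.

    Correlations (Kendall's tau of GC content against each per-bin column)
    use autosomal 4-fold bins only; SI bins and the X are excluded, the
    latter flagged underpowered when it has too few bins for a meaningful
    test (with four points the smallest achievable p is 0.08).
    """
    run_dir = Path(run_dir)
    per_bin = pd.read_csv(run_dir / "per_bin.tsv", sep="\t")
    out = {"per_bin": per_bin}
    mask = ((per_bin["chromosome_set"] == "autosomal")
            & ~per_bin["bin_id"].astype(str).str.startswith("SI"))
    auto = per_bin[mask]
    correlations = {}
    for col in ("rws", "rsw", "ratio", "daf_WS", "daf_SW", "daf_neu",
                "delta_pi", "tajima_d", "gamma_glemin", "gamma_zc"):
        if col in auto.columns and auto[col].notna().sum() >= 3:
            tau, p = sp_stats.kendalltau(auto["gc"], auto[col])
            correlations[col] = {"tau": float(tau), "p": float(p),
                                 "n_bins": int(auto[col].notna().sum())}
    out["correlations"] = correlations
    x_bins = per_bin[per_bin["chromosome_set"] == "X"]
    out["x_flag"] = ("underpowered: too few X bins for correlation tests"
                     if 0 < len(x_bins) <= 4 else "")
    return out
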