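"""End-to-end study pipeline with a reproducibility manifest.

Stages run in the study order — (simulate|load) -> filter -> admixture /
K selection -> PCA + cluster-count -> pairwise Fst -> linkage-block
sub-workflow (exclude one region, re-run PCA, detect the block, classify
individuals, contrast PCA with the block removed).  Every stage writes its
artifacts under one output root and records input/output checksums, its
derived seed and wall time in ``manifest.json``.  A stage whose outputs
already exist (and whose config hash matches) is skipped, which makes the
pipeline resumable: delete a downstream artifact and re-run to recompute
from that stage only.

One global seed is expanded into per-stage seeds as
``(seed * 10007 + stage_index) mod 2^31``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import (assign_individuals, cluster_summaries,
                        regional_assignment_summary, select_K, snmf_fit)
from .diversity import fst_group_summary, nei_pairwise_fst
from .filtering import CascadeStep, FilterConfig, full_filter
from .linkage_block import (block_haplotypes, block_regional_summary,
                            block_removal_contrast, classify_block_genotypes,
                            linkage_map_join, loading_block_detect)
from .pca_cluster import find_k_clusters, pca_genotypes
from .synthetic_data import SimConfig, write_fixture
from .vcf_io import read_sample_table, read_vcf, write_vcf

log = logging.getLogger("popstruct")

STAGES = ["data", "filter", "admixture", "pca", "fst", "block"]


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage_index: int) -> int:
    return (seed * 10007 + stage_index) % (2 ** 31)


def _filter_config(d: dict) -> FilterConfig:
    cfg = FilterConfig()
    for key, val in d.items():
        if key == "cascade_steps":
            cfg.cascade_steps = [CascadeStep(*step) for step in val]
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise ConfigError(f"unknown filter option {key!r}")
    return cfg


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the full recipe from a YAML config; returns the manifest."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    out = Path(out_dir or cfg.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config": str(config_path), "config_hash": cfg_hash,
                "seed": seed, "version": __version__, "stages": {},
                "warnings": []}

    def finish(stage, t0, outputs, extra=None, skipped=False):
        entry = {"seed": _stage_seed(seed, STAGES.index(stage)),
                 "wall_time_s": round(time.time() - t0, 3),
                 "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                 "skipped": skipped}
        if extra:
            entry.update(extra)
        manifest["stages"][stage] = entry
        log.info("[%s] done in %.2fs%s", stage, entry["wall_time_s"],
                 " (cached)" if skipped else "")

    def fresh(*paths):
        return not all(Path(p).exists() for p in paths)

    try:
        # ------------------------------------------------ stage: data
        t0 = time.time()
        data_dir = out / "data"
        if "simulate" in cfg:
            sim = SimConfig(**{**cfg["simulate"],
                               "seed": cfg["simulate"].get(
                                   "seed", _stage_seed(seed, 0))})
            vcf_path = data_dir / "genotypes.vcf"
            samples_path = data_dir / "samples.tsv"
            if fresh(vcf_path, samples_path):
                write_fixture(data_dir, sim, overwrite=True)
                finish("data", t0, [vcf_path, samples_path])
            else:
                finish("data", t0, [vcf_path, samples_path], skipped=True)
        elif "input" in cfg:
            vcf_path = Path(cfg["input"]["vcf"])
            samples_path = Path(cfg["input"]["samples"])
            if fresh(vcf_path, samples_path):
                raise ConfigError("input files do not exist")
            finish("data", t0, [vcf_path, samples_path], skipped=True)
        else:
            raise ConfigError("config needs a 'simulate' or 'input' section")

        st = read_sample_table(samples_path)

        # ------------------------------------------------ stage: filter
        t0 = time.time()
        fvcf = out / "filtered.vcf"
        freport = out / "filter_report.tsv"
        if fresh(fvcf, freport):
            gm, vt = read_vcf(vcf_path)
            fcfg = _filter_config(cfg.get("filter", {}))
            gm, report = full_filter(gm, vt, st.aligned_to(gm), fcfg)
            write_vcf(fvcf, gm)
            report.removed_frame().to_csv(freport, sep="\t", index=False)
            report.steps_frame().to_csv(out / "filter_steps.tsv", sep="\t", index=False)
            finish("filter", t0, [fvcf, freport],
                   {"n_samples": gm.n_samples, "n_loci": gm.n_loci})
        else:
            finish("filter", t0, [fvcf, freport], skipped=True)

        gm, _ = read_vcf(fvcf)
        st_al = st.aligned_to(gm)

        # ------------------------------------------------ stage: admixture
        t0 = time.time()
        acfg = cfg.get("admixture", {})
        a_out = out / "admixture"
        a_out.mkdir(exist_ok=True)
        ksel_path, q_path = a_out / "kselection.tsv", a_out / "Q.tsv"
        if fresh(ksel_path, q_path):
            a_seed = _stage_seed(seed, 2)
            krange = range(int(acfg.get("k_min", 1)), int(acfg.get("k_max", 5)) + 1)
            ksel = select_K(gm, krange, replicates=int(acfg.get("replicates", 3)),
                            seed=a_seed, mask_fraction=float(acfg.get("mask_fraction", 0.05)))
            pd.DataFrame([(k, r, v) for k in ksel.k_values
                          for r, v in enumerate(ksel.criterion[k])],
                         columns=["K", "replicate", "cross_entropy"]
                         ).to_csv(ksel_path, sep="\t", index=False)
            fit = snmf_fit(gm, ksel.best_k, seed=a_seed,
                           mask_fraction=float(acfg.get("mask_fraction", 0.05)))
            pd.DataFrame(fit.Q, index=gm.samples).to_csv(q_path, sep="\t")
            pd.DataFrame(fit.F, columns=gm.loci).to_csv(a_out / "F.tsv", sep="\t")
            labels = assign_individuals(fit)
            pd.DataFrame({"sample_id": gm.samples, "cluster": labels}
                         ).to_csv(a_out / "assignments.tsv", sep="\t", index=False)
            pct, counts = regional_assignment_summary(labels, st_al)
            pct.to_csv(a_out / "regional_pct.tsv", sep="\t")
            from .plotting import admixture_barplot
            admixture_barplot(fit.Q, st_al, a_out / "barplot.png")
            cs = cluster_summaries(fit)
            with open(a_out / "cluster_summary.json", "w") as fh:
                json.dump({"net_nucleotide_distance": cs.net_nucleotide_distance.tolist(),
                           "expected_heterozygosity": cs.expected_heterozygosity.tolist(),
                           "within_cluster_fst": cs.within_cluster_fst.tolist()}, fh, indent=1)
            extra = {"best_K": ksel.best_k,
                     "delta_k": {str(k): v for k, v in ksel.delta_k.items()}}
            finish("admixture", t0, [ksel_path, q_path], extra)
        else:
            finish("admixture", t0, [ksel_path, q_path], skipped=True)

        # ------------------------------------------------ stage: pca
        t0 = time.time()
        p_out = out / "pca"
        p_out.mkdir(exist_ok=True)
        scores_path = p_out / "scores.tsv"
        if fresh(scores_path):
            pcfg = cfg.get("pca", {})
            n_axes = int(pcfg.get("n_axes", 10))
            fit = pca_genotypes(gm, n_axes=min(n_axes, min(gm.n_samples, gm.n_loci)))
            pd.DataFrame(fit.scores, index=gm.samples).to_csv(scores_path, sep="\t")
            pd.DataFrame(fit.loadings, index=gm.loci).to_csv(p_out / "loadings.tsv", sep="\t")
            pd.Series(fit.eigenvalues).to_csv(p_out / "eigenvalues.tsv", sep="\t")
            bics, best_k = find_k_clusters(fit.scores, int(pcfg.get("max_k", 10)),
                                           seed=_stage_seed(seed, 3))
            pd.DataFrame({"k": np.arange(1, len(bics) + 1), "bic": bics}
                         ).to_csv(p_out / "bic.tsv", sep="\t", index=False)
            if fit.scores.shape[1] >= 2:
                from .plotting import pca_scatter
                pca_scatter(fit, st_al, p_out / "scatter.png")
            finish("pca", t0, [scores_path], {"best_k": best_k})
        else:
            finish("pca", t0, [scores_path], skipped=True)

        # ------------------------------------------------ stage: fst
        t0 = time.time()
        fst_path = out / "fst.tsv"
        if fresh(fst_path):
            dcfg = cfg.get("fst", {})
            fm = nei_pairwise_fst(gm, st_al, min_n=int(dcfg.get("min_n", 18)))
            fm.frame().to_csv(fst_path, sep="\t")
            mapping = {l: st_al.table.loc[st_al.table["locality_id"] == l,
                                          "region"].iloc[0] for l in fm.localities}
            fst_group_summary(fm, mapping).to_csv(out / "fst_groups.tsv",
                                                  sep="\t", index=False)
            finish("fst", t0, [fst_path])
        else:
            finish("fst", t0, [fst_path], skipped=True)

        # ------------------------------------------------ stage: block
        t0 = time.time()
        b_out = out / "block"
        b_out.mkdir(exist_ok=True)
        block_path = b_out / "block.json"
        if fresh(block_path):
            bcfg = cfg.get("block", {})
            axis = int(bcfg.get("axis", 1))
            excl = bcfg.get("exclude_region")
            sub = gm
            if excl:
                keep = st_al.table["region"].to_numpy() != excl
                sub = gm.take_samples(keep)
            fit = pca_genotypes(sub, n_axes=max(axis, 2))
            rep = loading_block_detect(fit, axis=axis,
                                       tau=float(bcfg.get("tau", 0.25)),
                                       min_size=int(bcfg.get("min_size", 2)))
            result = {"members": rep.members, "gap": rep.gap,
                      "loadings": np.asarray(rep.loadings).tolist()}
            if not rep.empty:
                hap_a, hap_b = block_haplotypes(gm, rep.members)
                classes = classify_block_genotypes(gm, rep.members, hap_a, hap_b)
                classes.to_csv(b_out / "block_classes.tsv", sep="\t")
                pct, unit = block_regional_summary(classes, st_al)
                pct.to_csv(b_out / "block_regions.tsv", sep="\t")
                # contrast on the same (region-excluded) matrix the block
                # axis was fitted on; classification stays on all samples
                before, after, ratio = block_removal_contrast(
                    sub, rep.members, axis, classes=classes)
                result.update({"hap_a": hap_a, "hap_b": hap_b,
                               "unit_fraction": unit,
                               "separation_before": before,
                               "separation_after": after,
                               "separation_ratio": ratio})
                if bcfg.get("map"):
                    ann = linkage_map_join(rep.members,
                                           pd.read_csv(bcfg["map"], sep="\t"))
                    ann.to_csv(b_out / "block_map.tsv", sep="\t", index=False)
                    result["modal_linkage_group"] = ann.attrs["modal_group"]
            with open(block_path, "w") as fh:
                json.dump(result, fh, indent=1)
            finish("block", t0, [block_path], {"block_size": len(rep.members)})
        else:
            finish("block", t0, [block_path], skipped=True)
    except ConfigError:
        raise
    except Exception as e:
        manifest["failed_stage"] = next(
            (s for s in STAGES if s not in manifest["stages"]), "unknown")
        manifest["error"] = str(e)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
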