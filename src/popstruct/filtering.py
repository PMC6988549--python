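"""Post-variant-calling SNP and individual filtering.

Four stages, applied in order:

1. ``site_filter`` — keep biallelic SNPs with adequate site quality; mask
   individual genotypes with low depth (DP) or low genotype quality (GQ);
   drop sites failing minor-allele-count or initial call-rate thresholds.
2. ``missingness_cascade`` — a sequence of steps, each removing individuals
   whose missing-data fraction exceeds the step's tolerance and then
   (recomputed on the reduced matrix) loci failing the step's minor-allele
   frequency and/or call-rate thresholds.  Tolerances tighten step by step;
   interleaving individual and locus removal retains more of both than a
   single harsh pass would.
3. ``heterozygosity_filter`` — drop loci whose observed heterozygosity
   exceeds 0.5, a signature of collapsed paralogs in reduced-representation
   data.
4. ``hwe_filter`` — drop loci out of Hardy-Weinberg equilibrium (1-df
   chi-square goodness of fit) in more than a set fraction of collection
   localities.

Each stage returns the reduced matrix plus a :class:`FilterReport` listing
every removal with a machine-readable reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .vcf_io import MISSING, GenotypeMatrix, SampleTable, VariantTable, missingness


@dataclass
class CascadeStep:
    """One step of the sequential cascade: individuals first, then loci.

    ``None`` disables the corresponding locus threshold for that step.
    """

    max_individual_missing: float
    min_maf: Optional[float] = None
    min_locus_callrate: Optional[float] = None


@dataclass
class FilterConfig:
    min_depth: int = 3
    min_site_quality: float = 30.0
    min_genotype_quality: float = 30.0
    min_minor_allele_count: int = 3
    initial_locus_callrate: float = 0.5
    cascade_steps: list = field(default_factory=lambda: [
        CascadeStep(0.70, 0.005, None),
        CascadeStep(0.65, 0.005, 0.90),
        CascadeStep(0.30, 0.005, 0.95),
        CascadeStep(0.20, None, 0.96),
        CascadeStep(0.15, None, None),
    ])
    max_locus_heterozygosity: float = 0.5
    hwe_alpha: float = 0.01
    hwe_locality_fraction: float = 0.60
    hwe_min_genotypes: int = 5


@dataclass
class FilterReport:
    """Per-step removal accounting.

    ``steps`` rows: (step, n_individuals_removed, n_loci_removed,
    n_samples_after, n_loci_after).  ``removed`` rows: (step, entity, id,
    reason) — one row per removed individual or locus.
    """

    steps: list = field(default_factory=list)
    removed: list = field(default_factory=list)

    def record(self, step: str, gm_after: GenotypeMatrix,
               individuals: list[tuple[str, str]], loci: list[tuple[str, str]]):
        self.steps.append((step, len(individuals), len(loci),
                           gm_after.n_samples, gm_after.n_loci))
        for sid, reason in individuals:
            self.removed.append((step, "individual", sid, reason))
        for lid, reason in loci:
            self.removed.append((step, "locus", lid, reason))

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=[
            "step", "individuals_removed", "loci_removed",
            "samples_after", "loci_after"])

    def removed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["step", "entity", "id", "reason"])

    def extend(self, other: "FilterReport") -> "FilterReport":
        self.steps.extend(other.steps)
        self.removed.extend(other.removed)
        return self


def _maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per locus over non-missing genotypes (VCFtools
    semantics: denominator is observed allele count)."""
    obs = gm.observed()
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, gm.codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def site_filter(gm: GenotypeMatrix, vt: VariantTable, cfg: FilterConfig
                ) -> tuple[GenotypeMatrix, VariantTable, FilterReport]:
    """Site-level filters plus per-genotype DP/GQ masking.

    Masking happens BEFORE minor-allele-count and call-rate computation, so
    a genotype failing depth/quality cannot rescue a site.
    """
    report = FilterReport()
    codes = gm.codes.copy()

    if vt.dp is not None:
        known = vt.dp >= 0
        codes[known & (vt.dp < cfg.min_depth)] = MISSING
    if vt.gq is not None:
        known = vt.gq >= 0
        codes[known & (vt.gq < cfg.min_genotype_quality)] = MISSING
    if vt.dp is None and vt.gq is None:
        warnings.warn("no DP/GQ fields present; genotype-level masking skipped")

    masked = GenotypeMatrix(gm.samples, gm.loci, codes, gm.ref_allele, gm.alt_allele)

    removed_loci: list[tuple[str, str]] = []
    keep = np.ones(masked.n_loci, dtype=bool)

    bial = vt.sites["biallelic_snp"].to_numpy(dtype=bool)
    qual = vt.sites["qual"].to_numpy(dtype=float)
    obs = masked.observed()
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, masked.codes, 0).sum(axis=0)
    mac = np.minimum(alt, 2 * n_obs - alt)
    callrate = n_obs / max(masked.n_samples, 1)

    qual_ok = np.isnan(qual) | (qual >= cfg.min_site_quality)
    for j, lid in enumerate(masked.loci):
        if not bial[j]:
            reason = "not_biallelic_snp"
        elif not qual_ok[j]:
            reason = f"site_quality<{cfg.min_site_quality:g}"
        elif mac[j] < cfg.min_minor_allele_count:
            reason = f"mac<{cfg.min_minor_allele_count}"
        elif callrate[j] < cfg.initial_locus_callrate:
            reason = f"callrate<{cfg.initial_locus_callrate:g}"
        else:
            continue
        keep[j] = False
        removed_loci.append((lid, reason))

    out = masked.take_loci(keep)
    vt_out = vt.take_loci(keep)
    report.record("site_filter", out, [], removed_loci)
    return out, vt_out, report


def missingness_cascade(gm: GenotypeMatrix, cfg: FilterConfig
                        ) -> tuple[GenotypeMatrix, FilterReport]:
    """Sequential individual/locus cascade.

    Within each step the order is normative: individuals over the missingness
    tolerance are removed first, then locus MAF / call rate are recomputed on
    the reduced matrix and failing loci removed.
    """
    report = FilterReport()
    for s_idx, step in enumerate(cfg.cascade_steps):
        name = f"cascade_{s_idx + 1}"
        per_sample, _ = missingness(gm)
        drop_ind = per_sample > step.max_individual_missing
        ind_removed = [(gm.samples[i], f"missing>{step.max_individual_missing:g}")
                       for i in np.flatnonzero(drop_ind)]
        gm = gm.take_samples(~drop_ind)
        if gm.n_samples == 0:
            raise ValueError(f"all individuals removed at {name}")

        keep = np.ones(gm.n_loci, dtype=bool)
        loci_removed: list[tuple[str, str]] = []
        maf = _maf(gm)
        _, per_locus = missingness(gm)
        callrate = 1.0 - per_locus
        for j, lid in enumerate(gm.loci):
            if step.min_maf is not None and maf[j] < step.min_maf:
                reason = f"maf<{step.min_maf:g}"
            elif (step.min_locus_callrate is not None
                  and callrate[j] < step.min_locus_callrate):
                reason = f"callrate<{step.min_locus_callrate:g}"
            else:
                continue
            keep[j] = False
            loci_removed.append((lid, reason))
        gm = gm.take_loci(keep)
        report.record(name, gm, ind_removed, loci_removed)
    return gm, report


def observed_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of heterozygous calls among non-missing genotypes."""
    obs = gm.observed()
    n_obs = obs.sum(axis=0)
    n_het = ((gm.codes == 1) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)


def heterozygosity_filter(gm: GenotypeMatrix, cfg: FilterConfig
                          ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop putative paralogs: loci with observed heterozygosity > threshold
    (strict inequality; a locus at exactly the threshold is kept)."""
    report = FilterReport()
    het = observed_heterozygosity(gm)
    keep = np.ones(gm.n_loci, dtype=bool)
    removed = []
    for j, lid in enumerate(gm.loci):
        if np.isnan(het[j]):
            keep[j] = False
            removed.append((lid, "no data"))
        elif het[j] > cfg.max_locus_heterozygosity:
            keep[j] = False
            removed.append((lid, f"heterozygosity>{cfg.max_locus_heterozygosity:g}"))
    gm = gm.take_loci(keep)
    report.record("heterozygosity", gm, [], removed)
    return gm, report


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p-value of genotype counts against
    Hardy-Weinberg proportions at the sample allele frequency.

    No continuity correction.  A monomorphic sample fits HWE exactly (p=1).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_alt + n_het) / (2.0 * n)
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p ** 2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    nz = exp > 0
    chi2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_filter(gm: GenotypeMatrix, st: SampleTable, cfg: FilterConfig
               ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci out of HWE (p < alpha) in more than a fraction of localities.

    Only localities with at least ``cfg.hwe_min_genotypes`` non-missing
    genotypes at the locus enter the denominator; loci with no qualifying
    locality are exempt (logged, kept).
    """
    report = FilterReport()
    st = st.aligned_to(gm)
    loc = st.table["locality_id"].to_numpy()
    localities = pd.unique(loc)
    groups = {l: np.flatnonzero(loc == l) for l in localities}

    keep = np.ones(gm.n_loci, dtype=bool)
    removed = []
    exempt = 0
    for j, lid in enumerate(gm.loci):
        col = gm.codes[:, j]
        n_tested = n_out = 0
        for rows in groups.values():
            sub = col[rows]
            sub = sub[sub != MISSING]
            if sub.size < cfg.hwe_min_genotypes:
                continue
            n_tested += 1
            pval = hwe_chisq_p(int((sub == 0).sum()), int((sub == 1).sum()),
                               int((sub == 2).sum()))
            if pval < cfg.hwe_alpha:
                n_out += 1
        if n_tested == 0:
            exempt += 1
            continue
        if n_out / n_tested > cfg.hwe_locality_fraction:
            keep[j] = False
            removed.append((lid, f"hwe_fail_fraction>{cfg.hwe_locality_fraction:g}"))
    if exempt:
        warnings.warn(f"{exempt} loci exempt from HWE filter (no locality with "
                      f">={cfg.hwe_min_genotypes} genotypes)")
    gm = gm.take_loci(keep)
    report.record("hwe", gm, [], removed)
    return gm, report


def full_filter(gm: GenotypeMatrix, vt: VariantTable, st: Optional[SampleTable],
                cfg: Optional[FilterConfig] = None
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the complete filtering recipe: site filter, cascade,
    heterozygosity filter, and (when sample metadata is given) the HWE rule."""
    cfg = cfg or FilterConfig()
    gm, vt, report = site_filter(gm, vt, cfg)
    gm, rep2 = missingness_cascade(gm, cfg)
    report.extend(rep2)
    gm, rep3 = heterozygosity_filter(gm, cfg)
    report.extend(rep3)
    if st is not None:
        gm, rep4 = hwe_filter(gm, st, cfg)
        report.extend(rep4)
    return gm, report
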