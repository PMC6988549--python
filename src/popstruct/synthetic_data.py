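"""Synthetic GBS-style genotype datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: K admixed subpopulations whose allele frequencies drift from a
shared ancestral frequency under the Balding-Nichols model, collection
localities arranged on a west-to-east longitudinal gradient, a low overall
level of differentiation, a small uniform missing-genotype rate, and one
fully linked block of SNPs whose two haplotypes change frequency across
regions (with one region fixed for one haplotype).  Ground truth (ancestry
proportions, subpopulation frequencies, block membership and per-individual
block class) is returned alongside the data for parameter-recovery tests.

The drift parameter ``fst_target`` is calibrated to the estimator applied
downstream: it is the expected Nei pairwise F_st between two localities
drawn from different subpopulations.  For two demes the Nei estimator has
expectation (c/2)/(1 - c/2) when each deme's frequencies follow a
Balding-Nichols Beta with drift c, so the generator draws frequencies with
c = 2F/(1+F), making realized pairwise differentiation match the requested
F.  (Quoting the raw Beta parameter instead would make pairwise estimates
come out near F/2.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .vcf_io import (MISSING, GenotypeMatrix, SampleTable, VariantTable,
                     write_sample_table, write_vcf)

#: region -> true subpopulation index (West Virginia is part of the eastern
#: subpopulation; it is tracked as its own region because its block-haplotype
#: frequency differs).
REGION_SUBPOP = {"western": 0, "central": 1, "eastern": 2, "west_virginia": 2}

_REGION_LON = {"western": (-165.0, -132.0), "central": (-120.0, -96.0),
               "eastern": (-94.0, -55.0), "west_virginia": (-79.7, -79.7)}
_REGION_LAT = {"western": (61.0, 65.0), "central": (50.0, 55.0),
               "eastern": (44.0, 50.0), "west_virginia": (38.6, 38.6)}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the analysis conditions: K=3 subpopulations, 12
    localities of 25 individuals (n=300), 1000 loci, weak differentiation
    (target pairwise F_st 0.02), mostly-pure ancestry with occasional
    admixture, ~1.5% missing genotypes, and a 3-SNP fully linked block whose
    haplotype-B frequency rises west to east and is fixed in the
    West-Virginia-analogue region.
    """

    k_true: int = 3
    n_localities: dict = field(default_factory=lambda: {
        "western": 2, "central": 4, "eastern": 5, "west_virginia": 1})
    individuals_per_locality: int = 25
    n_loci: int = 1000
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    # Drift per subpopulation (keyed by the subpopulation-defining regions),
    # or a single float applied to every subpopulation.  The default mirrors
    # the asymmetric structure of the study system: a strongly drifted
    # western subpopulation and weakly differentiated central/eastern ones.
    # Expected Nei pairwise Fst between localities of subpopulations j and k
    # is ~ (F_j + F_k) / 2; with a scalar F it is ~ F.
    fst_target: object = field(default_factory=lambda: {
        "western": 0.025, "central": 0.005, "eastern": 0.01})
    dirichlet_own: float = 15.0
    dirichlet_other: float = 0.2
    # optional per-region Dirichlet concentrations (region -> K floats),
    # overriding the own/other scalars where given; lets one region be more
    # admixed than the rest
    dirichlet_alpha: dict = field(default_factory=dict)
    block_size: int = 3
    block_hapB_freq: dict = field(default_factory=lambda: {
        "western": 0.0, "central": 0.05, "eastern": 0.5, "west_virginia": 1.0})
    block_recomb_rate: float = 0.0
    missing_rate: float = 0.015
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self):
        regions = set(self.n_localities)
        if regions != set(REGION_SUBPOP):
            raise ValueError(f"n_localities regions {sorted(regions)} must be "
                             f"{sorted(REGION_SUBPOP)}")
        if set(self.block_hapB_freq) != regions:
            raise ValueError("block_hapB_freq regions inconsistent with n_localities")
        for name in ("missing_rate", "genotype_error_rate", "block_recomb_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0, 1)")
        for v in self.subpop_drift():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"fst_target value {v} outside [0, 1)")
        if not 0 <= self.block_size <= self.n_loci:
            raise ValueError("block_size outside [0, n_loci]")

    def subpop_drift(self) -> np.ndarray:
        """Per-subpopulation drift values, index-aligned to cluster order."""
        if isinstance(self.fst_target, dict):
            try:
                vals = [float(self.fst_target[r])
                        for r in ("western", "central", "eastern")]
            except KeyError as e:
                raise ValueError(
                    "fst_target dict needs keys western/central/eastern"
                ) from e
            return np.asarray(vals)
        return np.full(self.k_true, float(self.fst_target))


@dataclass
class SimTruth:
    q: np.ndarray                  # n x K true ancestry proportions
    subpop_freq: np.ndarray        # K x m true subpopulation allele frequencies
    block_members: list            # locus ids of the planted block
    block_member_idx: np.ndarray   # column indices of the block
    block_hapB_is_alt: np.ndarray  # per member: does haplotype B carry alt?
    block_class: list              # per individual: hom_A / het / hom_B / other
    block_hapB_copies: np.ndarray  # per individual: 0/1/2 copies of haplotype B


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[GenotypeMatrix, VariantTable, SampleTable, SimTruth]:
    """Draw one dataset; all randomness flows from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    K, m = cfg.k_true, cfg.n_loci

    # --- samples and localities on a longitudinal gradient ----------------
    rows = []
    loc_counter = 0
    for region in sorted(cfg.n_localities):
        lon_lo, lon_hi = _REGION_LON[region]
        lat_lo, lat_hi = _REGION_LAT[region]
        nl = cfg.n_localities[region]
        for i in range(nl):
            loc_counter += 1
            lid = f"loc{loc_counter:02d}_{region}"
            frac = (i + 0.5) / nl
            lon = lon_lo + frac * (lon_hi - lon_lo)
            lat = lat_lo + frac * (lat_hi - lat_lo)
            for j in range(cfg.individuals_per_locality):
                rows.append((f"{lid}_ind{j + 1:02d}", lid,
                             round(lat, 4), round(lon, 4), region))
    st = SampleTable(pd.DataFrame(rows, columns=[
        "sample_id", "locality_id", "latitude", "longitude", "region"]))
    n = len(rows)
    region_arr = st.table["region"].to_numpy()

    # --- ancestral and drifted subpopulation frequencies ------------------
    p_anc = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=m)
    drift = cfg.subpop_drift()
    P = np.empty((K, m))
    for k in range(K):
        F = drift[k] if k < drift.size else drift[-1]
        if F > 0:
            c = 2.0 * F / (1.0 + F)
            a = p_anc * (1.0 - c) / c
            b = (1.0 - p_anc) * (1.0 - c) / c
            P[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        else:
            P[k] = p_anc

    # --- individual ancestry proportions ----------------------------------
    Q = np.empty((n, K))
    for region, sub in REGION_SUBPOP.items():
        sel = region_arr == region
        if not sel.any():
            continue
        if region in cfg.dirichlet_alpha:
            alpha = np.asarray(cfg.dirichlet_alpha[region], dtype=float)
            if alpha.shape != (K,):
                raise ValueError(f"dirichlet_alpha[{region!r}] needs {K} values")
        else:
            alpha = np.full(K, cfg.dirichlet_other)
            alpha[sub] = cfg.dirichlet_own
        Q[sel] = rng.dirichlet(alpha, size=int(sel.sum()))

    # --- unlinked genotypes: two allele draws through the admixture model --
    codes = np.zeros((n, m), dtype=np.int8)
    cumQ = np.cumsum(Q, axis=1)
    col_idx = np.arange(m)
    for _ in range(2):
        z = (rng.random((n, m))[:, :, None] > cumQ[:, None, :]).sum(axis=2)
        z = np.minimum(z, K - 1)
        codes += (rng.random((n, m)) < P[z, col_idx[None, :]]).astype(np.int8)

    # --- planted fully linked block ----------------------------------------
    block_idx = np.sort(rng.choice(m, size=cfg.block_size, replace=False)) \
        if cfg.block_size else np.empty(0, dtype=int)
    hapB_is_alt = rng.random(cfg.block_size) < 0.5
    hapB_copies = np.zeros(n, dtype=np.int8)
    for region, q in cfg.block_hapB_freq.items():
        sel = region_arr == region
        hapB_copies[sel] = rng.binomial(2, q, size=int(sel.sum()))
    if cfg.block_size:
        dose_b = hapB_copies[:, None].astype(np.int8)       # copies of hap B
        block_codes = np.where(hapB_is_alt[None, :], dose_b, 2 - dose_b)
        # recombinants: scramble one block locus of affected individuals
        rec = rng.random(n) < cfg.block_recomb_rate
        for i in np.flatnonzero(rec):
            j = rng.integers(cfg.block_size)
            block_codes[i, j] = rng.integers(3)
        codes[:, block_idx] = block_codes

    # --- genotype errors, then missingness ---------------------------------
    if cfg.genotype_error_rate > 0:
        err = rng.random((n, m)) < cfg.genotype_error_rate
        bump = np.where(rng.random((n, m)) < 0.5, -1, 1)
        flipped = np.clip(codes + np.where(err, bump, 0), 0, 2)
        codes = np.where(err, flipped, codes).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        codes[miss] = MISSING

    # --- assemble containers ------------------------------------------------
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    loci = [f"scf{j + 1}_{int(pos)}"
            for j, pos in enumerate(rng.integers(1_000, 99_999, size=m))]
    gm = GenotypeMatrix(samples=list(st.table["sample_id"]), loci=loci,
                        codes=codes, ref_allele=bases[ref_i], alt_allele=bases[alt_i])
    sites = pd.DataFrame({
        "locus": loci,
        "chrom": [l.split("_")[0] for l in loci],
        "pos": [int(l.split("_")[1]) for l in loci],
        "qual": np.round(rng.uniform(50, 900, size=m), 1),
        "biallelic_snp": True,
    })
    dp = rng.poisson(25, size=(n, m)).astype(np.int32)
    gq = rng.integers(40, 100, size=(n, m)).astype(np.int32)
    vt = VariantTable(sites=sites, dp=dp, gq=gq)

    cls_names = np.array(["hom_A", "het", "hom_B"])
    block_class = list(cls_names[hapB_copies]) if cfg.block_size else []
    if cfg.block_size:
        # recombination or genotype error can break the unit pattern
        planted = np.where(hapB_is_alt[None, :],
                           hapB_copies[:, None], 2 - hapB_copies[:, None])
        broken = (codes[:, block_idx] != planted).any(axis=1) & \
                 (codes[:, block_idx] != MISSING).all(axis=1)
        for i in np.flatnonzero(broken):
            block_class[i] = "other"
    truth = SimTruth(q=Q, subpop_freq=P,
                     block_members=[loci[j] for j in block_idx],
                     block_member_idx=block_idx,
                     block_hapB_is_alt=hapB_is_alt,
                     block_class=block_class,
                     block_hapB_copies=hapB_copies.astype(int))
    return gm, vt, st, truth


def write_fixture(out_dir, cfg: SimConfig | None = None, overwrite: bool = False
                  ) -> dict:
    """Simulate a dataset and write VCF + sample TSV + truth JSON.

    Output is deterministic in ``cfg.seed`` (byte-identical on repetition).
    Returns the paths written.
    """
    cfg = cfg or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "genotypes.vcf", "samples": out / "samples.tsv",
             "truth": out / "truth.json", "config": out / "sim_config.json"}
    existing = [str(p) for p in paths.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite {existing}")
    gm, vt, st, truth = simulate_dataset(cfg)
    write_vcf(paths["vcf"], gm, vt)
    write_sample_table(paths["samples"], st)
    with open(paths["truth"], "w") as fh:
        json.dump({
            "q": truth.q.round(6).tolist(),
            "subpop_freq": truth.subpop_freq.round(6).tolist(),
            "block_members": truth.block_members,
            "block_member_idx": truth.block_member_idx.tolist(),
            "block_hapB_is_alt": truth.block_hapB_is_alt.tolist(),
            "block_class": truth.block_class,
            "block_hapB_copies": truth.block_hapB_copies.tolist(),
        }, fh, indent=1)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
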