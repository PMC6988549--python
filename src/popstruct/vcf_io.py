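"""Genotype-matrix I/O for multi-sample VCF and sample-metadata tables.

The in-memory model is an individuals x loci matrix of alt-allele dosages
(0, 1, 2) with a reserved integer sentinel for missing genotypes, plus two
side tables: per-locus variant annotation (position, site quality, per-genotype
DP/GQ) and per-sample collection metadata (locality, coordinates, region).
Every downstream stage (filtering, admixture, PCA, Fst, block detection)
consumes these three objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Reserved integer code for a missing genotype.  An integer (never NaN) so
#: that genotype counting stays exact.
MISSING = -1

#: Fixed vocabulary of geographic region labels.
REGIONS = ("western", "central", "eastern", "west_virginia")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed; names the offending line."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage codes with a missing sentinel.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows).
    loci : list of str
        Ordered, unique locus identifiers (columns).
    codes : ndarray of int8, shape (n_samples, n_loci)
        Entries in {0, 1, 2} or :data:`MISSING`.
    ref_allele, alt_allele : ndarray of str
        Per-locus single-base reference / alternate alleles.
    """

    samples: list
    loci: list
    codes: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n, m = self.codes.shape
        if len(self.samples) != n or len(self.loci) != m:
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus identifiers")
        valid = (self.codes == MISSING) | ((self.codes >= 0) & (self.codes <= 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.codes != MISSING

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row subset; `keep` is a boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            loci=list(self.loci),
            codes=self.codes[keep, :],
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
        )

    def take_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset; `keep` is a boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in keep],
            codes=self.codes[:, keep],
            ref_allele=self.ref_allele[keep],
            alt_allele=self.alt_allele[keep],
        )


@dataclass
class VariantTable:
    """Per-locus annotation aligned to a :class:`GenotypeMatrix`.

    ``sites`` has one row per locus, in matrix order, with columns
    (locus, chrom, pos, qual, biallelic_snp).  ``dp`` and ``gq`` are
    n_samples x n_loci integer matrices (negative = unknown) or None when
    the VCF carried no DP/GQ FORMAT fields.
    """

    sites: pd.DataFrame
    dp: Optional[np.ndarray] = None
    gq: Optional[np.ndarray] = None

    def __post_init__(self):
        if (self.sites["pos"] < 1).any():
            raise ValueError("VCF positions must be >= 1")

    def take_loci(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantTable(
            sites=self.sites.iloc[keep].reset_index(drop=True),
            dp=None if self.dp is None else self.dp[:, keep],
            gq=None if self.gq is None else self.gq[:, keep],
        )

    def take_samples(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantTable(
            sites=self.sites,
            dp=None if self.dp is None else self.dp[keep, :],
            gq=None if self.gq is None else self.gq[keep, :],
        )


SAMPLE_COLUMNS = ["sample_id", "locality_id", "latitude", "longitude", "region"]


@dataclass
class SampleTable:
    """Collection metadata: one row per sample.

    Columns: sample_id, locality_id, latitude, longitude (decimal degrees),
    region (one of :data:`REGIONS`), and optionally life stage / source.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"sample table missing columns {missing_cols}")
        bad = set(self.table["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}; expected {REGIONS}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")

    def aligned_to(self, gm: GenotypeMatrix) -> "SampleTable":
        """Rows reordered to match ``gm.samples``; every sample must appear."""
        t = self.table.set_index("sample_id")
        absent = [s for s in gm.samples if s not in t.index]
        if absent:
            raise ValueError(f"samples missing from metadata: {absent[:5]}")
        return SampleTable(t.loc[gm.samples].reset_index())

    def locality_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["locality_id"]

    def region_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["region"]


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, VariantTable]:
    """Parse a VCF v4.x into a dosage matrix plus variant annotation.

    Diploid GT is converted to alt-allele dosage; any genotype containing a
    missing allele ("./.", "./1", ...) becomes :data:`MISSING` (half-calls are
    treated conservatively, as VCFtools does).  Phase separators are ignored.
    Multi-allelic or non-SNP records are retained but flagged
    ``biallelic_snp=False`` so the site filter can drop them.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as e:  # htslib rejects e.g. duplicate sample columns here
        raise VcfParseError(f"cannot parse VCF header of {path}: {e}") from e
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise VcfParseError("duplicate sample id in VCF header")
    n = len(samples)

    def has_format(tag):
        try:
            return vcf.get_header_type(tag) is not None
        except KeyError:
            return False

    header_dp, header_gq = has_format("DP"), has_format("GQ")

    codes_cols, dp_cols, gq_cols = [], [], []
    rows = []
    ref_l, alt_l = [], []
    seen_ids: dict[str, int] = {}
    any_dp = any_gq = False
    half_calls = 0
    rec_no = 0
    try:
        for v in vcf:
            rec_no += 1
            gts = v.genotypes  # [[a0, a1, phased], ...]
            col = np.full(n, MISSING, dtype=np.int8)
            for i, g in enumerate(gts):
                alleles = g[:-1]
                if len(alleles) != 2 or min(alleles) < 0:
                    if len(alleles) == 2 and max(alleles) >= 0 > min(alleles):
                        half_calls += 1
                    continue
                col[i] = np.int8(min(int(alleles[0] > 0) + int(alleles[1] > 0), 2)
                                 if len(v.ALT) != 1
                                 else alleles[0] + alleles[1])
            codes_cols.append(col)

            dp = v.format("DP") if header_dp else None
            if dp is not None:
                any_dp = True
                dp_cols.append(np.asarray(dp).reshape(n).astype(np.int32))
            else:
                dp_cols.append(np.full(n, -1, dtype=np.int32))
            gq = v.format("GQ") if header_gq else None
            if gq is not None:
                any_gq = True
                gq_cols.append(np.asarray(gq).reshape(n).astype(np.int32))
            else:
                gq_cols.append(np.full(n, -1, dtype=np.int32))

            locus = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
            if locus in seen_ids:
                seen_ids[locus] += 1
                locus = f"{locus}.{seen_ids[locus]}"
            else:
                seen_ids[locus] = 0
            ref = v.REF
            alts = list(v.ALT)
            biallelic_snp = (
                len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1
                and alts[0] in "ACGT" and ref in "ACGT"
            )
            rows.append((locus, v.CHROM, v.POS,
                         float(v.QUAL) if v.QUAL is not None else np.nan,
                         biallelic_snp))
            ref_l.append(ref)
            alt_l.append(alts[0] if alts else ".")
    except Exception as e:  # cyvcf2 raises on malformed records
        if isinstance(e, VcfParseError):
            raise
        raise VcfParseError(f"malformed VCF record near data line {rec_no + 1}: {e}") from e

    if half_calls:
        warnings.warn(f"{half_calls} half-called genotypes set to missing")

    codes = (np.stack(codes_cols, axis=1) if codes_cols
             else np.empty((n, 0), dtype=np.int8))
    sites = pd.DataFrame(rows, columns=["locus", "chrom", "pos", "qual", "biallelic_snp"])
    vt = VariantTable(
        sites=sites,
        dp=np.stack(dp_cols, axis=1) if any_dp else None,
        gq=np.stack(gq_cols, axis=1) if any_gq else None,
    )
    gm = GenotypeMatrix(
        samples=samples,
        loci=list(sites["locus"]),
        codes=codes,
        ref_allele=np.array(ref_l, dtype=object),
        alt_allele=np.array(alt_l, dtype=object),
    )
    return gm, vt


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(path, gm: GenotypeMatrix, vt: Optional[VariantTable] = None) -> None:
    """Emit a minimal deterministic VCF v4.2 (GT, plus DP/GQ when present)."""
    has_dp = vt is not None and vt.dp is not None
    has_gq = vt is not None and vt.gq is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, locus in enumerate(gm.loci):
            if vt is not None:
                row = vt.sites.iloc[j]
                chrom, pos = row["chrom"], int(row["pos"])
                qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            else:
                chrom, pos, qual = locus, j + 1, "."
            fields = [str(chrom), str(pos), locus, str(gm.ref_allele[j]),
                      str(gm.alt_allele[j]), qual, "PASS", ".", fmt]
            for i in range(gm.n_samples):
                cell = _DOSAGE_TO_GT[int(gm.codes[i, j])]
                if has_dp:
                    d = int(vt.dp[i, j])
                    cell += ":" + (str(d) if d >= 0 else ".")
                if has_gq:
                    q = int(vt.gq[i, j])
                    cell += ":" + (str(q) if q >= 0 else ".")
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def read_sample_table(path) -> SampleTable:
    """Read the tab-separated sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locality_id": str})
    return SampleTable(df)


def write_sample_table(path, st: SampleTable) -> None:
    cols = SAMPLE_COLUMNS + [c for c in st.table.columns if c not in SAMPLE_COLUMNS]
    st.table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Shared primitives
# ---------------------------------------------------------------------------

def allele_freq(gm: GenotypeMatrix, sample_subset: Optional[Sequence[str]] = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus alt-allele frequency over a sample subset.

    Returns ``(freq, defined)`` where ``freq[l] = sum(codes) / (2 * n_obs)``
    over non-missing genotypes and ``defined[l]`` is False for loci with no
    data in the subset (freq NaN there).
    """
    if sample_subset is None:
        codes = gm.codes
    else:
        idx = gm.sample_index(list(sample_subset))
        if idx.size == 0:
            raise ValueError("empty sample subset")
        codes = gm.codes[idx, :]
    if codes.shape[0] == 0:
        raise ValueError("empty sample subset")
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, codes, 0).sum(axis=0)
    defined = n_obs > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(defined, alt / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return freq, defined


def missingness(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-sample, per-locus) missing-genotype fractions on the current matrix."""
    miss = gm.codes == MISSING
    n, m = gm.codes.shape
    per_sample = miss.sum(axis=1) / m if m else np.zeros(n)
    per_locus = miss.sum(axis=0) / n if n else np.zeros(m)
    return per_sample, per_locus
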