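"""Detection and characterization of a linked SNP block from PC loadings.

A chromosomally localized block of fully linked SNPs that differs in
frequency between weakly differentiated subpopulations dominates the top of
the sorted PC-loading list: its members have near-identical absolute
loadings followed by a sharp drop to the genomic background.  The detector
formalizes that picture as a relative-drop rule on the sorted loading
magnitudes.  The block's two multilocus haplotypes are anchored on the most
common all-homozygous genotype combination; individuals are then classified
as homozygous for either haplotype, fully heterozygous, or "other" — under
complete linkage the first three classes should account for all individuals
(Mendelian-unit inheritance).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pca_cluster import PCAFit, pca_genotypes
from .vcf_io import MISSING, GenotypeMatrix, SampleTable

CLASSES = ("hom_A", "het", "hom_B", "other")


@dataclass
class BlockReport:
    members: list                          # locus ids, |loading| descending
    loadings: np.ndarray                   # signed loading values, same order
    gap: float                             # relative drop at the block boundary
    hap_a: list = field(default_factory=list)   # per-member allele, haplotype A
    hap_b: list = field(default_factory=list)
    classes: Optional[pd.Series] = None    # per-sample class (or "excluded")
    region_pct: Optional[pd.DataFrame] = None
    unit_fraction: Optional[float] = None
    annotations: Optional[pd.DataFrame] = None

    @property
    def empty(self) -> bool:
        return len(self.members) == 0


def loading_block_detect(fit: PCAFit, axis: int = 1, tau: float = 0.25,
                         min_size: int = 2, max_scan: int = 20) -> BlockReport:
    """Find the leading block on one PC axis by the relative-drop rule.

    Loadings are sorted by absolute value, v_1 >= v_2 >= ...; the block ends
    at the last index j before the first relative drop
    (v_i - v_{i+1}) / v_i > tau.  Only the top ``max_scan`` ranks are
    examined: the procedure characterizes top-contributing SNPs, and deep in
    the tail tiny loadings routinely show large relative drops that do not
    mark a block.  A block smaller than ``min_size`` (or no qualifying drop
    within the scan window) yields an empty report.  ``axis`` is 1-based.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if not 1 <= axis <= fit.loadings.shape[1]:
        raise ValueError(f"axis {axis} outside fitted axes")
    load = fit.loadings[:, axis - 1]
    order = np.argsort(-np.abs(load))
    v = np.abs(load[order])
    j = 0
    gap = float("nan")
    for i in range(min(v.size - 1, max_scan)):
        if v[i] <= 0:
            break
        drop = (v[i] - v[i + 1]) / v[i]
        if drop > tau:
            j = i + 1
            gap = float(drop)
            break
    if j < min_size or j >= v.size:
        return BlockReport(members=[], loadings=np.empty(0), gap=gap)
    ids = [fit.loci[k] for k in order[:j]] if fit.loci else list(order[:j])
    return BlockReport(members=ids, loadings=load[order[:j]], gap=gap)


def _member_index(gm: GenotypeMatrix, members: Sequence) -> np.ndarray:
    pos = {l: i for i, l in enumerate(gm.loci)}
    return np.array([pos[m] for m in members], dtype=int)


def block_haplotypes(gm: GenotypeMatrix, members: Sequence
                     ) -> tuple[list, list]:
    """Anchor the two block haplotypes on all-homozygous individuals.

    Haplotype A carries, per member locus, the allele of the most common
    fully homozygous multilocus genotype; haplotype B is the complementary
    allele vector.  With no all-homozygous individual the anchoring is
    ambiguous and an error is raised.
    """
    if len(members) < 2:
        raise ValueError("block must have >= 2 member loci")
    cols = _member_index(gm, members)
    sub = gm.codes[:, cols]
    full = (sub != MISSING).all(axis=1)
    homo = full & np.isin(sub, (0, 2)).all(axis=1)
    if not homo.any():
        raise ValueError("no all-homozygous individual anchors the block haplotypes")
    counts = Counter(tuple(int(c) for c in row) for row in sub[homo])
    best = max(sorted(counts), key=lambda t: counts[t])
    hap_a, hap_b = [], []
    for j, code in zip(cols, best):
        ref, alt = str(gm.ref_allele[j]), str(gm.alt_allele[j])
        hap_a.append(alt if code == 2 else ref)
        hap_b.append(ref if code == 2 else alt)
    return hap_a, hap_b


def classify_block_genotypes(gm: GenotypeMatrix, members: Sequence,
                             hap_a: Sequence[str], hap_b: Sequence[str]
                             ) -> pd.Series:
    """Per-individual block class.

    hom_A: homozygous for the haplotype-A allele at every member locus;
    hom_B symmetric; het: heterozygous at every member locus; other: any
    mixed pattern; "excluded": missing genotype at any member locus.
    """
    cols = _member_index(gm, members)
    sub = gm.codes[:, cols]
    a_dosage = np.array([2 if a == str(gm.alt_allele[j]) else 0
                         for j, a in zip(cols, hap_a)])
    out = []
    for row in sub:
        if (row == MISSING).any():
            out.append("excluded")
        elif (row == a_dosage).all():
            out.append("hom_A")
        elif (row == (2 - a_dosage)).all():
            out.append("hom_B")
        elif (row == 1).all():
            out.append("het")
        else:
            out.append("other")
    return pd.Series(out, index=gm.samples, name="block_class")


def block_regional_summary(classes: pd.Series, st: SampleTable
                           ) -> tuple[pd.DataFrame, float]:
    """Per-region class percentages and the overall unit-inheritance fraction.

    The unit fraction is (hom_A + het + hom_B) / classified, individuals
    with missing block genotypes excluded from the denominator.
    """
    st = st.table.set_index("sample_id")
    region = st.loc[classes.index, "region"]
    keep = classes != "excluded"
    df = pd.DataFrame({"region": region[keep], "class": classes[keep]})
    counts = (df.groupby(["region", "class"]).size().unstack(fill_value=0)
              .reindex(columns=CLASSES, fill_value=0))
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    total = int(counts.to_numpy().sum())
    unit = float(counts[["hom_A", "het", "hom_B"]].to_numpy().sum() / total) if total else float("nan")
    return pct, unit


def block_removal_contrast(gm: GenotypeMatrix, members: Sequence, axis: int,
                           classes: Optional[pd.Series] = None
                           ) -> tuple[float, float, float]:
    """Between-class separation of PC-axis scores before vs after removing
    the block loci.

    Separation is between-class variance / total variance of the axis scores,
    with classes from :func:`classify_block_genotypes`.  Returns
    ``(before, after, ratio)``; an empty member list trivially gives
    before == after (ratio 1).
    """
    if classes is None:
        hap_a, hap_b = block_haplotypes(gm, members)
        classes = classify_block_genotypes(gm, members, hap_a, hap_b)

    def separation(fit: PCAFit) -> float:
        s = pd.Series(fit.scores[:, axis - 1], index=fit.samples)
        cls = classes.loc[s.index]
        ok = cls != "excluded"
        s, cls = s[ok], cls[ok]
        if cls.nunique() < 2:
            warnings.warn("fewer than 2 block classes present; separation undefined")
            return float("nan")
        total = float(s.var(ddof=0))
        if total == 0:
            return float("nan")
        grand = s.mean()
        between = sum(len(g) * (g.mean() - grand) ** 2 for _, g in s.groupby(cls)) / len(s)
        return float(between / total)

    before = separation(pca_genotypes(gm, n_axes=axis))
    if len(members) == 0:
        return before, before, 1.0
    keep = ~np.isin(np.arange(gm.n_loci), _member_index(gm, members))
    after = separation(pca_genotypes(gm.take_loci(keep), n_axes=axis))
    ratio = after / before if before and np.isfinite(before) else float("nan")
    return before, after, ratio


def linkage_map_join(members: Sequence, map_table: pd.DataFrame,
                     ranked_loci: Optional[Sequence] = None,
                     stop_run: int = 5) -> pd.DataFrame:
    """Annotate block members with linkage-map positions.

    ``map_table`` columns: locus, linkage_group, cM (one row per locus;
    duplicates are an error).  Members absent from the map are reported as
    "unmapped".  The summary attribute ``modal_group`` / ``modal_fraction``
    records the most common linkage group among mapped members.

    Extended-scan mode: when ``ranked_loci`` (all loci in descending loading
    order) is given, the scan walks down the ranking collecting further loci
    of the modal group and stops after ``stop_run`` consecutive loci that
    are not on that group; the extra loci get ``in_block=False`` rows.
    """
    if map_table["locus"].duplicated().any():
        dups = map_table["locus"][map_table["locus"].duplicated()].tolist()
        raise ValueError(f"duplicate linkage-map entries: {dups[:5]}")
    lookup = map_table.set_index("locus")

    def annotate(locus):
        if locus in lookup.index:
            row = lookup.loc[locus]
            return str(row["linkage_group"]), float(row["cM"])
        return "unmapped", float("nan")

    rows = [(m, *annotate(m), True) for m in members]
    mapped = [g for _, g, _, _ in rows if g != "unmapped"]
    modal, modal_frac = None, float("nan")
    if mapped:
        c = Counter(mapped)
        modal = max(sorted(c), key=lambda g: c[g])
        modal_frac = c[modal] / len(mapped)

    if ranked_loci is not None and modal is not None:
        run = 0
        member_set = set(members)
        for locus in ranked_loci:
            if locus in member_set:
                continue
            group, cm = annotate(locus)
            if group == modal:
                rows.append((locus, group, cm, False))
                run = 0
            else:
                run += 1
                if run >= stop_run:
                    break
    out = pd.DataFrame(rows, columns=["locus", "linkage_group", "cM", "in_block"])
    out.attrs["modal_group"] = modal
    out.attrs["modal_fraction"] = modal_frac
    return out
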