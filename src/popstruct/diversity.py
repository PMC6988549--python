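"""Nei pairwise F_st between collection localities.

For a pair of localities the multilocus estimator is the ratio of sums
F_st = sum_l (H_t - H_s) / sum_l H_t over loci with data in both members,
where H_s is the unweighted mean of the two localities' expected
heterozygosities 2p(1-p) and H_t the expected heterozygosity at the pooled
allele frequency (weighted by observed allele counts).  Ratio-of-sums is
the standard multilocus G_st form and is stable at low-diversity loci.
Localities with fewer genotyped individuals than ``min_n`` are excluded
before any pair is computed.  Negative estimates are reported as computed
(flagged, never clamped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .vcf_io import MISSING, GenotypeMatrix, SampleTable


@dataclass
class FstMatrix:
    localities: list
    matrix: np.ndarray            # symmetric, zero diagonal, NaN = undefined
    sample_sizes: dict            # locality -> n genotyped individuals

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.localities, columns=self.localities)


def nei_pairwise_fst(gm: GenotypeMatrix, st: SampleTable, min_n: int = 18) -> FstMatrix:
    """Pairwise Nei F_st over all locality pairs with >= ``min_n`` individuals."""
    st = st.aligned_to(gm)
    loc = st.table["locality_id"].to_numpy()
    sizes = pd.Series(loc).value_counts()
    kept = sorted(sizes.index[sizes >= min_n])
    if len(kept) < 2:
        raise ValueError(f"fewer than two localities with >= {min_n} individuals")

    # Per-locality per-locus alt counts and observed allele counts.
    alt = {}
    cnt = {}
    for l in kept:
        rows = np.flatnonzero(loc == l)
        sub = gm.codes[rows, :]
        obs = sub != MISSING
        alt[l] = np.where(obs, sub, 0).sum(axis=0).astype(float)
        cnt[l] = 2.0 * obs.sum(axis=0)

    L = len(kept)
    M = np.zeros((L, L))
    n_undef = 0
    for a in range(L):
        for b in range(a + 1, L):
            la, lb = kept[a], kept[b]
            ok = (cnt[la] > 0) & (cnt[lb] > 0)
            if not ok.any():
                M[a, b] = M[b, a] = np.nan
                n_undef += 1
                continue
            pa = alt[la][ok] / cnt[la][ok]
            pb = alt[lb][ok] / cnt[lb][ok]
            hs = (2 * pa * (1 - pa) + 2 * pb * (1 - pb)) / 2.0
            pooled = (alt[la][ok] + alt[lb][ok]) / (cnt[la][ok] + cnt[lb][ok])
            ht = 2 * pooled * (1 - pooled)
            denom = ht.sum()
            if denom <= 0:
                M[a, b] = M[b, a] = np.nan
                n_undef += 1
                continue
            M[a, b] = M[b, a] = (ht.sum() - hs.sum()) / denom
    if n_undef:
        warnings.warn(f"{n_undef} locality pairs undefined (no informative loci)")
    if np.nanmin(M) < 0:
        warnings.warn("negative pairwise Fst estimates present (reported unclamped)")
    return FstMatrix(localities=kept, matrix=M,
                     sample_sizes={l: int(sizes[l]) for l in kept})


def fst_group_summary(fm: FstMatrix, locality_to_group: Mapping[str, str]) -> pd.DataFrame:
    """Min/mean/max of pairwise F_st between and within subpopulation groups.

    Rows: one per unordered group pair (within-group rows have
    ``group_a == group_b``).  Groups contributing fewer than two localities
    have an undefined (NaN) within-group summary, flagged by n_pairs = 0.
    """
    if not locality_to_group:
        raise ValueError("empty locality-to-group mapping")
    unmapped = [l for l in fm.localities if l not in locality_to_group]
    if unmapped:
        raise ValueError(f"localities missing from mapping: {unmapped[:5]}")
    groups = sorted(set(locality_to_group[l] for l in fm.localities))
    idx = {g: [i for i, l in enumerate(fm.localities) if locality_to_group[l] == g]
           for g in groups}
    rows = []
    for gi, ga in enumerate(groups):
        for gb in groups[gi:]:
            vals = []
            if ga == gb:
                members = idx[ga]
                for x in range(len(members)):
                    for y in range(x + 1, len(members)):
                        vals.append(fm.matrix[members[x], members[y]])
            else:
                for x in idx[ga]:
                    for y in idx[gb]:
                        vals.append(fm.matrix[x, y])
            vals = np.asarray([v for v in vals if np.isfinite(v)])
            if vals.size == 0:
                rows.append((ga, gb, 0, np.nan, np.nan, np.nan))
                if ga == gb:
                    warnings.warn(f"within-group summary undefined for {ga!r} "
                                  "(fewer than two localities)")
            else:
                rows.append((ga, gb, int(vals.size), float(vals.min()),
                             float(vals.mean()), float(vals.max())))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_pairs",
                                       "min", "mean", "max"])
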