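"""Chi-square / fold-enrichment machinery for selection-scan tails.

The same 2x2 machinery serves functional-class enrichment (non-synonymous
vs synonymous in scan tails), category enrichment with Benjamini-Hochberg
FDR, and GWAS-hit enrichment after MAF/P filtering. Tail membership is
passed in as flags so any scan (PHS, F_ST, diversity, imported tracks) can
feed it.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def chi2_table(counts_2x2) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table,
    df = 1. Raises on a zero row/column margin."""
    t = np.asarray(counts_2x2, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def _enrich_row(tail_c: int, tail_ref: int, out_c: int, out_ref: int):
    """Fold enrichment and chi-square of one category against its
    reference set; fold is (tail proportion)/(background proportion)."""
    tail_tot = tail_c + tail_ref
    out_tot = out_c + out_ref
    fold = np.nan
    if tail_tot > 0 and out_tot > 0 and out_c > 0:
        fold = (tail_c / tail_tot) / (out_c / out_tot)
    try:
        stat, p = chi2_table([[tail_c, tail_ref], [out_c, out_ref]])
    except ValueError:
        stat, p = np.nan, np.nan
    return fold, stat, p


def tail_enrichment(snp_classes, tail_flags, reference: str | None = None
                    ) -> pd.DataFrame:
    """Enrichment of each class in the scan tail.

    snp_classes and tail_flags are aligned arrays (one entry per SNP).
    With reference=None each category is tested against all others; with
    an explicit reference class (e.g. 'synonymous') each category is tested
    against that class only. BH-adjusted FDR is computed across the tested
    categories. Categories with no members anywhere are skipped.
    """
    cls = np.asarray(snp_classes, dtype=object)
    tail = np.asarray(tail_flags, dtype=bool)
    if len(cls) != len(tail):
        raise ValueError("snp_classes and tail_flags must align")
    rows = []
    for cat in pd.unique(cls):
        if reference is not None and cat == reference:
            continue
        is_cat = cls == cat
        if reference is None:
            is_ref = ~is_cat
        else:
            is_ref = cls == reference
        tail_c = int((tail & is_cat).sum())
        out_c = int((~tail & is_cat).sum())
        tail_ref = int((tail & is_ref).sum())
        out_ref = int((~tail & is_ref).sum())
        if tail_c + out_c == 0 or tail_ref + out_ref == 0:
            log.info("category %s absent; skipped", cat)
            continue
        fold, stat, p = _enrich_row(tail_c, tail_ref, out_c, out_ref)
        rows.append((cat, tail_c, out_c, tail_ref, out_ref, fold, stat, p))
    table = pd.DataFrame(rows, columns=["category", "n_tail", "n_background",
                                        "ref_tail", "ref_background", "fold",
                                        "chi2", "p"])
    table["fdr"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "fdr"] = multipletests(table.loc[ok, "p"],
                                             method="fdr_bh")[1]
    return table


def gwas_tail_enrichment(gwas_table: pd.DataFrame, tail_flags: pd.DataFrame,
                         maf_floor: float = 0.03, p_ceiling: float = 1e-3
                         ) -> dict:
    """Enrichment of filtered GWAS hits in the scan tail.

    gwas_table: chrom, pos, P, MAF per tested SNP. tail_flags: chrom, pos,
    tail (bool) for the scan's SNP universe. Hits are GWAS SNPs passing
    MAF > maf_floor and P < p_ceiling; fold compares hit density inside vs
    outside the tail.
    """
    uni = tail_flags[["chrom", "pos", "tail"]].drop_duplicates(["chrom", "pos"])
    merged = uni.merge(gwas_table[["chrom", "pos", "P", "MAF"]],
                       on=["chrom", "pos"], how="left")
    is_hit = ((merged["MAF"] > maf_floor)
              & (merged["P"] < p_ceiling)).fillna(False).to_numpy()
    if is_hit.sum() == 0:
        raise ValueError("no GWAS SNP survives the MAF/P filters")
    in_tail = merged["tail"].to_numpy(bool)
    hit_in = int((is_hit & in_tail).sum())
    hit_out = int((is_hit & ~in_tail).sum())
    non_in = int((~is_hit & in_tail).sum())
    non_out = int((~is_hit & ~in_tail).sum())
    tail_fraction = float(in_tail.mean())
    # fold = fraction of hits landing in the tail / tail's share of all SNPs
    fold = (hit_in / is_hit.sum()) / tail_fraction if tail_fraction > 0 else np.nan
    try:
        stat, p = chi2_table([[hit_in, non_in], [hit_out, non_out]])
    except ValueError:
        stat, p = np.nan, np.nan
    return {"n_hits": int(is_hit.sum()), "hits_in_tail": hit_in,
            "tail_fraction": tail_fraction,
            "fold": float(fold), "chi2": stat, "p": p}
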