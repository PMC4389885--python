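"""Per-site and sliding-window diversity statistics.

Nucleotide diversity pi, Tajima's D, Hudson's F_ST, LD r-squared, the
SNP-hiding probability, donor-allele introgression windows, and empirical
percentile outlier calling over windows. Lines are inbred and treated as
single haplotypes; all statistics use non-missing homozygous calls only.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .panel import ALT, REF, GenotypePanel
from .regions import SweepRegion, merge_adjacent, windows_on

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_pi(allele_count: int, n: int) -> float:
    """Unbiased per-site heterozygosity: pi = 2 p (1-p) n/(n-1)."""
    if n < 2:
        raise ValueError("site_pi needs >= 2 haplotypes")
    if not 0 <= allele_count <= n:
        raise ValueError("allele count outside [0, n]")
    p = allele_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def _site_arrays(panel: GenotypePanel):
    """(n_alt, n_called, pi) arrays over all variants; pi is NaN for n<2."""
    n_ref, n_alt = panel.allele_counts()
    n = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = n_alt / np.maximum(n, 1)
        pi = np.where(n >= 2, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1),
                      np.nan)
    return n_alt, n, pi


def tajima_constants(n: int) -> dict[str, float]:
    """The standard segregating-sites normalisation constants for sample
    size n (a1, a2, b1, b2, c1, c2, e1, e2)."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, n_segregating: int, n: int) -> float:
    """Tajima's D from the summed pairwise diversity and segregating-site
    count at sample size n (NaN when S = 0 or n < 2)."""
    if n_segregating == 0 or n < 2:
        return float("nan")
    k = tajima_constants(n)
    S = n_segregating
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / k["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def _chrom_lengths(panel: GenotypePanel,
                   chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    derived = {c: int(sub["pos"].max())
               for c, sub in panel.variants.groupby("chrom", sort=False)}
    if chrom_lengths is not None:
        derived.update(chrom_lengths)
    return derived


def window_diversity(panel: GenotypePanel, win_bp: int = 2_000_000,
                     step_bp: int = 1_000_000, min_covered_bp: int = 10_000,
                     chrom_lengths: dict[str, int] | None = None,
                     covered_bp: dict[tuple[str, int], int] | None = None
                     ) -> pd.DataFrame:
    """Sliding-window pi (per covered bp) and Tajima's D.

    Returns long-format window rows (chrom, start, end, subgenome,
    statistic, value, n_snps, covered_bp). Tajima's D uses the window's
    median non-missing sample size; windows with fewer than min_covered_bp
    covered bases get value NaN and are excluded from outlier calling.
    An optional covered_bp mapping (chrom, start) -> covered bases stands in
    for a real coverage track; by default windows count as fully covered.
    """
    n_alt, n_called, pi = _site_arrays(panel)
    seg = (n_alt > 0) & (n_alt < n_called)
    lengths = _chrom_lengths(panel, chrom_lengths)
    rows = []
    v = panel.variants
    for chrom, sub in v.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos0 = sub["pos"].to_numpy() - 1  # 0-based
        sg = sub["subgenome"].iat[0]
        clen = lengths[chrom]
        for start in windows_on(clen, win_bp, step_bp):
            end = int(start + win_bp)
            cov = int(min(end, clen) - start)
            if covered_bp is not None:
                cov = int(covered_bp.get((chrom, int(start)), cov))
            in_win = (pos0 >= start) & (pos0 < end)
            widx = idx[in_win]
            nsnp = int(len(widx))
            if cov < min_covered_bp:
                pi_val = d_val = float("nan")
            else:
                pi_sum = float(np.nansum(pi[widx])) if nsnp else 0.0
                S = int(seg[widx].sum()) if nsnp else 0
                pi_val = pi_sum / cov
                if S > 0:
                    n_med = int(np.median(n_called[widx][seg[widx]]))
                    d_val = tajimas_d(pi_sum, S, n_med)
                else:
                    d_val = float("nan")
            rows.append((chrom, int(start), end, sg, "pi", pi_val, nsnp, cov))
            rows.append((chrom, int(start), end, sg, "tajimas_d", d_val,
                         nsnp, cov))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "subgenome",
                                       "statistic", "value", "n_snps",
                                       "covered_bp"])


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _group_indices(panel: GenotypePanel, groups) -> tuple[list[int], list[int]]:
    if isinstance(groups, dict):
        (g1, lines1), (g2, lines2) = list(groups.items())
        return ([panel.lines.index(x) for x in lines1],
                [panel.lines.index(x) for x in lines2])
    g1, g2 = groups
    l1 = panel.group_lines(g1)
    l2 = panel.group_lines(g2)
    if not l1 or not l2:
        raise ValueError(f"group(s) absent from panel metadata: {groups}")
    return ([panel.lines.index(x) for x in l1],
            [panel.lines.index(x) for x in l2])


def fst_per_snp(panel: GenotypePanel,
                groups=("cultivar", "landrace")) -> np.ndarray:
    """Hudson's F_ST estimator per SNP between two line groups.

    Negative estimates are retained. NaN where either group has fewer than
    2 non-missing haplotypes or the between-group heterozygosity is zero.
    """
    i1, i2 = _group_indices(panel, groups)
    out = np.full(panel.n_variants, np.nan)
    for which, sel in ((0, i1), (1, i2)):
        calls = panel.calls[:, sel]
        n_alt = (calls == ALT).sum(axis=1).astype(float)
        n = ((calls == ALT) | (calls == REF)).sum(axis=1).astype(float)
        if which == 0:
            n1, a1 = n, n_alt
        else:
            n2, a2 = n, n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / n1
        p2 = a2 / n2
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        valid = (n1 >= 2) & (n2 >= 2) & (den > 0)
        out[valid] = (num / den)[valid]
    return out


def fst_overall(panel: GenotypePanel,
                groups=("cultivar", "landrace")) -> float:
    """Genome-wide Hudson F_ST as a ratio of means (summing the estimator's
    numerator and denominator over SNPs before dividing), the standard
    aggregate that avoids the per-SNP ratio bias."""
    i1, i2 = _group_indices(panel, groups)
    parts = []
    for sel in (i1, i2):
        calls = panel.calls[:, sel]
        n_alt = (calls == ALT).sum(axis=1).astype(float)
        n = ((calls == ALT) | (calls == REF)).sum(axis=1).astype(float)
        parts.append((n_alt, n))
    (a1, n1), (a2, n2) = parts
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (n1 >= 2) & (n2 >= 2) & (den > 0)
    if not ok.any():
        raise ValueError("no usable SNPs for F_ST")
    return float(num[ok].sum() / den[ok].sum())


def window_fst(panel: GenotypePanel, groups=("cultivar", "landrace"),
               win_bp: int = 2_000_000, step_bp: int = 1_000_000,
               chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sliding-window mean of per-SNP Hudson F_ST values."""
    per_snp = fst_per_snp(panel, groups)
    lengths = _chrom_lengths(panel, chrom_lengths)
    rows = []
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        sg = sub["subgenome"].iat[0]
        for start in windows_on(lengths[chrom], win_bp, step_bp):
            end = int(start + win_bp)
            widx = idx[(pos0 >= start) & (pos0 < end)]
            vals = per_snp[widx]
            vals = vals[~np.isnan(vals)]
            value = float(vals.mean()) if len(vals) else float("nan")
            rows.append((chrom, int(start), end, sg, "fst", value,
                         int(len(vals)), int(min(end, lengths[chrom]) - start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "subgenome",
                                       "statistic", "value", "n_snps",
                                       "covered_bp"])


# ---------------------------------------------------------------------------
# outlier calling
# ---------------------------------------------------------------------------

def call_outlier_windows(stats: pd.DataFrame, tail_fraction: float = 0.025,
                         tails: str = "upper") -> pd.DataFrame:
    """Flag windows beyond per-subgenome empirical percentile thresholds.

    Thresholds are the linear-interpolation (type-7) quantiles of the
    defined window values within each (subgenome, statistic) group; ties at
    the threshold are flagged. tails is 'upper', 'lower' or 'both'.
    """
    if tails not in ("upper", "lower", "both"):
        raise ValueError("tails must be upper|lower|both")
    out = stats.copy()
    out["outlier"] = False
    out["tail"] = "none"
    for (sg, stat), sub in out.groupby(["subgenome", "statistic"], sort=False):
        vals = sub["value"].to_numpy(float)
        defined = ~np.isnan(vals)
        if defined.sum() < 40:
            log.warning("only %d defined windows for %s/%s; thresholds "
                        "unstable", int(defined.sum()), sg, stat)
        if defined.sum() == 0:
            continue
        v = vals[defined]
        if tails in ("upper", "both"):
            thr = np.quantile(v, 1.0 - tail_fraction)
            sel = sub.index[defined][v >= thr]
            out.loc[sel, ["outlier", "tail"]] = [True, "upper"]
        if tails in ("lower", "both"):
            thr = np.quantile(v, tail_fraction)
            sel = sub.index[defined][v <= thr]
            out.loc[sel, ["outlier", "tail"]] = [True, "lower"]
    return out


def outlier_regions(flagged: pd.DataFrame, max_gap_bp: int = 0,
                    source: str = "scan") -> list[SweepRegion]:
    """Merge flagged outlier windows into regions (see regions.merge_adjacent)."""
    return merge_adjacent(flagged[flagged["outlier"]], max_gap_bp, source)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _hap_r2(gi: np.ndarray, gj: np.ndarray) -> float:
    """Haplotype r^2 over lines homozygous non-missing at both sites
    (NaN if either site is monomorphic after pairwise deletion)."""
    ok = ((gi == REF) | (gi == ALT)) & ((gj == REF) | (gj == ALT))
    a, b = gi[ok] == ALT, gj[ok] == ALT
    n = ok.sum()
    if n < 2:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (a & b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_r2(panel: GenotypePanel, min_maf: float = 0.05,
          max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """Pairwise haplotype r^2 for SNP pairs within max_dist_bp, both with
    MAF >= min_maf. Returns chrom, pos_i, pos_j, dist, r2."""
    maf = panel.maf()
    eligible = np.nan_to_num(maf, nan=-1) >= min_maf
    rows = []
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()[eligible[sub.index.to_numpy()]]
        pos = panel.variants["pos"].to_numpy()[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = int(pos[b] - pos[a])
                if dist > max_dist_bp:
                    break
                r2 = _hap_r2(panel.calls[idx[a]], panel.calls[idx[b]])
                if not np.isnan(r2):
                    rows.append((chrom, int(pos[a]), int(pos[b]), dist, r2))
    return pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "dist", "r2"])


def snp_hiding_test(panel: GenotypePanel,
                    distance_bins=((0, 2_000), (2_000, 4_000)),
                    r2_threshold: float = 0.8, seed: int = 0,
                    min_maf: float = 0.05,
                    max_snps: int | None = None) -> pd.DataFrame:
    """Probability that a SNP has a high-LD partner within a distance bin.

    For each eligible SNP and each bin (lo, hi], success means some other
    eligible SNP at distance in the bin has r^2 > r2_threshold. The
    probability is successes over SNPs that have at least one neighbour in
    the bin; bins without any such SNP are omitted.
    """
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    eligible = np.flatnonzero(np.nan_to_num(maf, nan=-1) >= min_maf)
    if max_snps is not None and len(eligible) > max_snps:
        eligible = np.sort(rng.choice(eligible, size=max_snps, replace=False))
    chroms = panel.variants["chrom"].to_numpy(object)
    pos = panel.variants["pos"].to_numpy()
    by_chrom = {c: eligible[chroms[eligible] == c]
                for c in pd.unique(chroms[eligible])}
    results = []
    for lo, hi in distance_bins:
        trials = successes = 0
        for c, idx in by_chrom.items():
            p = pos[idx]
            for k in range(len(idx)):
                dist = np.abs(p - p[k])
                nb = idx[(dist > lo) & (dist <= hi) & (idx != idx[k])]
                if len(nb) == 0:
                    continue
                trials += 1
                if any(_hap_r2(panel.calls[idx[k]], panel.calls[j])
                       > r2_threshold for j in nb):
                    successes += 1
        if trials:
            results.append((f"({lo},{hi}]", trials, successes,
                            successes / trials))
    return pd.DataFrame(results, columns=["bin", "n_trials", "n_success",
                                          "probability"])


# ---------------------------------------------------------------------------
# donor (outgroup accession) allele windows
# ---------------------------------------------------------------------------

def donor_allele_windows(panel: GenotypePanel, donor_table: pd.DataFrame,
                         lines_subset: list[str] | None = None,
                         win_bp: int = 3_000_000,
                         step_bp: int | None = None,
                         chrom_lengths: dict[str, int] | None = None
                         ) -> pd.DataFrame:
    """Mean donor-allele frequency per sliding window.

    donor_table has columns chrom, pos, allele naming the donor accession's
    allele; sites where it matches neither panel allele are uninformative.
    Windows without an informative SNP get value NaN.
    """
    sub_panel = panel.take_lines(lines_subset) if lines_subset else panel
    v = sub_panel.variants.merge(
        donor_table[["chrom", "pos", "allele"]].drop_duplicates(["chrom", "pos"]),
        on=["chrom", "pos"], how="left")
    n_ref, n_alt = sub_panel.allele_counts()
    tot = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(tot > 0, n_ref / np.maximum(tot, 1), np.nan)
        p_alt = np.where(tot > 0, n_alt / np.maximum(tot, 1), np.nan)
    donor_freq = np.where(v["allele"] == v["ref"], p_ref,
                          np.where(v["allele"] == v["alt"], p_alt, np.nan))
    lengths = _chrom_lengths(sub_panel, chrom_lengths)
    rows = []
    step = step_bp or win_bp
    for chrom, subv in v.groupby("chrom", sort=False):
        idx = subv.index.to_numpy()
        pos0 = subv["pos"].to_numpy() - 1
        sg = subv["subgenome"].iat[0]
        for start in windows_on(lengths[chrom], win_bp, step):
            end = int(start + win_bp)
            widx = idx[(pos0 >= start) & (pos0 < end)]
            vals = donor_freq[widx]
            vals = vals[~np.isnan(vals)]
            value = float(vals.mean()) if len(vals) else float("nan")
            rows.append((chrom, int(start), end, sg, "donor_freq", value,
                         int(len(vals)), int(min(end, lengths[chrom]) - start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "subgenome",
                                       "statistic", "value", "n_snps",
                                       "covered_bp"])
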