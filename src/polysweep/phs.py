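"""Pairwise haplotype sharing (PHS) selection scan.

For every pair of lines and every focal SNP, d_ijx is the genetic length
(cM) of the maximal interval around the SNP over which the two lines carry
identical non-missing alleles (boundaries at the first discordant SNP on
each side, or the chromosome's terminal SNP). Each pair's d values are
Z-standardised by the pair's mean and SD pooled over all focal SNPs in the
subgenome; the PHS of an allele at a SNP is the mean Z over carrier pairs
minus the mean Z over all pairs. Large values mean the allele sits on an
unusually long shared haplotype — the footprint of recent positive
selection on an allele at intermediate frequency.

Outliers are called against empirical percentile thresholds within carrier
frequency classes, and flagged SNPs are collapsed into 50-kb windows that
are merged into sweep regions.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .panel import ALT, REF, GenotypePanel
from .regions import SweepRegion

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PairSharing:
    """Shared-haplotype lengths for all line pairs of one subgenome.

    d has shape (n_pairs, n_snps); NaN where a pair is missing at the focal
    SNP. mean/sd are pooled over all focal SNPs (all chromosomes of the
    subgenome); pairs informative at fewer than the minimum SNP count have
    mean = sd = NaN and are excluded from every PHS sum.
    """

    subgenome: str
    pair_i: np.ndarray
    pair_j: np.ndarray
    d: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    variant_index: np.ndarray  # global panel indices of the columns

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)


def pair_sharing(panel: GenotypePanel, min_informative: int = 10
                 ) -> PairSharing:
    """Compute d_ijx for every pair over a single-subgenome panel.

    Missing calls are skipped, never treated as mismatches; the shared
    segment boundary is the position of the first discordant SNP, or the
    chromosome's terminal SNP when a side has none.
    """
    sgs = panel.variants["subgenome"].unique()
    if len(sgs) != 1:
        raise ValueError("pair_sharing expects a single-subgenome panel; "
                         "pooling across subgenomes is disallowed")
    if panel.n_lines < 3:
        raise ValueError("need >= 3 lines")
    n = panel.n_lines
    pair_i, pair_j = np.triu_indices(n, k=1)
    d = np.full((len(pair_i), panel.n_variants), np.nan)

    chrom_slices = []
    for chrom, sub in panel.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        chrom_slices.append((idx, sub["cm"].to_numpy(float)))

    calls = panel.calls
    hom = (calls == REF) | (calls == ALT)
    for p, (i, j) in enumerate(zip(pair_i, pair_j)):
        gi, gj = calls[:, i], calls[:, j]
        both_all = hom[:, i] & hom[:, j]
        for idx, cm in chrom_slices:
            both = both_all[idx]
            focal = np.flatnonzero(both)
            if len(focal) == 0:
                continue
            disc = np.flatnonzero(both & (gi[idx] != gj[idx]))
            if len(disc) == 0:
                d[p, idx[focal]] = cm[-1] - cm[0]
                continue
            left_rank = np.searchsorted(disc, focal, side="left")
            right_rank = np.searchsorted(disc, focal, side="right")
            left_cm = np.where(left_rank > 0,
                               cm[disc[np.maximum(left_rank - 1, 0)]], cm[0])
            right_cm = np.where(right_rank < len(disc),
                                cm[disc[np.minimum(right_rank, len(disc) - 1)]],
                                cm[-1])
            d[p, idx[focal]] = right_cm - left_cm

    counts = np.sum(~np.isnan(d), axis=1)
    mean = np.full(len(pair_i), np.nan)
    sd = np.full(len(pair_i), np.nan)
    ok = counts >= min_informative
    if (~ok).any():
        log.info("pair_sharing: %d pair(s) informative at <%d SNPs excluded",
                 int((~ok).sum()), min_informative)
    mean[ok] = np.nanmean(d[ok], axis=1)
    sd[ok] = np.nanstd(d[ok], axis=1)  # population SD (ddof=0)
    return PairSharing(str(sgs[0]), pair_i, pair_j, d, mean, sd,
                       panel.variants.index.to_numpy())


def phs(panel: GenotypePanel, profile: PairSharing, snp: int,
        allele: int) -> float:
    """PHS of one allele (REF or ALT code) at one SNP of a single-subgenome
    panel: mean Z over carrier pairs minus mean Z over all pairs, skipping
    pairs with sd = 0/undefined or missing at the focal SNP. NaN when no
    valid carrier pair exists."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (profile.d[:, snp] - profile.mean) / profile.sd
    valid = np.isfinite(z) & (profile.sd > 0)
    carrier = panel.calls[snp] == allele
    pair_in = carrier[profile.pair_i] & carrier[profile.pair_j]
    if carrier.sum() < 2 or not np.any(valid & pair_in):
        return float("nan")
    return float(z[valid & pair_in].mean() - z[valid].mean())


def compute_phs(panel: GenotypePanel, max_carrier_freq: float = 0.95,
                alleles: str = "both", min_informative: int = 10
                ) -> pd.DataFrame:
    """PHS for every SNP/allele of a panel, per subgenome.

    alleles='both' scores reference and alternate alleles with >= 2
    carriers and carrier frequency <= max_carrier_freq; alleles='derived'
    scores only the derived allele at ancestral-assigned sites.
    Returns chrom, pos, subgenome, vidx, allele, carrier_count,
    carrier_freq, phs.
    """
    rows = []
    for sg in panel.variants["subgenome"].unique():
        sub = panel.subgenome(sg)
        profile = pair_sharing(sub, min_informative=min_informative)
        valid_pair = np.isfinite(profile.mean) & (profile.sd > 0)
        calls = sub.calls
        anc = sub.variants.get("ancestral")
        for x in range(sub.n_variants):
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (profile.d[:, x] - profile.mean) / profile.sd
            valid = np.isfinite(z) & valid_pair
            if not valid.any():
                continue
            all_mean = z[valid].mean()
            if alleles == "both":
                test_alleles = (REF, ALT)
            else:
                if anc is None or anc.iat[x] not in ("ref", "alt"):
                    continue
                test_alleles = (ALT,) if anc.iat[x] == "ref" else (REF,)
            n_called = int(((calls[x] == REF) | (calls[x] == ALT)).sum())
            if n_called == 0:
                continue
            for code in test_alleles:
                carrier = calls[x] == code
                p = int(carrier.sum())
                freq = p / n_called
                if p < 2 or freq > max_carrier_freq:
                    continue
                pair_in = carrier[profile.pair_i] & carrier[profile.pair_j]
                sel = valid & pair_in
                if not sel.any():
                    continue
                val = float(z[sel].mean() - all_mean)
                row = sub.variants.iloc[x]
                rows.append((row["chrom"], int(row["pos"]), sg,
                             int(profile.variant_index[x]),
                             "ref" if code == REF else "alt", p, freq, val))
    return pd.DataFrame(rows, columns=["chrom", "pos", "subgenome", "vidx",
                                       "allele", "carrier_count",
                                       "carrier_freq", "phs"])


def phs_thresholds(results: pd.DataFrame, bin_width: float = 0.05,
                   tail_fraction: float = 0.025, min_bin_count: int = 200
                   ) -> pd.DataFrame:
    """Flag PHS outliers against per-frequency-class percentile thresholds.

    Carrier frequencies are binned into classes of bin_width on (0, 1]; the
    threshold is the empirical (1 - tail_fraction) quantile of PHS values in
    the class (per subgenome). Classes with fewer than min_bin_count values
    fall back to the subgenome's pooled threshold. Outliers are strictly
    above their threshold.
    """
    if len(results) == 0:
        raise ValueError("empty PHS results")
    out = results.copy()
    nbins = int(np.ceil(1.0 / bin_width))
    fbin = np.minimum(np.ceil(out["carrier_freq"].to_numpy() / bin_width
                              - 1e-12).astype(int) - 1, nbins - 1)
    out["freq_bin"] = np.maximum(fbin, 0)
    out["threshold"] = np.nan
    for sg, sub in out.groupby("subgenome", sort=False):
        pooled = float(np.quantile(sub["phs"].to_numpy(), 1 - tail_fraction))
        for b, bsub in sub.groupby("freq_bin", sort=False):
            if len(bsub) < min_bin_count:
                log.info("PHS bin %s/%d has %d values; pooled threshold used",
                         sg, b, len(bsub))
                thr = pooled
            else:
                thr = float(np.quantile(bsub["phs"].to_numpy(),
                                        1 - tail_fraction))
            out.loc[bsub.index, "threshold"] = thr
    out["outlier"] = out["phs"] > out["threshold"]
    return out


def call_sweeps(flagged_results: pd.DataFrame, window_bp: int = 50_000,
                merge_gap_bp: int = 1_000_000, source: str = "phs"
                ) -> list[SweepRegion]:
    """Collapse outlier SNPs into windows and merge nearby windows.

    A window is flagged when it contains >= 1 outlier SNP and is assigned
    the maximum PHS among them; flagged windows whose gap is <=
    merge_gap_bp are merged. Each region records its peak SNP/allele.
    """
    hits = flagged_results[flagged_results["outlier"]]
    regions: list[SweepRegion] = []
    if len(hits) == 0:
        return regions
    hits = hits.assign(win=(hits["pos"].to_numpy() - 1) // window_bp)
    for chrom, sub in hits.sort_values(["chrom", "pos"]).groupby("chrom",
                                                                 sort=False):
        cur = None
        for w, wsub in sub.groupby("win", sort=True):
            start = int(w * window_bp)
            end = start + window_bp
            peak = wsub.loc[wsub["phs"].idxmax()]
            if cur is None or start - cur.end > merge_gap_bp:
                cur = SweepRegion(chrom, start, end, source, 1,
                                  float(peak["phs"]), int(peak["pos"]),
                                  str(peak["allele"]))
                regions.append(cur)
            else:
                cur.end = end
                cur.n_windows += 1
                if peak["phs"] > cur.peak_value:
                    cur.peak_value = float(peak["phs"])
                    cur.peak_pos = int(peak["pos"])
                    cur.peak_allele = str(peak["allele"])
    return regions
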