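"""Genotype error-rate, concordance, and capture-efficiency arithmetic.

Comparisons are restricted to homozygous, non-missing calls present on both
sides; reported rates are rounded half-up to one decimal while raw counts
are retained for exact tests.
"""
from __future__ import annotations

import dataclasses
import decimal
import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _round1(x: float) -> float:
    return float(decimal.Decimal(x).quantize(decimal.Decimal("0.1"),
                                             rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass
class ConcordanceReport:
    n_compared: int
    n_discordant: int
    mode: str  # 'error' or 'concordance'
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not 0 <= self.n_discordant <= self.n_compared:
            raise ValueError("need 0 <= n_discordant <= n_compared")
        if self.mode not in ("error", "concordance"):
            raise ValueError("mode must be 'error' or 'concordance'")

    @property
    def rate(self) -> float:
        """Percent, rounded half-up to one decimal."""
        raw = 100.0 * self.n_discordant / self.n_compared
        if self.mode == "concordance":
            raw = 100.0 - raw
        return _round1(raw)

    @classmethod
    def from_counts(cls, n_compared: int, n_discordant: int,
                    mode: str = "error", stratum: str = "all"):
        return cls(n_compared, n_discordant, mode, stratum)


_KEY = ["chrom", "pos", "sample"]


def _paired_hom_calls(calls: pd.DataFrame, truth_calls: pd.DataFrame
                      ) -> pd.DataFrame:
    """Intersection of non-missing homozygous calls keyed by
    (chrom, pos, sample); call columns must be named 'call'."""
    def clean(df):
        df = df[_KEY + ["call"]].copy()
        return df[df["call"].isin([0, 1])]
    return clean(calls).merge(clean(truth_calls), on=_KEY,
                              suffixes=("", "_truth"))


def error_rate(calls: pd.DataFrame, truth_calls: pd.DataFrame,
               mode: str = "error") -> ConcordanceReport:
    """Compare a call set against truth calls over the intersection of
    homozygous non-missing genotypes.

    Both inputs are DataFrames with columns chrom, pos, sample, call where
    call uses the panel coding (0 ref-hom, 1 alt-hom; het/missing dropped).
    """
    paired = _paired_hom_calls(calls, truth_calls)
    if len(paired) == 0:
        raise ValueError("no overlapping homozygous calls to compare")
    n_disc = int((paired["call"] != paired["call_truth"]).sum())
    return ConcordanceReport(len(paired), n_disc, mode)


def stratified_error_rate(calls: pd.DataFrame, truth_calls: pd.DataFrame,
                          depth_table: pd.DataFrame,
                          bin_edges=None, cutoff: float | None = None,
                          mode: str = "error") -> list[ConcordanceReport]:
    """Error/concordance rate per read-depth bin (or for depth >= cutoff).

    depth_table has columns chrom, pos, sample, depth. Empty bins are
    omitted with a warning.
    """
    paired = _paired_hom_calls(calls, truth_calls)
    paired = paired.merge(depth_table[_KEY + ["depth"]], on=_KEY, how="inner")
    if len(paired) == 0:
        raise ValueError("no overlapping calls with depth information")
    disc = (paired["call"] != paired["call_truth"]).to_numpy()
    depth = paired["depth"].to_numpy(float)
    reports = []
    if cutoff is not None:
        sel = depth >= cutoff
        if sel.sum() == 0:
            log.warning("no calls at depth >= %s", cutoff)
        else:
            reports.append(ConcordanceReport(int(sel.sum()),
                                             int(disc[sel].sum()), mode,
                                             stratum=f"depth>={cutoff:g}"))
        return reports
    edges = np.asarray(bin_edges, dtype=float)
    for lo, hi in zip(edges, edges[1:]):
        sel = (depth >= lo) & (depth < hi)
        if sel.sum() == 0:
            log.warning("empty depth bin [%g, %g)", lo, hi)
            continue
        reports.append(ConcordanceReport(int(sel.sum()), int(disc[sel].sum()),
                                         mode, stratum=f"[{lo:g},{hi:g})"))
    return reports


# ---------------------------------------------------------------------------
# homoeologous capture efficiency
# ---------------------------------------------------------------------------

PAIRS = (("A", "B"), ("A", "D"), ("B", "D"))


@dataclasses.dataclass
class CaptureRatioSet:
    """log2 coverage-depth ratios between subgenome copies of homoeologous
    gene triplets, plus per-pair mean/SD summaries."""

    ratios: pd.DataFrame  # columns: gene, log2_A_B, log2_A_D, log2_B_D
    n_excluded: int  # triplets with a zero depth

    def summary(self) -> pd.DataFrame:
        rows = []
        for x, y in PAIRS:
            col = self.ratios[f"log2_{x}_{y}"]
            rows.append((f"{x}/{y}", col.mean(), col.std(ddof=1), len(col)))
        return pd.DataFrame(rows, columns=["pair", "mean", "sd", "n"])


def capture_ratios(depth_by_triplet: pd.DataFrame) -> CaptureRatioSet:
    """Per-triplet pairwise log2 depth ratios.

    Input columns: gene, depth_A, depth_B, depth_D. Triplets with any
    non-positive depth are excluded and counted.
    """
    d = depth_by_triplet
    ok = (d[["depth_A", "depth_B", "depth_D"]] > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    d = d[ok]
    if len(d) == 0:
        raise ValueError("no triplet with positive depths in all subgenomes")
    out = pd.DataFrame({"gene": d["gene"].to_numpy()})
    for x, y in PAIRS:
        out[f"log2_{x}_{y}"] = np.log2(d[f"depth_{x}"].to_numpy(float)
                                       / d[f"depth_{y}"].to_numpy(float))
    return CaptureRatioSet(out, n_excluded)
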