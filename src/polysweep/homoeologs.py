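"""Cross-subgenome projection of sweep regions and overlap testing.

A homoeolog anchor map (ordered gene triplets with positions in the A, B
and D subgenomes) supports projecting an interval from one subgenome to
another via its nearest flanking anchors. The significance of observed
sweep overlap between two subgenomes is assessed by permuting sweep-window
labels uniformly over all genome-wide 50-kb windows (preserving per-genome
counts) and ranking the observed overlap proportion, with the +1 empirical
P correction so P is never zero. Per-line co-occurrence asks whether any
line carries high-PHS alleles in both members of an overlapping region pair.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .panel import ALT, REF, GenotypePanel
from .regions import SweepRegion, windows_on

log = logging.getLogger(__name__)


def read_homoeolog_map(path) -> pd.DataFrame:
    hmap = pd.read_csv(path, sep="\t", dtype={"chrom_A": str, "chrom_B": str,
                                              "chrom_D": str})
    return clean_homoeolog_map(hmap)


def clean_homoeolog_map(hmap: pd.DataFrame) -> pd.DataFrame:
    """Drop anchors that break positional monotonicity in order index
    within any subgenome chromosome (violations logged)."""
    hmap = hmap.sort_values("order").reset_index(drop=True)
    keep = np.ones(len(hmap), dtype=bool)
    for sg in ("A", "B", "D"):
        for chrom, sub in hmap.groupby(f"chrom_{sg}", sort=False):
            pos = sub[f"pos_{sg}"].to_numpy()
            last = -np.inf
            for ridx, p in zip(sub.index, pos):
                if p < last:
                    keep[ridx] = False
                    log.warning("dropping non-monotone anchor %s (%s:%s)",
                                hmap.loc[ridx, "gene_id"], chrom, p)
                else:
                    last = p
    return hmap[keep].reset_index(drop=True)


def project_region(region: SweepRegion | tuple, hmap: pd.DataFrame,
                   from_genome: str, to_genome: str
                   ) -> tuple[str, int, int] | None:
    """Project an interval between subgenomes via flanking anchors.

    Returns (chrom, start, end) in the target subgenome (endpoints sorted,
    handling orientation inversions), or None when the region lies outside
    the anchor span or its chromosome is absent from the map.
    """
    if isinstance(region, SweepRegion):
        chrom, start, end = region.chrom, region.start, region.end
    else:
        chrom, start, end = region
    sub = hmap[hmap[f"chrom_{from_genome}"] == chrom]
    if len(sub) < 2:
        log.debug("chromosome %s absent from homoeolog map", chrom)
        return None
    sub = sub.sort_values(f"pos_{from_genome}")
    pos = sub[f"pos_{from_genome}"].to_numpy()
    left = np.searchsorted(pos, start, side="right") - 1
    right = np.searchsorted(pos, end, side="left")
    if left < 0 or right >= len(pos):
        return None  # outside the anchored span
    la, ra = sub.iloc[left], sub.iloc[right]
    if la[f"chrom_{to_genome}"] != ra[f"chrom_{to_genome}"]:
        return None
    p1, p2 = int(la[f"pos_{to_genome}"]), int(ra[f"pos_{to_genome}"])
    return (str(la[f"chrom_{to_genome}"]), min(p1, p2), max(p1, p2))


# ---------------------------------------------------------------------------
# permutation overlap test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OverlapResult:
    genomes: tuple[str, str]
    n_sweep_windows: tuple[int, int]
    prop_x_in_y: float
    prop_y_in_x: float
    p_x_in_y: float
    p_y_in_x: float
    n_perm: int
    perm_mean: tuple[float, float]

    def as_dict(self) -> dict:
        x, y = self.genomes
        return {"genomes": f"{x}-{y}",
                "n_sweep_windows_x": self.n_sweep_windows[0],
                "n_sweep_windows_y": self.n_sweep_windows[1],
                f"prop_{x}_in_{y}": self.prop_x_in_y,
                f"prop_{y}_in_{x}": self.prop_y_in_x,
                f"p_{x}_in_{y}": self.p_x_in_y,
                f"p_{y}_in_{x}": self.p_y_in_x,
                "n_perm": self.n_perm,
                "perm_mean_x_in_y": self.perm_mean[0],
                "perm_mean_y_in_x": self.perm_mean[1]}


class _GenomeWindows:
    """Genome-wide windows of one subgenome with projection index into
    another subgenome's windows."""

    def __init__(self, genome: str, chrom_lengths: dict[str, int],
                 window_bp: int):
        self.genome = genome
        self.window_bp = window_bp
        self.chroms, self.starts = [], []
        self.offsets, self.n_in_chrom = {}, {}
        for chrom, clen in sorted(chrom_lengths.items()):
            starts = windows_on(clen, window_bp)
            self.offsets[chrom] = len(self.starts)
            self.n_in_chrom[chrom] = len(starts)
            self.chroms.extend([chrom] * len(starts))
            self.starts.extend(starts.tolist())
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.n = len(self.starts)

    def labels_from_regions(self, regions: list[SweepRegion]) -> np.ndarray:
        lab = np.zeros(self.n, dtype=bool)
        for r in regions:
            if r.chrom not in self.offsets:
                continue
            off = self.offsets[r.chrom]
            lo = off + max(r.start // self.window_bp, 0)
            hi = off + min((r.end - 1) // self.window_bp + 1,
                           self.n_in_chrom[r.chrom])
            lab[lo:hi] = True
        return lab

    def window_index_range(self, chrom: str, start: int, end: int
                           ) -> tuple[int, int] | None:
        if chrom not in self.offsets:
            return None
        off = self.offsets[chrom]
        lo = max(start // self.window_bp, 0)
        hi = min((max(end, start + 1) - 1) // self.window_bp + 1,
                 self.n_in_chrom[chrom])
        if hi <= lo:
            return None
        return off + lo, off + hi


def _projection_table(wx: _GenomeWindows, wy: _GenomeWindows,
                      hmap: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """For each window of X, the [lo, hi) window-index range of its
    projection into Y (lo = -1 when unprojectable). Vectorised flanking-
    anchor lookup; agrees with project_region window by window."""
    lo = np.full(wx.n, -1, dtype=np.int64)
    hi = np.full(wx.n, -1, dtype=np.int64)
    wb = wx.window_bp
    chrom_arr = np.asarray(wx.chroms, dtype=object)
    for chrom in pd.unique(chrom_arr):
        widx = np.flatnonzero(chrom_arr == chrom)
        starts = wx.starts[widx]
        sub = hmap[hmap[f"chrom_{wx.genome}"] == chrom]
        if len(sub) < 2:
            continue
        sub = sub.sort_values(f"pos_{wx.genome}")
        apos = sub[f"pos_{wx.genome}"].to_numpy()
        tchrom = sub[f"chrom_{wy.genome}"].to_numpy(object)
        tpos = sub[f"pos_{wy.genome}"].to_numpy()
        left = np.searchsorted(apos, starts, side="right") - 1
        right = np.searchsorted(apos, starts + wb, side="left")
        ok = (left >= 0) & (right < len(apos))
        okl, okr = left[ok], right[ok]
        same = tchrom[okl] == tchrom[okr]
        p1, p2 = tpos[okl], tpos[okr]
        plo = np.minimum(p1, p2)
        phi = np.maximum(p1, p2)
        sel = np.flatnonzero(ok)[same]
        for s, a, b, tc in zip(sel, plo[same], phi[same], tchrom[okl][same]):
            rng = wy.window_index_range(str(tc), int(a), int(b))
            if rng is not None:
                lo[widx[s]], hi[widx[s]] = rng
    return lo, hi


def _overlap_prop(lx: np.ndarray, ly: np.ndarray, lo: np.ndarray,
                  hi: np.ndarray) -> float:
    """Proportion of labeled X windows whose projection hits a labeled Y
    window."""
    n_lab = int(lx.sum())
    if n_lab == 0:
        return 0.0
    cs = np.concatenate([[0], np.cumsum(ly)])
    valid = lx & (lo >= 0)
    hits = np.zeros(len(lx), dtype=bool)
    hits[valid] = (cs[hi[valid]] - cs[lo[valid]]) > 0
    return float(hits.sum() / n_lab)


def overlap_test(sweeps_by_genome: dict[str, list[SweepRegion]],
                 hmap: pd.DataFrame, chrom_lengths: dict[str, int],
                 window_bp: int = 50_000, n_perm: int = 10_000,
                 seed: int = 0) -> list[OverlapResult]:
    """Permutation test of sweep-window overlap for every subgenome pair.

    chrom_lengths maps every chromosome (all subgenomes) to its length.
    The null shuffles sweep labels uniformly over each genome's windows,
    preserving per-genome sweep-window counts; the empirical P uses the +1
    correction and is therefore never 0.
    """
    from .panel import subgenome_of

    if n_perm < 100:
        log.warning("n_perm=%d is small; empirical P resolution is coarse",
                    n_perm)
    rng = np.random.default_rng(seed)
    genomes = sorted(sweeps_by_genome)
    wins = {}
    for g in genomes:
        lens = {c: l for c, l in chrom_lengths.items() if subgenome_of(c) == g}
        wins[g] = _GenomeWindows(g, lens, window_bp)
    results = []
    for a in range(len(genomes)):
        for b in range(a + 1, len(genomes)):
            X, Y = genomes[a], genomes[b]
            wx, wy = wins[X], wins[Y]
            lx = wx.labels_from_regions(sweeps_by_genome[X])
            ly = wy.labels_from_regions(sweeps_by_genome[Y])
            if lx.sum() == 0 or ly.sum() == 0:
                raise ValueError(f"no sweep windows for pair {X}-{Y}")
            lo_xy, hi_xy = _projection_table(wx, wy, hmap)
            lo_yx, hi_yx = _projection_table(wy, wx, hmap)
            obs_xy = _overlap_prop(lx, ly, lo_xy, hi_xy)
            obs_yx = _overlap_prop(ly, lx, lo_yx, hi_yx)
            kx, ky = int(lx.sum()), int(ly.sum())
            ge_xy = ge_yx = 0
            sum_xy = sum_yx = 0.0
            for _ in range(n_perm):
                px = np.zeros(wx.n, dtype=bool)
                px[rng.choice(wx.n, size=kx, replace=False)] = True
                py = np.zeros(wy.n, dtype=bool)
                py[rng.choice(wy.n, size=ky, replace=False)] = True
                pr_xy = _overlap_prop(px, py, lo_xy, hi_xy)
                pr_yx = _overlap_prop(py, px, lo_yx, hi_yx)
                sum_xy += pr_xy
                sum_yx += pr_yx
                ge_xy += pr_xy >= obs_xy
                ge_yx += pr_yx >= obs_yx
            results.append(OverlapResult(
                (X, Y), (kx, ky), obs_xy, obs_yx,
                (1 + ge_xy) / (1 + n_perm), (1 + ge_yx) / (1 + n_perm),
                n_perm, (sum_xy / n_perm, sum_yx / n_perm)))
    return results


# ---------------------------------------------------------------------------
# per-line co-occurrence of high-PHS alleles
# ---------------------------------------------------------------------------

def overlapping_region_pairs(sweeps_x: list[SweepRegion],
                             sweeps_y: list[SweepRegion],
                             hmap: pd.DataFrame, from_genome: str,
                             to_genome: str
                             ) -> list[tuple[SweepRegion, SweepRegion]]:
    """Pairs (region in X, region in Y) whose projection overlaps."""
    pairs = []
    for rx in sweeps_x:
        proj = project_region(rx, hmap, from_genome, to_genome)
        if proj is None:
            continue
        chrom, lo, hi = proj
        for ry in sweeps_y:
            if ry.overlaps(chrom, lo, hi):
                pairs.append((rx, ry))
    return pairs


def _outlier_carriers(region: SweepRegion, phs_results: pd.DataFrame,
                      panel: GenotypePanel) -> set[str]:
    """Lines carrying any outlier-PHS allele at a SNP inside the region."""
    sel = phs_results[(phs_results["outlier"])
                      & (phs_results["chrom"] == region.chrom)
                      & (phs_results["pos"] - 1 >= region.start)
                      & (phs_results["pos"] - 1 < region.end)]
    carriers: set[str] = set()
    for row in sel.itertuples(index=False):
        code = REF if row.allele == "ref" else ALT
        mask = panel.calls[int(row.vidx)] == code
        carriers.update(np.asarray(panel.lines, dtype=object)[mask])
    return carriers


def coincident_selection(region_pairs: list[tuple[SweepRegion, SweepRegion]],
                         phs_results: pd.DataFrame, panel: GenotypePanel
                         ) -> tuple[pd.DataFrame, float]:
    """Per overlapping region pair: does any line carry outlier alleles in
    both regions? Returns the per-pair table and the fraction of scored
    pairs with NO co-occurring line; pairs lacking outlier alleles on
    either side are skipped and counted."""
    rows, n_skipped = [], 0
    for rx, ry in region_pairs:
        cx = _outlier_carriers(rx, phs_results, panel)
        cy = _outlier_carriers(ry, phs_results, panel)
        if not cx or not cy:
            n_skipped += 1
            continue
        shared = sorted(cx & cy)
        rows.append((f"{rx.chrom}:{rx.start}-{rx.end}",
                     f"{ry.chrom}:{ry.start}-{ry.end}",
                     len(cx), len(cy), len(shared), bool(shared)))
    table = pd.DataFrame(rows, columns=["region_x", "region_y", "n_carriers_x",
                                        "n_carriers_y", "n_shared",
                                        "co_occurring"])
    if n_skipped:
        log.info("coincident_selection: %d pair(s) without outlier alleles "
                 "skipped", n_skipped)
    if len(table) == 0:
        return table, float("nan")
    frac_without = float((~table["co_occurring"]).mean())
    return table, frac_without
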