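"""Genotype panel container, VCF ingestion, site filters and map interpolation.

The panel models a population of inbred allopolyploid lines: each line is
effectively a single haplotype per subgenome, so genotype calls are coded as
haploid states (reference, alternate) plus heterozygote and missing codes.
Variants carry both physical (bp) and genetic (cM) coordinates; the genetic
coordinate is interpolated from a sparse anchor map and is what the
haplotype-sharing statistics measure lengths in.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Call codes in the calls matrix (variants x lines, int8).
REF = 0
ALT = 1
HET = 2
MISSING = -1

SUBGENOMES = ("A", "B", "D")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "subgenome", "cm"]


def subgenome_of(chrom: str) -> str:
    """Subgenome label from a chromosome name ('1A', 'chr5D', ...)."""
    tag = chrom.rstrip()[-1].upper()
    if tag not in SUBGENOMES:
        raise ValueError(f"cannot infer subgenome from chromosome name {chrom!r}")
    return tag


@dataclasses.dataclass
class GeneticMap:
    """Sparse bp<->cM anchors, piecewise-linear interpolation between them.

    Positions outside the anchored span are clamped to the terminal anchor's
    cM value, which keeps interpolated positions monotone non-decreasing.
    """

    anchors: pd.DataFrame  # columns: chrom, bp, cm

    def __post_init__(self) -> None:
        self.anchors = self.anchors.sort_values(["chrom", "bp"]).reset_index(drop=True)
        for chrom, sub in self.anchors.groupby("chrom", sort=False):
            if len(sub) < 2:
                raise ValueError(f"genetic map needs >=2 anchors on {chrom}")
            if not np.all(np.diff(sub["cm"].to_numpy()) >= 0):
                raise ValueError(f"non-monotone genetic map anchors on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors["chrom"].unique())

    def interpolate(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        sub = self.anchors[self.anchors["chrom"] == chrom]
        if len(sub) < 2:
            raise KeyError(f"chromosome {chrom} absent from genetic map")
        # np.interp clamps beyond the terminal anchors by construction
        return np.interp(np.asarray(bp, dtype=float), sub["bp"].to_numpy(float),
                         sub["cm"].to_numpy(float))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df[["chrom", "bp", "cm"]])

    def to_tsv(self, path: str | Path) -> None:
        self.anchors.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class GenotypePanel:
    """Biallelic variant x line call matrix with coordinates and metadata.

    variants: DataFrame with columns chrom, pos (1-based bp), ref, alt,
        subgenome, cm, plus optional 'ancestral' (ref|alt|unknown) and
        'effect' columns.
    calls: int8 matrix coded REF/ALT/HET/MISSING, shape (n_variants, n_lines).
    lines: ordered line names.
    metadata: per-line DataFrame (index = line) with 'group' and
        'growth_habit' columns, or None.
    """

    variants: pd.DataFrame
    calls: np.ndarray
    lines: list[str]
    metadata: pd.DataFrame | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.lines)):
            raise ValueError("calls matrix shape does not match variants x lines")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def validate(self) -> None:
        """Assert panel invariants (sorted coordinates, monotone cM)."""
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) >= 0):
                raise ValueError(f"positions not sorted on {chrom}")
            cm = sub["cm"].to_numpy(float)
            if not np.all(np.diff(cm) >= -1e-12):
                raise ValueError(f"genetic positions not monotone on {chrom}")
        if self.metadata is not None:
            missing = [ln for ln in self.lines if ln not in self.metadata.index]
            if missing:
                raise ValueError(f"lines without metadata: {missing}")

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (n_ref, n_alt) over non-missing homozygous calls."""
        n_ref = (self.calls == REF).sum(axis=1)
        n_alt = (self.calls == ALT).sum(axis=1)
        return n_ref, n_alt

    def maf(self) -> np.ndarray:
        """Minor-allele frequency over non-missing homozygous calls."""
        n_ref, n_alt = self.allele_counts()
        tot = n_ref + n_alt
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, n_alt / np.maximum(tot, 1), np.nan)
        return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))

    def mac(self) -> np.ndarray:
        n_ref, n_alt = self.allele_counts()
        return np.minimum(n_ref, n_alt)

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(self.variants.iloc[idx].reset_index(drop=True),
                             self.calls[idx], list(self.lines), self.metadata,
                             dict(self.provenance))

    def take_lines(self, names: Sequence[str]) -> "GenotypePanel":
        pos = [self.lines.index(n) for n in names]
        meta = self.metadata.loc[list(names)] if self.metadata is not None else None
        return GenotypePanel(self.variants.copy(), self.calls[:, pos],
                             list(names), meta, dict(self.provenance))

    def subgenome(self, label: str) -> "GenotypePanel":
        return self.take_variants((self.variants["subgenome"] == label).to_numpy())

    def chromosomes(self) -> list[str]:
        return list(self.variants["chrom"].unique())

    def group_lines(self, group: str) -> list[str]:
        if self.metadata is None:
            raise ValueError("panel has no sample metadata")
        return [ln for ln in self.lines if self.metadata.loc[ln, "group"] == group]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line", "group", "growth_habit"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["line"].duplicated().any():
        dup = meta.loc[meta["line"].duplicated(), "line"].tolist()
        raise ValueError(f"duplicate metadata rows for lines: {dup}")
    return meta.set_index("line")


def read_panel(vcf_path: str | Path, metadata_path: str | Path | None = None,
               map_path: str | Path | None = None,
               genetic_map: GeneticMap | None = None) -> GenotypePanel:
    """Load a VCF into a GenotypePanel with interpolated genetic positions.

    Multiallelic records and records on chromosomes absent from the genetic
    map are dropped (counts logged and stored in panel.provenance). Every
    VCF sample must have a metadata row when metadata is given.
    """
    from cyvcf2 import VCF

    if genetic_map is None and map_path is not None:
        genetic_map = GeneticMap.read_tsv(map_path)

    vcf = VCF(str(vcf_path))
    lines = list(vcf.samples)

    metadata = None
    if metadata_path is not None:
        metadata = read_metadata(metadata_path)
        absent = [s for s in lines if s not in metadata.index]
        if absent:
            raise ValueError(f"VCF sample(s) missing from metadata: {absent}")

    rows, call_rows = [], []
    n_multi = n_unmapped = 0
    map_chroms = set(genetic_map.chromosomes) if genetic_map is not None else None
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if map_chroms is not None and v.CHROM not in map_chroms:
            n_unmapped += 1
            continue
        gt = v.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        calls = np.full(len(lines), MISSING, dtype=np.int8)
        calls[gt == 0] = REF
        calls[gt == 3] = ALT
        calls[gt == 1] = HET
        anc = dict(v.INFO).get("AA", None)
        eff = dict(v.INFO).get("EFF", None)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], subgenome_of(v.CHROM), anc, eff))
        call_rows.append(calls)
    if n_multi or n_unmapped:
        log.info("read_panel: dropped %d multiallelic and %d unmapped records",
                 n_multi, n_unmapped)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "subgenome", "ancestral", "effect"])
    calls = (np.vstack(call_rows) if call_rows
             else np.empty((0, len(lines)), dtype=np.int8))
    cm = np.full(len(variants), np.nan)
    if genetic_map is not None:
        for chrom, sub in variants.groupby("chrom", sort=False):
            cm[sub.index] = genetic_map.interpolate(chrom, sub["pos"].to_numpy())
    variants["cm"] = cm
    variants = variants[["chrom", "pos", "ref", "alt", "subgenome", "cm",
                         "ancestral", "effect"]]
    panel = GenotypePanel(variants, calls, lines, metadata,
                          {"dropped_multiallelic": n_multi,
                           "dropped_unmapped": n_unmapped})
    panel.validate()
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as VCF 4.2 with GT only (plus AA/EFF INFO tags)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.lines) + "\n")
        gt_map = {REF: "0/0", ALT: "1/1", HET: "0/1", MISSING: "./."}
        has_anc = "ancestral" in panel.variants.columns
        has_eff = "effect" in panel.variants.columns
        for i, row in enumerate(panel.variants.itertuples(index=False)):
            info = []
            if has_anc and isinstance(row.ancestral, str):
                info.append(f"AA={row.ancestral}")
            if has_eff and isinstance(row.effect, str):
                info.append(f"EFF={row.effect}")
            info_s = ";".join(info) if info else "."
            gts = "\t".join(gt_map[c] for c in panel.calls[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                     f"{info_s}\tGT\t{gts}\n")


def write_panel(panel: GenotypePanel, out_dir: str | Path,
                prefix: str = "panel") -> dict[str, Path]:
    """Write VCF + variant TSV (+ metadata TSV); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / f"{prefix}.vcf", "variants": out / f"{prefix}.variants.tsv"}
    write_vcf(panel, paths["vcf"])
    tab = panel.variants.copy()
    tab["maf"] = panel.maf()
    tab.to_csv(paths["variants"], sep="\t", index=False)
    if panel.metadata is not None:
        paths["metadata"] = out / f"{prefix}.metadata.tsv"
        panel.metadata.rename_axis("line").reset_index().to_csv(
            paths["metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_sites(panel: GenotypePanel, min_called_lines: int = 46,
                 max_het_lines: int = 1) -> tuple[GenotypePanel, dict[str, int]]:
    """Call-rate and heterozygosity site filters.

    Keeps sites with >= min_called_lines non-missing calls and
    <= max_het_lines heterozygous calls; surviving heterozygous calls are
    recoded to missing (inbred lines are treated as one haplotype each).
    Returns the filtered panel and a per-rule removal tally.
    """
    if min_called_lines < 0 or max_het_lines < 0:
        raise ValueError("thresholds must be >= 0")
    n_called = (panel.calls != MISSING).sum(axis=1)
    n_het = (panel.calls == HET).sum(axis=1)
    low_call = n_called < min_called_lines
    many_het = n_het > max_het_lines
    keep = ~(low_call | many_het)
    tally = {"low_call_rate": int(low_call.sum()),
             "excess_het": int((many_het & ~low_call).sum()),
             "kept": int(keep.sum())}
    out = panel.take_variants(keep)
    out.calls = out.calls.copy()
    out.calls[out.calls == HET] = MISSING
    if tally["kept"] == 0:
        log.warning("filter_sites removed every site")
    return out, tally


def maf_filter(panel: GenotypePanel, min_maf: float = 0.016) -> GenotypePanel:
    """Keep variants with MAF strictly greater than min_maf."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = panel.maf()
    keep = np.nan_to_num(maf, nan=-1.0) > min_maf
    return panel.take_variants(keep)
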