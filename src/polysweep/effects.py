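"""Variant functional-consequence classification against gene models.

Classifies SNPs and small indels into effect classes (premature termination
codon, splice-site disruption, frameshift, ...) using single-transcript gene
models on contig sequences, assigns ancestral states from an outgroup allele
table, and computes allele-frequency spectra by class plus the
homoeolog-compensation fraction for duplicated genes.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .panel import GenotypePanel

log = logging.getLogger(__name__)

# Most severe first; the per-variant label is the most severe class across
# overlapping genes.
SEVERITY_ORDER = ["PTC", "SSD", "frameshift_indel", "non_synonymous",
                  "inframe_indel", "synonymous", "UTR", "intronic",
                  "intergenic"]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


def most_severe(classes) -> str:
    classes = [c for c in classes if c is not None]
    if not classes:
        return "intergenic"
    return min(classes, key=lambda c: _RANK[c])


@dataclasses.dataclass
class GeneModel:
    """Single-transcript gene model; intervals are 1-based inclusive."""

    gene_id: str
    seqid: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in
                zip(self.exons, self.exons[1:]) if s2 - e1 > 1]

    def cds_sequence(self, seq: str) -> str:
        parts = [seq[s - 1:e] for s, e in self.cds]
        joined = "".join(parts)
        if self.strand == "-":
            joined = str(Seq(joined).reverse_complement())
        return joined

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the coding sequence,
        in translation order (None if the position is not coding)."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def validate(self, seq: str | None = None) -> None:
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS outside exons")
        total = sum(e - s + 1 for s, e in self.cds)
        if total % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: CDS length not divisible by 3")
        if seq is not None:
            aa = str(Seq(self.cds_sequence(seq)).translate())
            if "*" in aa[:-1]:
                raise ValueError(f"gene {self.gene_id}: internal stop in "
                                 "reference CDS")


def read_gene_models(gff_path: str | Path, validate: bool = False,
                     sequences: dict[str, str] | None = None
                     ) -> list[GeneModel]:
    """Parse single-transcript gene models from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in
                 db.children(gene, featuretype="exon", order_by="start")]
        cds = [(f.start, f.end) for f in
               db.children(gene, featuretype="CDS", order_by="start")]
        gm = GeneModel(gene.id, gene.seqid, gene.strand, exons, cds)
        if validate:
            gm.validate(sequences.get(gene.seqid) if sequences else None)
        models.append(gm)
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _in_splice_site(gene: GeneModel, lo: int, hi: int) -> bool:
    """Does [lo, hi] touch the first/last 2 bases of any intron?"""
    for s, e in gene.introns():
        for ds, de in ((s, min(s + 1, e)), (max(e - 1, s), e)):
            if lo <= de and hi >= ds:
                return True
    return False


def _classify_snp_in_gene(gene: GeneModel, pos: int, alt: str,
                          seq: str) -> str | None:
    lo, hi = gene.span
    if not lo <= pos <= hi:
        return None
    ci = gene.cds_index(pos)
    if ci is not None:
        cds_seq = gene.cds_sequence(seq)
        base = alt.upper() if gene.strand == "+" else alt.upper().translate(_COMPLEMENT)
        codon_i, within = divmod(ci, 3)
        ref_codon = cds_seq[3 * codon_i:3 * codon_i + 3]
        alt_codon = ref_codon[:within] + base + ref_codon[within + 1:]
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_alt == "*" and aa_ref != "*":
            return "PTC"
        if aa_ref == aa_alt:
            return "synonymous"
        return "non_synonymous"  # stop-loss folded in here
    if _in_splice_site(gene, pos, pos):
        return "SSD"
    if any(s <= pos <= e for s, e in gene.exons):
        return "UTR"
    return "intronic"


def classify_snp(chrom: str, pos: int, ref: str, alt: str,
                 gene_models: list[GeneModel],
                 sequences: dict[str, str]) -> str:
    """Effect class of a SNP: codon-level for coding positions, splice-site
    check for the 2-bp intron termini, positional class otherwise; most
    severe class across overlapping genes."""
    hits = []
    for gene in gene_models:
        if gene.seqid != chrom:
            continue
        seq = sequences[gene.seqid]
        if pos < 1 or pos > len(seq):
            raise ValueError(f"position {chrom}:{pos} outside sequence")
        hits.append(_classify_snp_in_gene(gene, pos, alt, seq))
    return most_severe(hits)


def classify_indel(chrom: str, pos: int, ref: str, alt: str,
                   gene_models: list[GeneModel]) -> str:
    """Effect class of a small indel (unequal ref/alt lengths): frameshift
    or in-frame when it touches coding sequence, splice disruption when it
    touches the 2-bp intron termini, positional class otherwise. An indel
    spanning several features takes the most severe touched one."""
    lo, hi = pos, pos + max(len(ref) - 1, 0)
    shift = abs(len(ref) - len(alt)) % 3 != 0
    hits = []
    for gene in gene_models:
        if gene.seqid != chrom:
            continue
        gl, gh = gene.span
        if hi < gl or lo > gh:
            continue
        candidates = []
        if any(lo <= ce and hi >= cs for cs, ce in gene.cds):
            candidates.append("frameshift_indel" if shift else "inframe_indel")
        if _in_splice_site(gene, lo, hi):
            candidates.append("SSD")
        if any(lo <= ee and hi >= es for es, ee in gene.exons):
            candidates.append("UTR")
        if any(lo <= ie and hi >= is_ for is_, ie in gene.introns()):
            candidates.append("intronic")
        hits.append(most_severe(candidates) if candidates else None)
    return most_severe(hits)


def classify_panel(panel: GenotypePanel, gene_models: list[GeneModel],
                   sequences: dict[str, str]) -> GenotypePanel:
    """Tag every panel variant with its effect class."""
    out = panel.take_variants(np.arange(panel.n_variants))
    effects = []
    for row in out.variants.itertuples(index=False):
        if len(row.ref) == len(row.alt) == 1:
            effects.append(classify_snp(row.chrom, row.pos, row.ref, row.alt,
                                        gene_models, sequences))
        else:
            effects.append(classify_indel(row.chrom, row.pos, row.ref,
                                          row.alt, gene_models))
    out.variants["effect"] = effects
    return out


# ---------------------------------------------------------------------------
# ancestral states and frequency spectra
# ---------------------------------------------------------------------------

def assign_ancestral(panel: GenotypePanel, outgroup_table: pd.DataFrame
                     ) -> GenotypePanel:
    """Set per-variant ancestral state (ref|alt|unknown) from an outgroup
    allele table with columns chrom, pos, allele."""
    out = panel.take_variants(np.arange(panel.n_variants))
    merged = out.variants.merge(
        outgroup_table[["chrom", "pos", "allele"]].drop_duplicates(
            ["chrom", "pos"]),
        on=["chrom", "pos"], how="left")
    anc = np.full(len(merged), "unknown", dtype=object)
    anc[merged["allele"] == merged["ref"]] = "ref"
    anc[merged["allele"] == merged["alt"]] = "alt"
    out.variants["ancestral"] = anc
    out.provenance["n_ancestral_assigned"] = int((anc != "unknown").sum())
    return out


def derived_allele_frequency(panel: GenotypePanel) -> np.ndarray:
    """Per-site DAF over non-missing homozygous calls (NaN where the
    ancestral state is unknown)."""
    n_ref, n_alt = panel.allele_counts()
    tot = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(tot > 0, n_alt / np.maximum(tot, 1), np.nan)
    anc = panel.variants.get("ancestral",
                             pd.Series("unknown", index=panel.variants.index))
    anc = anc.to_numpy(object)
    daf = np.where(anc == "ref", p_alt,
                   np.where(anc == "alt", 1.0 - p_alt, np.nan))
    return daf


def daf_spectrum_by_class(panel: GenotypePanel, bins: np.ndarray | None = None,
                          mode: str = "daf") -> pd.DataFrame:
    """Allele-frequency spectrum per effect class.

    Returns a class x bin table of proportions (each class sums to 1).
    Bins are left-open/right-closed on (0, 1]; default width 0.05.
    mode='daf' uses derived allele frequency (ancestral-assigned sites only),
    mode='maf' the folded minor allele frequency.
    """
    if bins is None:
        upper = 1.0 if mode == "daf" else 0.5
        bins = np.round(np.arange(0.0, upper + 1e-9, 0.05), 10)
    if mode == "daf":
        freq = derived_allele_frequency(panel)
    elif mode == "maf":
        freq = panel.maf()
    else:
        raise ValueError("mode must be 'daf' or 'maf'")
    classes = panel.variants["effect"].to_numpy(object)
    ok = ~pd.isna(freq) & (freq > 0)
    labels = pd.IntervalIndex.from_breaks(bins, closed="right")
    rows = {}
    for cls in pd.unique(classes[ok]):
        f = freq[ok & (classes == cls)]
        if len(f) == 0:
            log.warning("effect class %s has no usable sites; omitted", cls)
            continue
        counts = pd.cut(pd.Series(f), bins=labels).value_counts(sort=False)
        rows[cls] = counts / counts.sum()
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# homoeolog compensation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompensationResult:
    n_disrupted: int
    n_with_intact_copy: int
    fraction_pct: int  # nearest percent
    n_unmapped: int

    @classmethod
    def from_counts(cls, n_disrupted: int, n_with_intact: int,
                    n_unmapped: int = 0) -> "CompensationResult":
        import decimal
        pct = int(decimal.Decimal(100 * n_with_intact / n_disrupted)
                  .quantize(0, rounding=decimal.ROUND_HALF_UP)) if n_disrupted else 0
        return cls(n_disrupted, n_with_intact, pct, n_unmapped)


def homoeolog_compensation(triplet_map: pd.DataFrame,
                           disruption_flags: dict[str, bool]
                           ) -> CompensationResult:
    """Fraction of disrupted genes whose homoeolog triplet retains at least
    one intact copy.

    triplet_map needs columns gene_A, gene_B, gene_D (missing members may be
    NaN). A gene counts as disrupted when its flag is True; triplet members
    without a flag are treated as intact. Flagged genes absent from the map
    are excluded and counted.
    """
    cols = ["gene_A", "gene_B", "gene_D"]
    gene_to_triplet: dict[str, int] = {}
    for ti, row in enumerate(triplet_map[cols].itertuples(index=False)):
        for g in row:
            if isinstance(g, str):
                gene_to_triplet[g] = ti
    triplets = triplet_map[cols].to_numpy(object)
    n_disrupted = n_intact = n_unmapped = 0
    for gene, flag in disruption_flags.items():
        if not flag:
            continue
        ti = gene_to_triplet.get(gene)
        if ti is None:
            n_unmapped += 1
            continue
        partners = [g for g in triplets[ti] if isinstance(g, str) and g != gene]
        if not partners:
            n_unmapped += 1
            continue
        n_disrupted += 1
        if any(not disruption_flags.get(g, False) for g in partners):
            n_intact += 1
    return CompensationResult.from_counts(n_disrupted, n_intact, n_unmapped)
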