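"""Variant effect classification, ancestral assignment, spectra,
homoeolog compensation."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from polysweep.effects import (CompensationResult, GeneModel, assign_ancestral,
                               classify_indel, classify_snp,
                               daf_spectrum_by_class, homoeolog_compensation,
                               most_severe, read_fasta, read_gene_models)
from polysweep.genespace import make_gene_space, mirror_gene
from polysweep.panel import ALT

from conftest import make_panel


def simple_gene():
    """Hand-built 2-exon forward gene with known codons.

    Contig layout (1-based):
      1-10   upstream
      11-16  exon1 5'UTR
      17-31  exon1 CDS: ATG GCT TGG AAA CAA
      32-71  intron (GT .. AG)
      72-86  exon2 CDS: GAT TTT CGG GGA TAA
      87-92  exon2 3'UTR
    """
    cds1 = "ATGGCTTGGAAACAA"
    cds2 = "GATTTTCGGGGATAA"
    intron = "GT" + "C" * 36 + "AG"
    seq = ("T" * 10 + "AACCGG" + cds1 + intron + cds2 + "TTGGCC"
           + "A" * 10)
    gene = GeneModel("g1", "ctg1", "+", exons=[(11, 31), (72, 92)],
                     cds=[(17, 31), (72, 86)])
    gene.validate(seq)
    return seq, gene


class TestClassifySnp:
    def test_stop_gain_is_ptc(self):
        seq, gene = simple_gene()
        # TGG codon at CDS positions 7-9 (genomic 23-25); G->A at codon pos 3
        assert seq[22:25] == "TGG"
        assert classify_snp("ctg1", 25, "G", "A", [gene], {"ctg1": seq}) == "PTC"

    def test_synonymous_third_position(self):
        seq, gene = simple_gene()
        # GCT (Ala) at genomic 20-22; T->C stays Ala
        assert seq[19:22] == "GCT"
        assert classify_snp("ctg1", 22, "T", "C", [gene],
                            {"ctg1": seq}) == "synonymous"

    def test_donor_site_disruption(self):
        seq, gene = simple_gene()
        # first intron base (genomic 32) is the canonical GT donor
        assert seq[31] == "G"
        assert classify_snp("ctg1", 32, "G", "A", [gene],
                            {"ctg1": seq}) == "SSD"

    def test_positional_classes(self):
        seq, gene = simple_gene()
        assert classify_snp("ctg1", 13, "C", "T", [gene], {"ctg1": seq}) == "UTR"
        assert classify_snp("ctg1", 50, "C", "T", [gene],
                            {"ctg1": seq}) == "intronic"
        assert classify_snp("ctg1", 5, "T", "C", [gene],
                            {"ctg1": seq}) == "intergenic"

    def test_missense(self):
        seq, gene = simple_gene()
        # AAA (Lys) at genomic 26-28; A->G at first position -> Glu
        assert classify_snp("ctg1", 26, "A", "G", [gene],
                            {"ctg1": seq}) == "non_synonymous"


class TestClassifyIndel:
    def test_frameshift_vs_inframe(self):
        seq, gene = simple_gene()
        assert classify_indel("ctg1", 20, "CTT", "C", [gene]) == "frameshift_indel"
        assert classify_indel("ctg1", 19, "GCTT", "G", [gene]) == "inframe_indel"

    def test_intronic_deletion(self):
        seq, gene = simple_gene()
        assert classify_indel("ctg1", 40, "CCCCC", "C", [gene]) == "intronic"

    def test_splice_touching_deletion_is_ssd(self):
        seq, gene = simple_gene()
        # deletion reaching into the donor GT outranks intronic
        assert classify_indel("ctg1", 31, "GGTC", "G", [gene]) == "SSD"


def brute_force_snp_class(gene: GeneModel, seq: str, pos: int, alt: str) -> str:
    """Independent oracle: rebuild the whole mutant CDS and translate."""
    mutant = seq[:pos - 1] + alt + seq[pos:]
    aa_ref = str(Seq(gene.cds_sequence(seq)).translate())
    aa_alt = str(Seq(gene.cds_sequence(mutant)).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if "*" in aa_alt[:-1] and "*" not in aa_ref[:-1]:
        return "PTC"
    return "non_synonymous"


def test_classify_snp_agrees_with_full_cds_rebuild_oracle():
    space = make_gene_space(seed=21, n_genes=30)
    rng = np.random.default_rng(0)
    bases = "ACGT"
    n_checked = 0
    for gene in space.genes:
        seq = space.contigs[gene.seqid]
        cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
        for pos in rng.choice(cds_positions, size=12, replace=False):
            pos = int(pos)
            ref = seq[pos - 1]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            got = classify_snp(gene.seqid, pos, ref, alt, [gene],
                               {gene.seqid: seq})
            assert got == brute_force_snp_class(gene, seq, pos, alt), \
                f"{gene.gene_id}:{pos} {ref}>{alt}"
            n_checked += 1
    assert n_checked >= 300


def test_reverse_strand_mirror_equivalence():
    """Classification is invariant under mirroring the contig to the
    opposite strand."""
    space = make_gene_space(seed=22, n_genes=8, minus_fraction=0.0)
    rng = np.random.default_rng(1)
    bases = "ACGT"
    for gene in space.genes:
        seq = space.contigs[gene.seqid]
        mseq, mgene = mirror_gene(seq, gene)
        L = len(seq)
        lo, hi = gene.span
        for pos in rng.integers(lo, hi + 1, size=15):
            pos = int(pos)
            ref = seq[pos - 1]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            fwd = classify_snp(gene.seqid, pos, ref, alt, [gene],
                               {gene.seqid: seq})
            mpos = L - pos + 1
            malt = str(Seq(alt).reverse_complement())
            mref = str(Seq(ref).reverse_complement())
            rev = classify_snp(mgene.seqid, mpos, mref, malt, [mgene],
                               {mgene.seqid: mseq})
            assert fwd == rev


def test_gff3_fasta_round_trip(tmp_path):
    space = make_gene_space(seed=23, n_genes=6)
    space.write_fasta(tmp_path / "g.fa")
    space.write_gff3(tmp_path / "g.gff3")
    seqs = read_fasta(tmp_path / "g.fa")
    models = read_gene_models(tmp_path / "g.gff3", validate=True,
                              sequences=seqs)
    assert {m.gene_id for m in models} == {g.gene_id for g in space.genes}
    by_id = {m.gene_id: m for m in models}
    for g in space.genes:
        m = by_id[g.gene_id]
        assert (m.exons, m.cds, m.strand) == (g.exons, g.cds, g.strand)
    assert seqs == space.contigs


def test_invalid_gene_model_names_gene():
    gene = GeneModel("broken", "c", "+", exons=[(1, 10)], cds=[(1, 10)])
    with pytest.raises(ValueError, match="broken"):
        gene.validate()


class TestAssignAncestral:
    def test_assignment_and_counts(self):
        calls = np.zeros((3, 4), dtype=np.int8)
        calls[:, 0] = ALT
        panel = make_panel(calls, ref=["A", "C", "G"], alt=["G", "T", "A"])
        outgroup = pd.DataFrame({"chrom": ["1A"] * 3,
                                 "pos": [1000, 2000, 3000],
                                 "allele": ["A", "T", "C"]})
        out = assign_ancestral(panel, outgroup)
        assert out.variants["ancestral"].tolist() == ["ref", "alt", "unknown"]
        assert out.provenance["n_ancestral_assigned"] == 2

    def test_unmatched_sites_stay_unknown(self):
        panel = make_panel(np.zeros((2, 4), dtype=np.int8))
        out = assign_ancestral(panel, pd.DataFrame(
            {"chrom": ["1A"], "pos": [1000], "allele": ["A"]}))
        assert out.variants["ancestral"].tolist() == ["ref", "unknown"]


class TestSpectrum:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        n_sites, n_lines = 400, 40
        calls = (rng.random((n_sites, n_lines))
                 < rng.uniform(0.05, 0.95, n_sites)[:, None]).astype(np.int8)
        panel = make_panel(calls)
        panel.variants["effect"] = rng.choice(["synonymous", "non_synonymous"],
                                              n_sites)
        panel.variants["ancestral"] = "ref"
        spec = daf_spectrum_by_class(panel, mode="daf")
        assert np.allclose(spec.sum(axis=1), 1.0, atol=1e-12)

    def test_all_singletons_fall_in_lowest_bin(self):
        calls = np.zeros((20, 62), dtype=np.int8)
        calls[np.arange(20), np.arange(20) % 62] = ALT
        panel = make_panel(calls)
        panel.variants["effect"] = "synonymous"
        panel.variants["ancestral"] = "ref"
        spec = daf_spectrum_by_class(panel, mode="daf")
        assert spec.iloc[0, 0] == pytest.approx(1.0)

    def test_deleterious_class_depleted_at_high_daf(self):
        """Construction: PTC sites only at low DAF, synonymous across the
        range -> PTC mass above 0.5 is below the synonymous mass."""
        rng = np.random.default_rng(3)
        n_lines = 62
        rows, classes = [], []
        for _ in range(300):
            f = rng.uniform(0.02, 0.3)
            rows.append(rng.random(n_lines) < f)
            classes.append("PTC")
        for _ in range(300):
            f = rng.uniform(0.02, 0.98)
            rows.append(rng.random(n_lines) < f)
            classes.append("synonymous")
        panel = make_panel(np.array(rows, dtype=np.int8))
        panel.variants["effect"] = classes
        panel.variants["ancestral"] = "ref"
        spec = daf_spectrum_by_class(panel, mode="daf")
        high = [c for c in spec.columns if c.left >= 0.5]
        assert spec.loc["PTC", high].sum() < spec.loc["synonymous", high].sum()


class TestHomoeologCompensation:
    def test_printed_counts_give_78_percent(self):
        assert CompensationResult.from_counts(6230, 4870).fraction_pct == 78

    def test_all_copies_disrupted(self):
        tmap = pd.DataFrame({"gene_A": ["a1"], "gene_B": ["b1"],
                             "gene_D": ["d1"]})
        flags = {"a1": True, "b1": True, "d1": True}
        res = homoeolog_compensation(tmap, flags)
        assert res.n_disrupted == 3 and res.fraction_pct == 0

    def test_single_disruption_per_triplet(self):
        tmap = pd.DataFrame({"gene_A": ["a1", "a2"], "gene_B": ["b1", "b2"],
                             "gene_D": ["d1", "d2"]})
        flags = {"a1": True, "b2": True}
        res = homoeolog_compensation(tmap, flags)
        assert res.n_disrupted == 2
        assert res.fraction_pct == 100

    def test_unmapped_genes_counted(self):
        tmap = pd.DataFrame({"gene_A": ["a1"], "gene_B": ["b1"],
                             "gene_D": [None]})
        res = homoeolog_compensation(tmap, {"zz": True, "a1": True})
        assert res.n_unmapped == 1 and res.n_disrupted == 1


def test_severity_collapse_order():
    assert most_severe(["synonymous", "PTC", "intronic"]) == "PTC"
    assert most_severe(["UTR", "intronic"]) == "UTR"
    assert most_severe([]) == "intergenic"
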