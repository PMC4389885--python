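"""Synthetic gene-space generator: short genes on small contigs.

Emits 2-3-exon genes with canonical GT/AG introns on random contig
sequences, used to exercise the effect-classification code (and its
brute-force oracle) without any real genome. Reverse-strand genes are built
on a forward-strand template and mirrored, which also provides the
strand-symmetry fixture.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .effects import GeneModel

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + non-stop codons + TAA, length divisible by 3."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@dataclasses.dataclass
class GeneSpace:
    contigs: dict[str, str]
    genes: list[GeneModel]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                lo, hi = g.span
                fh.write(f"{g.seqid}\tpolysweep\tgene\t{lo}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
                fh.write(f"{g.seqid}\tpolysweep\tmRNA\t{lo}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n")
                for s, e in g.exons:
                    fh.write(f"{g.seqid}\tpolysweep\texon\t{s}\t{e}\t.\t"
                             f"{g.strand}\t.\tParent={g.gene_id}.1\n")
                phase = 0
                cds = g.cds if g.strand == "+" else list(reversed(g.cds))
                for s, e in cds:
                    fh.write(f"{g.seqid}\tpolysweep\tCDS\t{s}\t{e}\t.\t"
                             f"{g.strand}\t{phase}\tParent={g.gene_id}.1\n")
                    phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def _build_forward_gene(rng: np.random.Generator, gene_id: str, seqid: str,
                        contig_len: int) -> tuple[str, GeneModel]:
    """Lay a forward-strand gene into a fresh random contig sequence."""
    n_exons = int(rng.integers(2, 4))
    n_codons = int(rng.integers(20, 41))
    cds = _random_cds(rng, n_codons)
    utr5 = int(rng.integers(20, 41))
    utr3 = int(rng.integers(20, 41))
    # split CDS into n_exons chunks (each >= 6 bp)
    cuts = np.sort(rng.choice(np.arange(6, len(cds) - 6), size=n_exons - 1,
                              replace=False))
    chunks = np.split(np.frombuffer(cds.encode(), dtype="S1"), cuts)
    chunks = ["".join(c.astype(str)) for c in chunks]
    intron_lens = [int(rng.integers(40, 81)) for _ in range(n_exons - 1)]

    start = int(rng.integers(100, 160))
    pieces, exons, cds_ivals = [], [], []
    cursor = start  # 1-based position of next written base
    # first exon: 5' UTR + first CDS chunk
    for i, chunk in enumerate(chunks):
        ex_start = cursor
        if i == 0:
            pieces.append(_random_seq(rng, utr5))
            cursor += utr5
        cds_start = cursor
        pieces.append(chunk)
        cursor += len(chunk)
        cds_ivals.append((cds_start, cursor - 1))
        if i == len(chunks) - 1:
            pieces.append(_random_seq(rng, utr3))
            cursor += utr3
        exons.append((ex_start, cursor - 1))
        if i < len(chunks) - 1:
            ilen = intron_lens[i]
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            pieces.append(intron)
            cursor += ilen
    gene_seq = "".join(pieces)
    tail = contig_len - (start - 1) - len(gene_seq)
    contig = _random_seq(rng, start - 1) + gene_seq + _random_seq(rng, max(tail, 50))
    model = GeneModel(gene_id, seqid, "+", exons, cds_ivals)
    model.validate(contig)
    return contig, model


def mirror_gene(contig: str, model: GeneModel) -> tuple[str, GeneModel]:
    """Reverse-complement the contig and flip the model to the minus strand;
    the mirrored gene encodes the identical protein."""
    L = len(contig)
    flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
    mirrored = GeneModel(model.gene_id, model.seqid, "-",
                         [flip(iv) for iv in model.exons],
                         [flip(iv) for iv in model.cds])
    return str(Seq(contig).reverse_complement()), mirrored


def make_gene_space(seed: int, n_genes: int = 12, contig_len: int = 1200,
                    minus_fraction: float = 0.5) -> GeneSpace:
    rng = np.random.default_rng(seed)
    contigs, genes = {}, []
    for i in range(n_genes):
        name = f"ctg{i + 1:04d}"
        contig, model = _build_forward_gene(rng, f"gene{i + 1:04d}", name,
                                            contig_len)
        if rng.random() < minus_fraction:
            contig, model = mirror_gene(contig, model)
        model.validate(contig)
        contigs[name] = contig
        genes.append(model)
    return GeneSpace(contigs, genes)
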