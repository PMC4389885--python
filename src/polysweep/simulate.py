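"""Synthetic allohexaploid population generator with known ground truth.

The generator emulates the statistical structure of a resequenced panel of
inbred allohexaploid lines (three subgenomes A/B/D): a mosaic-of-founders
model produces realistic linkage-disequilibrium blocks at O(SNPs x lines)
cost, the D subgenome gets fewer founders and a singleton-skewed founder
spectrum (lower diversity, excess rare alleles), cultivars are drifted away
from landraces by a Balding-Nichols-style perturbation of founder weights,
and hard sweeps / diverged introgression tracts are planted with recorded
truth so downstream detection can be scored.

This is an emulation of the data-generating process the analyses assume, not
a population-genetic simulation of wheat demography.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (ALT, HET, MISSING, REF, GeneticMap, GenotypePanel,
                    write_panel)

DEFAULT_EFFECT_PROPORTIONS = {
    "intergenic": 0.62, "intronic": 0.12, "UTR": 0.05,
    "synonymous": 0.095, "non_synonymous": 0.10,
    "PTC": 0.002, "SSD": 0.002, "frameshift_indel": 0.006,
    "inframe_indel": 0.005,
}


@dataclasses.dataclass
class ChromosomeSpec:
    name: str
    length_bp: int
    map_cm: float
    n_snps: int


@dataclasses.dataclass
class SubgenomeSpec:
    chromosomes: list[ChromosomeSpec]
    founders: int = 16
    spectrum_skew: float = 1.0  # founder derived count i ~ 1/i**skew


@dataclasses.dataclass
class SweepSpec:
    chrom: str
    center_bp: int
    half_width_bp: int
    carrier_fraction: float
    group: str | None = None  # restrict carriers to a metadata group

    @property
    def interval(self) -> tuple[int, int]:
        return (self.center_bp - self.half_width_bp,
                self.center_bp + self.half_width_bp)


@dataclasses.dataclass
class IntrogressionSpec:
    tracts: list[tuple[str, int, int]]  # (chrom, start_bp, end_bp)
    divergence: float  # per-site probability the donor differs from reference
    recipient_fraction: float


@dataclasses.dataclass
class SimConfig:
    """All knobs of the generator; (config, seed) fully determine the output."""

    seed: int = 0
    n_lines: int = 62
    n_landrace: int = 26
    n_cultivar: int = 29  # remainder are 'other' (breeding/synthetic lines)
    n_winter: int = 13
    subgenomes: dict[str, SubgenomeSpec] = dataclasses.field(default_factory=dict)
    switch_rate_per_cm: float = 0.2  # founder-mosaic breakpoint density
    f_drift: float = 0.02  # Wright's F between landraces and cultivars
    missing_rate: float = 0.02
    het_rate: float = 0.002
    sweeps: list[SweepSpec] = dataclasses.field(default_factory=list)
    introgressions: list[IntrogressionSpec] = dataclasses.field(default_factory=list)
    effect_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROPORTIONS))
    anchor_spacing_bp: int = 10_000_000
    homoeolog_anchor_spacing_bp: int = 1_000_000
    outgroup_coverage: float = 0.7
    outgroup_error: float = 0.02

    def __post_init__(self) -> None:
        if not self.subgenomes:
            self.subgenomes = default_subgenomes()
        for sw in self.sweeps:
            if not 0.0 < sw.carrier_fraction < 1.0:
                raise ValueError("sweep carrier fraction must be in (0, 1)")
            lo, hi = sw.interval
            spec = self._chrom_spec(sw.chrom)
            if lo < 0 or hi > spec.length_bp:
                raise ValueError(f"sweep interval outside chromosome {sw.chrom}")

    def _chrom_spec(self, chrom: str) -> ChromosomeSpec:
        for sg in self.subgenomes.values():
            for c in sg.chromosomes:
                if c.name == chrom:
                    return c
        raise ValueError(f"chromosome {chrom} not in config")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain (YAML-loaded) mapping."""
    d = dict(d)
    if "scale" in d:
        d["subgenomes"] = default_subgenomes(float(d.pop("scale")))
    elif "subgenomes" in d:
        d["subgenomes"] = {
            sg: SubgenomeSpec(
                [ChromosomeSpec(**c) for c in spec["chromosomes"]],
                founders=spec.get("founders", 16),
                spectrum_skew=spec.get("spectrum_skew", 1.0))
            for sg, spec in d["subgenomes"].items()}
    d["sweeps"] = [SweepSpec(**s) for s in d.get("sweeps", [])]
    d["introgressions"] = [
        IntrogressionSpec(tracts=[tuple(t) for t in s["tracts"]],
                          divergence=s["divergence"],
                          recipient_fraction=s["recipient_fraction"])
        for s in d.get("introgressions", [])]
    return SimConfig(**d)


def default_subgenomes(scale: float = 1.0) -> dict[str, SubgenomeSpec]:
    """Default study conditions: one ~300 Mb / 150 cM chromosome per
    subgenome, A/B with ~2.5x the variant count of D, D with fewer founders
    and a singleton-skewed spectrum."""
    def chrom(name, n_snps):
        return ChromosomeSpec(name, int(300e6 * scale), 150.0 * scale,
                              max(int(n_snps * scale), 40))
    return {
        "A": SubgenomeSpec([chrom("1A", 3000)], founders=16, spectrum_skew=1.0),
        "B": SubgenomeSpec([chrom("1B", 3000)], founders=16, spectrum_skew=1.0),
        "D": SubgenomeSpec([chrom("1D", 1200)], founders=8, spectrum_skew=1.5),
    }


@dataclasses.dataclass
class SimResult:
    panel: GenotypePanel
    genetic_map: GeneticMap
    homoeolog_map: pd.DataFrame
    donor_table: pd.DataFrame
    outgroup_table: pd.DataFrame
    truth: dict

    def chrom_lengths(self, config: SimConfig) -> dict[str, int]:
        return {c.name: c.length_bp for sg in config.subgenomes.values()
                for c in sg.chromosomes}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = write_panel(self.panel, out, prefix="sim")
        paths["map"] = out / "sim.map.tsv"
        self.genetic_map.to_tsv(paths["map"])
        paths["homoeologs"] = out / "sim.homoeologs.tsv"
        self.homoeolog_map.to_csv(paths["homoeologs"], sep="\t", index=False)
        paths["donor"] = out / "sim.donor.tsv"
        self.donor_table.to_csv(paths["donor"], sep="\t", index=False)
        paths["outgroup"] = out / "sim.outgroup.tsv"
        self.outgroup_table.to_csv(paths["outgroup"], sep="\t", index=False)
        paths["truth"] = out / "sim.truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# spectrum helpers
# ---------------------------------------------------------------------------

def founder_spectrum(founders: int, skew: float) -> np.ndarray:
    """P(derived copies = i) over i = 1..F-1, proportional to 1/i**skew."""
    i = np.arange(1, founders)
    w = 1.0 / i.astype(float) ** skew
    return w / w.sum()


def expected_site_pi(founders: int, skew: float, n_lines: int) -> float:
    """Closed-form expectation of the unbiased per-site pi estimator under
    the configured founder spectrum (lines draw founders uniformly iid, so
    the estimator is unbiased for 2p(1-p) at founder frequency p)."""
    i = np.arange(1, founders)
    p = i / founders
    w = founder_spectrum(founders, skew)
    return float(np.sum(w * 2.0 * p * (1.0 - p)))


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _group_assignment(cfg: SimConfig, rng: np.random.Generator):
    lines = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    groups = (["landrace"] * cfg.n_landrace + ["cultivar"] * cfg.n_cultivar
              + ["other"] * (cfg.n_lines - cfg.n_landrace - cfg.n_cultivar))
    habit = np.array(["spring"] * cfg.n_lines, dtype=object)
    winter_idx = rng.choice(cfg.n_lines, size=cfg.n_winter, replace=False)
    habit[winter_idx] = "winter"
    meta = pd.DataFrame({"line": lines, "group": groups, "growth_habit": habit})
    return lines, meta.set_index("line")


def _random_alleles(rng: np.random.Generator, n: int):
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return ref, alt


def simulate_population(config: SimConfig) -> SimResult:
    """Run the mosaic-of-founders generator; returns panel + truth record."""
    master = np.random.SeedSequence(config.seed)
    keys = master.spawn(6)
    rng_geno = np.random.default_rng(keys[0])
    rng_meta = np.random.default_rng(keys[1])
    rng_noise = np.random.default_rng(keys[2])
    rng_sweep = np.random.default_rng(keys[3])
    rng_intro = np.random.default_rng(keys[4])
    rng_out = np.random.default_rng(keys[5])

    lines, metadata = _group_assignment(config, rng_meta)
    n = config.n_lines
    is_cultivar = (metadata["group"] == "cultivar").to_numpy()

    var_frames, call_blocks, anchor_rows = [], [], []
    for sg_label, sg in config.subgenomes.items():
        F = sg.founders
        spec_p = founder_spectrum(F, sg.spectrum_skew)
        # per-group founder weights (Balding-Nichols-style drift for cultivars)
        if config.f_drift > 0:
            c = (1.0 - config.f_drift) / config.f_drift
            w_cult = rng_geno.dirichlet(np.full(F, c / F))
        else:
            w_cult = np.full(F, 1.0 / F)
        w_base = np.full(F, 1.0 / F)

        for chrom in sg.chromosomes:
            S = chrom.n_snps
            pos = np.sort(rng_geno.choice(chrom.length_bp, size=S, replace=False)) + 1
            cm = pos / chrom.length_bp * chrom.map_cm
            # founder haplotypes: site i gets k_i derived copies, k ~ spectrum
            k = rng_geno.choice(np.arange(1, F), size=S, p=spec_p)
            ranks = rng_geno.random((F, S)).argsort(axis=0)
            founder_hap = (ranks < k).astype(np.int8)  # F x S, 1 = derived/alt

            calls = np.empty((S, n), dtype=np.int8)
            for li in range(n):
                w = w_cult if is_cultivar[li] else w_base
                n_bk = rng_geno.poisson(config.switch_rate_per_cm * chrom.map_cm)
                breaks = np.sort(rng_geno.uniform(0, chrom.map_cm, size=n_bk))
                seg_founders = rng_geno.choice(F, size=n_bk + 1, p=w)
                seg = np.searchsorted(breaks, cm)
                calls[:, li] = founder_hap[seg_founders[seg], np.arange(S)]

            ref, alt = _random_alleles(rng_geno, S)
            var_frames.append(pd.DataFrame({
                "chrom": chrom.name, "pos": pos, "ref": ref, "alt": alt,
                "subgenome": sg_label, "cm": cm}))
            call_blocks.append(calls)

            bp_anchors = np.unique(np.r_[1, np.arange(
                config.anchor_spacing_bp, chrom.length_bp,
                config.anchor_spacing_bp), chrom.length_bp])
            for bp in bp_anchors:
                anchor_rows.append((chrom.name, int(bp),
                                    bp / chrom.length_bp * chrom.map_cm))

    variants = pd.concat(var_frames, ignore_index=True)
    calls = np.vstack(call_blocks)

    # noise: sprinkle missing and heterozygous calls
    noise = rng_noise.random(calls.shape)
    calls[noise < config.missing_rate] = MISSING
    het_mask = (noise >= config.missing_rate) & (
        noise < config.missing_rate + config.het_rate)
    calls[het_mask] = HET

    # ancestral states: founder-derived allele is alt, so the true ancestral
    # allele is ref everywhere; the outgroup table observes it with error
    variants["ancestral"] = "ref"
    variants["effect"] = rng_noise.choice(
        list(config.effect_proportions.keys()), size=len(variants),
        p=np.array(list(config.effect_proportions.values()))
        / sum(config.effect_proportions.values()))

    panel = GenotypePanel(variants, calls, lines, metadata)
    gmap = GeneticMap(pd.DataFrame(anchor_rows, columns=["chrom", "bp", "cm"]))

    truth: dict = {"seed": config.seed, "sweeps": [], "introgressions": []}
    for sw in config.sweeps:
        panel, rec = plant_sweep(panel, sw, rng_sweep)
        truth["sweeps"].append(rec)
    donor_frames = []
    for spec in config.introgressions:
        panel, rec, donor = plant_introgression(panel, spec, rng_intro)
        truth["introgressions"].append(rec)
        donor_frames.append(donor)

    donor_table = _donor_table(panel, donor_frames)
    outgroup = _outgroup_table(panel, config, rng_out)
    hmap = _homoeolog_map(config)
    panel.validate()
    return SimResult(panel, gmap, hmap, donor_table, outgroup, truth)


def _homoeolog_map(config: SimConfig) -> pd.DataFrame:
    """Collinear anchor triplets, one per ~homoeolog_anchor_spacing_bp of the
    A-subgenome chromosome, projected by relative physical position."""
    cols = ["gene_id", "chrom_A", "pos_A", "chrom_B", "pos_B", "chrom_D",
            "pos_D", "order"]
    if not all(sg in config.subgenomes for sg in "ABD"):
        return pd.DataFrame(columns=cols)
    chroms = {sg: spec.chromosomes for sg, spec in config.subgenomes.items()}
    n_chrom = min(len(v) for v in chroms.values())
    rows = []
    gi = 0
    for ci in range(n_chrom):
        ca, cb, cd = chroms["A"][ci], chroms["B"][ci], chroms["D"][ci]
        n_anchor = max(ca.length_bp // config.homoeolog_anchor_spacing_bp, 2)
        for k in range(n_anchor):
            r = (k + 0.5) / n_anchor
            gi += 1
            rows.append((f"HG{gi:05d}", ca.name, int(r * ca.length_bp),
                         cb.name, int(r * cb.length_bp),
                         cd.name, int(r * cd.length_bp), gi))
    return pd.DataFrame(rows, columns=cols)


def _outgroup_table(panel: GenotypePanel, config: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Outgroup alleles for a random subset of sites: the true ancestral
    (reference) base, flipped to a third base at the error rate."""
    m = len(panel.variants)
    covered = rng.random(m) < config.outgroup_coverage
    allele = panel.variants["ref"].to_numpy(object).copy()
    err = covered & (rng.random(m) < config.outgroup_error)
    bases = np.array(list("ACGT"))
    allele[err] = bases[rng.integers(0, 4, int(err.sum()))]
    tab = panel.variants.loc[covered, ["chrom", "pos"]].copy()
    tab["allele"] = allele[covered]
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# planted signals
# ---------------------------------------------------------------------------

def plant_sweep(panel: GenotypePanel, spec: SweepSpec,
                rng: np.random.Generator | int) -> tuple[GenotypePanel, dict]:
    """Copy one line's haplotype over the sweep interval into a random
    carrier subset — the hard-sweep signal the PHS scan is built to detect."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if not 0.0 < spec.carrier_fraction < 1.0:
        raise ValueError("carrier fraction must be in (0, 1)")
    lo, hi = spec.interval
    v = panel.variants
    idx = np.flatnonzero((v["chrom"] == spec.chrom).to_numpy()
                         & (v["pos"].to_numpy() >= lo)
                         & (v["pos"].to_numpy() <= hi))
    if len(idx) < 10:
        raise ValueError(f"sweep interval on {spec.chrom} contains "
                         f"{len(idx)} SNPs (<10)")
    if spec.group is not None:
        eligible = [panel.lines.index(ln) for ln in panel.group_lines(spec.group)]
    else:
        eligible = list(range(panel.n_lines))
    n_car = int(round(spec.carrier_fraction * len(eligible)))
    carriers = rng.choice(eligible, size=n_car, replace=False)
    out = panel.take_variants(np.arange(panel.n_variants))
    core = out.calls[np.ix_(idx, [carriers[0]])]
    core = np.where(core == MISSING, REF, core)  # core haplotype fully called
    out.calls[np.ix_(idx, carriers)] = core
    rec = {"chrom": spec.chrom, "start": int(lo), "end": int(hi),
           "carrier_fraction": spec.carrier_fraction,
           "carriers": [panel.lines[i] for i in sorted(carriers)],
           "n_snps": int(len(idx))}
    return out, rec


def plant_introgression(panel: GenotypePanel, spec: IntrogressionSpec,
                        rng: np.random.Generator | int,
                        ) -> tuple[GenotypePanel, dict, pd.DataFrame]:
    """Insert a diverged donor haplotype into a recipient subset of lines.

    The donor is the reference haplotype with sites flipped to the alternate
    allele at the configured per-site divergence; only flipped sites are
    written into recipients, so divergence 0 changes nothing beyond the
    donor-allele bookkeeping.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    tracts = sorted(spec.tracts, key=lambda t: (t[0], t[1]))
    for (c1, s1, e1), (c2, s2, e2) in zip(tracts, tracts[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError("introgression tracts overlap")
    out = panel.take_variants(np.arange(panel.n_variants))
    recipients = rng.choice(panel.n_lines,
                            size=int(round(spec.recipient_fraction * panel.n_lines)),
                            replace=False)
    donor_rows = []
    v = out.variants
    for chrom, lo, hi in tracts:
        idx = np.flatnonzero((v["chrom"] == chrom).to_numpy()
                             & (v["pos"].to_numpy() >= lo)
                             & (v["pos"].to_numpy() <= hi))
        flips = rng.random(len(idx)) < spec.divergence
        flip_idx = idx[flips]
        out.calls[np.ix_(flip_idx, recipients)] = ALT
        donor_allele = np.where(flips, v["alt"].to_numpy(object)[idx],
                                v["ref"].to_numpy(object)[idx])
        for j, site in enumerate(idx):
            donor_rows.append((v["chrom"].iat[site], int(v["pos"].iat[site]),
                               donor_allele[j]))
    donor = pd.DataFrame(donor_rows, columns=["chrom", "pos", "allele"])
    rec = {"tracts": [list(t) for t in tracts],
           "divergence": spec.divergence,
           "recipients": [panel.lines[i] for i in sorted(recipients)]}
    return out, rec, donor


def _donor_table(panel: GenotypePanel, donor_frames: list[pd.DataFrame]
                 ) -> pd.DataFrame:
    """Genome-wide donor-allele table for the D subgenome: the reference
    (ancestral) allele outside planted tracts, the donor haplotype inside."""
    v = panel.variants
    d_sites = v[v["subgenome"] == "D"][["chrom", "pos", "ref"]].rename(
        columns={"ref": "allele"})
    if not donor_frames:
        return d_sites.reset_index(drop=True)
    planted = pd.concat(donor_frames, ignore_index=True)
    merged = d_sites.merge(planted, on=["chrom", "pos"], how="left",
                           suffixes=("_ref", "_donor"))
    merged["allele"] = merged["allele_donor"].fillna(merged["allele_ref"])
    return merged[["chrom", "pos", "allele"]]
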