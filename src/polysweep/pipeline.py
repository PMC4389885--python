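"""End-to-end workflow: simulate/load -> filter -> annotate -> diversity ->
PHS -> sweeps -> overlap -> enrichment -> report.

Every stage writes plain files (VCF/TSV/BED/JSON) into the run directory so
any stage can be re-run standalone; the manifest records the configuration,
per-stage parameters and SHA-256 checksums of all outputs (relative paths
only, no timestamps) so a repeated run with the same configuration produces
a byte-identical manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import effects as fx
from . import enrichment as en
from . import homoeologs as hm
from . import phs as ph
from .panel import (GeneticMap, filter_sites, maf_filter, read_panel,
                    write_panel)
from .regions import SweepRegion, regions_to_bed
from .simulate import config_from_dict, simulate_population

log = logging.getLogger(__name__)

DEFAULTS = {
    "filter": {"min_called_lines": 46, "max_het_lines": 1, "min_maf": 0.016},
    "diversity": {"win_bp": 2_000_000, "step_bp": 1_000_000,
                  "min_covered_bp": 10_000, "tail_fraction": 0.025,
                  "tails": "both"},
    "fst_groups": ["cultivar", "landrace"],
    "phs": {"window_bp": 50_000, "merge_gap_bp": 1_000_000,
            "bin_width": 0.05, "tail_fraction": 0.025, "min_bin_count": 200,
            "max_carrier_freq": 0.95},
    "donor": {"win_bp": 3_000_000},
    "overlap": {"window_bp": 50_000, "n_perm": 1_000},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_params(config: dict, stage: str) -> dict:
    merged = dict(DEFAULTS.get(stage, {}))
    merged.update(config.get(stage, {}) or {})
    return merged


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise ValueError("config must set a top-level seed")
    seed = int(config["seed"])
    manifest: dict = {"config": config, "stages": {}, "outputs": {},
                      "summary": {}}
    files: dict[str, Path] = {}

    def record(stage: str, params: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = params
        for name, path in outputs.items():
            files[f"{stage}/{name}"] = Path(path)

    try:
        # ------------------------------------------------------------ inputs
        if "simulate" in config:
            sim_cfg = config_from_dict({"seed": seed,
                                        **(config["simulate"] or {})})
            sim = simulate_population(sim_cfg)
            sim_paths = sim.write(out / "sim")
            panel = sim.panel
            gmap = sim.genetic_map
            hmap = sim.homoeolog_map
            donor_table = sim.donor_table
            outgroup = sim.outgroup_table
            chrom_lengths = sim.chrom_lengths(sim_cfg)
            record("simulate", {"seed": seed, **(config["simulate"] or {})},
                   sim_paths)
        else:
            inputs = config["inputs"]
            gmap = GeneticMap.read_tsv(inputs["map"])
            panel = read_panel(inputs["vcf"], inputs["metadata"],
                               genetic_map=gmap)
            hmap = hm.read_homoeolog_map(inputs["homoeologs"]) \
                if "homoeologs" in inputs else None
            donor_table = (pd.read_csv(inputs["donor"], sep="\t",
                                       dtype={"chrom": str})
                           if "donor" in inputs else None)
            outgroup = (pd.read_csv(inputs["outgroup"], sep="\t",
                                    dtype={"chrom": str})
                        if "outgroup" in inputs else None)
            chrom_lengths = {c: int(l) for c, l in
                             (inputs.get("chrom_lengths") or {}).items()} or None
            record("load", {k: str(v) for k, v in inputs.items()}, {})

        # ------------------------------------------------------------ filter
        fpar = _stage_params(config, "filter")
        panel, tally = filter_sites(panel, fpar["min_called_lines"],
                                    fpar["max_het_lines"])
        panel = maf_filter(panel, fpar["min_maf"])
        fpaths = write_panel(panel, out / "filtered", prefix="filtered")
        record("filter", {**fpar, "tally": tally,
                          "n_after_maf": panel.n_variants}, fpaths)

        # ---------------------------------------------------------- annotate
        if outgroup is not None:
            panel = fx.assign_ancestral(panel, outgroup)
        spectrum = fx.daf_spectrum_by_class(panel, mode="maf")
        spath = out / "annotate.maf_spectrum.tsv"
        spectrum.to_csv(spath, sep="\t")
        record("annotate",
               {"n_ancestral_assigned":
                panel.provenance.get("n_ancestral_assigned", 0)},
               {"maf_spectrum": spath})

        # --------------------------------------------------------- diversity
        dpar = _stage_params(config, "diversity")
        wdiv = dv.window_diversity(panel, dpar["win_bp"], dpar["step_bp"],
                                   dpar["min_covered_bp"],
                                   chrom_lengths=chrom_lengths)
        wfst = dv.window_fst(panel, tuple(config.get("fst_groups",
                                                     DEFAULTS["fst_groups"])),
                             dpar["win_bp"], dpar["step_bp"],
                             chrom_lengths=chrom_lengths)
        windows = pd.concat([wdiv, wfst], ignore_index=True)
        windows = dv.call_outlier_windows(windows, dpar["tail_fraction"],
                                          dpar["tails"])
        wpath = out / "diversity.windows.tsv"
        windows.to_csv(wpath, sep="\t", index=False)
        div_outputs = {"windows": wpath}
        if donor_table is not None and len(donor_table):
            dnpar = _stage_params(config, "donor")
            landraces = panel.group_lines("landrace")
            donor_win = dv.donor_allele_windows(panel, donor_table, landraces,
                                                dnpar["win_bp"],
                                                chrom_lengths=chrom_lengths)
            dpath = out / "diversity.donor_windows.tsv"
            donor_win.to_csv(dpath, sep="\t", index=False)
            div_outputs["donor_windows"] = dpath
            dsub = donor_win["value"].dropna()
            manifest["summary"]["mean_donor_freq"] = (
                float(dsub.mean()) if len(dsub) else None)
        record("diversity", dpar, div_outputs)
        pi_rows = windows[(windows["statistic"] == "pi")
                          & windows["value"].notna()]
        manifest["summary"]["mean_pi_per_bp"] = {
            sg: float(s["value"].mean())
            for sg, s in pi_rows.groupby("subgenome")}

        # --------------------------------------------------------------- PHS
        ppar = _stage_params(config, "phs")
        phs_res = ph.compute_phs(panel, ppar["max_carrier_freq"])
        phs_res = ph.phs_thresholds(phs_res, ppar["bin_width"],
                                    ppar["tail_fraction"],
                                    ppar["min_bin_count"])
        ppath = out / "phs.results.tsv"
        phs_res.to_csv(ppath, sep="\t", index=False)
        record("phs", ppar, {"results": ppath})

        # ------------------------------------------------------------ sweeps
        sweeps_by_genome: dict[str, list[SweepRegion]] = {}
        for sg in sorted(phs_res["subgenome"].unique()):
            regs = ph.call_sweeps(phs_res[phs_res["subgenome"] == sg],
                                  ppar["window_bp"], ppar["merge_gap_bp"])
            sweeps_by_genome[sg] = regs
        bpath = out / "sweeps.phs.bed"
        regions_to_bed([r for regs in sweeps_by_genome.values()
                        for r in regs], bpath)
        record("sweeps", {"window_bp": ppar["window_bp"],
                          "merge_gap_bp": ppar["merge_gap_bp"]},
               {"phs_bed": bpath})
        manifest["summary"]["n_sweep_regions"] = {
            sg: len(regs) for sg, regs in sweeps_by_genome.items()}

        # ----------------------------------------------------------- overlap
        if hmap is not None and all(len(r) for r in sweeps_by_genome.values()) \
                and chrom_lengths is not None:
            opar = _stage_params(config, "overlap")
            oseed = int(opar.get("seed", seed + 1))
            if "seed" not in opar and "seed" not in (config.get("overlap") or {}):
                opar["seed"] = oseed
            results = hm.overlap_test(sweeps_by_genome, hmap, chrom_lengths,
                                      opar["window_bp"], opar["n_perm"],
                                      oseed)
            opath = out / "overlap.json"
            odata = [r.as_dict() for r in results]
            with open(opath, "w") as fh:
                json.dump(odata, fh, indent=1, sort_keys=True)
            co_rows = []
            for r in results:
                X, Y = r.genomes
                pairs = hm.overlapping_region_pairs(
                    sweeps_by_genome[X], sweeps_by_genome[Y], hmap, X, Y)
                table, frac = hm.coincident_selection(pairs, phs_res, panel)
                co_rows.append({"genomes": f"{X}-{Y}",
                                "n_region_pairs": len(table),
                                "fraction_without_cooccurrence": frac})
            cpath = out / "overlap.cooccurrence.json"
            with open(cpath, "w") as fh:
                json.dump(co_rows, fh, indent=1, sort_keys=True)
            record("overlap", opar, {"results": opath, "cooccurrence": cpath})
            manifest["summary"]["overlap"] = odata
            manifest["summary"]["cooccurrence"] = co_rows
        else:
            log.info("overlap stage skipped (no map/sweeps)")

        # -------------------------------------------------------- enrichment
        if "effect" in panel.variants.columns:
            snp_tail = np.zeros(panel.n_variants, dtype=bool)
            hits = phs_res[phs_res["outlier"]]
            snp_tail[hits["vidx"].to_numpy(int)] = True
            classes = panel.variants["effect"].to_numpy(object)
            each = en.tail_enrichment(classes, snp_tail)
            ns = en.tail_enrichment(classes, snp_tail, reference="synonymous")
            epath = out / "enrichment.classes.tsv"
            each.to_csv(epath, sep="\t", index=False)
            npath = out / "enrichment.vs_synonymous.tsv"
            ns.to_csv(npath, sep="\t", index=False)
            record("enrich", {"reference": "synonymous"},
                   {"classes": epath, "vs_synonymous": npath})
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        done = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}") from exc

    manifest["outputs"] = {k: _sha256(p) for k, p in sorted(files.items())}
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(manifest: dict, out_dir: str | Path, plot: bool = True) -> Path:
    """Render a summary document (markdown + optional window plot) from a
    completed manifest; every number is taken from the manifest/summary or
    the recorded stage outputs."""
    out = Path(out_dir)
    summary = manifest.get("summary", {})
    lines = ["# polysweep run report", ""]
    if "mean_pi_per_bp" in summary:
        lines.append("## Diversity (mean window pi per bp)")
        for sg, v in sorted(summary["mean_pi_per_bp"].items()):
            lines.append(f"- {sg}: {v:.3e}")
        lines.append("")
    if "mean_donor_freq" in summary and summary["mean_donor_freq"] is not None:
        lines.append(f"Mean donor-allele frequency (D windows): "
                     f"{summary['mean_donor_freq']:.3f}")
        lines.append("")
    nsweeps = summary.get("n_sweep_regions", {})
    lines.append("## PHS sweep regions")
    if any(nsweeps.values()):
        for sg, k in sorted(nsweeps.items()):
            lines.append(f"- {sg}: {k} region(s)")
    else:
        lines.append("Zero regions called.")
    lines.append("")
    if "overlap" in summary and any(nsweeps.values()):
        lines.append("## Homoeologous overlap")
        for row in summary["overlap"]:
            lines.append(f"- {row['genomes']}: "
                         + ", ".join(f"{k}={v:.4g}" for k, v in row.items()
                                     if k.startswith(("prop_", "p_"))))
        for row in summary.get("cooccurrence", []):
            frac = row["fraction_without_cooccurrence"]
            frac_s = "n/a" if frac is None or (isinstance(frac, float)
                                               and np.isnan(frac)) else f"{frac:.2f}"
            lines.append(f"- {row['genomes']}: {row['n_region_pairs']} "
                         f"overlapping pair(s), fraction without "
                         f"co-occurrence {frac_s}")
        lines.append("")
    rpath = out / "report.md"
    rpath.write_text("\n".join(lines) + "\n")
    if plot:
        wfile = out / "diversity.windows.tsv"
        if wfile.exists():
            _plot_windows(wfile, out / "report.windows.png")
    return rpath


def _plot_windows(windows_tsv: Path, png: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    win = pd.read_csv(windows_tsv, sep="\t")
    stats = [s for s in ("pi", "tajimas_d", "fst")
             if s in set(win["statistic"])]
    fig, axes = plt.subplots(len(stats), 1, figsize=(8, 2.2 * len(stats)),
                             sharex=True, squeeze=False)
    for ax, stat in zip(axes[:, 0], stats):
        for chrom, sub in win[win["statistic"] == stat].groupby("chrom"):
            ax.plot(sub["start"] / 1e6, sub["value"], label=chrom, lw=0.8)
        ax.set_ylabel(stat)
        ax.legend(fontsize=6)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(png, dpi=100)
    plt.close(fig)
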