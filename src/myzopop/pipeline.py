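"""End-to-end orchestration: simulate (or load) → filter → classify →
statistics → report.

``run_full_analysis`` drives the whole analysis and writes a report
directory of TSV artifacts shaped like the study's summary tables: windowed
and compartment-averaged pi / dxy / FST / Tajima's D, quartet introgression
summaries (D, f4 ratio, fdM) for the two topologies, triangle-plot records,
PCA coordinates, maternal-marker contingency tests, private/fixed/shared
allele counts, and the mitochondrial haplotype network.  Every output file
carries the configuration hash in a header comment so mixed-provenance
reports are detectable.

Two input modes share the downstream code path: ``simulate`` (default,
self-contained) and ``vcf`` (user-supplied all-sites VCF + sample sheet +
compartment BED).
"""

from __future__ import annotations

import json
import logging
import pathlib


import numpy as np
import pandas as pd

from . import alleles as alleles_mod
from . import diversity as div
from . import genotype_io as gio
from . import haplonet as hn
from . import hybrids as hyb
from . import introgression as intro
from . import sexlinkage as sexl
from . import simulate as sim

log = logging.getLogger("myzopop")

#: the filter cascade in its mandatory order
FILTER_ORDER = ("hard_site_filters", "depth_filters", "female_hemizygote_mask")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s ...", name)
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def _write_tsv(df: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _setup_logging(outdir: pathlib.Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [
        h for h in log.handlers if not isinstance(h, logging.FileHandler)
    ]
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


# ---------------------------------------------------------------------------
# population bookkeeping
# ---------------------------------------------------------------------------

def _pops(sheet: pd.DataFrame) -> dict[str, list[str]]:
    g = gio.samples_for
    return {
        "card_allo": g(sheet, species="card", locality="allopatric"),
        "card_sym": g(sheet, species="card", locality="sympatric"),
        "tris_allo": g(sheet, species="tris", locality="allopatric"),
        "tris_sym": g(sheet, species="tris", locality="sympatric"),
        "pulc": g(sheet, species="pulc"),
        "sympatric_all": sheet.loc[
            sheet["locality"] == "sympatric", "sample_id"
        ].tolist(),
    }


def _females(sheet: pd.DataFrame, ids: list[str]) -> list[str]:
    sex = dict(zip(sheet["sample_id"], sheet["sex"]))
    return [s for s in ids if sex.get(s) == "F"]


def _region_contigs(cmap: gio.CompartmentMap, labels) -> list[str]:
    iv = cmap.intervals
    return iv.loc[iv["label"].isin(list(labels)), "contig"].unique().tolist()


def _subset_region(table: gio.GenotypeTable, contigs: list[str]) -> gio.GenotypeTable:
    m = table.sites["contig"].isin(contigs).to_numpy()
    return table.take_sites(np.flatnonzero(m))


# ---------------------------------------------------------------------------
# the orchestrator
# ---------------------------------------------------------------------------

def run_full_analysis(
    config=None,
    outdir="myzopop_report",
    mode: str = "simulate",
    vcf_path=None,
    sample_sheet_path=None,
    bed_path=None,
    coverage_path=None,
    write_vcf: bool = True,
    plots: bool = True,
) -> dict:
    """Run the full analysis and write a report directory.

    ``config`` is a :class:`~myzopop.simulate.ScenarioConfig`, a mapping of
    overrides, or a path to a JSON file of overrides.  In ``vcf`` mode the
    three input paths replace the simulation stage (the scenario config then
    only carries thresholds/seed).  Returns a dict of artifact paths.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)

    if isinstance(config, sim.ScenarioConfig):
        cfg = config
    elif isinstance(config, (str, pathlib.Path)):
        with open(config) as fh:
            cfg = sim.build_scenario_config(json.load(fh))
    else:
        cfg = sim.build_scenario_config(config or {})
    chash = cfg.config_hash()
    (out / "scenario.json").write_text(cfg.to_json())
    log.info("config hash %s", chash)
    paths: dict[str, str] = {"outdir": str(out)}

    # ---- inputs ----------------------------------------------------------
    if mode == "simulate":
        dataset = _stage("simulate")(sim.simulate_dataset)(cfg, materialize=True)
        sheet = dataset.sample_sheet
        cmap = dataset.compartment_map
        table = dataset.allsites
        coverage = dataset.coverage
        if write_vcf:
            paths.update(_stage("emit")(sim.emit_dataset)(dataset, out / "data"))
        _write_tsv(dataset.truth.samples, out / "truth.tsv", chash)
    elif mode == "vcf":
        sheet = gio.read_sample_sheet(sample_sheet_path)
        cmap = gio.CompartmentMap.from_bed(bed_path)
        table = _stage("read_vcf")(gio.read_allsites_vcf)(vcf_path, sheet, cmap)
        coverage = None
        if coverage_path is not None:
            coverage = sexl.CoverageProfile.from_tsv(
                coverage_path, sheet, _region_contigs(cmap, ["autosome"])
            )
        dataset = None
    else:
        raise StageError(f"unknown mode {mode!r}")

    # ---- filtering cascade ----------------------------------------------
    @_stage("filter")
    def _filter(t):
        t = gio.apply_hard_site_filters(t)
        t = gio.apply_depth_filters(t, cmap)
        t = gio.mask_female_sex_heterozygotes(t, cmap, sheet)
        stages = tuple(e["stage"] for e in t.filter_log)
        assert stages == FILTER_ORDER, f"filter order violated: {stages}"
        counts = [e["sites_out"] for e in t.filter_log]
        assert all(a >= b for a, b in zip(counts, counts[1:])), "site counts increased"
        return t

    table = _filter(table)
    gio.write_filter_log(table, out / "filter_log.tsv")

    # ---- sex-linkage classification --------------------------------------
    if coverage is not None:
        @_stage("sexlinkage")
        def _sexlink():
            norm = sexl.compute_normalized_coverage(coverage)
            calls = sexl.classify_contigs(norm)
            _write_tsv(calls, out / "sexlinkage_calls.tsv", chash)
            return calls

        _sexlink()
        paths["sexlinkage"] = str(out / "sexlinkage_calls.tsv")

    pops = _pops(sheet)

    # ---- diversity --------------------------------------------------------
    @_stage("diversity")
    def _diversity():
        summaries = []
        for name in ("card_allo", "card_sym", "tris_allo", "tris_sym"):
            if not pops[name]:
                continue
            pi = div.windowed_pi(table, pops[name], cmap, sample_sheet=sheet)
            _write_tsv(pi, out / f"pi_windows_{name}.tsv", chash)
            s = div.compartment_summary(pi)
            s.insert(0, "population", name)
            s.insert(1, "statistic", "pi")
            summaries.append(s)
            td = div.windowed_tajimas_d(table, pops[name], cmap)
            _write_tsv(td, out / f"tajimas_d_windows_{name}.tsv", chash)
            ts = div.compartment_summary(td)
            ts.insert(0, "population", name)
            ts.insert(1, "statistic", "tajimas_d")
            summaries.append(ts)
        pairs = [
            ("card_allo", "card_sym"), ("tris_allo", "tris_sym"),
            ("card_allo", "tris_allo"), ("card_allo", "tris_sym"),
            ("tris_allo", "card_sym"), ("card_sym", "tris_sym"),
        ]
        for a, b in pairs:
            if not (pops[a] and pops[b]):
                continue
            fst = div.windowed_fst(table, pops[a], pops[b], cmap, sample_sheet=sheet)
            _write_tsv(fst, out / f"fst_windows_{a}_vs_{b}.tsv", chash)
            fs = div.compartment_summary(fst)
            fs.insert(0, "population", f"{a}_vs_{b}")
            fs.insert(1, "statistic", "fst")
            summaries.append(fs)
            dxy = div.windowed_dxy(table, pops[a], pops[b], cmap, sample_sheet=sheet)
            _write_tsv(dxy, out / f"dxy_windows_{a}_vs_{b}.tsv", chash)
            dx = div.compartment_summary(dxy)
            dx.insert(0, "population", f"{a}_vs_{b}")
            dx.insert(1, "statistic", "dxy")
            summaries.append(dx)
        allsum = pd.concat(summaries, ignore_index=True)
        _write_tsv(allsum, out / "compartment_summaries.tsv", chash)
        return allsum

    _diversity()
    paths["compartment_summaries"] = str(out / "compartment_summaries.tsv")

    # ---- introgression ----------------------------------------------------
    @_stage("introgression")
    def _introgression():
        if not (pops["pulc"] and pops["card_sym"] and pops["tris_sym"]):
            log.info("skipping quartets: missing populations")
            return None
        topologies = {
            "McardP3": intro.QuartetSpec(
                pops["tris_allo"], pops["tris_sym"], pops["card_sym"], pops["pulc"],
                "McardP3",
            ),
            "MtrisP3": intro.QuartetSpec(
                pops["card_allo"], pops["card_sym"], pops["tris_sym"], pops["pulc"],
                "MtrisP3",
            ),
        }
        regions = {
            "autosome": (("autosome",), 100, False),
            "neoPAR": (("neoPAR",), 100, False),
            "Z": (("Z",), 100, False),
            "neoZ": (("neoZ",), 100, False),
            "WneoW": (("W", "neoW"), 50, True),
        }
        results, fdm_frames = [], []
        for rname, (labels, wsnps, females_only) in regions.items():
            sub = _subset_region(table, _region_contigs(cmap, labels))
            for tname, q in topologies.items():
                if females_only:
                    q = intro.QuartetSpec(
                        _females(sheet, q.p1), _females(sheet, q.p2),
                        _females(sheet, q.p3), _females(sheet, q.p4), q.label,
                    )
                    if not all((q.p1, q.p2, q.p3, q.p4)):
                        continue
                f, _ = intro.derived_frequencies(sub, q)
                if len(f) < 40:
                    log.info("region %s topology %s: too few SNPs (%d)", rname, tname, len(f))
                    continue
                n_blocks = min(20, max(2, len(f) // 20))
                res = intro.quartet_analysis(sub, q, n_blocks=n_blocks, fdm_window_snps=wsnps)
                res.label = f"{tname}:{rname}"
                results.append(res)
                if res.fdm_windows is not None:
                    fw = res.fdm_windows.copy()
                    fw.insert(0, "label", res.label)
                    fdm_frames.append(fw)
        if results:
            _write_tsv(intro.results_table(results), out / "quartet_summary.tsv", chash)
            if fdm_frames:
                _write_tsv(pd.concat(fdm_frames, ignore_index=True), out / "fdm_windows.tsv", chash)
        return results

    intro_results = _introgression()
    paths["quartet_summary"] = str(out / "quartet_summary.tsv")

    # ---- hybrids ----------------------------------------------------------
    @_stage("hybrids")
    def _hybrids():
        if not (pops["card_allo"] and pops["tris_allo"]):
            log.info("skipping hybrid analyses: no allopatric reference panels")
            return None
        panel = hyb.fixed_difference_panel(
            table, pops["card_allo"], pops["tris_allo"], compartment_map=cmap
        )
        panel.to_tsv(out / "diagnostic_panel.tsv")
        sym = pops["sympatric_all"]
        auto_panel = panel.subset(("autosome", "neoPAR"))
        tri = hyb.triangle_records(table, auto_panel, sym)
        tri.insert(1, "panel", "autosome")
        males = [s for s in sym if dict(zip(sheet["sample_id"], sheet["sex"]))[s] == "M"]
        z_panel = panel.subset(("Z", "neoZ"))
        if len(z_panel) and males:
            triz = hyb.triangle_records(table, z_panel, males)
            triz.insert(1, "panel", "ZneoZ")
            tri = pd.concat([tri, triz], ignore_index=True)
        _write_tsv(tri, out / "triangle_records.tsv", chash)

        anc_rows = []
        for s in sym:
            props = hyb.ancestry_proportion(table, panel, s)
            for comp, p in props.items():
                anc_rows.append({"sample_id": s, "compartment": comp, **p})
        _write_tsv(pd.DataFrame(anc_rows), out / "ancestry_proportions.tsv", chash)

        mat = hyb.maternal_assignments(table, panel, sheet["sample_id"].tolist())
        _write_tsv(mat, out / "maternal_assignments.tsv", chash)

        pruned = gio.prepare_individual_dataset(table)
        auto_sub = _subset_region(pruned, _region_contigs(cmap, ["autosome", "neoPAR"]))
        everyone = sheet.loc[sheet["species"] != "pulc", "sample_id"].tolist()
        coords, explained = hyb.genotype_pca(
            auto_sub, everyone, orient_negative=pops["card_allo"] or None
        )
        coords["explained_PC1"] = explained[0] if len(explained) else np.nan
        _write_tsv(coords, out / "pca_autosomes.tsv", chash)
        return panel, tri, mat, coords

    hybrid_out = _hybrids()
    paths["triangle_records"] = str(out / "triangle_records.tsv")

    # ---- allele classes + maternal asymmetry ------------------------------
    @_stage("alleles")
    def _alleles():
        rows = []
        for focal, other in (("card", "tris"), ("tris", "card")):
            fs = gio.samples_for(sheet, species=focal)
            os_ = gio.samples_for(sheet, species=other)
            if not (fs and os_):
                continue
            res = alleles_mod.private_alleles(
                table, fs, os_,
                sample_localities=dict(zip(sheet["sample_id"], sheet["locality"])),
                region="genome",
            )
            rows.append({"comparison": f"private_{focal}", "n_private": res.n_private})
        if pops["card_allo"] and pops["tris_allo"]:
            res = alleles_mod.fixed_and_shared(
                table, pops["card_allo"], pops["tris_allo"], region="genome"
            )
            rows.append(
                {
                    "comparison": "allo_card_vs_allo_tris",
                    "n_fixed": res.n_fixed,
                    "n_shared": res.n_shared_polymorphic,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "allele_classes.tsv", chash)

        if hybrid_out is None:
            return None
        mat = hybrid_out[2]
        tests = []
        for females_only, label in ((True, "W_neoW_females"), (False, "mt_all")):
            ct = alleles_mod.build_maternal_contingency(
                mat, sheet, females_only=females_only
            )
            if ct.sum() == 0:
                continue
            odds, p = alleles_mod.maternal_marker_asymmetry_test(ct)
            tests.append(
                {
                    "test": label, "card_match": ct[0, 0], "card_mismatch": ct[0, 1],
                    "tris_match": ct[1, 0], "tris_mismatch": ct[1, 1],
                    "odds_ratio": odds, "p": p,
                }
            )
        _write_tsv(pd.DataFrame(tests), out / "maternal_asymmetry_tests.tsv", chash)
        return tests

    _alleles()
    paths["maternal_asymmetry"] = str(out / "maternal_asymmetry_tests.tsv")

    # ---- mitochondrial haplotype network ----------------------------------
    @_stage("haplonet")
    def _haplonet():
        mt_sub = _subset_region(table, _region_contigs(cmap, ["mt"]))
        if not mt_sub.is_biallelic_snp().any():
            log.info("no mitochondrial variant sites; skipping network")
            return None
        nodes = hn.collapse_haplotypes(
            mt_sub, sheet["sample_id"].tolist(), sample_sheet=sheet
        )
        net = hn.build_network(nodes)
        net.to_tsvs(out / "haplonet_nodes.tsv", out / "haplonet_edges.tsv")
        net.to_graphml(out / "haplonet.graphml")
        return net

    net = _haplonet()
    paths["haplonet_nodes"] = str(out / "haplonet_nodes.tsv")

    if plots:
        try:
            _make_plots(out, hybrid_out, intro_results, net)
        except Exception as e:  # plotting is best-effort presentation
            log.warning("plotting failed: %s", e)

    log.info("report complete: %s", out)
    return paths


def _make_plots(out: pathlib.Path, hybrid_out, intro_results, net) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    if hybrid_out is not None:
        _, tri, _, coords = hybrid_out
        fig, ax = plt.subplots(figsize=(5, 4))
        sub = tri[tri["panel"] == "autosome"]
        ax.scatter(sub["h"], sub["h_int"], s=18)
        ax.plot([0, 0.5, 1], [0, 1, 0], "k--", lw=0.8)
        ax.set_xlabel("hybrid index (tris allele fraction)")
        ax.set_ylabel("interspecific heterozygosity")
        fig.savefig(plots / "triangle.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(coords["PC1"], coords.get("PC2", coords["PC1"] * 0), s=18)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.savefig(plots / "pca.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
    if intro_results:
        fig, ax = plt.subplots(figsize=(6, 4))
        for r in intro_results:
            if r.fdm_windows is not None and len(r.fdm_windows):
                ax.plot(r.fdm_windows["window"], r.fdm_windows["fdm"], label=r.label, lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("window")
        ax.set_ylabel("fdM")
        ax.legend(fontsize=6)
        fig.savefig(plots / "fdm_tracks.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
    if net is not None:
        import networkx as nx

        fig, ax = plt.subplots(figsize=(5, 5))
        pos = nx.spring_layout(net.graph, seed=0)
        sizes = [30 * net.graph.nodes[n]["multiplicity"] for n in net.graph]
        nx.draw_networkx(net.graph, pos, ax=ax, node_size=sizes, font_size=6)
        fig.savefig(plots / "haplonet.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
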