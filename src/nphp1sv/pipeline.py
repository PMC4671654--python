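"""Pipeline orchestration: run the analysis stages in dependency order over
a configured output directory, with per-stage logging and provenance.

Stages (in order): simulate -> detect-lcr -> scan-motifs -> call-fosmid ->
call-rmap -> call-dosage -> genotype -> popstats.  Each stage reads only
files written by earlier stages, so any subset can be re-run as long as its
inputs exist; a missing upstream artifact raises an error naming the stage
that produces it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import caller, dosage, fosmid, lcr, popstats, rmap as rmap_mod, simulate
from .io import (
    PipelineConfig,
    architecture_to_bed,
    read_dosage,
    read_esps,
    read_fasta,
    read_rmaps,
    read_tsv,
    write_dosage,
    write_esps,
    write_fasta,
    write_rmaps,
    write_tsv,
)
from .locus import Genotype, build_reference_architecture, make_haplotype

__all__ = ["STAGES", "run_pipeline"]

log = logging.getLogger("nphp1sv")

STAGES = ("simulate", "detect-lcr", "scan-motifs", "call-fosmid",
          "call-rmap", "call-dosage", "genotype", "popstats")

# artifact -> stage that writes it
_PRODUCERS = {
    "h1_sequence.fa": "simulate",
    "esps.tsv": "simulate",
    "rmap_molecules.tsv": "simulate",
    "acgh.tsv": "simulate",
    "readdepth.tsv": "simulate",
    "population.tsv": "simulate",
    "fosmid_calls.tsv": "call-fosmid",
    "fosmid_evidence.tsv": "call-fosmid",
    "rmap_calls.tsv": "call-rmap",
    "dosage_calls.tsv": "call-dosage",
}


def _require(outdir: Path, artifact: str, stage: str) -> Path:
    path = outdir / artifact
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires '{artifact}', which is produced by "
            f"stage '{_PRODUCERS[artifact]}'; run that stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, stages=None, outdir=None) -> dict:
    """Execute the requested stages; returns {artifact name: path}."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    arch = build_reference_architecture()
    params = config.sim_params()
    artifacts: dict = {}

    for stage in todo:
        log.info("stage %s: starting", stage)
        if stage == "simulate":
            truth = Genotype.diploid(*(make_haplotype(l, arch)
                                       for l in config.truth_genotype))
            h1 = make_haplotype("H1", arch)
            write_fasta(out / "h1_sequence.fa",
                        {"H1": simulate.synth_haplotype_sequence(arch, h1, params)})
            (out / "architecture.bed").write_text(architecture_to_bed(arch))
            esps = simulate.simulate_fosmid_library(truth, config.n_clones, params)
            write_esps(out / "esps.tsv", esps, config, config.seed)
            mols = []
            for hap_label in dict.fromkeys(config.truth_genotype):
                hap = make_haplotype(hap_label, arch)
                for m in simulate.simulate_rmaps(hap, params, config.n_molecules):
                    mols.append(rmap_mod.Rmap(f"{hap_label}:{m.map_id}",
                                              m.enzyme, m.fragments))
            write_rmaps(out / "rmap_molecules.tsv", mols, config, config.seed)
            # NA10851-like universal aCGH reference: four 45 kb copies (H2/H2)
            ref = Genotype.diploid(make_haplotype("H2", arch),
                                   make_haplotype("H2", arch))
            probes = simulate.default_probe_table(arch)
            write_dosage(out / "acgh.tsv",
                         simulate.simulate_acgh(truth, ref, probes, params, arch),
                         config, config.seed, width=60)
            write_dosage(out / "readdepth.tsv",
                         simulate.simulate_readdepth(truth, params, arch),
                         config, config.seed, width=params.readdepth_window)
            pop = simulate.sample_population(config.populations,
                                             config.n_individuals, params, arch)
            write_tsv(out / "population.tsv", pd.DataFrame(
                [(s.individual_id, s.population, int(round(s.genotype.total45)))
                 for s in pop],
                columns=["individual_id", "population", "cn45"],
            ), config, config.seed)

        elif stage == "detect-lcr":
            seqs = read_fasta(_require(out, "h1_sequence.fa", stage))
            seq = next(iter(seqs.values()))
            pairs = lcr.detect_paralogs(seq, k=config.lcr_k,
                                        min_block=config.lcr_min_block,
                                        min_identity=config.lcr_min_identity)
            fams = lcr.group_paralog_families(pairs)
            write_tsv(out / "paralog_pairs.tsv", pd.DataFrame(
                [(p.block_a.start, p.block_a.end, p.block_b.start, p.block_b.end,
                  p.relative_orientation, round(p.identity, 6),
                  round(p.identity_gapped, 6), p.n_anchors) for p in pairs],
                columns=["a_start", "a_end", "b_start", "b_end", "orientation",
                         "identity", "identity_gapped", "n_anchors"],
            ), config, config.seed)
            bed = []
            for fi, fam in enumerate(fams):
                for m in fam.members:
                    bed.append(f"seq\t{m.start}\t{m.end}\tfamily{fi}\t0\t+")
            (out / "paralog_blocks.bed").write_text("\n".join(bed) + "\n")

        elif stage == "scan-motifs":
            seqs = read_fasta(_require(out, "h1_sequence.fa", stage))
            seq = next(iter(seqs.values()))
            hits = lcr.scan_prdm9(seq, threshold=config.motif_threshold)
            write_tsv(out / "prdm9_hits.tsv", pd.DataFrame(
                [(h.position, h.strand, h.score_fraction) for h in hits],
                columns=["position", "strand", "score_fraction"],
            ), config, config.seed)

        elif stage == "call-fosmid":
            esps = read_esps(_require(out, "esps.tsv", stage))
            calls = [fosmid.classify_esp(e, config.insert_min, config.insert_max,
                                         config.min_mapq, arch) for e in esps]
            write_tsv(out / "fosmid_calls.tsv", pd.DataFrame(
                [(c.clone_id, c.call_class, c.ref_span, c.side) for c in calls],
                columns=["clone_id", "call_class", "ref_span", "side"],
            ), config, config.seed)
            ev = fosmid.aggregate_individual(calls, config.min_support)
            write_tsv(out / "fosmid_evidence.tsv", pd.DataFrame(
                [(dict(ev.counts).get(c, 0)) for c in fosmid.CLASSES],
                index=list(fosmid.CLASSES), columns=["count"],
            ).T, config, config.seed)

        elif stage == "call-rmap":
            mols = read_rmaps(_require(out, "rmap_molecules.tsv", stage))
            clusters: dict = {}
            for m in mols:
                origin = m.map_id.split(":", 1)[0]
                clusters.setdefault(origin, []).append(m)
            sites = (simulate.default_swai_sites(arch)
                     if params.swai_sites is None else params.swai_sites)
            candidates = rmap_mod.candidate_rmaps(arch, sites)
            consensi = [
                rmap_mod.consensus_rmap(cluster, config.rmap_sigma_rel,
                                        config.rmap_c_cut, config.rmap_delta,
                                        map_id=origin)
                for origin, cluster in clusters.items()
            ]
            callset = rmap_mod.call_haplotype_rmap(
                consensi, candidates, config.rmap_margin, config.rmap_sigma_rel,
                config.rmap_c_cut, config.rmap_delta, config.rmap_min_fragment_kb)
            write_tsv(out / "rmap_calls.tsv", pd.DataFrame(
                [(c.map_id, c.best, round(c.cost, 3), c.runner_up,
                  round(c.margin, 3), c.ambiguous) for c in callset.calls],
                columns=["map_id", "best", "cost", "runner_up", "margin",
                         "ambiguous"],
            ), config, config.seed)

        elif stage == "call-dosage":
            d = read_dosage(_require(out, "acgh.tsv", stage))
            c45 = arch.copy("45MID").interval
            region = d.subset(c45.start, c45.end)
            mean_lr, dlrs = dosage.summarize_region(region)
            call = dosage.estimate_cn_intra(mean_lr, cn_ref=config.cn_ref)
            write_tsv(out / "dosage_calls.tsv", pd.DataFrame(
                [["45K", round(mean_lr, 4),
                  round(dlrs, 4) if dlrs is not None else "", call.cn, call.rule]],
                columns=["target", "mean_lr", "dlrs", "cn", "rule"],
            ), config, config.seed)

        elif stage == "genotype":
            calls_df = read_tsv(_require(out, "rmap_calls.tsv", stage),
                                ["map_id", "best", "ambiguous"])
            fos_df = read_tsv(_require(out, "fosmid_calls.tsv", stage),
                              ["clone_id", "call_class", "ref_span", "side"])
            dos_df = read_tsv(_require(out, "dosage_calls.tsv", stage),
                              ["target", "mean_lr", "cn"])
            fcalls = [fosmid.ESPCall(str(r.clone_id), str(r.call_class),
                                     int(r.ref_span), str(r.side))
                      for r in fos_df.itertuples(index=False)]
            ev = fosmid.aggregate_individual(fcalls, config.min_support)
            cn_call = dosage.estimate_cn_intra(float(dos_df["mean_lr"].iloc[0]),
                                               cn_ref=config.cn_ref)
            report = caller.integrate_evidence(
                ev, list(calls_df["best"]), cn_call, sample_id="sample")
            write_tsv(out / "genotype_report.tsv", pd.DataFrame(
                [[report.sample_id, ",".join(report.allele_types),
                  ";".join("/".join(g) for g in report.consistent_genotypes),
                  report.total45, ";".join(report.protection),
                  report.mosaic, ",".join(report.flags)]],
                columns=["sample_id", "allele_types", "consistent_genotypes",
                         "total45", "protection", "mosaic", "flags"],
            ), config, config.seed)
            (out / "genotype_report.txt").write_text(_report_text(report))

        elif stage == "popstats":
            pop_df = read_tsv(_require(out, "population.tsv", stage),
                              ["individual_id", "population", "cn45"])
            groups = [g["cn45"].to_numpy()
                      for _, g in pop_df.groupby("population")]
            res = popstats.kruskal_wallis(groups)
            freq = (pop_df.groupby("population")["cn45"]
                    .value_counts(normalize=True).rename("frequency")
                    .reset_index())
            write_tsv(out / "cn_distribution.tsv", freq, config, config.seed)
            write_tsv(out / "popstats.tsv", pd.DataFrame(
                [[res.method, round(res.statistic, 6), res.df,
                  round(res.p_value, 6)]],
                columns=["method", "statistic", "df", "p_value"],
            ), config, config.seed)

        log.info("stage %s: done", stage)

    for name in _PRODUCERS:
        if (out / name).exists():
            artifacts[name] = out / name
    return artifacts


def _report_text(report) -> str:
    lines = [
        f"sample: {report.sample_id}",
        f"rmap allele types: {', '.join(report.allele_types) or 'none'}",
        f"diploid 45 kb LCR copies (dosage): {report.total45}",
        "consistent genotypes: "
        + ("; ".join("/".join(g) + f" [{p}]" for g, p in
                     zip(report.consistent_genotypes, report.protection))
           or "none"),
        f"mosaic: {'yes' if report.mosaic else 'no'}",
        f"flags: {', '.join(report.flags) or 'none'}",
    ]
    return "\n".join(lines) + "\n"
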