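"""End-to-end orchestration: simulate -> filter -> assign -> statistics.

:func:`run_pipeline` drives every stage over a shared :class:`RunConfig`,
writes each stage's outputs under the run directory, and produces a
machine-readable ``summary.json`` plus a ``manifest.txt`` of every
resolved parameter.  The default threshold profile, named ``kim2016``,
encodes the analysis constants used throughout: call rate > 0.5, MAC >= 4,
100-SNP windows, 10 Mb LD cap with 12-accession sub-sampling (100
replicates), 1000 Mantel permutations, 0.75 admixture threshold, MAF >
0.05 / < 3 % missing / Fisher p < 1e-5 for the introgression SNP screen,
and a 6-step haplotype-network connection limit.

A single run seed is expanded into per-stage seeds by a fixed counter
scheme (``seed + 10007 * stage_index``, mod 2^31) so any stage can be
re-run in isolation with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    domestication,
    geo_ibd,
    haplonet,
    io_meta,
    ld_decay,
    popgen_stats,
    structure_concordance,
    synthetic_data,
)

logger = logging.getLogger("orscpop")

ALL_STAGES = [
    "simulate", "filter", "assign", "fst", "pi", "dist", "tree",
    "ld", "mantel", "cpnet", "domestication", "concordance",
]

_STAGE_INDEX = {s: i for i, s in enumerate(ALL_STAGES)}


@dataclass
class RunConfig:
    """All pipeline thresholds plus the simulation config (profile kim2016)."""

    sim: synthetic_data.SimConfig = field(
        default_factory=lambda: synthetic_data.SimConfig(recomb_block_bp=2_000_000)
    )
    min_call_rate: float = 0.5
    min_mac: int = 4
    admix_threshold: float = 0.75
    maf_min: float = 0.05
    missing_max: float = 0.03
    p_cutoff: float = 1e-5
    connection_limit: int = 6
    group_limit: int = 2
    snps_per_window: int = 100
    ld_max_dist_bp: int = 10_000_000
    ld_bin_step_bp: int = 1_000_000
    n_sub: int = 12
    n_reps: int = 100
    n_perm: int = 1000
    seed: int = 0
    outdir: str = "orscpop_run"
    stages: tuple = tuple(ALL_STAGES)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + 10007 * _STAGE_INDEX[stage]) % (2**31)


def parse_config(path) -> RunConfig:
    """Read a flat ``key: value`` config file into a RunConfig."""
    cfg = RunConfig()
    sim_kwargs = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key.startswith("sim."):
            sim_kwargs[key[4:]] = _coerce(val)
        elif key == "stages":
            cfg = replace(cfg, stages=tuple(v.strip() for v in val.split(",")))
        elif hasattr(cfg, key):
            cfg = replace(cfg, **{key: _coerce(val)})
        else:
            raise ValueError(f"unknown config key {key!r}")
    if sim_kwargs:
        for k in sim_kwargs:
            if not hasattr(cfg.sim, k):
                raise ValueError(f"unknown simulation key sim.{k!r}")
        cfg = replace(cfg, sim=replace(cfg.sim, **sim_kwargs))
    return cfg


def _coerce(val: str):
    if val.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if "," in val:
        return tuple(_coerce(v.strip()) for v in val.split(","))
    return val


def write_manifest(cfg: RunConfig, path) -> None:
    with open(str(path), "w") as fh:
        for k, v in asdict(cfg).items():
            if k == "sim":
                for sk, sv in v.items():
                    fh.write(f"sim.{sk}: {sv}\n")
            else:
                fh.write(f"{k}: {v}\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages end to end; returns the summary dict.

    Stage outputs land under ``cfg.outdir``; any stage failure is re-raised
    annotated with the stage name.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cfg, out / "manifest.txt")
    state: dict = {}
    summary: dict = {"stages": {}}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FN[stage](cfg, state, summary, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _ensure_sim(cfg: RunConfig, state: dict) -> None:
    """Regenerate the simulated panel in memory when the simulate stage was
    not part of this run (generators are pure, so results are identical)."""
    if "g" in state:
        return
    g, meta, truth = synthetic_data.simulate_structured_genotypes(cfg.sim)
    meta = synthetic_data.simulate_geography(meta, truth, seed=cfg.stage_seed("simulate"))
    state.update(g=g, meta=meta, truth=truth)


def _ensure_groups(cfg: RunConfig, state: dict) -> None:
    """Derive subpopulation assignments if the assign stage was skipped."""
    _ensure_sim(cfg, state)
    if "groups" in state:
        return
    truth = state["truth"]
    assigned = structure_concordance.assign_subpop(
        truth.true_q, truth.group_names, threshold=cfg.admix_threshold
    )
    state["assigned"] = assigned
    groups = {
        name: [a for a, s in assigned.items() if s == name]
        for name in truth.group_names
    }
    state["groups"] = {k: v for k, v in groups.items() if len(v) >= 2}


def _stage_simulate(cfg, state, summary, out):
    g, meta, truth = synthetic_data.simulate_structured_genotypes(cfg.sim)
    meta = synthetic_data.simulate_geography(
        meta, truth, seed=cfg.stage_seed("simulate")
    )
    io_meta.write_genotypes(g, out / "genotypes.vcf", format="vcf")
    io_meta.write_metadata(meta, out / "metadata.tsv")
    io_meta.write_qmatrix(truth.true_q, out / "ancestry.meanQ")
    state.update(g=g, meta=meta, truth=truth)
    summary["stages"]["simulate"] = {
        "n_snps": g.n_snps, "n_accessions": g.n_accessions,
    }


def _stage_filter(cfg, state, summary, out):
    _ensure_sim(cfg, state)
    g, report = io_meta.filter_snps(
        state["g"], cfg.min_call_rate, cfg.min_mac, return_report=True
    )
    state["g"] = g
    summary["stages"]["filter"] = {
        "n_input": report.n_input,
        "n_removed_call_rate": report.n_removed_call_rate,
        "n_removed_mac": report.n_removed_mac,
        "n_retained": report.n_retained,
    }


def _stage_assign(cfg, state, summary, out):
    _ensure_sim(cfg, state)
    truth = state["truth"]
    qpath = out / "ancestry.meanQ"
    if qpath.exists():
        q = io_meta.read_qmatrix(qpath, list(truth.true_q.accession_ids))
    else:
        q = truth.true_q
    assigned = structure_concordance.assign_subpop(
        q, truth.group_names, threshold=cfg.admix_threshold
    )
    meta = state["meta"].copy()
    meta["subpop"] = meta["accession_id"].map(assigned.to_dict())
    state["meta"] = meta
    state["assigned"] = assigned
    groups = {
        name: [a for a, s in assigned.items() if s == name]
        for name in truth.group_names
    }
    state["groups"] = {k: v for k, v in groups.items() if len(v) >= 2}
    frac = float((assigned == structure_concordance.ADMIXED).mean())
    io_meta.write_metadata(meta, out / "metadata_assigned.tsv")
    summary["stages"]["assign"] = {
        "admixed_fraction": frac,
        "group_sizes": {k: len(v) for k, v in groups.items()},
    }


def _stage_fst(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    m = popgen_stats.pairwise_fst(state["g"], state["groups"], cfg.snps_per_window)
    m.to_frame().to_csv(out / "pairwise_fst.tsv", sep="\t")
    summary["stages"]["fst"] = {"pairwise_fst": m.to_frame().to_dict()}


def _stage_pi(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    windows = popgen_stats.make_windows(state["g"], cfg.snps_per_window)
    means = {}
    frames = []
    for name, ids in state["groups"].items():
        df = popgen_stats.pi_within(state["g"], ids, windows)
        df.insert(0, "pop", name)
        frames.append(df)
        means[name] = float(df["per_kb"].mean())
    pd.concat(frames, ignore_index=True).to_csv(out / "pi_windows.tsv", sep="\t", index=False)
    summary["stages"]["pi"] = {"mean_per_kb": means}


def _stage_dist(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    m = popgen_stats.pairwise_distance(state["g"], state["groups"])
    m.to_frame().to_csv(out / "pairwise_distance.tsv", sep="\t")
    state["group_dist"] = m
    summary["stages"]["dist"] = {"pairwise_d": m.to_frame().to_dict()}


def _stage_tree(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    m = state.get("group_dist")
    if m is None:
        m = popgen_stats.pairwise_distance(state["g"], state["groups"])
    if len(m.labels) >= 3:
        tree = popgen_stats.nj_tree(m)
        popgen_stats.write_newick(tree, out / "nj_groups.nwk")
        summary["stages"]["tree"] = {"n_taxa": len(m.labels)}
    else:
        summary["stages"]["tree"] = {"n_taxa": len(m.labels), "skipped": True}


def _stage_ld(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    pops = {k: v for k, v in state["groups"].items() if len(v) >= cfg.n_sub}
    edges = ld_decay.default_bin_edges(cfg.ld_max_dist_bp, cfg.ld_bin_step_bp)
    bins = ld_decay.subsample_ld(
        state["g"], pops, n_sub=cfg.n_sub, n_reps=cfg.n_reps,
        seed=cfg.stage_seed("ld"), bin_edges_bp=edges,
        max_dist_bp=cfg.ld_max_dist_bp,
    )
    ld_decay.write_ld_bins(bins, out / "ld_bins.tsv")
    summary["stages"]["ld"] = {
        name: {"first_bin_mean_r2": (None if np.isnan(df["mean_r2"].iloc[0])
                                     else float(df["mean_r2"].iloc[0]))}
        for name, df in bins.items()
    }


def _stage_mantel(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    meta = state["meta"]
    assigned = state["assigned"]
    keep = meta["accession_id"].map(
        lambda a: assigned.get(a) not in (None, structure_concordance.ADMIXED)
    )
    sub = meta[keep & meta["latitude"].notna() & meta["longitude"].notna()]
    geo = geo_ibd.geographic_matrix(sub)
    gen = popgen_stats.individual_distances(state["g"], ids=geo.labels)
    res = geo_ibd.mantel(gen, geo, n_perm=cfg.n_perm, seed=cfg.stage_seed("mantel"))
    geo_ibd.write_mantel(res, out / "mantel.tsv")
    summary["stages"]["mantel"] = {
        "r": res.r, "r2": res.r2, "p": res.p, "n": res.n, "n_perm": res.n_perm,
    }


def _stage_cpnet(cfg, state, summary, out):
    _ensure_sim(cfg, state)
    aln = synthetic_data.simulate_chloroplast(
        cfg.sim, state["truth"], seed=cfg.stage_seed("cpnet")
    )
    haplonet.write_alignment_tsv(aln, out / "chloroplast_sites.tsv")
    haplonet.write_alignment_fasta(aln, out / "chloroplast_sites.fasta")
    haps = haplonet.collapse_haplotypes(aln)
    net = haplonet.build_network(haps, connection_limit=cfg.connection_limit)
    groups = haplonet.delineate_groups(net, threshold_limit=cfg.group_limit)
    haplonet.write_network(net, out / "cp_network_edges.tsv", out / "cp_network.gml")
    haplonet.write_group_assignments(net, out / "cp_groups.tsv")
    polarity = haplonet.classify_ancestral_derived(
        aln, {synthetic_data.OUTGROUP_LABEL}
    )
    polarity.to_csv(out / "cp_polarity.tsv", sep="\t", index=False)
    n_groups = len({v for v in groups.values() if v != "independent"})
    summary["stages"]["cpnet"] = {
        "n_haplotypes": int(len(haps)),
        "n_cp_groups": n_groups,
        "n_independent": sum(1 for v in groups.values() if v == "independent"),
    }


def _stage_domestication(cfg, state, summary, out):
    _ensure_sim(cfg, state)
    truth = state["truth"]
    g, meta = synthetic_data.simulate_domestication_panel(
        cfg.sim, truth, seed=cfg.stage_seed("domestication")
    )
    cult = [a for a, s in zip(meta["accession_id"], meta["species_label"])
            if s == "O. sativa-subpop"]
    red_wild = [
        a for a, s, p in zip(meta["accession_id"], meta["species_label"],
                             meta["pericarp_score"])
        if s != "O. sativa-subpop" and p == 1.0
    ]
    orsc = [a for a in meta["accession_id"] if a not in set(cult)]
    selected = domestication.select_region_snps(
        g.take_accessions(cult), g.take_accessions(red_wild), truth.dom_region,
        maf_min=cfg.maf_min, missing_max=cfg.missing_max, p_cutoff=cfg.p_cutoff,
    )
    calls: dict[str, str] = {}
    if selected:
        haps = domestication.build_extended_haplotypes(g, selected, cult)
        indel = dict(zip(meta["accession_id"], meta["rc_indel"]))
        domestication.assemble_focal_markers(haps, truth.dom_ingene_snp_ids, indel)
        calls = {
            h.accession_id: domestication.classify_introgression(h)
            for h in haps if h.accession_id in set(orsc)
        }
        pd.DataFrame(
            [{"accession_id": a, "call": c} for a, c in calls.items()]
        ).to_csv(out / "introgression_calls.tsv", sep="\t", index=False)
    pheno = domestication.phenotype_genotype_concordance(meta)
    pheno.to_csv(out / "phenotype_concordance.tsv", sep="\t", index=False)
    summary["stages"]["domestication"] = {
        "n_selected_snps": len(selected),
        "n_introgressed_called": sum(1 for c in calls.values() if c == "introgressed"),
        "n_truth_introgressed": len(truth.introgressed_ids),
        "n_phenotype_discordant": int((~pheno["concordant"]).sum()) if len(pheno) else 0,
    }


def _stage_concordance(cfg, state, summary, out):
    _ensure_groups(cfg, state)
    meta = state["meta"]
    assigned = state["assigned"]
    species = pd.Series(
        meta["species_label"].to_numpy(), index=meta["accession_id"], name="species"
    )
    res = structure_concordance.concordance(assigned, species)
    res.contingency.to_csv(out / "concordance_table.tsv", sep="\t")
    comp = structure_concordance.species_composition(assigned, species)
    comp.to_csv(out / "species_composition.tsv", sep="\t")
    summary["stages"]["concordance"] = {
        "chi2": res.chi2, "df": res.df, "p": res.p,
        "effect_r2": res.effect_r2, "n": res.n,
    }


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "assign": _stage_assign,
    "fst": _stage_fst,
    "pi": _stage_pi,
    "dist": _stage_dist,
    "tree": _stage_tree,
    "ld": _stage_ld,
    "mantel": _stage_mantel,
    "cpnet": _stage_cpnet,
    "domestication": _stage_domestication,
    "concordance": _stage_concordance,
}
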