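"""End-to-end orchestration: diversity → NCM → null models → niche → networks.

A single :class:`PipelineConfig` collects every input path, threshold,
replicate count and the master seed.  Stage-level randomness is derived
from the master seed via ``numpy.random.SeedSequence([master, crc32(stage
label)])`` so one integer fixes the whole run, and each stage (and each
vegetation-zone subset) gets an independent, reproducible stream.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, ncm, network, niche
from .io import (
    OtuTable,
    SampleMetadata,
    rarefy,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    write_otu_table,
)

logger = logging.getLogger(__name__)


def stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed below 2³¹."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    otu_table: str
    metadata: str | None = None
    tree: str | None = None
    taxonomy: str | None = None
    out_dir: str = "ecoassembly_out"
    rarefaction_depth: int | None = None
    rare_cut: float = 0.001
    abundant_cut: float = 0.01
    rho_min: float = 0.6
    q_max: float = 0.01
    min_occupancy: float = 0.5
    top_n: int = 300
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    n_null: int = 999
    n_boot: int = 1000
    n_random_graphs: int = 1000
    robustness_reps: int = 100
    seed: int = 0
    zone_column: str = "zone"
    stages: tuple = ("diversity", "ncm", "assembly", "niche", "network")
    per_zone: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        if "stages" in data:
            cfg.stages = tuple(data["stages"])
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def _run_diversity(table, out, cfg, summary):
    alpha = diversity.alpha_diversity(table)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    rel = diversity.relative_abundance(table)
    cats = diversity.classify_abundance_categories(rel, cfg.rare_cut, cfg.abundant_cut)
    cats.rename("category").to_frame().to_csv(
        out / "categories.tsv", sep="\t", index_label="otu_id"
    )
    fit = diversity.preston_fit(table.otu_sums().to_numpy())
    pd.DataFrame(
        {"octave": fit.octave_index, "species": fit.observed_octave_counts}
    ).to_csv(out / "preston_octaves.tsv", sep="\t", index=False)
    summary["diversity"] = {
        "mean_richness": float(alpha["richness"].mean()),
        "mean_shannon": float(alpha["shannon"].mean()),
        "category_counts": cats.value_counts().to_dict(),
        "preston_coverage": fit.coverage,
        "preston_extrapolated_richness": fit.extrapolated_richness,
    }


def _run_ncm(table, out, cfg, summary):
    fit = ncm.fit_ncm(table, n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "ncm"))
    fit.otus.to_csv(out / "ncm_fit.tsv", sep="\t")
    payload = {
        "m": fit.m,
        "m_ci": list(fit.m_ci),
        "r_squared": fit.r_squared,
        "N": fit.N,
        "detection_limit": fit.d,
        "neutral_fraction": fit.neutral_fraction,
    }
    (out / "ncm_summary.json").write_text(json.dumps(payload, indent=2))
    summary["ncm"] = payload


def _run_assembly(table, tree, out, cfg, summary):
    if tree is None:
        raise ValueError("assembly stage requires a phylogenetic tree (tree=...)")
    bnti = assembly.beta_nti(
        table, tree, n_null=cfg.n_null, seed=stage_seed(cfg.seed, "bnti")
    )
    rc = assembly.raup_crick_bray(
        table, n_null=cfg.n_null, seed=stage_seed(cfg.seed, "rc")
    )
    bnti.to_csv(out / "bnti.tsv", sep="\t")
    rc.to_csv(out / "rc_bray.tsv", sep="\t")
    part = assembly.partition_processes(bnti, rc)
    payload = {
        "fractions": part.fractions,
        "counts": part.counts,
        "n_pairs": part.n_pairs,
        "determinism_fraction": part.determinism_fraction,
        "stochasticity_fraction": part.stochasticity_fraction,
    }
    (out / "partition.json").write_text(json.dumps(payload, indent=2))
    summary["assembly"] = payload


def _run_niche(table, meta, out, cfg, summary):
    B = niche.levins_breadth(table)
    B.to_frame().to_csv(out / "niche_breadth.tsv", sep="\t", index_label="otu_id")
    bcom = niche.community_breadth(table)
    frame = bcom.to_frame()
    if meta is not None:
        frame[cfg.zone_column] = meta.zone_of(frame.index)
    frame.to_csv(out / "bcom.tsv", sep="\t", index_label="sample_id")
    summary["niche"] = {"mean_Bcom": float(bcom.mean())}


def _run_network(table, taxonomy, out, cfg, summary, label="overall"):
    filtered = network.filter_for_network(table, cfg.min_occupancy, cfg.top_n)
    g = network.build_network(filtered, cfg.rho_min, cfg.q_max)
    seed = stage_seed(cfg.seed, f"network:{label}")
    topo = network.graph_topology(g, seed=seed)
    modules, _ = network.detect_modules(g, seed=seed)
    nodes = network.node_topology(g)
    zp = network.zipi_classify(g, modules, cfg.zi_cut, cfg.pi_cut)
    nodes = nodes.join(zp)
    if taxonomy is not None:
        nodes = nodes.join(taxonomy, how="left")
    nodes.to_csv(out / "nodes.tsv", sep="\t")
    edges = pd.DataFrame(
        [(u, v, d["rho"], d["q"], d["sign"]) for u, v, d in g.edges(data=True)],
        columns=["u", "v", "rho", "q", "sign"],
    )
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    (out / "topology.json").write_text(json.dumps(topo.to_dict(), indent=2))
    if g.number_of_edges() > 0:
        ens = network.random_ensemble(
            g.number_of_nodes(),
            g.number_of_edges(),
            reps=cfg.n_random_graphs,
            seed=stage_seed(cfg.seed, f"ensemble:{label}"),
        )
        (out / "random_ensemble.json").write_text(json.dumps(ens.to_dict(), indent=2))
        rob = network.robustness_curve(
            g,
            strategy="random",
            reps=cfg.robustness_reps,
            seed=stage_seed(cfg.seed, f"robustness:{label}"),
        )
        rob.to_frame().to_csv(out / "robustness.tsv", sep="\t", index=False)
    network.write_graphml(g, out / "network.graphml")
    summary.setdefault("network", {})[label] = {
        "topology": topo.to_dict(),
        "n_keystone": int(zp["keystone"].sum()),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages for the overall sample set and per zone.

    Returns the output directory; every stage writes its own tab-separated
    and JSON outputs plus a combined ``summary.json``.  Any stage failure
    aborts with the stage name; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)

    table = read_otu_table(config.otu_table)
    meta = read_metadata(config.metadata) if config.metadata else None
    tree = read_tree(config.tree) if config.tree else None
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
    if config.rarefaction_depth:
        table = rarefy(
            table, config.rarefaction_depth, seed=stage_seed(config.seed, "rarefy")
        )
        write_otu_table(table, out / "rarefied.tsv")

    subsets = {"overall": table}
    if meta is not None and config.per_zone:
        zones = meta.zone_of(table.sample_ids)
        for z in sorted(zones.unique()):
            ids = [s for s in table.sample_ids if zones[s] == z]
            subsets[z] = OtuTable(table.counts.loc[ids]).drop_empty_otus()

    summary: dict = {"config": {k: v for k, v in asdict(config).items()}, "subsets": {}}
    runners = {
        "diversity": lambda t, o, s: _run_diversity(t, o, config, s),
        "ncm": lambda t, o, s: _run_ncm(t, o, config, s),
        "assembly": lambda t, o, s: _run_assembly(t, tree, o, config, s),
        "niche": lambda t, o, s: _run_niche(t, meta, o, config, s),
    }
    for label, sub in subsets.items():
        sub_out = out / label
        sub_out.mkdir(exist_ok=True)
        sub_summary: dict = {"n_samples": sub.n_samples, "n_otus": sub.n_otus}
        for stage in config.stages:
            t0 = time.time()
            try:
                if stage == "network":
                    _run_network(sub, taxonomy, sub_out, config, sub_summary, label)
                else:
                    runners[stage](sub, sub_out, sub_summary)
            except Exception as exc:
                logger.error("stage %s failed on subset %s: %s", stage, label, exc)
                (out / "summary.json").write_text(
                    json.dumps(summary, indent=2, sort_keys=True, default=str)
                )
                raise StageError(f"{stage}[{label}]", exc) from exc
            logger.info(
                "stage %s [%s] done in %.1fs (seed=%s)",
                stage,
                label,
                time.time() - t0,
                config.seed,
            )
        summary["subsets"][label] = sub_summary

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    logging.getLogger().removeHandler(handler)
    return out
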