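"""End-to-end orchestration: simulate -> assembly -> network -> envstats.

A run is driven by a :class:`RunConfig` (loadable from YAML/JSON); every
stochastic stage records its seed in the output manifest, and rerunning
the same configuration reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .otu import OtuTable, EnvTable, read_otu_table, read_env_table, rarefy, filter_prevalence, write_otu_table, write_env_table
from .trees import read_newick, write_newick
from .assembly import (
    NullModelResult,
    beta_nti,
    raup_crick_bray,
    classify_pairs,
    summarize_processes,
    bray_curtis_matrix,
)
from .sparcc import sparcc_bootstrap_p
from .networks import build_network, topology_stats, louvain_partition, identify_keystones, write_graph
from .envstats import heterogeneity_index, mantel_test, euclidean_matrix
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("ecoassembly")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` holds generator parameters, or ``otu_table`` /
    ``tree`` / ``env`` point at input files.  Stage blocks carry their
    parameters and seeds; ``group_column`` names the metadata column that
    partitions samples (default "season").
    """

    outdir: str = "ecoassembly_run"
    simulate: dict | None = None
    otu_table: str | None = None
    tree: str | None = None
    env: str | None = None
    group_column: str = "season"
    rarefaction_depth: int | None = None
    prevalence_min_total: int | None = 10
    assembly: dict = field(default_factory=lambda: {"enabled": True, "reps": 999, "seed": 1})
    network: dict = field(default_factory=lambda: {"enabled": True, "r_min": 0.5, "p_max": 0.05,
                                                  "n_boot": 100, "seed": 2})
    envstats: dict = field(default_factory=lambda: {"enabled": True, "standardize": True,
                                                   "n_perm": 999, "seed": 3})

    def validate(self) -> None:
        if self.simulate is None and self.otu_table is None:
            raise ConfigError("either 'simulate' parameters or an 'otu_table' path is required")
        if self.simulate is None:
            if self.assembly.get("enabled", True) and self.tree is None:
                raise ConfigError("assembly stage enabled but no tree given")
            if self.envstats.get("enabled", True) and self.env is None:
                raise ConfigError("envstats stage enabled but no env table given")
        for stage in ("assembly", "network", "envstats"):
            block = getattr(self, stage)
            if block.get("enabled", True) and "seed" not in block:
                raise ConfigError(f"stage {stage!r} needs an explicit seed")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header_info: dict) -> None:
    with open(path, "w") as fh:
        for key, val in header_info.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Outputs: process_summary.tsv, bnti.tsv, rc.tsv, labels.tsv, per-group
    network GMLs + network_stats.tsv + modules.tsv + keystones.tsv,
    heterogeneity.tsv, mantel.tsv, and manifest.json (versions, seeds,
    parameters, input hashes).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ecoassembly_version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                result = fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            dt = time.time() - t0
            logger.info("stage %s: done in %.1fs", name, dt)
            manifest["stages"][name] = {"seconds": round(dt, 2)}
            return result
        return deco

    # ------------------------------------------------------------- inputs
    if config.simulate is not None:
        sim_params = dict(config.simulate)
        cfg = SimulationConfig(**sim_params)
        ds = stage("simulate")(lambda: simulate_dataset(cfg))
        table, tree, env = ds.otu_table, ds.tree, ds.env
        write_otu_table(table, outdir / "otu_table.tsv")
        write_newick(tree, outdir / "tree.nwk")
        write_env_table(env, outdir / "env.csv")
        truth = {
            "true_regime": ds.true_regime.to_dict(),
            "optima": {k: float(v) for k, v in ds.optima.items()},
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        manifest["inputs"]["simulate_seed"] = cfg.seed
    else:
        table = stage("read_inputs")(lambda: read_otu_table(config.otu_table))
        manifest["inputs"]["otu_table"] = _sha256(Path(config.otu_table))
        tree = None
        if config.tree is not None:
            tree = read_newick(config.tree)
            manifest["inputs"]["tree"] = _sha256(Path(config.tree))
        env = None
        if config.env is not None:
            env = read_env_table(config.env)
            manifest["inputs"]["env"] = _sha256(Path(config.env))

    if config.rarefaction_depth:
        table = rarefy(table, config.rarefaction_depth,
                       seed=int(config.assembly.get("seed", 0)), drop_small=True)
    if config.prevalence_min_total is not None:
        table = filter_prevalence(table, config.prevalence_min_total)

    grouping = None
    if env is not None and config.group_column in env.grouping.columns:
        grouping = env.grouping[config.group_column]

    # ------------------------------------------------------------ assembly
    if config.assembly.get("enabled", True):
        if tree is None:
            raise ConfigError("assembly stage enabled but no tree available")
        reps = int(config.assembly.get("reps", 999))
        seed = int(config.assembly["seed"])

        def _assembly():
            bnti, degen = beta_nti(table, tree, reps=reps, seed=seed)
            rc = raup_crick_bray(table, reps=reps, seed=seed + 1)
            result = NullModelResult(bnti, rc, degen, reps, seed)
            labels = classify_pairs(result)
            summary = summarize_processes(labels, grouping)
            return bnti, rc, labels, summary

        bnti, rc, labels, summary = stage("assembly")(_assembly)
        info = {"reps": reps, "seed": seed}
        _write_tsv(bnti, outdir / "bnti.tsv", info)
        _write_tsv(rc, outdir / "rc.tsv", info)
        _write_tsv(labels.set_index(["sample_a", "sample_b"]), outdir / "labels.tsv", info)
        _write_tsv(summary, outdir / "process_summary.tsv", info)

    # ------------------------------------------------------------- network
    if config.network.get("enabled", True):
        r_min = float(config.network.get("r_min", 0.5))
        p_max = float(config.network.get("p_max", 0.05))
        n_boot = int(config.network.get("n_boot", 100))
        seed = int(config.network["seed"])
        groups = (
            {g: list(idx) for g, idx in grouping.groupby(grouping).groups.items()}
            if grouping is not None
            else {"all": table.sample_ids}
        )

        def _network():
            stats_rows, module_rows, keystone_rows = [], [], []
            for gname, samples in sorted(groups.items()):
                sub = OtuTable(table.data.loc[samples])
                sub = OtuTable(sub.data.loc[:, sub.data.sum(axis=0) > 0])
                corr = sparcc_bootstrap_p(sub, n_boot=n_boot, seed=seed)
                net = build_network(corr, r_min=r_min, p_max=p_max,
                                   taxonomy=table.taxonomy)
                write_graph(net, outdir / f"network_{gname}.gml")
                st = topology_stats(net)
                row = {"group": gname, "n_nodes": st.n_nodes, "n_edges": st.n_edges,
                       "average_degree": st.average_degree,
                       "clustering_coefficient": st.clustering_coefficient,
                       "average_path_length": st.average_path_length,
                       "diameter": st.diameter,
                       "positive_edge_fraction": st.positive_edge_fraction}
                if net.number_of_nodes():
                    part = louvain_partition(net, seed=seed)
                    row["modularity"] = part.modularity
                    for node, mod in part.membership.items():
                        module_rows.append({"group": gname, "node": node, "module": mod})
                    for node in identify_keystones(net):
                        keystone_rows.append({"group": gname, "node": node})
                stats_rows.append(row)
            return (pd.DataFrame(stats_rows).set_index("group"),
                    pd.DataFrame(module_rows),
                    pd.DataFrame(keystone_rows))

        stats_df, modules_df, keystones_df = stage("network")(_network)
        info = {"r_min": r_min, "p_max": p_max, "n_boot": n_boot, "seed": seed}
        _write_tsv(stats_df, outdir / "network_stats.tsv", info)
        _write_tsv(modules_df, outdir / "modules.tsv", info)
        _write_tsv(keystones_df, outdir / "keystones.tsv", info)

    # ------------------------------------------------------------ envstats
    if config.envstats.get("enabled", True) and env is not None:
        standardize = bool(config.envstats.get("standardize", True))
        n_perm = int(config.envstats.get("n_perm", 999))
        seed = int(config.envstats["seed"])

        def _envstats():
            het = heterogeneity_index(env, grouping, standardize=standardize)
            bc = bray_curtis_matrix(table)
            envd = euclidean_matrix(env, standardize=standardize).loc[bc.index, bc.index]
            r, p = mantel_test(bc, envd, n_perm=n_perm, seed=seed)
            mantel_df = pd.DataFrame(
                [{"comparison": "bray_curtis~env_euclidean", "mantel_r": r, "p_value": p,
                  "n_perm": n_perm}]
            ).set_index("comparison")
            return het, mantel_df

        het, mantel_df = stage("envstats")(_envstats)
        info = {"standardize": standardize, "n_perm": n_perm, "seed": seed}
        _write_tsv(het, outdir / "heterogeneity.tsv", info)
        _write_tsv(mantel_df, outdir / "mantel.tsv", info)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
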