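"""End-to-end pipeline orchestration from a single YAML config.

Stages: data (load or simulate) -> niche classification -> assembly-process
partitioning (overall and per salinity level) -> neutral-model fit ->
per-level co-occurrence networks with stability and cohesion -> Mantel /
PERMANOVA. Every randomized stage derives its own seed from the master seed;
re-running an identical config reproduces every output byte for byte. The
config (with all defaults filled in) and per-stage counts are recorded in
``manifest.json``; a failure leaves partial outputs plus a FAILED marker
naming the stage.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    CommunityTable,
    SalinityBinning,
    assign_salinity_levels,
    read_community_table,
    read_metadata,
    read_phylogeny,
    to_relative,
    validate_metadata,
    write_community_table,
)
from . import assembly as asm
from . import network_stability as ns
from . import niche as niche_mod
from . import stats as stats_mod
from .neutral_model import fit_ncm
from .synthetic_data import ScenarioConfig, simulate, config_dict

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULTS = {
    "niche": {"n_permutations": 1000, "null_model": "fixed_margins", "alpha": 0.05},
    "assembly": {"n_null": 999, "abundance_weighted": True, "per_level": True},
    "ncm": {"detection_limit": "auto"},
    "network": {
        "min_mean_relative_abundance": 0.001,
        "rho_threshold": 0.6,
        "alpha": 0.05,
        "p_adjust": "fdr_bh",
        "min_samples": 5,
        "removal_fraction": 0.5,
        "n_repetitions": 100,
        "cohesion_n_null": 200,
    },
    "stats": {"n_permutations": 999, "method": "spearman"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; every stage seed derives from seed."""

    seed: int
    output_dir: str
    scenario: dict | None = None  # synthetic input (ScenarioConfig fields)
    input: dict | None = None  # real input: otu_table, tree, metadata paths
    salinity_bin_edges: list = field(default_factory=lambda: [0, 1, 2, 4, 7, 11])
    niche: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    ncm: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if (self.scenario is None) == (self.input is None):
            raise ValueError("config must set exactly one of 'scenario' or 'input'")
        for section in ("niche", "assembly", "ncm", "network", "stats"):
            merged = dict(_DEFAULTS[section])
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage substream, kept below 2**31."""
    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] % 2**31)


def _load_data(cfg: PipelineConfig, outdir: Path):
    if cfg.scenario is not None:
        sc = dict(cfg.scenario)
        sc.setdefault("seed", cfg.seed)
        scenario_cfg = ScenarioConfig(**sc)
        ds = simulate(scenario_cfg)
        write_community_table(ds.table, outdir / "otu_table.tsv")
        (outdir / "tree.nwk").write_text(ds.newick + "\n")
        pd.DataFrame(
            [
                {"sample_id": m.sample_id, "site_id": m.site_id, "salinity": m.salinity}
                for m in ds.metadata
            ]
        ).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"otu_id": o, "genus": t[0], "family": t[1], "order": t[2]} for o, t in ds.taxonomy.items()]
        ).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"config": config_dict(scenario_cfg), "truth": ds.truth}, fh, indent=1)
        return ds.table, ds.metadata, ds.distances
    paths = cfg.input
    table = read_community_table(paths["otu_table"], paths.get("orientation", "samples_as_rows"))
    meta = read_metadata(paths["metadata"])
    validate_metadata(table, meta)
    dist = read_phylogeny(paths["tree"], list(table.otu_ids)) if paths.get("tree") else None
    return table, meta, dist


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "data"
    try:
        table, meta, dist = _load_data(config, outdir)
        binning = SalinityBinning(tuple(config.salinity_bin_edges))
        levels = assign_salinity_levels(meta, binning)
        manifest["stages"]["data"] = {
            "n_samples": table.n_samples,
            "n_otus": table.n_otus,
            "levels": {lab: sum(1 for v in levels.values() if v == lab) for lab in binning.bin_labels},
        }

        stage = "niche"
        ncfg = config.niche
        classifications = niche_mod.classify_generalists_specialists(
            table,
            n_permutations=ncfg["n_permutations"],
            alpha=ncfg["alpha"],
            seed=_stage_seed(config.seed, "niche"),
            null_model=ncfg["null_model"],
        )
        pd.DataFrame(
            [
                {
                    "otu_id": c.otu_id,
                    "breadth": c.breadth_observed,
                    "lower95": c.null_lower_95,
                    "upper95": c.null_upper_95,
                    "label": c.label,
                }
                for c in classifications
            ]
        ).to_csv(outdir / "niche.tsv", sep="\t", index=False)
        manifest["stages"]["niche"] = {
            lab: sum(c.label == lab for c in classifications)
            for lab in ("generalist", "specialist", "neutral")
        }

        stage = "assembly"
        acfg = config.assembly
        if dist is None:
            manifest["stages"]["assembly"] = {"skipped": "no phylogeny provided"}
        else:
            rows, summaries = [], []
            groups = {"all": list(table.sample_ids)}
            if acfg["per_level"]:
                for lab in binning.bin_labels:
                    members = [s for s in table.sample_ids if levels[s] == lab]
                    if len(members) >= 3:
                        groups[lab] = members
            for gname, members in groups.items():
                sub = table.subset_samples(members)
                pairs = asm.pairwise_assembly(
                    sub,
                    dist,
                    n_null=acfg["n_null"],
                    seed=_stage_seed(config.seed, f"assembly:{gname}"),
                    abundance_weighted=acfg["abundance_weighted"],
                )
                for p in pairs:
                    rows.append(
                        {
                            "group": gname,
                            "sample_a": p.sample_a,
                            "sample_b": p.sample_b,
                            "bmntd": p.bmntd_obs,
                            "bnti": p.bnti,
                            "rc_bray": p.rc_bray,
                            "process": p.process or f"flagged:{p.flag}",
                        }
                    )
                summary = asm.summarize_assembly(pairs)
                summaries.append(
                    {"group": gname, "n_pairs": summary.n_pairs,
                     "stochastic_fraction": summary.stochastic_fraction, **summary.fractions}
                )
            pd.DataFrame(rows).to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
            pd.DataFrame(summaries).to_csv(outdir / "assembly_summary.tsv", sep="\t", index=False)
            manifest["stages"]["assembly"] = {
                s["group"]: round(s["stochastic_fraction"], 4) for s in summaries
            }

        stage = "ncm"
        ncm_res = fit_ncm(table, detection_limit=config.ncm["detection_limit"])
        ncm_res.otu_table.to_csv(outdir / "ncm_otus.tsv", sep="\t")
        ncm_summary = {
            "m": ncm_res.m,
            "Nm": ncm_res.Nm,
            "N": ncm_res.N,
            "r_squared": ncm_res.r_squared,
            "detection_limit": ncm_res.detection_limit,
        }
        with open(outdir / "ncm_summary.json", "w") as fh:
            json.dump(ncm_summary, fh, indent=1)
        manifest["stages"]["ncm"] = {"m": round(ncm_res.m, 6), "r_squared": round(ncm_res.r_squared, 4)}

        stage = "network"
        wcfg = config.network
        net_reports = []
        for lab in binning.bin_labels:
            members = [s for s in table.sample_ids if levels[s] == lab]
            entry = {"level": lab, "n_samples": len(members)}
            try:
                sub = table.subset_samples(members)
                filt = ns.filter_abundant_otus(sub, wcfg["min_mean_relative_abundance"])
                net = ns.build_network(
                    filt,
                    rho_threshold=wcfg["rho_threshold"],
                    alpha=wcfg["alpha"],
                    p_adjust=wcfg["p_adjust"],
                    min_samples=wcfg["min_samples"],
                )
                net.edge_table().to_csv(outdir / f"network_{lab}_edges.tsv", sep="\t", index=False)
                nx.write_graphml(net.graph, outdir / f"network_{lab}.graphml")
                entry.update(ns.topological_properties(net))
                if net.n_nodes >= 4:
                    rep = ns.robustness(
                        net,
                        removal_fraction=wcfg["removal_fraction"],
                        n_repetitions=wcfg["n_repetitions"],
                        seed=_stage_seed(config.seed, f"network:{lab}"),
                    )
                    entry.update(
                        robustness_mean=rep.robustness_mean,
                        robustness_sd=rep.robustness_sd,
                        vulnerability=rep.vulnerability,
                    )
                coh = ns.cohesion(
                    filt, n_null=wcfg["cohesion_n_null"], seed=_stage_seed(config.seed, f"cohesion:{lab}")
                )
                coh.to_dataframe().to_csv(outdir / f"cohesion_{lab}.tsv", sep="\t")
                entry["positive_cohesion"] = float(coh.positive_cohesion.mean())
                entry["negative_cohesion"] = float(coh.negative_cohesion.mean())
                entry["complexity"] = float(coh.complexity.mean())
            except ValueError as exc:
                entry["skipped"] = str(exc)
            net_reports.append(entry)
        pd.DataFrame(net_reports).to_csv(outdir / "network_stability.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            e["level"]: ("skipped" if "skipped" in e else e.get("n_edges")) for e in net_reports
        }

        stage = "stats"
        scfg = config.stats
        dcomm = stats_mod.bray_curtis_matrix(table)
        sal = np.array([m.salinity for m in meta if m.sample_id in set(table.sample_ids)])
        by_id = {m.sample_id: m.salinity for m in meta}
        sal = np.array([by_id[s] for s in table.sample_ids])
        denv = stats_mod.euclidean_matrix(table.sample_ids, sal[:, None])
        r, p = stats_mod.mantel(
            dcomm, denv, n_permutations=scfg["n_permutations"], method=scfg["method"],
            seed=_stage_seed(config.seed, "mantel"),
        )
        f_stat, p_perm = stats_mod.permanova(
            dcomm, levels, n_permutations=scfg["n_permutations"],
            seed=_stage_seed(config.seed, "permanova"),
        )
        stats_rows = [
            {"test": "mantel_salinity", "statistic": r, "p_value": p},
            {"test": "permanova_salinity_level", "statistic": f_stat, "p_value": p_perm},
        ]
        pd.DataFrame(stats_rows).to_csv(outdir / "stats.tsv", sep="\t", index=False)
        manifest["stages"]["stats"] = {row["test"]: round(row["p_value"], 4) for row in stats_rows}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
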