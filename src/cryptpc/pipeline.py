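"""Config-driven pipeline chaining simulate -> qc -> pca -> screen -> gradient -> admix.

Each stage writes its outputs under ``out_dir`` before the next starts, so
a failure in stage *k* leaves the outputs of stages < *k* intact.  A run
manifest (written last) records the tool version, a hash of the resolved
configuration, the seed, and a SHA-256 digest of every output file;
re-running the same config reproduces identical digests for all
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .admix import block_bootstrap_ci
from .genotype_io import write_genotypes, write_metadata
from .gradient import (
    classical_mds,
    linkage_to_newick,
    nearest_reference_distances,
    pairwise_pc_distances,
    ward_clustering,
)
from .pca import compute_pcs
from .qc import QCThresholds, apply_qc_pipeline
from .screening import DiscriminationSpec, search_pc_combinations
from .simulate import SCENARIO_NAMES, make_study_scenario, simulate_scenario

log = logging.getLogger("cryptpc")

STAGES = ("simulate", "qc", "pca", "screen", "gradient", "admix")


class ConfigError(ValueError):
    """Configuration problem, annotated with the offending config path."""

    def __init__(self, path: str, message: str):
        super().__init__(f"config error at {path}: {message}")


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path]):
        self.stages.append(
            {
                "stage": name,
                "outputs": {str(p): _sha256(p) for p in outputs.values()},
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("<root>", "config must be a mapping")
    for key in ("out_dir", "seed"):
        if key not in config:
            raise ConfigError(key, "required key missing")
    sim = config.get("simulate", {})
    if "scenario" not in sim:
        raise ConfigError("simulate.scenario", "required key missing")
    if sim["scenario"] not in SCENARIO_NAMES:
        raise ConfigError(
            "simulate.scenario",
            f"unknown scenario {sim['scenario']!r}; options: {', '.join(SCENARIO_NAMES)}",
        )
    admix_cfg = config.get("admix", {})
    for key in ("target", "sources", "right"):
        if admix_cfg and key not in admix_cfg:
            raise ConfigError(f"admix.{key}", "required key missing")
    return config


def default_config(scenario: str = "gradient", out_dir: str = "cryptpc_run", seed: int = 7) -> dict:
    """A complete, runnable configuration for one of the named scenarios."""
    cfg = {
        "out_dir": out_dir,
        "seed": seed,
        "simulate": {"scenario": scenario, "n_snps": 20_000},
        "qc": {
            "maf_min": 0.01,
            "hwe_p_min": 1e-6,
            "snp_missing_max": 0.8,
            "ld_r2_max": 0.25,
            "ld_window": 200,
            "ld_step": 50,
            # synthetic panels are far smaller than an empirical SNP array,
            # so the coverage floor scales with the simulated SNP count
            "sample_min_snps": 1000,
            "sample_missing_max": 0.8,
            "pi_hat_max": 0.25,
        },
        "pca": {"k": 20, "sign_anchor": None},
        "screen": {"arity": 3, "z_threshold": 2.0, "min_group_n": 3},
    }
    if scenario == "gradient":
        cfg["screen"]["groups"] = {
            "baltic": ["Baltic_BA"],
            "balkan": ["Balkan_IA"],
            "cline": ["Cline_050"],
        }
        cfg["gradient"] = {
            "reference_sets": {"Baltic": ["Baltic_BA"], "Balkan": ["Balkan_IA"]},
            "pcs": None,
        }
        cfg["admix"] = {
            "target": "Cline_050",
            "sources": ["Baltic_BA", "Balkan_IA"],
            "right": ["Outgroup1", "Outgroup2", "Outgroup3", "Outgroup4"],
            "n_reps": 200,
        }
    elif scenario == "three_wave":
        cfg["screen"]["groups"] = {
            "baltic": ["Baltic_BA"],
            "balkan": ["Balkan_IA"],
            "waves": ["Wave1_Early", "Wave2_Avar", "Wave3_Late"],
        }
        cfg["gradient"] = {
            "reference_sets": {"Baltic": ["Baltic_BA"], "Balkan": ["Balkan_IA"]},
            "pcs": None,
        }
        cfg["admix"] = {
            "target": "Wave1_Early",
            "sources": ["Baltic_BA", "Balkan_IA"],
            "right": ["Outgroup1", "Outgroup2", "Outgroup3", "Outgroup4"],
            "n_reps": 200,
        }
    elif scenario == "barbaricum5":
        cfg["screen"]["groups"] = {
            "germanic": ["Germanic"],
            "proto_slavic": ["Proto_Slavic"],
            "target": ["Barbaricum"],
        }
        cfg["gradient"] = {
            "reference_sets": {
                "ProtoSlavic": ["Proto_Slavic"],
                "Germanic": ["Germanic"],
            },
            "pcs": None,
        }
        cfg["admix"] = {
            "target": "Barbaricum",
            "sources": ["Germanic", "Balkan_IA", "Proto_Slavic", "Byzantine", "Steppe"],
            "right": ["Outgroup1", "Outgroup2", "Outgroup3", "Outgroup4", "Outgroup5", "Outgroup6"],
            "n_reps": 200,
        }
    return cfg


def run_pipeline(config) -> RunManifest:
    """Execute the full pipeline described by ``config`` (dict or YAML path)."""
    config = _validate(load_config(config))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(version=__version__, seed=seed, config_hash=cfg_hash)

    # --- simulate -------------------------------------------------------
    sim_cfg = config["simulate"]
    spec = make_study_scenario(
        sim_cfg["scenario"], n_snps=int(sim_cfg.get("n_snps", 20_000)), seed=seed
    )
    sim = simulate_scenario(spec)
    matrix = sim.matrix
    paths = write_genotypes(matrix, out / "simulated", format="eigenstrat")
    write_metadata(matrix, out / "simulated_metadata.tsv")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths.update({"meta": out / "simulated_metadata.tsv", "truth": out / "truth.tsv"})
    manifest.add_stage("simulate", paths)
    log.info("simulate: %d samples x %d SNPs", matrix.n_samples, matrix.n_snps)

    # --- qc -------------------------------------------------------------
    qc_cfg = dict(config.get("qc", {}))
    thresholds = QCThresholds(**qc_cfg) if qc_cfg else QCThresholds()
    matrix, report = apply_qc_pipeline(matrix, thresholds)
    report.to_json(out / "qc_report.json")
    report.to_tsv(out / "qc_report.tsv")
    qpaths = write_genotypes(matrix, out / "filtered", format="eigenstrat")
    qpaths.update({"json": out / "qc_report.json", "tsv": out / "qc_report.tsv"})
    manifest.add_stage("qc", qpaths)
    log.info("qc: %d samples x %d SNPs retained", matrix.n_samples, matrix.n_snps)

    # --- pca ------------------------------------------------------------
    pca_cfg = config.get("pca", {})
    k = int(pca_cfg.get("k", 20))
    pcs = compute_pcs(
        matrix, k=k, sign_anchor_population=pca_cfg.get("sign_anchor") or None
    )
    pcs.to_tsv(out / "pcs.tsv")
    manifest.add_stage("pca", {"pcs": out / "pcs.tsv"})
    log.info("pca: %d components", k)

    # --- screen ---------------------------------------------------------
    scr_cfg = config.get("screen", {})
    arity = int(scr_cfg.get("arity", 3))
    if k < 3:
        warnings.warn(
            "fewer than 3 PCs: marginal screening is degenerate", stacklevel=2
        )
        arity = min(arity, k)
    spec_groups = DiscriminationSpec(
        groups={g: tuple(v) for g, v in scr_cfg["groups"].items()},
        min_group_n=int(scr_cfg.get("min_group_n", 3)),
    )
    screen_report = search_pc_combinations(pcs, spec_groups, arity=arity)
    screen_report.to_json(out / "screening.json")
    manifest.add_stage("screen", {"json": out / "screening.json"})
    selected = screen_report.selected_triple
    log.info("screen: selected PCs %s", selected)

    # --- gradient -------------------------------------------------------
    grad_cfg = config.get("gradient", {})
    pc_subset = tuple(grad_cfg.get("pcs") or selected)
    table = nearest_reference_distances(
        pcs,
        {g: tuple(v) for g, v in grad_cfg["reference_sets"].items()},
        pc_subset,
    )
    table.to_tsv(out / "gradient.tsv")
    table.population_means().to_csv(
        out / "gradient_population_means.tsv", sep="\t", index=False
    )
    dmat = pairwise_pc_distances(pcs, pc_subset)
    dmat.to_csv(out / "distances.tsv", sep="\t", float_format="%.8g")
    Z = ward_clustering(dmat.to_numpy())
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(linkage_to_newick(Z, list(dmat.index)) + "\n")
    coords = classical_mds(dmat.to_numpy(), dims=2)
    pd.DataFrame(coords, columns=["MDS1", "MDS2"]).assign(
        sample_id=list(dmat.index)
    ).to_csv(out / "mds.tsv", sep="\t", index=False, float_format="%.8g")
    manifest.add_stage(
        "gradient",
        {
            "table": out / "gradient.tsv",
            "means": out / "gradient_population_means.tsv",
            "dist": out / "distances.tsv",
            "nwk": out / "dendrogram.nwk",
            "mds": out / "mds.tsv",
        },
    )
    log.info("gradient: distances in PC subspace %s", pc_subset)

    # --- admix ----------------------------------------------------------
    adm_cfg = config.get("admix", {})
    fit = block_bootstrap_ci(
        matrix,
        adm_cfg["target"],
        tuple(adm_cfg["sources"]),
        tuple(adm_cfg["right"]),
        n_reps=int(adm_cfg.get("n_reps", 1000)),
        seed=seed,
    )
    fit.to_frame().to_csv(out / "admixture.tsv", sep="\t", index=False)
    with open(out / "admixture.json", "w") as fh:
        json.dump(
            {
                "target": fit.target,
                "sources": list(fit.sources),
                "weights": [float(w) for w in fit.weights],
                "weight_se": [float(s) for s in fit.weight_se],
                "p_value": fit.p_value,
                "feasible": fit.feasible,
                "bootstrap_ci": fit.bootstrap_ci,
            },
            fh,
            indent=2,
        )
    manifest.add_stage(
        "admix", {"tsv": out / "admixture.tsv", "json": out / "admixture.json"}
    )
    log.info("admix: target %s p=%.3f", fit.target, fit.p_value)

    manifest.write(out / "manifest.json")
    return manifest
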