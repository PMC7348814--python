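"""End-to-end orchestration of the orchard analysis workflow.

A :class:`RunConfig` names the inputs (files, or synthetic-data parameters),
the stages to run, and one master seed; :func:`run_pipeline` executes

    phenotype ANOVA -> standardized clonal values -> Mahalanobis + UPGMA
    diversity table -> AMOVA -> admixture K-scan + delta-K -> NJ tree
    Mantel(phenotypic D, molecular D)

writing delimited reports, two Newick trees, the Q matrix and a JSON manifest
of seeds and outputs into the configured directory.  Every stage draws its
randomness from a child of the master seed, so reruns are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import align_runs, delta_k, run_k_range
from .amova import amova_report, amova_two_level
from .distances import (individual_distance, mahalanobis_matrix, mantel,
                        neighbor_joining, pearson_upgma)
from .diversity import diversity_table
from .genotypes import read_genalex, write_genalex, write_structure
from .quantgen import fit_rcb, standardize_clonal_values, trait_report
from .simulate import OrchardSimSpec, SsrSimSpec, simulate_trial

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Pipeline configuration; unset stages are skipped.

    With no input paths, data are simulated from the orchard/SSR specs below.
    ``n_clusters > 1`` overlays a latent clone clustering shared by both data
    layers (equal-size genotype populations and shifted phenotype groups),
    otherwise the two origin sites stratify the genotypes.  MCMC lengths
    default to desk-scale values (K = 1..6, 5 replicates, 500 burn-in + 1000
    recorded sweeps).
    """

    output_dir: str = "orchardkit_out"
    seed: int = 0
    phenotype_path: str | None = None
    genotype_path: str | None = None
    # synthetic-data parameters
    n_clones: int = 110
    n_blocks: int = 10
    site_sizes: tuple[int, ...] = (90, 20)
    fst: float = 0.03
    n_clusters: int = 1
    cluster_shift_sd: float = 2.0
    # stage toggles and knobs
    stages: tuple[str, ...] = ("phenotype", "diversity", "amova", "admixture",
                               "tree", "mantel")
    k_min: int = 1
    k_max: int = 6
    structure_replicates: int = 5
    burnin: int = 500
    mcmc_reps: int = 1000
    amova_permutations: int = 999
    mantel_permutations: int = 999
    cut_k: int = 3

    def __post_init__(self) -> None:
        if self.k_max < self.k_min:
            raise ValueError("K range must be non-empty")
        unknown = set(self.stages) - {"phenotype", "diversity", "amova",
                                      "admixture", "tree", "mantel"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "mantel" in self.stages and not {"phenotype", "tree"} <= set(self.stages):
            raise ValueError("mantel needs the phenotype and tree stages")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("site_sizes", "stages"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _child_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, ["simulate", "amova", "admixture", "mantel"])
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": seeds, "outputs": {}, "summary": {}}

    # ------------------------------------------------------------------ data
    records = genotypes = None
    if config.phenotype_path:
        records = pd.read_csv(config.phenotype_path)
    if config.genotype_path:
        genotypes = read_genalex(config.genotype_path)
    if records is None or genotypes is None:
        if config.n_clusters > 1:
            sizes = tuple(np.bincount((np.arange(config.n_clones) * config.n_clusters)
                                      // config.n_clones).tolist())
            ssr = SsrSimSpec(pop_sizes=sizes, fst=config.fst)
            orchard = OrchardSimSpec(n_clones=config.n_clones,
                                     n_blocks=config.n_blocks,
                                     site_sizes=config.site_sizes,
                                     n_clone_groups=config.n_clusters,
                                     group_shift_sd=config.cluster_shift_sd)
        else:
            ssr = SsrSimSpec(pop_sizes=config.site_sizes, fst=config.fst)
            orchard = OrchardSimSpec(n_clones=config.n_clones,
                                     n_blocks=config.n_blocks,
                                     site_sizes=config.site_sizes)
        sim_records, sim_genotypes = simulate_trial(orchard, ssr, seed=seeds["simulate"])
        records = sim_records if records is None else records
        genotypes = sim_genotypes if genotypes is None else genotypes
        manifest["simulated"] = True
        records.to_csv(out / "phenotypes.csv", index=False)
        write_genalex(genotypes, out / "genotypes_genalex.csv")
        manifest["outputs"]["data"] = ["phenotypes.csv", "genotypes_genalex.csv"]

    clone_means = phen_dm = None
    try:
        # ------------------------------------------------------------ phenotype
        if "phenotype" in config.stages:
            report = trait_report(records)
            report.to_csv(out / "trait_variation.csv", index=False)
            manifest["outputs"]["phenotype"] = ["trait_variation.csv",
                                                "upgma_tree.nwk",
                                                "phenotype_groups.csv"]
            cm = {}
            for trait in report["trait"]:
                cm[trait] = fit_rcb(records, trait).clone_means
            clone_means = pd.DataFrame(cm)
            z = standardize_clonal_values(clone_means)
            phen_dm = mahalanobis_matrix(z)
            tree = pearson_upgma(z)
            (out / "upgma_tree.nwk").write_text(tree.newick() + "\n")
            groups = tree.cut(config.cut_k)
            groups.to_csv(out / "phenotype_groups.csv")
            manifest["summary"]["phenotype"] = {
                "n_traits": int(len(report)),
                "n_clones": int(len(clone_means)),
            }

        # ------------------------------------------------------------ diversity
        if "diversity" in config.stages:
            div = diversity_table(genotypes)
            div.to_csv(out / "diversity_table.csv", index=False)
            manifest["outputs"]["diversity"] = ["diversity_table.csv"]
            mean_row = div[div["locus"] == "Mean"].iloc[0]
            manifest["summary"]["diversity"] = {
                "mean_ne": float(mean_row["ne"]), "mean_he": float(mean_row["he"]),
                "mean_fst": float(mean_row["fst"]),
            }

        # ---------------------------------------------------------------- amova
        if "amova" in config.stages:
            res = amova_two_level(genotypes, n_perm=config.amova_permutations,
                                  seed=seeds["amova"])
            amova_report(res, out / "amova_table.csv")
            manifest["outputs"]["amova"] = ["amova_table.csv"]
            manifest["summary"]["amova"] = {
                "phi_st": res.phi_st, "p": res.p_value,
                "pct_among": float(res.table.loc["among_groups", "pct"]),
            }

        # ------------------------------------------------------------ admixture
        if "admixture" in config.stages:
            write_structure(genotypes, out / "genotypes.str")
            runs = run_k_range(genotypes, range(config.k_min, config.k_max + 1),
                               n_reps=config.structure_replicates,
                               burnin=config.burnin, reps=config.mcmc_reps,
                               seed=seeds["admixture"])
            dk = delta_k(runs)
            dk.table.to_csv(out / "delta_k.csv", index=False)
            best_k = dk.selected_k or config.cut_k
            _, q_mean = align_runs([r for r in runs if r.k == best_k])
            qdf = pd.DataFrame(q_mean, index=genotypes.individuals,
                               columns=[f"cluster_{i + 1}" for i in range(best_k)])
            qdf.to_csv(out / "q_matrix.csv")
            bar = qdf.reset_index(names="individual").melt(
                id_vars="individual", var_name="cluster", value_name="membership")
            bar.to_csv(out / "structure_barplot.csv", index=False)
            manifest["outputs"]["admixture"] = ["genotypes.str", "delta_k.csv",
                                               "q_matrix.csv", "structure_barplot.csv"]
            manifest["summary"]["admixture"] = {"selected_k": dk.selected_k,
                                                "ambiguous": dk.ambiguous}

        # ----------------------------------------------------------------- tree
        mol_dm = None
        if "tree" in config.stages:
            mol_dm = individual_distance(genotypes)
            nj = neighbor_joining(mol_dm)
            (out / "nj_tree.nwk").write_text(str(nj))
            mol_df = mol_dm.to_data_frame()
            mol_df.to_csv(out / "molecular_distance.csv")
            manifest["outputs"]["tree"] = ["nj_tree.nwk", "molecular_distance.csv"]

        # --------------------------------------------------------------- mantel
        if "mantel" in config.stages:
            if phen_dm is None or mol_dm is None:
                raise RuntimeError("mantel stage needs phenotype and tree stages")
            ids = list(phen_dm.ids)
            if set(ids) != set(mol_dm.ids):
                raise RuntimeError("phenotype and genotype labels differ")
            mol_aligned = mol_dm.filter(ids)
            mres = mantel(phen_dm, mol_aligned,
                          n_perm=config.mantel_permutations, seed=seeds["mantel"])
            summary = {"r": mres.r, "p": mres.p_value,
                       "permutations": mres.permutations}
            (out / "mantel.json").write_text(json.dumps(summary, indent=1))
            manifest["outputs"]["mantel"] = ["mantel.json"]
            manifest["summary"]["mantel"] = summary
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        manifest["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    cfg = asdict(config)
    cfg["site_sizes"] = list(cfg["site_sizes"])
    cfg["stages"] = list(cfg["stages"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return manifest
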