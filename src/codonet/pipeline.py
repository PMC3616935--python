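"""End-to-end orchestration: fits -> tests -> corrections -> associations.

A run is a pure function of (inputs, config, seed).  Per-gene results are
checkpointed as JSON under ``<outdir>/checkpoints`` and reloaded on resume;
per-gene failures are quarantined into ``failures.tsv`` instead of aborting
the batch.  Correction families mirror the study design: each site test is
corrected across genes, the branch-site test across all gene x branch
combinations.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import run_associations
from .fit import FitConfig, ModelFit, choose_tree, estimate_rates, fit_model
from .genetic_code import universal_code
from .network import centralities, write_centralities
from .selection import (
    SelectionTestResult,
    attach_adjusted,
    beb_site_posteriors,
    branch_site_test,
    site_model_tests,
)
from .simulate import SimulationSpec, simulate_study
from .tree import PhyloTree, read_tree

logger = logging.getLogger(__name__)

ALL_STAGES = ("rates", "site_tests", "branch_site", "network", "associate")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Exactly one of ``simulation`` or the real-input paths
    (``alignment_glob``, ``tree_path``) must be provided.
    """

    outdir: str = "codonet_run"
    seed: int = 0
    # real inputs
    alignment_glob: str | None = None
    tree_path: str | None = None
    gene_tree_dir: str | None = None  # optional per-gene candidate trees
    network_path: str | None = None
    annotation_path: str | None = None
    # or simulation
    simulation: SimulationSpec | None = None
    # analysis options
    stages: tuple[str, ...] = ALL_STAGES
    fit: FitConfig = field(default_factory=FitConfig)
    foreground_branches: tuple[str, ...] | None = None  # default: internal branches
    correction_method: str = "fdr_bh"
    alpha: float = 0.05
    threads: int = 1
    resume: bool = True

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_real = self.alignment_glob is not None
        if has_sim == has_real:
            raise ValueError("provide either real inputs or a simulation spec")
        if self.fit.tol <= 0:
            raise ValueError("tolerances must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fit = FitConfig(**raw.pop("fit", {}))
    sim = raw.pop("simulation", None)
    simulation = SimulationSpec(**sim) if sim is not None else None
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "foreground_branches" in raw and raw["foreground_branches"] is not None:
        raw["foreground_branches"] = tuple(raw["foreground_branches"])
    return RunConfig(fit=fit, simulation=simulation, **raw)


@dataclass
class RunResult:
    per_gene: pd.DataFrame
    selection: pd.DataFrame
    association: dict
    site_posteriors: dict
    paths: dict
    failures: pd.DataFrame


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def _gather_inputs(config: RunConfig):
    code = universal_code()
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        alignments, network, annotations, truth = simulate_study(sim, code)
        trees = {g: [sim.resolved_tree()] for g in alignments}
        return alignments, trees, network, annotations, truth
    alignments = {}
    for path in sorted(glob.glob(config.alignment_glob)):
        aln = cio.read_codon_alignment(path, code)
        alignments[aln.gene_id] = aln
    if not alignments:
        raise FileNotFoundError(
            f"no alignments matched {config.alignment_glob!r}"
        )
    species_tree = read_tree(config.tree_path)
    trees = {}
    for g in alignments:
        candidates = [species_tree]
        if config.gene_tree_dir:
            p = os.path.join(config.gene_tree_dir, f"{g}.nwk")
            if os.path.exists(p):
                candidates.append(read_tree(p))
        trees[g] = candidates
    network = cio.read_network(config.network_path) if config.network_path else None
    annotations = (
        cio.read_annotations(config.annotation_path)
        if config.annotation_path
        else None
    )
    return alignments, trees, network, annotations, None


# ---------------------------------------------------------------------------
# checkpoint helpers
# ---------------------------------------------------------------------------

def _ckpt_path(outdir: str, gene: str, stage: str) -> str:
    return os.path.join(outdir, "checkpoints", f"{gene}.{stage}.json")


def _load_ckpt(path: str):
    if os.path.exists(path):
        with open(path) as fh:
            return json.load(fh)
    return None


def _save_ckpt(path: str, payload) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages and write the report bundle."""
    os.makedirs(config.outdir, exist_ok=True)
    code = universal_code()
    alignments, trees, network, annotations, truth = _gather_inputs(config)
    genes = sorted(alignments)
    failures: list[dict] = []

    def quarantine(gene: str, stage: str, exc: Exception) -> None:
        logger.error("%s failed at %s: %s", gene, stage, exc)
        failures.append({"gene": gene, "stage": stage, "error": str(exc)})

    # --- stage: rates (M0, tree choice, dN/dS) ----------------------------
    rate_rows: dict[str, dict] = {}
    chosen_tree: dict[str, PhyloTree] = {}

    def fit_gene(gene: str):
        ck = _ckpt_path(config.outdir, gene, "rates")
        cached = _load_ckpt(ck) if config.resume else None
        tree_list = trees[gene]
        if cached is not None:
            chosen_tree[gene] = tree_list[cached["tree_index"]].with_branch_lengths(
                np.array(cached["fit"]["branch_lengths"])
            )
            rate_rows[gene] = cached["row"]
            return
        best_tree, lnLs = (
            choose_tree(alignments[gene], tree_list, config.fit, code)
            if len(tree_list) > 1
            else (tree_list[0], None)
        )
        m0 = fit_model(alignments[gene], best_tree, "M0", config.fit, code)
        rates = estimate_rates(m0, code)
        row = {
            "gene": gene,
            "n_codons": alignments[gene].n_sites,
            "lnL": m0.lnL,
            "kappa": m0.kappa,
            "omega": rates.omega,
            "dN": rates.dN,
            "dS": rates.dS,
            "tree_length": rates.tree_length,
        }
        rate_rows[gene] = row
        chosen_tree[gene] = best_tree.with_branch_lengths(m0.branch_lengths)
        _save_ckpt(ck, {
            "row": row,
            "tree_index": tree_list.index(best_tree),
            "fit": m0.to_dict(),
        })

    if "rates" in config.stages:
        _map_genes(fit_gene, genes, config.threads, quarantine, "rates")

    ok_genes = [g for g in genes if g in rate_rows]

    # --- stage: site tests -------------------------------------------------
    sel_results: list[SelectionTestResult] = []
    site_fits: dict[str, list] = {}

    def site_gene(gene: str):
        ck = _ckpt_path(config.outdir, gene, "site_tests")
        cached = _load_ckpt(ck) if config.resume else None
        if cached is not None:
            site_fits[gene] = [_result_from_payload(r, config) for r in cached]
            return
        res = site_model_tests(alignments[gene], chosen_tree[gene], config.fit, code)
        site_fits[gene] = res
        _save_ckpt(ck, [_result_payload(r, with_fits=True) for r in res])

    if "site_tests" in config.stages:
        _map_genes(site_gene, ok_genes, config.threads, quarantine, "site_tests")
        for test_name in ("M1a_vs_M2a", "M7_vs_M8"):
            fam = [
                r
                for g in ok_genes
                if g in site_fits
                for r in site_fits[g]
                if r.test == test_name
            ]
            attach_adjusted(fam, config.correction_method)
            sel_results.extend(fam)

    # --- stage: branch-site tests -----------------------------------------
    bs_results: list[SelectionTestResult] = []
    if "branch_site" in config.stages:
        bs_by_gene: dict[str, list] = {}

        def bs_gene(gene: str):
            tree = chosen_tree[gene]
            branches = (
                list(config.foreground_branches)
                if config.foreground_branches
                else tree.internal_branch_labels()
            )
            ck = _ckpt_path(config.outdir, gene, "branch_site")
            cached = _load_ckpt(ck) if config.resume else None
            if cached is not None:
                bs_by_gene[gene] = [_result_from_payload(r, config) for r in cached]
                return
            mine = [
                branch_site_test(alignments[gene], tree, br, config.fit, code)
                for br in branches
            ]
            bs_by_gene[gene] = mine
            _save_ckpt(ck, [_result_payload(r, with_fits=True) for r in mine])

        _map_genes(bs_gene, ok_genes, config.threads, quarantine, "branch_site")
        bs_results = [r for g in ok_genes if g in bs_by_gene for r in bs_by_gene[g]]
        attach_adjusted(bs_results, config.correction_method)
        sel_results.extend(bs_results)

    # --- BEB on significant alternatives ----------------------------------
    site_posteriors = {}
    for r in sel_results:
        if (
            r.p_adjusted is not None
            and r.p_adjusted < config.alpha
            and r.fit_alt is not None
            and r.fit_alt.model.name in ("M2a", "M8", "branch_site_A")
        ):
            tree = chosen_tree[r.gene_id]
            if r.test == "branch_site":
                tree = tree.with_foreground(r.branch)
            post = beb_site_posteriors(alignments[r.gene_id], tree, r.fit_alt, code)
            site_posteriors[(r.gene_id, r.test, r.branch)] = post

    # --- stage: network -----------------------------------------------------
    cent = None
    if "network" in config.stages and network is not None:
        cent = centralities(network)
        write_centralities(cent, os.path.join(config.outdir, "centralities.tsv"))

    # --- assemble per-gene table -------------------------------------------
    rate_cols = [
        "gene", "n_codons", "lnL", "kappa", "omega", "dN", "dS", "tree_length",
    ]
    per_gene = (
        pd.DataFrame([rate_rows[g] for g in ok_genes], columns=rate_cols)
        if ok_genes
        else pd.DataFrame(columns=["gene"])
    )
    if cent is not None and len(per_gene):
        per_gene = per_gene.merge(
            cent.rename(columns={"node": "gene"})[
                ["gene", "degree", "closeness", "betweenness"]
            ],
            on="gene", how="left",
        )
    if annotations is not None and len(per_gene):
        per_gene = per_gene.merge(annotations, on="gene", how="left")

    # --- stage: associations ------------------------------------------------
    association: dict = {}
    if "associate" in config.stages and annotations is not None and len(per_gene):
        report = run_associations(per_gene, network)
        association = report.to_dict()
        association["metadata"]["seed"] = config.seed

    selection_df = pd.DataFrame(
        [_result_payload(r) for r in sel_results],
        columns=cio.SELECTION_COLUMNS,
    )
    failures_df = pd.DataFrame(failures, columns=["gene", "stage", "error"])
    failures_df.to_csv(
        os.path.join(config.outdir, "failures.tsv"), sep="\t", index=False
    )
    paths = cio.write_report(per_gene, selection_df, association, config.outdir)
    _write_posteriors(site_posteriors, config.outdir, paths)
    if truth is not None:
        truth_path = os.path.join(config.outdir, "truth.tsv")
        truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
    return RunResult(
        per_gene=per_gene,
        selection=selection_df,
        association=association,
        site_posteriors=site_posteriors,
        paths=paths,
        failures=failures_df,
    )


def _map_genes(fn, genes, threads, quarantine, stage) -> None:
    def safe(gene):
        try:
            fn(gene)
        except Exception as exc:  # per-gene quarantine is the contract
            quarantine(gene, stage, exc)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            list(ex.map(safe, genes))
    else:
        for g in genes:
            safe(g)


def _result_payload(r: SelectionTestResult, with_fits: bool = False) -> dict:
    out = {
        "gene_id": r.gene_id,
        "gene": r.gene_id,
        "test": r.test,
        "branch": r.branch or "",
        "lnL_alt": r.lnL_alt,
        "lnL_null": r.lnL_null,
        "statistic": r.statistic,
        "df": r.df,
        "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted,
    }
    if with_fits and r.fit_alt is not None:
        out["fit_alt"] = r.fit_alt.to_dict()
    return out


def _result_from_payload(d: dict, config: RunConfig) -> SelectionTestResult:
    fit_alt = (
        ModelFit.from_dict(d["fit_alt"], K=config.fit.n_beta_categories)
        if "fit_alt" in d
        else None
    )
    return SelectionTestResult(
        gene_id=d["gene_id"],
        test=d["test"],
        branch=d["branch"] or None,
        lnL_alt=d["lnL_alt"],
        lnL_null=d["lnL_null"],
        statistic=d["statistic"],
        df=d["df"],
        p_raw=d["p_raw"],
        p_adjusted=d.get("p_adjusted"),
        fit_alt=fit_alt,
    )


def _write_posteriors(posteriors: dict, outdir: str, paths: dict) -> None:
    rows = []
    for (gene, test, branch), post in sorted(
        posteriors.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2] or "")
    ):
        for site in range(len(post.beb)):
            rows.append(
                {
                    "gene": gene,
                    "test": test,
                    "branch": branch or "",
                    "site": site + 1,
                    "neb": post.neb[site],
                    "beb": post.beb[site],
                }
            )
    path = os.path.join(outdir, "site_posteriors.tsv")
    pd.DataFrame(rows, columns=["gene", "test", "branch", "site", "neb", "beb"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    paths["site_posteriors"] = path
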