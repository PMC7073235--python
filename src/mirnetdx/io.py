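"""File formats, pipeline configuration and the end-to-end orchestrator.

All tables are tab-separated with ``#`` comment headers carrying the tool
version and the seed; every writer has a matching reader that round-trips
losslessly.  ``run_all`` wires the full discovery pipeline together:
simulate -> differential expression (both platforms) -> network scoring and
selection -> platform overlap -> topology/DE filtering -> diagnostic
meta-analysis (singles and combination) -> survival, and writes a manifest
with per-stage row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .diffexp import differential_expression
from .meta import Study2x2, bayesian_meta, fit_diagnostic_lr, heterogeneity_i2
from .network import (
    Interactome,
    build_disease_network,
    overlap_platforms,
    score_mirnas,
    select_candidates,
)
from .survival import logrank_test, split_by_expression
from .synthetic import (
    CohortSpec,
    ExpressionSpec,
    InteractomeSpec,
    generate_expression,
    generate_interactome,
    generate_mirna_cohorts,
    generate_mirna_expression,
    generate_survival,
)
from .topology import compute_topology, filter_by_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_all",
    "write_table",
    "read_table",
    "write_edges",
    "read_edges",
    "write_lines",
    "read_lines",
    "write_expression",
    "read_expression",
    "write_samples",
    "read_samples",
    "read_tables_csv",
]


def _header(seed: int | None) -> str:
    tag = f"# mirnetdx v{__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


def write_table(df: pd.DataFrame, path, seed: int | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_edges(interactome: Interactome, path, seed: int | None = None) -> None:
    df = pd.DataFrame(interactome.edges, columns=["mirna_id", "gene_id"])
    df["source"] = "synthetic"
    write_table(df, path, seed=seed, index=False)


def read_edges(path) -> list[tuple[str, str]]:
    df = read_table(path, index_col=None)
    return [(str(m), str(g)) for m, g in zip(df["mirna_id"], df["gene_id"])]


def write_lines(items: Iterable[str], path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for it in items:
            fh.write(f"{it}\n")


def read_lines(path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_expression(matrix: pd.DataFrame, path, seed: int | None = None) -> None:
    write_table(matrix, path, seed=seed)


def read_expression(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def write_samples(labels: pd.Series, path, cohort: str = "main", seed: int | None = None) -> None:
    df = pd.DataFrame(
        {"sample_id": labels.index, "group": labels.to_numpy(), "cohort": cohort}
    )
    write_table(df, path, seed=seed, index=False)


def read_samples(path) -> pd.Series:
    df = read_table(path, index_col=None)
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def read_tables_csv(path) -> list[Study2x2]:
    """Read pre-made 2x2 tables (study_id, tp, fp, fn, tn; comma or tab)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return [
        Study2x2(
            study_id=str(r["study_id"]), tp=int(r["tp"]), fp=int(r["fp"]),
            tn=int(r["tn"]), fn=int(r["fn"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Thresholds, generator settings and MCMC settings for ``run_all``.

    Defaults reflect the synthetic study conditions documented in the
    methods note: 5 planted biomarkers among 200 disease miRNAs on a
    2000-gene interactome, two expression platforms, six diagnostic cohorts.
    """

    seed: int = 0
    out_dir: str = "mirnetdx_out"
    # interactome
    n_mirna: int = 200
    n_gene: int = 2000
    tf_fraction: float = 0.10
    mean_targets_per_mirna: float = 80.0
    degree_dispersion: float = 0.5
    planted_biomarkers: tuple[str, ...] = (
        "miR-186-5p", "miR-10b-5p", "miR-30e-5p", "miR-21-5p", "miR-31-5p",
    )
    planted_exclusive_targets: int = 8
    planted_tf_boost: float = 0.30
    known_biomarkers: tuple[str, ...] = ("miR-21-5p", "miR-31-5p")
    # expression / DE
    n_de_genes: int = 300
    lfc_mean: float = 2.0
    lfc_sd: float = 0.4
    noise_sd: float = 0.6
    nb_dispersion: float = 0.1
    n_cases: int = 40
    n_controls: int = 40
    de_alpha: float = 0.05
    lfc_min: float = 1.0
    # NSR/TFP selection
    nsr_min: int = 1
    alpha_nsr: float = 0.05
    tf_count_min: int = 1
    alpha_tfp: float = 0.05
    wilcoxon_method: str = "signed_rank"
    # topology filter
    k_sigma: float = 2.0
    mirna_de_alpha: float = 0.05
    # cohorts / meta-analysis
    n_studies: int = 6
    cases_per_study: int = 12
    controls_per_study: int = 8
    mu_se: float = 1.0986122886681098   # logit(0.75)
    mu_sp: float = 0.9444616088408514   # logit(0.72)
    tau_se: float = 0.3
    tau_sp: float = 0.3
    rho: float = -0.4
    lr_cutoff: float = 0.5
    robust: bool = False
    mcmc_chains: int = 2
    mcmc_iterations: int = 4000
    # survival
    surv_n: int = 400
    surv_rate: float = 0.1
    surv_assoc: float = 0.0
    surv_censor_rate: float = 0.05

    def __post_init__(self) -> None:
        self.planted_biomarkers = tuple(self.planted_biomarkers)
        self.known_biomarkers = tuple(self.known_biomarkers)
        for name in ("de_alpha", "alpha_nsr", "alpha_tfp", "mirna_de_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        unknown = set(self.known_biomarkers) - set(self.planted_biomarkers)
        if unknown:
            raise ValueError(f"known biomarkers not planted: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing config file: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        valid = {f.name for f in fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# orchestrator


def _predict_platform(interactome, deg, mirna_list, config):
    net = build_disease_network(interactome, deg, mirna_list)
    scores = score_mirnas(net, interactome.tf_genes, method=config.wilcoxon_method)
    selected = select_candidates(
        scores,
        nsr_min=config.nsr_min,
        alpha_nsr=config.alpha_nsr,
        tf_count_min=config.tf_count_min,
        alpha_tfp=config.alpha_tfp,
    )
    return net, scores, selected


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic-discovery pipeline; returns the manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    logger.info("simulate: interactome")
    ispec = InteractomeSpec(
        n_mirna=config.n_mirna,
        n_gene=config.n_gene,
        tf_fraction=config.tf_fraction,
        mean_targets_per_mirna=config.mean_targets_per_mirna,
        degree_dispersion=config.degree_dispersion,
        planted_biomarkers=config.planted_biomarkers,
        planted_exclusive_targets=config.planted_exclusive_targets,
        planted_tf_boost=config.planted_tf_boost,
        seed=seed,
    )
    interactome, planted = generate_interactome(ispec)
    mirna_list = sorted(interactome.mirna_universe)
    write_edges(interactome, out / "edges.tsv", seed=seed)
    write_lines(sorted(interactome.tf_genes), out / "tf_genes.txt", seed=seed)
    write_lines(mirna_list, out / "mirna_list.txt", seed=seed)
    must_de = planted.mandatory_de

    logger.info("simulate + de: both platforms")
    deg = {}
    truth_de = {}
    for k, platform in enumerate(("array", "counts")):
        espec = ExpressionSpec(
            platform=platform,
            n_de_genes=config.n_de_genes,
            lfc_mean=config.lfc_mean,
            lfc_sd=config.lfc_sd,
            noise_sd=config.noise_sd,
            nb_dispersion=config.nb_dispersion,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            seed=(seed + 11 * (k + 1)) % 2**31,
        )
        mat, labels, truth = generate_expression(interactome, espec, must_de=must_de)
        write_expression(mat, out / f"expr_{platform}.tsv", seed=espec.seed)
        write_samples(labels, out / f"samples_{platform}.tsv", cohort=platform, seed=espec.seed)
        deg[platform] = differential_expression(
            mat, labels, platform, alpha=config.de_alpha, lfc_min=config.lfc_min
        )
        truth_de[platform] = sorted(truth)
        write_table(deg[platform], out / f"deg_{platform}.tsv", seed=espec.seed)

    logger.info("predict: NSR/TFP scoring and selection")
    nets, selections = {}, {}
    for platform in ("array", "counts"):
        net, scores, selected = _predict_platform(
            interactome, deg[platform], mirna_list, config
        )
        nets[platform] = net
        selections[platform] = selected
        write_table(scores, out / f"scores_{platform}.tsv", seed=seed)
    candidates = overlap_platforms(selections["array"], selections["counts"])
    write_lines(candidates, out / "candidates.txt", seed=seed)

    logger.info("filter: miRNA DE + topology similarity")
    mirna_mat, mirna_labels = generate_mirna_expression(
        mirna_list, config.planted_biomarkers, seed=(seed + 101) % 2**31,
        n_cases=config.n_cases, n_controls=config.n_controls,
    )
    mirna_de = differential_expression(
        mirna_mat, mirna_labels, "array", alpha=config.mirna_de_alpha, lfc_min=0.0
    )
    write_table(mirna_de, out / "mirna_de.tsv", seed=seed)
    features = compute_topology(nets["array"])
    final = filter_by_similarity(
        candidates,
        config.known_biomarkers,
        features,
        mirna_de,
        k_sigma=config.k_sigma,
        de_alpha=config.mirna_de_alpha,
    )
    write_lines(final, out / "final_candidates.txt", seed=seed)

    truth_doc = {
        "planted_biomarkers": list(config.planted_biomarkers),
        "exclusive_targets": {m: list(v) for m, v in planted.exclusive.items()},
        "tf_boost_targets": {m: list(v) for m, v in planted.tf_boost.items()},
        "true_de": {k: v for k, v in truth_de.items()},
    }

    logger.info("meta: singles and combination")
    meta_summary = {}
    biomarkers = final if final else list(config.planted_biomarkers)
    cspec = CohortSpec(
        n_studies=config.n_studies,
        cases_per_study=config.cases_per_study,
        controls_per_study=config.controls_per_study,
        mu_se=config.mu_se,
        mu_sp=config.mu_sp,
        tau_se=config.tau_se,
        tau_sp=config.tau_sp,
        rho=config.rho,
        seed=(seed + 211) % 2**31,
    )
    cohorts, cohort_truth = generate_mirna_cohorts(biomarkers, cspec)
    truth_doc["study_accuracy"] = {
        s: {"se": float(r["se"]), "sp": float(r["sp"])}
        for s, r in cohort_truth.iterrows()
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))

    def _meta_for(cols: list[str], name: str, k: int) -> None:
        tables = [
            fit_diagnostic_lr(expr[cols], labels, study_id=study, cutoff=config.lr_cutoff)[0]
            for study, (expr, labels) in cohorts.items()
        ]
        post = bayesian_meta(
            tables,
            robust=config.robust,
            chains=config.mcmc_chains,
            iterations=config.mcmc_iterations,
            seed=(seed + 307 * (k + 1)) % 2**31,
        )
        meta_summary[name] = post.summary()
        meta_summary[name]["i2_sensitivity"] = heterogeneity_i2(tables, "sensitivity").i2
        meta_summary[name]["i2_specificity"] = heterogeneity_i2(tables, "specificity").i2

    for k, b in enumerate(biomarkers):
        _meta_for([b], b, k)
    if len(biomarkers) > 1:
        _meta_for(list(biomarkers), "combined", len(biomarkers))
    (out / "meta_summary.json").write_text(
        json.dumps(meta_summary, indent=2, sort_keys=True)
    )

    logger.info("survival: per-candidate log-rank")
    surv_rows = []
    for k, b in enumerate(biomarkers):
        table = generate_survival(
            n=config.surv_n,
            rate=config.surv_rate,
            assoc=config.surv_assoc,
            censor_rate=config.surv_censor_rate,
            seed=(seed + 401 * (k + 1)) % 2**31,
        )
        table["group"] = split_by_expression(table["expression"])
        res = logrank_test(table)
        surv_rows.append((b, res.chi2, res.p))
        if k == 0:
            write_table(table, out / "survival.tsv", seed=seed)
    surv_df = pd.DataFrame(surv_rows, columns=["biomarker", "chi2", "p"])
    write_table(surv_df, out / "survival_summary.tsv", seed=seed, index=False)

    manifest = {
        "version": __version__,
        "seed": seed,
        "counts": {
            "edges": len(interactome.edges),
            "mirnas": len(mirna_list),
            "tf_genes": len(interactome.tf_genes),
            "deg_array": int(deg["array"]["is_de"].sum()),
            "deg_counts": int(deg["counts"]["is_de"].sum()),
            "selected_array": int(len(selections["array"])),
            "selected_counts": int(len(selections["counts"])),
            "overlap_candidates": len(candidates),
            "final_candidates": len(final),
        },
        "final_candidates": list(final),
        "planted_biomarkers": list(config.planted_biomarkers),
        "meta": meta_summary,
        "survival": {b: {"chi2": c, "p": p} for b, c, p in surv_rows},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
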