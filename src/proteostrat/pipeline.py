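"""End-to-end discovery and validation runs with seeds and reports.

``run_discovery`` executes simulate -> consensus clustering ->
subgroup characterization (differential abundance + enrichment) ->
splicing statistics -> survival -> correlation network on one cohort
and emits a machine-readable JSON report plus TSV tables.
``run_validation`` trains the k-TSP and PLS-DA classifiers on a
discovery cohort, applies them to an independent cohort, and reports
predicted prevalences and survival splits.

Per-stage seeds are derived from the single global seed with
``numpy.random.SeedSequence(seed).generate_state`` in a fixed stage
order, so individual stages can be re-run in isolation and whole runs
are bit-reproducible.  Reports contain no timestamps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers, consensus, differential, network, splicing, survival
from .simulate import CohortBundle, CohortConfig, simulate_cohort, write_bundle

__all__ = ["RunConfig", "stage_seeds", "run_discovery", "run_validation"]

_STAGES = ["simulate", "cluster", "differential", "splicing", "survival",
           "network", "classify"]


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES),
                                                        dtype=np.uint64)
    return {stage: int(s % (2**31 - 1)) for stage, s in zip(_STAGES, state)}


@dataclass
class RunConfig:
    """Parameters of a discovery/validation run (YAML-loadable)."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    k_override: int | None = 6
    k_range: tuple = (2, 8)
    consensus_iters: int = 200
    item_frac: float = 0.8
    inner: str = "kmeans"
    n_perm: int = 57
    splice_fdr: float = 0.01
    min_dpsi: float = 0.1
    min_mean_incl: float = 20.0
    n_top_sd: int = 300
    r_edge: float = 0.6
    kcore_k: int = 3
    resolution: float = 0.8
    tsp_k_grid: tuple = (3, 5, 7, 9)
    tsp_splits: int = 50
    validation_n: int = 165

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        return cfg


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_report(report: dict, out_dir: Path | None) -> None:
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_discovery(config: RunConfig, out_dir=None,
                  bundle: CohortBundle | None = None) -> dict:
    """Execute the discovery pipeline; returns the report dict.

    Stages toggled off are marked ``"skipped"`` in the report.  Any
    stage failure aborts with the stage name in the exception message;
    previously written outputs are retained.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    seeds = stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stage_seeds": seeds}

    cohort_cfg = config.cohort
    if bundle is None:
        if config.stages.get("simulate", True):
            cohort_cfg = CohortConfig(**{**cohort_cfg.__dict__,
                                         "seed": seeds["simulate"]})
            bundle = simulate_cohort(cohort_cfg)
        else:
            raise ValueError("no bundle provided and simulate stage disabled")
    truth = bundle.truth
    report["cohort"] = {
        "n_samples": len(truth),
        "group_sizes": truth.value_counts().sort_index().to_dict(),
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir / "bundle")

    labels = None
    try:
        if config.stages.get("cluster", True):
            res = consensus.consensus_cluster(
                bundle.protein, range(config.k_range[0], config.k_range[1] + 1)
                if config.k_override is None else [config.k_override],
                n_iter=config.consensus_iters, item_frac=config.item_frac,
                inner=config.inner, seed=seeds["cluster"])
            k = consensus.choose_k(res, override=config.k_override)
            labels = res.labels[k]
            from sklearn.metrics import adjusted_rand_score
            ari = adjusted_rand_score(truth, labels.loc[truth.index])
            enr = consensus.genotype_enrichment(
                labels, bundle.annotation[
                    ["trisomy12", "IGHV_mutated", "TP53mut", "SF3B1mut",
                     "del17p13", "del11q22", "del13q14", "gain8q24"]])
            # name the cluster best matching planted ASB samples
            asb_truth = set(truth.index[truth == "ASB"])
            jaccards = {}
            for g in labels.unique():
                members = set(labels.index[labels == g])
                jaccards[int(g)] = (len(members & asb_truth)
                                    / len(members | asb_truth))
            asb_cluster = max(jaccards, key=jaccards.get)
            report["cluster"] = {
                "k": int(k), "ari_vs_truth": float(ari),
                "asb_cluster": asb_cluster,
                "asb_jaccard": jaccards[asb_cluster],
                "n_enrichment_hits": int(enr["hit"].sum()),
            }
            if out_dir is not None:
                labels.rename("group").to_csv(out_dir / "labels.tsv", sep="\t")
                enr.to_csv(out_dir / "genotype_enrichment.tsv", sep="\t")
        else:
            report["cluster"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    asb_mask = (labels == report["cluster"]["asb_cluster"]) \
        if isinstance(report.get("cluster"), dict) else (truth == "ASB")
    asb_labels = pd.Series(np.where(asb_mask.loc[truth.index], "ASB", "other"),
                           index=truth.index)

    try:
        if config.stages.get("differential", True):
            design = differential.two_group_design(asb_labels, "ASB")
            fit = differential.moderated_fit(bundle.protein, design, "group")
            hits = differential.call_hits(fit, 0.5, 0.001)
            hit_ids = set(hits.index[hits["hit"]])
            enrich = differential.fisher_overrepresentation_table(
                hit_ids, set(fit.table.index), bundle.gene_sets)
            corr = differential.mrna_protein_spearman(bundle.protein,
                                                      bundle.mrna)
            summ = differential.correlation_summaries(corr)
            report["differential"] = {
                "n_hits_asb": int(hits["hit"].sum()),
                "top_enriched_set": enrich["p"].idxmin(),
                "median_rho": summ["median_rho"],
                "median_rho_by_class": summ["median_rho_by_class"],
            }
            if out_dir is not None:
                hits.to_csv(out_dir / "differential_asb.tsv", sep="\t")
                corr.to_csv(out_dir / "mrna_protein_corr.tsv", sep="\t")
        else:
            report["differential"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage 'differential' failed: {exc}") from exc

    try:
        if config.stages.get("splicing", True):
            diff = splicing.differential_psi(
                bundle.events, asb_labels, "ASB", fdr=config.splice_fdr,
                min_dpsi=config.min_dpsi, min_mean_incl=config.min_mean_incl)
            perm = splicing.permutation_null(
                bundle.events, asb_labels, "ASB", n_perm=config.n_perm,
                seed=seeds["splicing"], fdr=config.splice_fdr,
                min_dpsi=config.min_dpsi, min_mean_incl=config.min_mean_incl)
            psi = splicing.compute_psi(bundle.events)
            mean_by_cat = {}
            for cat in ("SE", "A3SS", "A5SS"):
                top = splicing.top_variable_events(psi, bundle.events, cat,
                                                   1000)
                mean_by_cat[cat] = splicing.mean_psi(top)
            spl_corr = splicing.spliceosome_psi_correlation(
                bundle.protein, bundle.gene_sets["SPLICEOSOME"], mean_by_cat)
            report["splicing"] = {
                "n_significant": perm.observed,
                "permutation_p": perm.p,
                "n_perm": perm.n_perm,
                "spliceosome_psi_rho": spl_corr["rho"].to_dict(),
            }
            if out_dir is not None:
                diff[diff["significant"]].to_csv(
                    out_dir / "significant_events.tsv", sep="\t")
        else:
            report["splicing"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage 'splicing' failed: {exc}") from exc

    try:
        if config.stages.get("survival", True):
            ann = bundle.annotation
            groups = [
                pd.DataFrame({"time_days": ann.loc[idx, "ttnt_days"],
                              "event": ann.loc[idx, "ttnt_event"]})
                for g, idx in ann.groupby(asb_labels).groups.items()
            ]
            chi2, df, p = survival.logrank(groups)
            covs = pd.DataFrame({
                "ASB": (asb_labels == "ASB").astype(float),
                "TP53": ann["TP53mut"].astype(float),
            })
            covs["ASB:TP53"] = covs["ASB"] * covs["TP53"]
            covs = covs.loc[:, covs.nunique() > 1]
            endpoint = pd.DataFrame({"time_days": ann["os_days"],
                                     "event": ann["os_event"]})
            cox = survival.cox_fit(covs, endpoint)
            growth = survival.lymphocyte_growth(bundle.lymph_series)
            report["survival"] = {
                "ttnt_logrank_chi2": chi2, "ttnt_logrank_p": p,
                "os_cox_hr": cox.table["hr"].to_dict(),
                "n_growth_samples": int(len(growth)),
            }
            if out_dir is not None:
                cox.table.to_csv(out_dir / "cox_os.tsv", sep="\t")
        else:
            report["survival"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc

    try:
        if config.stages.get("network", True):
            graph = network.build_network(bundle.protein,
                                          n_top_sd=config.n_top_sd,
                                          r_edge=config.r_edge)
            core = network.kcore(graph, config.kcore_k)
            if core.number_of_nodes() > 0:
                mods = network.modules(core, config.resolution,
                                       seed=seeds["network"])
                means = network.module_group_means(
                    bundle.protein, mods, truth)
                report["network"] = {
                    "n_nodes": core.number_of_nodes(),
                    "n_edges": core.number_of_edges(),
                    "n_modules": int(mods.nunique()),
                }
                if out_dir is not None:
                    mods.rename("module").to_csv(
                        out_dir / "network_modules.tsv", sep="\t")
                    means.to_csv(out_dir / "module_group_means.tsv", sep="\t")
            else:
                report["network"] = {"n_nodes": 0, "n_edges": 0,
                                     "n_modules": 0}
        else:
            report["network"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    _write_report(report, out_dir)
    return report


def run_validation(config: RunConfig, out_dir=None,
                   discovery: CohortBundle | None = None,
                   validation: CohortBundle | None = None) -> dict:
    """Train classifiers on a discovery cohort, apply to a validation
    cohort, and report prevalence plus survival splits."""
    out_dir = Path(out_dir) if out_dir is not None else None
    seeds = stage_seeds(config.seed)
    if discovery is None:
        cfg = CohortConfig(**{**config.cohort.__dict__,
                              "seed": seeds["simulate"]})
        discovery = simulate_cohort(cfg)
    if validation is None:
        cfg = CohortConfig(**{**config.cohort.__dict__,
                              "n_samples": config.validation_n,
                              "seed": seeds["classify"]})
        validation = simulate_cohort(cfg)
    report: dict = {"seed": config.seed}

    panel = (discovery.gene_sets["BCR"]
             + discovery.gene_sets["SPLICEOSOME"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsp = classifiers.tsp_train_mccv(
            discovery.protein.values, discovery.truth, "ASB", panel,
            k_grid=config.tsp_k_grid, n_splits=config.tsp_splits,
            seed=seeds["classify"])
        pred, _ = classifiers.tsp_predict(tsp, validation.protein.values)
    prevalence = float((pred == "ASB").mean() * 100.0)
    report["ktsp"] = {
        "k": tsp.k, "vote_threshold": tsp.vote_threshold,
        "predicted_asb_percent": prevalence,
        "true_asb_percent": float(
            (validation.truth == "ASB").mean() * 100.0),
    }

    # survival split of the predicted groups in the validation cohort
    ann = validation.annotation
    asb_pred = pred.fillna("other")
    groups = [
        pd.DataFrame({"time_days": ann.loc[idx, "os_days"],
                      "event": ann.loc[idx, "os_event"]})
        for g, idx in ann.groupby(asb_pred).groups.items()
    ]
    chi2, df, p = survival.logrank(groups)
    covs = pd.DataFrame({
        "ASB": (asb_pred == "ASB").astype(float),
        "TP53": ann["TP53mut"].astype(float),
    })
    covs["ASB:TP53"] = covs["ASB"] * covs["TP53"]
    covs = covs.loc[:, covs.nunique() > 1]  # degenerate cells drop terms
    endpoint = pd.DataFrame({"time_days": ann["os_days"],
                             "event": ann["os_event"]})
    cox = survival.cox_fit(covs, endpoint)
    report["survival"] = {"os_logrank_chi2": chi2, "os_logrank_p": p,
                          "os_cox_hr": cox.table["hr"].to_dict(),
                          "os_cox_p": cox.table["p"].to_dict()}

    # PLS-DA on the discovery cohort's significant splicing events
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff = splicing.differential_psi(
            discovery.events, discovery.truth, "ASB",
            fdr=config.splice_fdr, min_dpsi=config.min_dpsi,
            min_mean_incl=config.min_mean_incl)
        sig = diff.index[diff["significant"]].tolist()
        if len(sig) >= 2:
            psi_train = splicing.compute_psi(
                discovery.events.loc[sig]).T.fillna(0.5)
            plsda = classifiers.plsda_train(psi_train, discovery.truth, "ASB")
            psi_val = splicing.compute_psi(
                validation.events.loc[sig]).T.fillna(0.5)
            plabels, _ = classifiers.plsda_predict(plsda, psi_val)
            report["plsda"] = {
                "n_predictors": len(sig),
                "n_components": plsda.n_components,
                "loo_auroc": plsda.loo_auroc,
                "predicted_asb_percent": float(
                    (plabels == "ASB").mean() * 100.0),
            }
        else:
            report["plsda"] = "skipped (too few significant events)"

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ktsp_model.json").write_text(tsp.to_json())
        pred.rename("label").to_csv(out_dir / "ktsp_predictions.tsv",
                                    sep="\t")
        with open(out_dir / "validation_report.json", "w") as fh:
            json.dump(_round_floats(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
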