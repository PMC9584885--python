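"""Synthetic multi-omics CLL-like cohort generator.

Emulates the statistical structure of a proteogenomic stratification
study: six planted patient subgroups (four driven by trisomy 12 and IGHV
mutation status, one TP53-driven, one detectable only at the proteome
level, "ASB", at roughly 20% prevalence), chromosome-12 gene-dosage
effects, class-dependent mRNA~protein coupling, ASB-specific
spliceosome-up / B-cell-receptor-down protein shifts, exon-skipping PSI
shifts, group-dependent survival hazards, lymphocyte growth series, and
a plate-based ex-vivo drug screen.

The mRNA~protein coupling targets are median Spearman correlations:
0.69 for trisomy-12-responsive proteins, 0.86 for IGHV-responsive
proteins, 0.29 for SF3B1-responsive proteins, and a background level
that places the overall median near 0.243.  Coupling is implemented by
a shared latent signal per gene with class-specific mRNA noise solved
in closed form against the Pearson equivalent of the Spearman target
(r = 2 sin(pi * rho / 6) for bivariate normal data).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    OmicsMatrix,
    SchemaError,
    load_gmt,
    load_matrix,
    write_gmt,
    write_matrix,
)

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "ConfigError",
    "simulate_cohort",
    "simulate_splice_events",
    "write_bundle",
    "read_bundle",
]

SUBGROUPS = ["Tris12M", "Tris12U", "M", "U", "TP53", "ASB"]
LESIONS = [
    "trisomy12", "IGHV_mutated", "TP53mut", "SF3B1mut",
    "del17p13", "del11q22", "del13q14", "gain8q24",
]
EVENT_CATEGORIES = ["SE", "A3SS", "A5SS", "RI", "MXE"]


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


def _spearman_to_pearson(rho: float) -> float:
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass
class CohortConfig:
    """Study conditions for :func:`simulate_cohort`.

    Subgroup proportions approximate the discovery-cohort composition
    (ASB near 20%).  ``dosage_log2fc`` is the log2 fold change applied
    to chromosome-12 features in trisomy-12 carriers, log2(3/2) by
    default.  The four ``asb_*_shift`` values are log2 shifts applied to
    the spliceosome, B-cell-receptor, proteasome and branched-chain
    amino-acid gene sets in ASB samples.  ``delta_psi_asb`` is a
    logit-scale inclusion shift for ASB-affected splice events, sized to
    give a mean absolute PSI difference of about 0.15.
    """

    n_samples: int = 68
    subgroup_proportions: dict = field(default_factory=lambda: {
        "Tris12M": 0.13, "Tris12U": 0.12, "M": 0.26,
        "U": 0.25, "TP53": 0.06, "ASB": 0.18,
    })
    lesion_prevalences: dict = field(default_factory=lambda: {
        "SF3B1mut": 0.15, "del17p13": 0.06, "del11q22": 0.15,
        "del13q14": 0.55, "gain8q24": 0.07,
    })
    dosage_log2fc: float = 0.585  # log2(3/2)
    trisomy_response_log2fc: float = 0.6
    ighv_log2fc: float = 0.8
    sf3b1_log2fc: float = 0.6
    tp53_log2fc: float = 0.9
    asb_spliceosome_shift: float = 0.7
    asb_bcr_shift: float = -0.7
    asb_proteasome_shift: float = -0.4
    asb_bcaa_shift: float = 0.4
    coupling_by_class: dict = field(default_factory=lambda: {
        "trisomy12": 0.69, "ighv": 0.86, "sf3b1": 0.29, "background": 0.243,
    })
    delta_psi_asb: float = 0.65  # logit units; mean |dPSI| about 0.15
    n_features_protein: int = 1500
    n_features_rna: int = 1500
    n_events: int = 2000          # skipped-exon events
    n_events_other: int = 300     # per other category
    n_asb_events: int = 150       # planted SE events
    survival_loghr: dict = field(default_factory=lambda: {
        "ttnt": {"Tris12M": 0.2, "Tris12U": 0.5, "M": -0.8,
                 "U": 0.4, "TP53": 0.8, "ASB": 1.1},
        "os": {"Tris12M": 0.0, "Tris12U": 0.25, "M": -0.4,
               "U": 0.3, "TP53": 0.8, "ASB": 1.1},
        "ttft": {"Tris12M": 0.5, "Tris12U": 0.6, "M": -0.9,
                 "U": 0.5, "TP53": 0.6, "ASB": 0.8},
    })
    noise_sd: float = 0.35
    missing_rate: float = 0.05
    pretreated_rate: float = 0.34
    censor_horizon_days: float = 2920.0
    seed: int = 0
    # seed of the cohort-independent "biology": per-feature baseline
    # abundances and per-event baseline PSI are properties of the
    # simulated organism, not of a cohort draw, so cohorts generated
    # with different seeds share them (rank-based classifiers transfer
    # across cohorts exactly as they do across real datasets)
    universe_seed: int = 777

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be > 0")
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"subgroup_proportions must sum to 1 (got {total!r})"
            )
        for grp, p in self.subgroup_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"subgroup_proportions[{grp!r}] outside [0,1]")
            if grp not in SUBGROUPS:
                raise ConfigError(f"unknown subgroup {grp!r}")
        for lesion, p in self.lesion_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"lesion_prevalences[{lesion!r}] outside [0,1]")
        for name in ("n_features_protein", "n_features_rna", "n_events",
                     "n_events_other", "n_asb_events"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate outside [0,1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


@dataclass
class CohortBundle:
    """Everything a downstream analysis stage consumes, sample-aligned."""

    annotation: pd.DataFrame          # indexed by sample_id
    protein: OmicsMatrix
    mrna: OmicsMatrix
    events: pd.DataFrame              # splice event table (wide counts)
    exon_quant: OmicsMatrix           # exon x sample log2 matrix
    exon_gene_map: pd.Series          # exon id -> gene id
    drug_plate: pd.DataFrame
    lymph_series: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: pd.Series                  # sample_id -> subgroup label

    @property
    def sample_ids(self) -> list[str]:
        return self.annotation.index.tolist()

    def validate(self) -> None:
        samples = self.sample_ids
        for name, got in [
            ("protein", self.protein.sample_ids),
            ("mrna", self.mrna.sample_ids),
            ("exon_quant", self.exon_quant.sample_ids),
            ("truth", self.truth.index.tolist()),
        ]:
            if got != samples:
                raise SchemaError(f"sample order mismatch in {name}")
        event_samples = [c[5:] for c in self.events.columns
                         if c.startswith("incl:")]
        if event_samples != samples:
            raise SchemaError("sample order mismatch in events")
        counts = self.events[[c for c in self.events.columns
                              if c.startswith(("incl:", "skip:"))]]
        arr = counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise SchemaError("splice counts must be non-negative integers")
        feature_ids = set(self.protein.feature_ids)
        for name in self.gene_sets.names():
            missing = set(self.gene_sets[name]) - feature_ids
            if missing:
                raise SchemaError(
                    f"gene set {name!r} members absent from protein matrix: "
                    f"{sorted(missing)[:5]}"
                )


# ---------------------------------------------------------------------------
# feature layout

def _feature_layout(cfg: CohortConfig) -> pd.DataFrame:
    """Deterministic feature metadata: positions, classes, set memberships."""
    n = cfg.n_features_protein
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    meta = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    meta["gene_symbol"] = [f"G{i:05d}" for i in range(1, n + 1)]

    n_chr12 = 100
    sizes = {
        "tris_off": 70, "ighv": 80, "sf3b1": 50, "tp53sig": 50,
        "spliceosome": 100, "bcr": 60, "proteasome": 30, "bcaa": 20,
    }
    n_coexpr_blocks, coexpr_size = 6, 12
    needed = n_chr12 + sum(sizes.values()) + n_coexpr_blocks * coexpr_size
    if n < needed + 100:
        raise ConfigError(
            f"n_features_protein must be at least {needed + 100}"
        )
    cursor = 0
    blocks = {}
    blocks["chr12"] = ids[cursor:cursor + n_chr12]; cursor += n_chr12
    for key, size in sizes.items():
        blocks[key] = ids[cursor:cursor + size]; cursor += size
    # six co-expression modules (complex-like shared latent factors)
    coexpr = {}
    for b in range(n_coexpr_blocks):
        coexpr[f"N{b + 1}"] = ids[cursor:cursor + coexpr_size]
        cursor += coexpr_size
    blocks["coexpr"] = coexpr

    chroms = [str(c) for c in range(1, 23) if c != 12]
    meta["chromosome"] = [chroms[i % len(chroms)] for i in range(n)]
    meta.loc[blocks["chr12"], "chromosome"] = "12"
    # spread positions along each chromosome (0-based half-open internally)
    pos = np.zeros(n, dtype=int)
    for chrom, grp in meta.groupby("chromosome").groups.items():
        k = len(grp)
        pos_on = np.linspace(1e6, 1.3e8, k).astype(int)
        pos[meta.index.get_indexer(grp)] = pos_on
    meta["start"] = pos
    meta["end"] = pos + 5000

    meta["feature_class"] = "background"
    meta.loc[blocks["chr12"][:40], "feature_class"] = "trisomy12"
    meta.loc[blocks["tris_off"], "feature_class"] = "trisomy12"
    meta.loc[blocks["ighv"], "feature_class"] = "ighv"
    meta.loc[blocks["sf3b1"], "feature_class"] = "sf3b1"
    meta["coexpr_module"] = ""
    for name, members in blocks["coexpr"].items():
        meta.loc[members, "coexpr_module"] = name

    meta.attrs["blocks"] = blocks
    return meta


def _assign_groups(cfg: CohortConfig, rng: np.random.Generator) -> pd.Series:
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    groups = list(cfg.subgroup_proportions)
    probs = np.array([cfg.subgroup_proportions[g] for g in groups])
    labels = rng.choice(groups, size=cfg.n_samples, p=probs / probs.sum())
    return pd.Series(labels, index=pd.Index(samples, name="sample_id"),
                     name="true_group")


def _assign_lesions(cfg: CohortConfig, truth: pd.Series,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = len(truth)
    ann = pd.DataFrame(index=truth.index)
    g = truth.to_numpy()
    ann["trisomy12"] = np.isin(g, ["Tris12M", "Tris12U"]).astype(int)
    ighv = np.zeros(n, dtype=int)
    ighv[np.isin(g, ["Tris12M", "M"])] = 1
    mixed = np.isin(g, ["TP53", "ASB"])
    ighv[mixed] = rng.random(mixed.sum()) < 0.5
    ann["IGHV_mutated"] = ighv
    tp53 = (rng.random(n) < 0.04).astype(int)
    tp53[g == "TP53"] = (rng.random((g == "TP53").sum()) < 0.85).astype(int)
    ann["TP53mut"] = tp53
    prev = cfg.lesion_prevalences
    ann["SF3B1mut"] = (rng.random(n) < prev.get("SF3B1mut", 0.15)).astype(int)
    del17 = rng.random(n) < prev.get("del17p13", 0.06)
    del17 |= (ann["TP53mut"].to_numpy() == 1) & (rng.random(n) < 0.3)
    ann["del17p13"] = del17.astype(int)
    for lesion in ("del11q22", "del13q14", "gain8q24"):
        ann[lesion] = (rng.random(n) < prev.get(lesion, 0.1)).astype(int)
    ann["pretreated"] = (rng.random(n) < cfg.pretreated_rate).astype(int)
    return ann


def _shift_matrix(cfg: CohortConfig, meta: pd.DataFrame,
                  ann: pd.DataFrame, truth: pd.Series) -> np.ndarray:
    """Planted log2 shifts, features x samples."""
    blocks = meta.attrs["blocks"]
    n_feat, n_samp = len(meta), len(ann)
    shift = np.zeros((n_feat, n_samp))
    fidx = {f: i for i, f in enumerate(meta.index)}

    def add(features, amount, mask):
        rows = [fidx[f] for f in features]
        shift[np.ix_(rows, mask.to_numpy().astype(bool))] += amount

    is_asb = truth == "ASB"
    add(blocks["chr12"], cfg.dosage_log2fc, ann["trisomy12"] == 1)
    add(blocks["tris_off"], cfg.trisomy_response_log2fc, ann["trisomy12"] == 1)
    # the IGHV-driven proteomic program (largely BcR-coupled) is damped
    # in ASB samples: their low BcR signaling is independent of IGHV status
    add(blocks["ighv"], cfg.ighv_log2fc,
        (ann["IGHV_mutated"] == 1) & ~is_asb)
    add(blocks["ighv"], 0.25 * cfg.ighv_log2fc,
        (ann["IGHV_mutated"] == 1) & is_asb)
    add(blocks["sf3b1"], cfg.sf3b1_log2fc, ann["SF3B1mut"] == 1)
    add(blocks["tp53sig"], cfg.tp53_log2fc, truth == "TP53")
    add(blocks["spliceosome"], cfg.asb_spliceosome_shift, is_asb)
    add(blocks["bcr"], cfg.asb_bcr_shift, is_asb)
    add(blocks["proteasome"], cfg.asb_proteasome_shift, is_asb)
    add(blocks["bcaa"], cfg.asb_bcaa_shift, is_asb)
    return shift


_CLASS_LATENT_VAR = {
    # shared-signal variance tau^2 added on top of the between-group
    # variance of the planted shifts, per coupling class
    "trisomy12": 0.06, "ighv": 0.23, "sf3b1": 0.03, "background": 0.04,
}

# variance of the per-sample factor shared within a co-expression module
# (within-module Pearson r about 0.75 at the default noise level)
_COEXPR_FACTOR_VAR = 0.36


def _coupling_noise_sd(cfg: CohortConfig, meta: pd.DataFrame,
                       shift: np.ndarray) -> np.ndarray:
    """Per-feature mRNA noise SD hitting the class Spearman targets.

    For protein P = c + e_p and mRNA R = c + e_r sharing latent c,
    Pearson r = Var(c) / sqrt((Var(c)+s_p^2)(Var(c)+s_r^2)); solve for
    s_r given the target (converted from the Spearman scale).
    """
    sp2 = cfg.noise_sd ** 2
    var_c = shift.var(axis=1) + np.array(
        [_CLASS_LATENT_VAR.get(c, 0.04) for c in meta["feature_class"]]
    )
    if "coexpr_module" in meta.columns:
        var_c = var_c + np.where(meta["coexpr_module"].to_numpy() != "",
                                 _COEXPR_FACTOR_VAR, 0.0)
    out = np.empty(len(meta))
    for i, cls in enumerate(meta["feature_class"]):
        rho = cfg.coupling_by_class.get(cls, cfg.coupling_by_class["background"])
        r = _spearman_to_pearson(rho)
        vc = var_c[i]
        denom = r * r * (vc + sp2)
        sr2 = vc * vc / denom - vc if denom > 0 else np.inf
        out[i] = math.sqrt(max(sr2, 1e-6))
    return out


def _omics_matrices(cfg: CohortConfig, meta: pd.DataFrame,
                    ann: pd.DataFrame, truth: pd.Series,
                    rng: np.random.Generator) -> tuple[OmicsMatrix, OmicsMatrix]:
    n_feat, n_samp = len(meta), len(ann)
    universe = np.random.default_rng(cfg.universe_seed)
    baseline = universe.normal(20.0, 2.0, size=n_feat)
    rna_baseline = universe.normal(8.0, 1.5, size=n_feat)
    shift = _shift_matrix(cfg, meta, ann, truth)
    tau = np.sqrt(np.array(
        [_CLASS_LATENT_VAR.get(c, 0.04) for c in meta["feature_class"]]
    ))
    latent = shift + rng.normal(0.0, 1.0, (n_feat, n_samp)) * tau[:, None]
    # shared co-expression factors (inside the latent signal, so mRNA
    # co-varies too, as for transcriptionally co-regulated complexes)
    coexpr = meta["coexpr_module"].to_numpy()
    for name in sorted(set(coexpr) - {""}):
        factor = rng.normal(0.0, math.sqrt(_COEXPR_FACTOR_VAR), n_samp)
        latent[coexpr == name] += factor[None, :]
    protein = baseline[:, None] + latent + rng.normal(
        0.0, cfg.noise_sd, (n_feat, n_samp))
    sr = _coupling_noise_sd(cfg, meta, shift)
    mrna = rna_baseline[:, None] + latent + rng.normal(
        0.0, 1.0, (n_feat, n_samp)) * sr[:, None]
    if cfg.missing_rate > 0:
        mask = rng.random((n_feat, n_samp)) < cfg.missing_rate
        protein = np.where(mask, np.nan, protein)
    samples = ann.index
    n_rna = min(cfg.n_features_rna, n_feat)
    prot_df = pd.DataFrame(protein, index=meta.index, columns=samples)
    rna_df = pd.DataFrame(mrna[:n_rna], index=meta.index[:n_rna],
                          columns=samples)
    return (OmicsMatrix(prot_df, meta.drop(columns=[]).copy()),
            OmicsMatrix(rna_df, meta.iloc[:n_rna].copy()))


def simulate_splice_events(
    rng: np.random.Generator,
    n_samples: int,
    affected_mask: np.ndarray,
    n_events: int,
    n_affected_events: int,
    shift: float,
    shift_scale: str = "logit",
    category: str = "SE",
    mean_total: float = 60.0,
    dispersion: float = 0.3,
    low_coverage_frac: float = 0.15,
    incl_len: int = 2,
    skip_len: int = 1,
    event_offset: int = 0,
    bio_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one category of exon-skipping-style events.

    Totals per (event, sample) are negative binomial (``mean_total``,
    ``dispersion`` with variance mu + disp*mu^2); a ``low_coverage_frac``
    fraction of events is drawn at mean 10 so the >20-mean-inclusion
    coverage filter has bite.  Inclusion counts are binomial with the
    length-normalized inclusion probability implied by the event PSI;
    the first ``n_affected_events`` events have their PSI shifted in
    samples flagged by ``affected_mask`` (logit or linear scale).

    Returns the wide event table used throughout the package:
    ``event_id, category, incl_len, skip_len, incl:<sample>..., skip:<sample>...``.
    """
    if shift_scale not in ("logit", "linear"):
        raise ValueError("shift_scale must be 'logit' or 'linear'")
    if bio_rng is None:
        bio_rng = rng
    affected_mask = np.asarray(affected_mask, dtype=bool)
    psi0 = np.empty(n_events)
    psi0[:n_affected_events] = bio_rng.uniform(0.2, 0.65, n_affected_events)
    psi0[n_affected_events:] = bio_rng.uniform(0.05, 0.95,
                                               n_events - n_affected_events)
    psi = np.tile(psi0[:, None], (1, n_samples))
    if n_affected_events:
        if shift_scale == "logit":
            logit = np.log(psi0[:n_affected_events] /
                           (1 - psi0[:n_affected_events]))
            shifted = 1.0 / (1.0 + np.exp(-(logit + shift)))
        else:
            shifted = np.clip(psi0[:n_affected_events] + shift, 0.01, 0.99)
        psi[:n_affected_events, :][:, affected_mask] = shifted[:, None]

    mu = np.full(n_events, mean_total)
    n_low = int(round(low_coverage_frac * n_events))
    if n_low:
        low = bio_rng.permutation(n_events)[:n_low]
        mu[low] = 10.0
    size = 1.0 / dispersion
    p = size / (size + mu)
    totals = rng.negative_binomial(size, p[:, None], (n_events, n_samples))
    # length-normalized inclusion probability at the read-count level
    rho = psi * incl_len / (psi * incl_len + (1 - psi) * skip_len)
    incl = rng.binomial(totals, rho)
    skip = totals - incl

    ids = [f"{category}{i + 1 + event_offset:05d}" for i in range(n_events)]
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    head = pd.DataFrame({"event_id": ids, "category": category,
                         "incl_len": incl_len, "skip_len": skip_len})
    incl_df = pd.DataFrame(incl, columns=[f"incl:{s}" for s in samples])
    skip_df = pd.DataFrame(skip, columns=[f"skip:{s}" for s in samples])
    return pd.concat([head, incl_df, skip_df], axis=1).set_index("event_id")


def _splice_tables(cfg: CohortConfig, truth: pd.Series,
                   rng: np.random.Generator) -> pd.DataFrame:
    is_asb = (truth == "ASB").to_numpy()
    n = len(truth)
    bio = np.random.default_rng(cfg.universe_seed + 1)
    parts = [simulate_splice_events(
        rng, n, is_asb, cfg.n_events, cfg.n_asb_events,
        cfg.delta_psi_asb, "logit", "SE", bio_rng=bio)]
    # more 3'/5' alternative splice-site usage in ASB; RI/MXE untouched
    for cat, n_aff in [("A3SS", 80), ("A5SS", 80), ("RI", 0), ("MXE", 0)]:
        parts.append(simulate_splice_events(
            rng, n, is_asb, cfg.n_events_other, n_aff,
            cfg.delta_psi_asb, "logit", cat, bio_rng=bio))
    table = pd.concat(parts)
    # restore the cohort's actual sample ids (simulate_splice_events
    # names samples positionally)
    rename = {}
    for j, s in enumerate(truth.index):
        rename[f"incl:S{j + 1:03d}"] = f"incl:{s}"
        rename[f"skip:S{j + 1:03d}"] = f"skip:{s}"
    return table.rename(columns=rename)


def _exon_quant(cfg: CohortConfig, truth: pd.Series,
                rng: np.random.Generator) -> tuple[OmicsMatrix, pd.Series]:
    n_genes, n_exons = 200, 4
    n_affected = 40
    samples = truth.index
    n = len(samples)
    is_asb = (truth == "ASB").to_numpy()
    rows, gene_of = [], []
    values = np.empty((n_genes * n_exons, n))
    for g in range(n_genes):
        gene = f"EG{g + 1:04d}"
        base = rng.normal(18.0, 1.5)
        gene_effect = rng.normal(0.0, 0.4, n)
        for e in range(n_exons):
            exon = f"{gene}:E{e + 1}"
            vals = base + gene_effect + rng.normal(0.0, 0.25, n)
            if g < n_affected and e == 0:
                vals = vals + 0.8 * is_asb
            values[g * n_exons + e] = vals
            rows.append(exon)
            gene_of.append(gene)
    df = pd.DataFrame(values, index=pd.Index(rows, name="exon_id"),
                      columns=samples)
    return OmicsMatrix(df), pd.Series(gene_of, index=df.index, name="gene_id")


def _survival(cfg: CohortConfig, truth: pd.Series,
              rng: np.random.Generator) -> pd.DataFrame:
    n = len(truth)
    out = pd.DataFrame(index=truth.index)
    baseline_median = {"ttnt": 1095.0, "os": 1800.0, "ttft": 1460.0}
    for endpoint, loghr in cfg.survival_loghr.items():
        lam0 = math.log(2) / baseline_median[endpoint]
        lam = lam0 * np.exp(np.array([loghr[g] for g in truth]))
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(30.0, cfg.censor_horizon_days, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        out[f"{endpoint}_days"] = np.round(time, 1)
        out[f"{endpoint}_event"] = event
    return out


def _lymph_series(cfg: CohortConfig, truth: pd.Series,
                  rng: np.random.Generator) -> pd.DataFrame:
    rate = {"Tris12M": 3e-4, "Tris12U": 4e-4, "M": 1e-4,
            "U": 3e-4, "TP53": 4e-4, "ASB": 9e-4}
    records = []
    for i, (sample, grp) in enumerate(truth.items()):
        # a few samples get too-few time points (exercises exclusion)
        n_points = 3 if i % 10 == 9 else 7
        days = np.arange(n_points) * 90.0
        r = rate[grp] + rng.normal(0, 5e-5)
        c0 = rng.uniform(2e4, 8e4)
        counts = c0 * 10 ** (r * days) * 10 ** rng.normal(0, 0.02, n_points)
        for d, c in zip(days, counts):
            records.append((sample, d, round(float(c), 1)))
    return pd.DataFrame(records, columns=["sample_id", "day", "count"])


_DRUGS = {
    "fludarabine": (0.45, "dna_damage"), "nutlin_3a": (0.55, "dna_damage"),
    "doxorubicin": (0.5, "dna_damage"), "ibrutinib": (0.7, "bcr"),
    "idelalisib": (0.75, "bcr"), "venetoclax": (0.35, "bcl2"),
    "everolimus": (0.8, "mtor"), "selinexor": (0.6, "xpo1"),
    "duvelisib": (0.75, "bcr"), "dasatinib": (0.7, "kinase"),
}


def _drug_plate(cfg: CohortConfig, truth: pd.Series,
                rng: np.random.Generator) -> pd.DataFrame:
    records = []
    for sample, grp in truth.items():
        base_alive = rng.uniform(0.75, 0.92)
        well = 0
        for _ in range(4):  # solvent controls
            n_cells = rng.poisson(400)
            n_alive = rng.binomial(n_cells, base_alive)
            records.append((sample, "DMSO", 0, f"{sample}_W{well:03d}",
                            n_cells, n_alive, 1))
            well += 1
        for drug, (strength, mech) in _DRUGS.items():
            for conc_index in range(3):
                effect = strength * (0.5 + 0.25 * conc_index)
                if mech == "dna_damage" and grp == "TP53":
                    effect *= 0.3  # TP53-driven resistance
                if mech == "bcr" and grp in ("Tris12M", "Tris12U"):
                    effect *= 1.3
                frac = base_alive * max(1.0 - effect, 0.02)
                n_cells = rng.poisson(400)
                n_alive = rng.binomial(n_cells, min(frac, 1.0))
                records.append((sample, drug, conc_index,
                                f"{sample}_W{well:03d}", n_cells, n_alive, 0))
                well += 1
    return pd.DataFrame(records, columns=[
        "sample_id", "drug", "conc_index", "well_id",
        "n_cells", "n_alive", "is_solvent_control"])


def _gene_sets(meta: pd.DataFrame) -> GeneSetCollection:
    blocks = meta.attrs["blocks"]
    sets = {
        "BCR": list(blocks["bcr"]),
        "SPLICEOSOME": list(blocks["spliceosome"]),
        "PROTEASOME": list(blocks["proteasome"]),
        "BCAA": list(blocks["bcaa"]),
        "CHR12": list(blocks["chr12"]),
        "TP53SIG": list(blocks["tp53sig"]),
    }
    for name, members in blocks["coexpr"].items():
        sets[name] = list(members)
    desc = {
        "BCR": "B-cell receptor signaling proteins",
        "SPLICEOSOME": "spliceosome components",
        "PROTEASOME": "proteasome subunits",
        "BCAA": "branched-chain amino-acid degradation enzymes",
        "CHR12": "chromosome 12 features",
        "TP53SIG": "TP53-group protein signature",
    }
    for name in blocks["coexpr"]:
        desc[name] = f"co-expression module {name}"
    return GeneSetCollection(sets, desc)


def simulate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a fully aligned synthetic cohort bundle.

    Identical (config, seed) pairs give bit-identical bundles.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_groups(cfg, rng)
    ann = _assign_lesions(cfg, truth, rng)
    meta = _feature_layout(cfg)
    protein, mrna = _omics_matrices(cfg, meta, ann, truth, rng)
    events = _splice_tables(cfg, truth, rng)
    exon_quant, exon_gene_map = _exon_quant(cfg, truth, rng)
    surv = _survival(cfg, truth, rng)
    lymph = _lymph_series(cfg, truth, rng)
    plate = _drug_plate(cfg, truth, rng)
    annotation = pd.concat([ann, surv], axis=1)
    annotation.insert(0, "cohort", "synthetic")
    annotation["true_group"] = truth
    bundle = CohortBundle(
        annotation=annotation, protein=protein, mrna=mrna, events=events,
        exon_quant=exon_quant, exon_gene_map=exon_gene_map,
        drug_plate=plate, lymph_series=lymph,
        gene_sets=_gene_sets(meta), truth=truth,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# bundle round-trip

_FILES = {
    "annotation": "annotation.tsv",
    "protein": "protein.tsv",
    "protein_meta": "protein_meta.tsv",
    "mrna": "mrna.tsv",
    "mrna_meta": "mrna_meta.tsv",
    "events": "events.tsv",
    "exon_quant": "exon_quant.tsv",
    "exon_gene_map": "exon_gene_map.tsv",
    "drug_plate": "drug_plate.tsv",
    "lymph_series": "lymph_series.tsv",
    "gene_sets": "gene_sets.gmt",
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: CohortBundle, directory) -> dict:
    """Write all bundle components as TSV/GMT plus a checksum manifest."""
    if not str(directory):
        raise ValueError("empty directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.protein, directory / _FILES["protein"],
                 directory / _FILES["protein_meta"])
    write_matrix(bundle.mrna, directory / _FILES["mrna"],
                 directory / _FILES["mrna_meta"])
    bundle.annotation.to_csv(directory / _FILES["annotation"], sep="\t")
    bundle.events.to_csv(directory / _FILES["events"], sep="\t")
    write_matrix(bundle.exon_quant, directory / _FILES["exon_quant"])
    bundle.exon_gene_map.rename("gene_id").to_csv(
        directory / _FILES["exon_gene_map"], sep="\t")
    bundle.drug_plate.to_csv(directory / _FILES["drug_plate"], sep="\t",
                             index=False)
    bundle.lymph_series.to_csv(directory / _FILES["lymph_series"], sep="\t",
                               index=False)
    write_gmt(bundle.gene_sets, directory / _FILES["gene_sets"])
    manifest = {"files": {}}
    for key, fname in _FILES.items():
        manifest["files"][fname] = _checksum(directory / fname)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_bundle(directory) -> CohortBundle:
    """Reconstruct a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {directory}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    for fname in manifest["files"]:
        if not (directory / fname).exists():
            raise FileNotFoundError(f"bundle file missing: {fname}")
    protein = load_matrix(directory / _FILES["protein"],
                          directory / _FILES["protein_meta"])
    mrna = load_matrix(directory / _FILES["mrna"],
                       directory / _FILES["mrna_meta"])
    annotation = pd.read_csv(directory / _FILES["annotation"], sep="\t",
                             index_col=0)
    events = pd.read_csv(directory / _FILES["events"], sep="\t", index_col=0)
    count_cols = [c for c in events.columns
                  if c.startswith(("incl:", "skip:"))]
    counts = events[count_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise SchemaError("non-numeric splice counts")
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise SchemaError(
            f"negative splice count at event {events.index[i]!r}, "
            f"column {count_cols[j]!r}")
    exon_quant = load_matrix(directory / _FILES["exon_quant"])
    exon_gene_map = pd.read_csv(directory / _FILES["exon_gene_map"], sep="\t",
                                index_col=0)["gene_id"]
    drug_plate = pd.read_csv(directory / _FILES["drug_plate"], sep="\t")
    lymph = pd.read_csv(directory / _FILES["lymph_series"], sep="\t")
    gene_sets = load_gmt(directory / _FILES["gene_sets"])
    samples = annotation.index.tolist()
    for name, got in [("protein", protein.sample_ids),
                      ("mrna", mrna.sample_ids)]:
        extra = set(samples) - set(got)
        if extra:
            raise SchemaError(
                f"annotation sample(s) absent from {name} matrix: "
                f"{sorted(extra)[:5]}")
    bundle = CohortBundle(
        annotation=annotation, protein=protein, mrna=mrna, events=events,
        exon_quant=exon_quant, exon_gene_map=exon_gene_map,
        drug_plate=drug_plate, lymph_series=lymph, gene_sets=gene_sets,
        truth=annotation["true_group"],
    )
    bundle.validate()
    return bundle
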