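"""End-to-end replicate and experiment management.

A replicate runs: population simulation -> trait simulation with 20%
mortality -> pedigree-based AI-REML per model -> per-scenario relationship
construction -> EBV prediction -> validation metrics.  Within a replicate
all scenarios and models see identical pedigree, phenotypes and TBVs; only
the genotype mask (and hence K) differs.  Variance components for EBV
prediction always come from the pedigree-based fit, for every scenario and
model (the protocol of the study this package reproduces).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ExperimentConfig
from .popsim import (
    PopulationState,
    breed_generation,
    found_base_population,
    make_marker_map,
    simulate_history,
)
from .trait_model import (
    calibrate_effects,
    compute_tbv,
    sample_qtl_effects,
    simulate_liability,
    threshold_survival,
)
from .relmatrices import (
    RelationshipMatrix,
    adjust_G,
    blend_G,
    build_A,
    build_A_inverse,
    build_G,
    build_H_inverse,
)
from .mme_engine import (
    ModelFit,
    estimate_varcomps_aireml,
    fit_glmm,
    fit_linear,
    make_model_data,
)
from . import evaluation

logger = logging.getLogger("pigsurv")

MODEL_LINKS = {"LM": "identity", "LG": "logit", "PM": "probit"}

__all__ = [
    "ReplicateData",
    "ReplicateBundle",
    "simulate_replicate",
    "prune_pedigree",
    "apply_genotyping_scenario",
    "extend_ebvs",
    "run_replicate",
    "run_experiment",
    "summarize_experiment",
    "relative_gain",
]


@dataclass
class ReplicateData:
    """Simulated population, true breeding values and phenotypes."""

    state: PopulationState
    tbv_a: pd.Series
    tbv_m: pd.Series
    phenotypes: pd.DataFrame
    history_summary: dict


@dataclass
class ReplicateBundle:
    """Everything computed for one replicate."""

    replicate: int
    data: ReplicateData
    metrics: pd.DataFrame
    varcomps: pd.DataFrame
    masks: dict = field(default_factory=dict)


def simulate_replicate(cfg: ExperimentConfig, seed_seq) -> ReplicateData:
    """Simulate one replicate population with trait and survival."""
    arch = cfg.architecture
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(6)]
    rng_map, rng_hist, rng_base, rng_qtl, rng_breed, rng_trait = rngs
    mmap = make_marker_map(cfg.genome, rng_map)
    haps, sexes, hist_summary = simulate_history(mmap, cfg.history, rng_hist)
    state = found_base_population(haps, sexes, mmap, cfg.breeding, rng_base)

    effects = sample_qtl_effects(mmap.qtl_idx.size, arch, rng_qtl)
    base_ids = state.pedigree["id"].to_numpy()
    calibrate_effects(effects, state.dosages(base_ids, mmap.qtl_idx), arch)
    a, m = compute_tbv(state.dosages(base_ids, mmap.qtl_idx), effects)
    tbv_a = pd.Series(a, index=base_ids)
    tbv_m = pd.Series(m, index=base_ids)

    phenos = []
    for g in range(1, cfg.breeding.n_generations + 1):
        new_ids = breed_generation(state, cfg.breeding, rng_breed)
        a, m = compute_tbv(state.dosages(new_ids, mmap.qtl_idx), effects)
        tbv_a = pd.concat([tbv_a, pd.Series(a, index=new_ids)])
        tbv_m = pd.concat([tbv_m, pd.Series(m, index=new_ids)])
        ped_g = state.pedigree[state.pedigree["generation"] == g]
        ph = simulate_liability(ped_g, tbv_a, tbv_m, arch, rng_trait)
        ph["y"] = threshold_survival(
            ph["liability"].to_numpy(), ph["id"].to_numpy(), cfg.breeding.mortality
        )
        rows = state.pedigree["generation"] == g
        state.pedigree.loc[rows, "alive"] = ph["y"].to_numpy()
        phenos.append(ph)
    return ReplicateData(
        state=state,
        tbv_a=tbv_a,
        tbv_m=tbv_m,
        phenotypes=pd.concat(phenos, ignore_index=True),
        history_summary=hist_summary,
    )


def prune_pedigree(pedigree: pd.DataFrame, keep_ids: np.ndarray) -> pd.DataFrame:
    """Restrict the pedigree to ``keep_ids`` and all their ancestors.

    Animals outside this set carry no phenotype or genotype and are not
    parents of anything in it, so dropping them from the equations is exact;
    their EBVs can be back-filled by parent averages (`extend_ebvs`).
    """
    parents = dict(
        zip(pedigree["id"], zip(pedigree["sire"], pedigree["dam"]))
    )
    keep = set(int(i) for i in keep_ids)
    stack = list(keep)
    while stack:
        i = stack.pop()
        for p in parents.get(i, (0, 0)):
            if p != 0 and p not in keep:
                keep.add(p)
                stack.append(p)
    out = pedigree[pedigree["id"].isin(keep)].copy()
    return out.sort_values(["generation", "id"], kind="stable").reset_index(drop=True)


def apply_genotyping_scenario(
    cohort_ids: np.ndarray,
    alive: np.ndarray,
    scenario: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotyped-ID mask for one scenario over the analysis cohort.

    G_all: everyone; G80_ran: a uniform random sample of the same size as
    the alive subset (80% by construction); G_alive: exactly the alive
    animals; G_none: nobody.
    """
    cohort_ids = np.asarray(cohort_ids)
    alive = np.asarray(alive).astype(bool)
    if scenario == "G_all":
        return cohort_ids.copy()
    if scenario == "G_alive":
        return cohort_ids[alive]
    if scenario == "G80_ran":
        n = int(alive.sum())
        return np.sort(rng.choice(cohort_ids, size=n, replace=False))
    if scenario == "G_none":
        return cohort_ids[:0]
    raise ValueError(f"unknown genotyping scenario {scenario!r}")


def extend_ebvs(
    fit_ids: np.ndarray,
    values: pd.Series,
    pedigree: pd.DataFrame,
) -> pd.Series:
    """Extend EBVs from a pruned pedigree to every pedigree ID.

    Animals absent from the fit have no data and no descendants with data,
    so their conditional mean is the parent average (0 for unknown
    parents), applied in generation order.
    """
    out = {}
    have = set(int(i) for i in fit_ids)
    for i, v in values.items():
        out[int(i)] = float(v)
    ped_sorted = pedigree.sort_values(["generation", "id"], kind="stable")
    for i, s, d in zip(ped_sorted["id"], ped_sorted["sire"], ped_sorted["dam"]):
        i = int(i)
        if i in have:
            continue
        vs = out.get(int(s), 0.0)
        vd = out.get(int(d), 0.0)
        out[i] = 0.5 * (vs + vd)
        have.add(i)
    ids = pedigree["id"].to_numpy()
    return pd.Series([out[int(i)] for i in ids], index=ids)


def _fit(model: str, mmd, K_inv, vc, dense_cutoff=6000) -> ModelFit:
    link = MODEL_LINKS[model]
    if link == "identity":
        return fit_linear(mmd, K_inv, vc, dense_cutoff)
    return fit_glmm(mmd, K_inv, vc, link, dense_cutoff=dense_cutoff)


def _scenario_K_inverses(
    cfg: ExperimentConfig,
    rep: ReplicateData,
    A: RelationshipMatrix,
    A_inv: sp.spmatrix,
    masks: dict,
) -> dict:
    K_invs = {}
    for scenario, geno_ids in masks.items():
        if geno_ids.size == 0:
            K_invs[scenario] = A_inv
            continue
        dosages = rep.state.dosages(geno_ids, rep.state.mmap.marker_idx)
        G = build_G(dosages, geno_ids)
        A11 = A.loc(geno_ids)
        Gw = blend_G(adjust_G(G, A11), A11, cfg.omega)
        K_invs[scenario] = build_H_inverse(A_inv, A.ids, Gw, A11)
    return K_invs


def run_replicate(
    cfg: ExperimentConfig, replicate: int, seed_seq
) -> ReplicateBundle:
    """Execute the full protocol for one replicate."""
    ss_sim, ss_mask = seed_seq.spawn(2)
    rep = simulate_replicate(cfg, ss_sim)
    arch = cfg.architecture
    gens = list(cfg.analysis_generations)
    data = rep.phenotypes[rep.phenotypes["generation"].isin(gens)].copy()
    cohort_ids = data["id"].to_numpy()
    alive = data["y"].to_numpy().astype(bool)

    pruned = prune_pedigree(rep.state.pedigree, cohort_ids)
    A = build_A(pruned)
    A_inv = build_A_inverse(pruned, np.diag(A.values) - 1.0)
    mmd_whole = make_model_data(pruned, data)
    ref_mask = data["generation"].to_numpy() != cfg.validation_generation
    mmd_ref = mmd_whole.subset(ref_mask)
    val_ids = data.loc[
        data["generation"] == cfg.validation_generation, "id"
    ].to_numpy()
    tbv_val = pd.DataFrame(
        {"tbv_a": rep.tbv_a.loc[val_ids], "tbv_m": rep.tbv_m.loc[val_ids]},
    )
    tbv_val.index = val_ids

    rng_mask = np.random.default_rng(ss_mask)
    scenarios = list(dict.fromkeys(list(cfg.scenarios) + ["G_all"]))
    masks = {
        s: apply_genotyping_scenario(cohort_ids, alive, s, rng_mask)
        for s in scenarios
    }
    K_invs = _scenario_K_inverses(cfg, rep, A, A_inv, masks)

    # pedigree-based variance components, reused for all scenarios/models
    vc_rows = []
    vcs = {}
    for model in cfg.models:
        link = MODEL_LINKS[model]
        vc = estimate_varcomps_aireml(
            mmd_whole, A.values, link=link, K_inv=A_inv,
            glmm_rounds=cfg.glmm_reml_rounds,
        )
        vcs[model] = vc
        props = vc.proportions()
        vc_rows.append(
            {
                "replicate": replicate, "trait": cfg.trait, "model": model,
                "var_litter": vc.var_litter, "var_direct": vc.var_direct,
                "var_maternal": vc.var_maternal, "cov_am": vc.cov_am,
                "var_residual": vc.var_residual, "converged": vc.converged,
                **props,
            }
        )

    rows = []
    for model in cfg.models:
        whole_fit = _fit(model, mmd_whole, K_invs["G_all"], vcs[model])
        w_a = whole_fit.ebv_a.loc[val_ids].to_numpy()
        w_m = whole_fit.ebv_m.loc[val_ids].to_numpy()
        for scenario in cfg.scenarios:
            ref_fit = _fit(model, mmd_ref, K_invs[scenario], vcs[model])
            r_a = ref_fit.ebv_a.loc[val_ids].to_numpy()
            r_m = ref_fit.ebv_m.loc[val_ids].to_numpy()
            ebv_total = pd.Series(r_a + r_m, index=val_ids)
            sel1 = evaluation.selection_differential(ebv_total, tbv_val, 0.01)
            sel30 = evaluation.selection_differential(ebv_total, tbv_val, 0.30)
            rows.append(
                {
                    "replicate": replicate,
                    "trait": cfg.trait,
                    "scenario": scenario,
                    "model": model,
                    "n_validation": val_ids.size,
                    "n_genotyped": masks[scenario].size,
                    "acc_a": evaluation.accuracy(r_a, tbv_val["tbv_a"]),
                    "acc_m": evaluation.accuracy(r_m, tbv_val["tbv_m"]),
                    "acc_t": evaluation.accuracy(
                        r_a + r_m, tbv_val["tbv_a"] + tbv_val["tbv_m"]
                    ),
                    "slope_a": evaluation.dispersion_regression(w_a, r_a),
                    "slope_m": evaluation.dispersion_regression(w_m, r_m),
                    "slope_t": evaluation.dispersion_regression(
                        w_a + w_m, r_a + r_m
                    ),
                    "top1_a": sel1["a"], "top1_m": sel1["m"],
                    "top1_t": sel1["total"],
                    "top30_a": sel30["a"], "top30_m": sel30["m"],
                    "top30_t": sel30["total"],
                }
            )
    return ReplicateBundle(
        replicate=replicate,
        data=rep,
        metrics=pd.DataFrame(rows),
        varcomps=pd.DataFrame(vc_rows),
        masks=masks,
    )


def reml_selective_genotyping_contrast(
    cfg: ExperimentConfig, seed_seq
) -> dict:
    """Variance estimation under ssGBLUP with alive-only genotypes.

    Fits a reduced linear model (direct genetic + litter effects, no
    maternal term) twice by AI-REML on the same simulated data: once with
    the pedigree matrix A and once with the single-step H built from the
    G_alive genotype mask.  Selective genotyping of survivors makes the
    ssGBLUP fit inflate the additive variance and push the residual towards
    zero; the pedigree fit does not.  Returns both estimates plus the
    observed-scale truth implied by the liability-scale architecture.
    """
    ss_sim, ss_mask = seed_seq.spawn(2)
    rep = simulate_replicate(cfg, ss_sim)
    gens = list(cfg.analysis_generations)
    data = rep.phenotypes[rep.phenotypes["generation"].isin(gens)].copy()
    cohort_ids = data["id"].to_numpy()
    alive = data["y"].to_numpy().astype(bool)
    pruned = prune_pedigree(rep.state.pedigree, cohort_ids)
    A = build_A(pruned)
    mmd = make_model_data(pruned, data)
    rng_mask = np.random.default_rng(ss_mask)
    geno_ids = apply_genotyping_scenario(cohort_ids, alive, "G_alive", rng_mask)
    dosages = rep.state.dosages(geno_ids, rep.state.mmap.marker_idx)
    G = build_G(dosages, geno_ids)
    A11 = A.loc(geno_ids)
    Gw = blend_G(adjust_G(G, A11), A11, cfg.omega)
    from .relmatrices import build_H

    H = build_H(A, Gw)
    est_A = estimate_varcomps_aireml(mmd, A.values, include_maternal=False)
    est_H = estimate_varcomps_aireml(mmd, H.values, include_maternal=False)
    arch = cfg.architecture
    p = 1.0 - cfg.breeding.mortality
    from .mme_engine import liability_to_observed_h2

    va_obs_truth = liability_to_observed_h2(arch.h2_direct, p) * p * (1.0 - p)
    return {
        "pedigree": est_A,
        "ssgblup_alive": est_H,
        "va_observed_truth": va_obs_truth,
    }


def run_experiment(
    cfg: ExperimentConfig, keep_data: bool = False, log_path=None
):
    """Run all replicates; failures abort the replicate, not the experiment.

    Returns ``(metrics, varcomps, bundles)`` where the first two are tidy
    DataFrames over replicates and ``bundles`` holds per-replicate detail
    (empty unless ``keep_data``).  With ``log_path`` a JSON-lines log is
    written: one record per replicate with its spawn key (so any cell can
    be re-derived in isolation), wall time and status.
    """
    import json
    import time

    master = np.random.SeedSequence(cfg.seed)
    seeds = master.spawn(cfg.n_replicates)
    metrics, varcomps, bundles, log = [], [], [], []
    for r, ss in enumerate(seeds):
        t0 = time.time()
        rec = {
            "replicate": r,
            "master_seed": cfg.seed,
            "spawn_key": list(ss.spawn_key),
            "trait": cfg.trait,
        }
        try:
            bundle = run_replicate(cfg, r, ss)
        except Exception as exc:  # noqa: BLE001 - log the failure, continue
            logger.exception("replicate %d failed; continuing", r)
            rec.update(status="failed", error=repr(exc))
            log.append(rec)
            continue
        rec.update(status="ok", seconds=round(time.time() - t0, 2))
        log.append(rec)
        metrics.append(bundle.metrics)
        varcomps.append(bundle.varcomps)
        if keep_data:
            bundles.append(bundle)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    if not metrics:
        raise RuntimeError("all replicates failed")
    return (
        pd.concat(metrics, ignore_index=True),
        pd.concat(varcomps, ignore_index=True),
        bundles,
    )


def relative_gain(acc_genomic: float, acc_pedigree: float) -> float:
    """Percent accuracy gain of a genomic scenario over the pedigree model."""
    return 100.0 * (acc_genomic - acc_pedigree) / acc_pedigree


def summarize_experiment(metrics: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Study-style summary tables with paired-t significance letters.

    Returns a dict of DataFrames: one per metric family (accuracy,
    dispersion slope, top-1% and top-30% selection differentials) with
    scenario means per model, plus a relative-gain table
    (G_* vs G_none, total-EBV accuracy).  With a single replicate the
    letters are suppressed (a warning is logged).
    """
    single = metrics["replicate"].nunique() < 2
    if single:
        logger.warning("single replicate: significance letters suppressed")
    tables = {}
    metric_cols = {
        "accuracy": ["acc_a", "acc_m", "acc_t"],
        "dispersion": ["slope_a", "slope_m", "slope_t"],
        "top1": ["top1_a", "top1_m", "top1_t"],
        "top30": ["top30_a", "top30_m", "top30_t"],
    }
    for fam, cols in metric_cols.items():
        recs = []
        for (trait, model), sub in metrics.groupby(["trait", "model"]):
            piv = {
                col: {
                    scen: g.sort_values("replicate")[col].to_numpy()
                    for scen, g in sub.groupby("scenario")
                }
                for col in cols
            }
            letters = {
                col: (
                    {s: "" for s in piv[col]}
                    if single
                    else evaluation.significance_letters(piv[col], alpha)
                )
                for col in cols
            }
            for scen in piv[cols[0]]:
                rec = {"trait": trait, "model": model, "scenario": scen}
                for col in cols:
                    rec[col] = float(np.mean(piv[col][scen]))
                    rec[col + "_se"] = float(
                        np.std(piv[col][scen], ddof=1) / np.sqrt(len(piv[col][scen]))
                    ) if not single else float("nan")
                    rec[col + "_letter"] = letters[col][scen]
                recs.append(rec)
        tables[fam] = pd.DataFrame(recs)
    # relative gains on total-EBV accuracy
    acc = tables["accuracy"]
    gains = []
    for (trait, model), sub in acc.groupby(["trait", "model"]):
        base = sub.loc[sub["scenario"] == "G_none", "acc_t"]
        if base.empty:
            continue
        for _, row in sub.iterrows():
            if row["scenario"] == "G_none":
                continue
            gains.append(
                {
                    "trait": trait, "model": model, "scenario": row["scenario"],
                    "gain_pct": relative_gain(row["acc_t"], float(base.iloc[0])),
                }
            )
    tables["relative_gain"] = pd.DataFrame(gains)
    return tables
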