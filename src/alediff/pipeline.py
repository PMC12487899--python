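"""End-to-end orchestration: records -> survival fits -> delta_e -> BPGLS.

`run_survival` applies the inclusion filters, fits the Siler model per
species and sex at a shared age at first reproduction, applies the
convergence and survivorship gates, and assembles the per-species
delta_e posterior table.  `run_comparative` fits the requested
hypothesis designs by weighted BPGLS on a phylogeny and ranks them by
DIC, and `group_means` aggregates delta_e by class or order with
inverse-SD weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import build_design
from .diff_metrics import summarize_delta, weighted_group_mean
from .phylo import PGLSConfig, fit_bpgls
from .survival_fit import (
    MCMCConfig,
    filter_records,
    fit_siler,
    survivorship_check,
)

__all__ = ["run_survival", "run_comparative", "group_means"]

DELTA_COLUMNS = [
    "species",
    "mean",
    "sd",
    "ci_low",
    "ci_high",
    "zero_overlap",
    "evidence",
]


def run_survival(
    records: pd.DataFrame,
    alphas: dict,
    mcmc: MCMCConfig = None,
    *,
    window=None,
    min_per_sex: int = 35,
    survivorship_threshold: float = 0.1,
    keep_chains: bool = False,
) -> tuple:
    """Filter, fit and gate every species; return the delta_e table.

    Parameters
    ----------
    records : DataFrame
        Individual records (species, sex, entry_age, end_age, event).
    alphas : dict
        Age at first reproduction per species (the maximum of the two
        sexes' values, applied to both sexes).
    mcmc : MCMCConfig
        Sampler settings; chain seeds are derived per species-sex so
        reruns are reproducible.

    Returns
    -------
    (delta_table, gate_report[, chains]) where ``gate_report`` lists each
    excluded species with the failed gate.
    """
    if mcmc is None:
        mcmc = MCMCConfig()
    filtered, filter_report = filter_records(
        records, window=window, min_per_sex=min_per_sex
    )
    gates = {"filters": filter_report, "species": {}}
    rows = []
    chains_out = {}
    for i_sp, (species, sub) in enumerate(sorted(filtered.groupby("species"))):
        if species not in alphas:
            gates["species"][species] = "no age at first reproduction"
            continue
        alpha = float(alphas[species])
        fits = {}
        failed = None
        for i_sex, sex in enumerate(("female", "male")):
            sex_records = sub[sub["sex"] == sex]
            if sex_records.empty:
                failed = f"no {sex} records"
                break
            if not survivorship_check(sex_records, alpha, survivorship_threshold):
                failed = f"{sex} survivorship above {survivorship_threshold}"
                break
            cfg = MCMCConfig(
                n_chains=mcmc.n_chains,
                n_iter=mcmc.n_iter,
                burn_in=mcmc.burn_in,
                thinning=mcmc.thinning,
                seed=int((mcmc.seed * 1_000 + i_sp * 2 + i_sex) % 2**31),
                proposal_scales=mcmc.proposal_scales,
                adapt_interval=mcmc.adapt_interval,
                target_acceptance=mcmc.target_acceptance,
            )
            fit = fit_siler(sex_records, alpha, cfg)
            if not fit.converged:
                failed = f"{sex} fit not converged (max R-hat {max(fit.rhat.values()):.3f})"
                break
            fits[sex] = fit
        if failed is not None:
            gates["species"][species] = failed
            continue
        n_pair = min(fits["female"].flat_ale.size, fits["male"].flat_ale.size)
        summary = summarize_delta(
            species, fits["female"].flat_ale[:n_pair], fits["male"].flat_ale[:n_pair]
        )
        rows.append(summary.as_row())
        if keep_chains:
            chains_out[species] = fits
    delta = pd.DataFrame(rows, columns=DELTA_COLUMNS)
    if keep_chains:
        return delta, gates, chains_out
    return delta, gates


def run_comparative(
    delta_table: pd.DataFrame,
    covariates: pd.DataFrame,
    tree,
    hypotheses=("precopulatory", "postcopulatory", "cost"),
    interactions: str = "class-intercept",
    config: PGLSConfig = None,
    *,
    min_overlap: int = 10,
) -> tuple:
    """Weighted BPGLS of delta_e on each hypothesis design plus DIC ranking.

    ``delta_table`` needs species/mean/sd columns; species are matched to
    covariate rows and tree tips, and an error is raised if fewer than
    ``min_overlap`` species survive the join.
    """
    if config is None:
        config = PGLSConfig()
    merged = delta_table.merge(covariates, on="species", how="inner")
    results = {}
    ranking_rows = []
    for hyp in hypotheses:
        design, mask, report = build_design(merged, hyp, interactions)
        rows = merged.loc[mask.values if hasattr(mask, "values") else mask]
        if len(design) < min_overlap:
            raise ValueError(
                f"only {len(design)} species available for {hyp!r}; "
                f"need at least {min_overlap}"
            )
        res = fit_bpgls(
            rows["mean"].to_numpy(),
            design.to_numpy(),
            tree,
            rows["sd"].to_numpy(),
            config,
            taxa=list(design.index),
            predictor_names=list(design.columns),
        )
        results[hyp] = res
        ranking_rows.append(
            {"hypothesis": hyp, "DIC": res.dic, "pD": res.pd_eff, "n": len(design)}
        )
    ranking = (
        pd.DataFrame(ranking_rows).sort_values("DIC").reset_index(drop=True)
    )
    return results, ranking


def group_means(delta_table: pd.DataFrame, by: str = "class") -> pd.DataFrame:
    """Inverse-SD-weighted delta_e means per group (class or order)."""
    if by not in delta_table:
        raise KeyError(f"delta table has no {by!r} column")
    rows = []
    for label, sub in delta_table.groupby(by):
        g = weighted_group_mean(sub["mean"], sub["sd"], group=str(label))
        rows.append(
            {
                by: g.group,
                "weighted_mean": g.mean,
                "weighted_se": g.se,
                "ci_low": g.ci_low,
                "ci_high": g.ci_high,
                "n_species": g.n_species,
            }
        )
    return pd.DataFrame(rows)
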