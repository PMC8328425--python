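"""End-to-end runs: survey summary, model ladders, multivariate fits.

Bees and wasps are always separate analysis streams. Reports mirror the
usual layout of trap-nest studies: a per-taxon summary of offspring
production and mortality (one column per taxon), a univariate table with
the four AICc values per predictor/response pair, and a multivariate table
with one row per response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, Taxon
from .models import ModelFit, Variant, fit_multivariate, fit_univariate_ladder, significance_stars
from .resampling import (
    DiversitySummary,
    ResamplingConfig,
    eligible_sites,
    summaries_to_frame,
    summarize_all,
)
from .traits import nest_traits

__all__ = ["run_summary", "run_models", "ENV_PREDICTORS", "RESPONSES", "DIVERSITY_PREDICTORS"]

ENV_PREDICTORS = ("edge_density", "impervious", "open_green")
DIVERSITY_PREDICTORS = ("top", "ted", "fdis")
RESPONSES = (
    "mean_prop_non_emerged",
    "mean_prop_parasite_free",
    "mean_total_cells",
    "top",
    "ted",
    "fdis",
    "offspring_production",
)


def run_summary(data: Dataset, config: ResamplingConfig | None = None) -> pd.DataFrame:
    """Survey summary per taxon, restricted to eligible sites.

    Rows: nests evaluated, nests per site, brood cells per nest, % of
    cells parasite-free and non-emerged (per-nest proportions averaged,
    as percentages), emerged cells per nest, and the three most frequent
    species with their nest shares.
    """
    config = config or ResamplingConfig()
    columns: dict[str, dict[str, object]] = {}
    for taxon in (Taxon.BEE, Taxon.WASP):
        sites = eligible_sites(data, taxon, config)
        nests = [n for n in data.nests if n.taxon == taxon and n.site_id in set(sites)]
        if not nests:
            continue
        traits = [nest_traits(n) for n in nests]
        per_site = pd.Series([n.site_id for n in nests]).value_counts()
        totals = np.array([t.total_cells for t in traits])
        pf = np.array([t.prop_parasite_free for t in traits]) * 100
        ne = np.array([t.prop_non_emerged for t in traits]) * 100
        em = np.array([t.emerged_cells for t in traits])
        species = pd.Series([n.species for n in nests]).value_counts(normalize=True)
        top3 = "; ".join(f"{name} ({share * 100:.1f}%)" for name, share in species.head(3).items())
        columns[taxon.value] = {
            "n_sites": len(sites),
            "total_nests_evaluated": len(nests),
            "nests_per_site_mean": per_site.mean(),
            "nests_per_site_min": int(per_site.min()),
            "nests_per_site_max": int(per_site.max()),
            "brood_cells_per_nest_mean": totals.mean(),
            "brood_cells_per_nest_min": int(totals.min()),
            "brood_cells_per_nest_max": int(totals.max()),
            "pct_parasite_free_mean": pf.mean(),
            "pct_parasitized_mean": 100.0 - pf.mean(),
            "pct_non_emerged_mean": ne.mean(),
            "emerged_per_nest_mean": em.mean(),
            "emerged_per_nest_min": int(em.min()),
            "emerged_per_nest_max": int(em.max()),
            "top_species": top3,
        }
    if not columns:
        raise ValueError("no taxon has any nest at an eligible site")
    return pd.DataFrame(columns)


@dataclass(frozen=True)
class ModelReport:
    """Univariate ladder table, multivariate table, and the raw fits."""

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    fits: dict[tuple[str, str, str], ModelFit]  # (taxon, response, predictor-set)


def _ladder_row(
    taxon: str, predictor: str, response: str, fits: list[ModelFit], winner: ModelFit
) -> dict[str, object]:
    by_variant = {f.spec.variant: f for f in fits}
    row: dict[str, object] = {"taxon": taxon, "predictor": predictor, "response": response}
    for variant in Variant:
        f = by_variant.get(variant)
        row[f"aicc_{variant.value}"] = f.aicc if f else np.nan
    row["best_variant"] = (
        winner.spec.variant.value if isinstance(winner.spec.variant, Variant) else None
    )
    row["r2"] = winner.r2
    row["p_value"] = winner.p_overall
    row["stars"] = significance_stars(winner.p_overall)
    return row


def run_models(
    data: Dataset,
    config: ResamplingConfig | None = None,
    summaries: list[DiversitySummary] | None = None,
    min_sites: int = 10,
) -> ModelReport:
    """Fit every univariate ladder and the term-plan multivariate models.

    Per taxon: three environmental predictors crossed with seven
    responses, plus the three diversity indices as predictors of offspring
    production; then one multivariate model per response (environment
    block) and one for offspring production (diversity block).
    """
    config = config or ResamplingConfig()
    if summaries is None:
        summaries = summarize_all(data, config)
    div = summaries_to_frame(summaries)
    sites = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "ugs_type": s.ugs_type.value,
                "open_green": s.open_green,
                "impervious": s.impervious,
                "edge_density": s.edge_density,
            }
            for s in data.sites
        ]
    )
    table = div.merge(sites, on="site_id", how="left")
    uni_rows: list[dict[str, object]] = []
    multi_rows: list[dict[str, object]] = []
    fits: dict[tuple[str, str, str], ModelFit] = {}
    for taxon in ("bee", "wasp"):
        sub = table[table["taxon"] == taxon].reset_index(drop=True)
        if len(sub) == 0:
            continue
        if len(sub) < min_sites:
            raise ValueError(
                f"{taxon}: only {len(sub)} eligible sites; at least {min_sites} required"
            )
        ugs = sub["ugs_type"]
        # environment block: ladders, then one multivariate model per response
        for response in RESPONSES:
            term_plan: dict[str, Variant] = {}
            for predictor in ENV_PREDICTORS:
                ladder, winner = fit_univariate_ladder(
                    sub[predictor], sub[response], ugs, name=predictor, response=response
                )
                uni_rows.append(_ladder_row(taxon, predictor, response, ladder, winner))
                fits[(taxon, response, predictor)] = winner
                term_plan[predictor] = winner.spec.variant
            mfit = fit_multivariate(sub, sub[response], term_plan, ugs, response=response)
            fits[(taxon, response, "environment")] = mfit
            multi_rows.append(
                {
                    "taxon": taxon,
                    "predictors": "environmental_gradients",
                    "response": response,
                    "r2": mfit.r2,
                    "p_value": mfit.p_overall,
                    "stars": significance_stars(mfit.p_overall),
                }
            )
        # diversity block: indices as predictors of offspring production
        term_plan = {}
        for predictor in DIVERSITY_PREDICTORS:
            ladder, winner = fit_univariate_ladder(
                sub[predictor],
                sub["offspring_production"],
                ugs,
                name=predictor,
                response="offspring_production",
            )
            uni_rows.append(
                _ladder_row(taxon, predictor, "offspring_production", ladder, winner)
            )
            fits[(taxon, "offspring_production", predictor)] = winner
            term_plan[predictor] = winner.spec.variant
        mfit = fit_multivariate(
            sub, sub["offspring_production"], term_plan, ugs, response="offspring_production"
        )
        fits[(taxon, "offspring_production", "diversity")] = mfit
        multi_rows.append(
            {
                "taxon": taxon,
                "predictors": "trait_diversity_indices",
                "response": "offspring_production",
                "r2": mfit.r2,
                "p_value": mfit.p_overall,
                "stars": significance_stars(mfit.p_overall),
            }
        )
    return ModelReport(
        univariate=pd.DataFrame(uni_rows),
        multivariate=pd.DataFrame(multi_rows),
        fits=fits,
    )
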