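"""Site-level bootstrap of trait diversity and mean reproductive traits.

Trap-nest sites differ in how many tubes were occupied, and every diversity
index here is sensitive to sample size. The analysis therefore standardises
effort: only sites with at least ``min_tubes`` occupied tubes (per taxon)
enter, and each statistic is computed on repeated random subsamples of
``draw_size`` distinct tubes, then averaged over replicates. Defaults are
min_tubes=8, draw_size=7, reps=999.

Draws are without replacement, so a draw can never contain duplicate
points (with replacement, coincident points would collapse TOP and TED
degenerately). Each site x taxon gets its own random substream derived
from the master seed, so results do not depend on processing order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import ReferenceEvenDistribution, fdis, make_reference, ted, top
from .io import Dataset, NestRecord, Taxon
from .traits import TraitMatrix, TraitVector, nest_traits, z_transform

__all__ = [
    "ResamplingConfig",
    "DiversitySummary",
    "eligible_sites",
    "bootstrap_site",
    "summarize_all",
    "summaries_to_frame",
]

_STAT_NAMES = (
    "top",
    "ted",
    "fdis",
    "mean_total_cells",
    "mean_prop_parasite_free",
    "mean_prop_non_emerged",
    "offspring_production",
)


@dataclass(frozen=True)
class ResamplingConfig:
    min_tubes: int = 8
    draw_size: int = 7
    reps: int = 999
    seed: int = 0
    #: "bootstrap" averages mean traits over draws like the indices;
    #: "all_tubes" computes them once on every tube at the site.
    mean_traits: str = "bootstrap"
    #: scope of the z-transform: "taxon" (default) or "pooled"
    z_scope: str = "taxon"

    def __post_init__(self):
        if not self.draw_size < self.min_tubes:
            raise ValueError("draw_size must be smaller than min_tubes")
        if self.draw_size <= 3:
            raise ValueError("draw_size must exceed the trait dimension (3)")
        if self.mean_traits not in ("bootstrap", "all_tubes"):
            raise ValueError("mean_traits must be 'bootstrap' or 'all_tubes'")
        if self.z_scope not in ("taxon", "pooled"):
            raise ValueError("z_scope must be 'taxon' or 'pooled'")


@dataclass(frozen=True)
class DiversitySummary:
    """Bootstrap-averaged statistics for one site x taxon."""

    site_id: str
    taxon: str
    n_tubes: int
    top: float
    ted: float
    fdis: float
    mean_total_cells: float
    mean_prop_parasite_free: float
    mean_prop_non_emerged: float
    offspring_production: float


def _site_seed(master_seed: int, site_id: str, taxon: Taxon) -> np.random.Generator:
    """Independent, order-insensitive substream for one site x taxon."""
    key = zlib.crc32(f"{site_id}|{taxon.value}".encode())
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def eligible_sites(data: Dataset, taxon: Taxon, config: ResamplingConfig) -> list[str]:
    """Site ids with at least min_tubes occupied tubes of the given taxon.

    Order follows the site table, so the result is deterministic.
    """
    counts: dict[str, int] = {}
    for n in data.nests:
        if n.taxon == taxon:
            counts[n.site_id] = counts.get(n.site_id, 0) + 1
    return [s.site_id for s in data.sites if counts.get(s.site_id, 0) >= config.min_tubes]


def _bootstrap_draws(
    z_rows: np.ndarray,
    traits: list[TraitVector],
    config: ResamplingConfig,
    rng: np.random.Generator,
    reference: ReferenceEvenDistribution,
) -> pd.DataFrame:
    """Per-draw statistics; one row per bootstrap replicate.

    A draw whose points are affinely degenerate contributes TOP = 0; a draw
    whose points all coincide has no defined TED and contributes NaN there
    (averaged out later). Neither case triggers a redraw, which would bias
    the averages.
    """
    n = len(traits)
    raw = np.array(
        [[t.total_cells, t.prop_parasite_free, t.prop_non_emerged, t.emerged_cells] for t in traits]
    )
    rows = np.empty((config.reps, len(_STAT_NAMES)))
    for r in range(config.reps):
        idx = rng.choice(n, size=config.draw_size, replace=False)
        pts = z_rows[idx]
        try:
            ted_val = ted(pts, reference)
        except ValueError:
            ted_val = np.nan
        sub = raw[idx]
        rows[r] = (
            top(pts),
            ted_val,
            fdis(pts),
            sub[:, 0].mean(),
            sub[:, 1].mean(),
            sub[:, 2].mean(),
            sub[:, 3].mean(),
        )
    return pd.DataFrame(rows, columns=_STAT_NAMES)


def bootstrap_site(
    nests: list[NestRecord],
    z_rows: np.ndarray,
    config: ResamplingConfig,
    rng: np.random.Generator | None = None,
    reference: ReferenceEvenDistribution | None = None,
) -> DiversitySummary:
    """Bootstrap one site's nests (all of one taxon).

    ``z_rows`` are the z-scored trait 3-vectors of exactly these nests, in
    the same order, scaled over the full-dataset scope (not per site).
    """
    if len(nests) < config.min_tubes:
        raise ValueError(
            f"site has {len(nests)} tubes; bootstrap requires at least {config.min_tubes}"
        )
    if z_rows.shape[0] != len(nests):
        raise ValueError("z_rows must align with nests")
    taxon = nests[0].taxon
    site_id = nests[0].site_id
    if rng is None:
        rng = _site_seed(config.seed, site_id, taxon)
    if reference is None:
        reference = make_reference(config.draw_size, z_rows.shape[1], seed=config.seed)
    traits = [nest_traits(n) for n in nests]
    draws = _bootstrap_draws(z_rows, traits, config, rng, reference)
    means = draws.mean(axis=0, skipna=True)
    if config.mean_traits == "all_tubes":
        raw = np.array(
            [[t.total_cells, t.prop_parasite_free, t.prop_non_emerged, t.emerged_cells] for t in traits]
        )
        means["mean_total_cells"] = raw[:, 0].mean()
        means["mean_prop_parasite_free"] = raw[:, 1].mean()
        means["mean_prop_non_emerged"] = raw[:, 2].mean()
        means["offspring_production"] = raw[:, 3].mean()
    return DiversitySummary(
        site_id=site_id,
        taxon=taxon.value,
        n_tubes=len(nests),
        **{k: float(means[k]) for k in _STAT_NAMES},
    )


def summarize_all(
    data: Dataset,
    config: ResamplingConfig,
    taxa: tuple[Taxon, ...] = (Taxon.BEE, Taxon.WASP),
) -> list[DiversitySummary]:
    """Bootstrap every eligible site x taxon.

    The z-transform is computed once over every analysed nest — all tubes
    at eligible sites, per taxon by default — before any subsampling, so
    replicates from different sites live on a common scale and ineligible
    sites cannot perturb it. Nests are processed in nest_id order, making
    the output invariant to input row order.
    """
    out: list[DiversitySummary] = []
    reference = make_reference(config.draw_size, 3, seed=config.seed)
    eligible: dict[Taxon, list[str]] = {t: eligible_sites(data, t, config) for t in taxa}
    analysed = {
        t: sorted(
            (n for n in data.nests if n.taxon == t and n.site_id in set(eligible[t])),
            key=lambda n: n.nest_id,
        )
        for t in taxa
    }
    pooled_matrix: TraitMatrix | None = None
    if config.z_scope == "pooled":
        pooled_nests = [n for t in taxa for n in analysed[t]]
        pooled_matrix = z_transform([nest_traits(n) for n in pooled_nests], scope="pooled")
        pooled_row = {id(n): i for i, n in enumerate(pooled_nests)}
    for taxon in taxa:
        taxon_nests = analysed[taxon]
        if not taxon_nests:
            continue
        if config.z_scope == "pooled":
            z_all = pooled_matrix.values[[pooled_row[id(n)] for n in taxon_nests]]
        else:
            z_all = z_transform([nest_traits(n) for n in taxon_nests], scope=taxon).values
        row_of = {id(n): i for i, n in enumerate(taxon_nests)}
        for site_id in eligible[taxon]:
            site_nests = [n for n in taxon_nests if n.site_id == site_id]
            idx = [row_of[id(n)] for n in site_nests]
            rng = _site_seed(config.seed, site_id, taxon)
            out.append(
                bootstrap_site(site_nests, z_all[idx], config, rng=rng, reference=reference)
            )
    return out


def summaries_to_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "taxon": s.taxon,
                "n_tubes": s.n_tubes,
                **{k: getattr(s, k) for k in _STAT_NAMES},
            }
            for s in summaries
        ]
    )


def config_metadata(config: ResamplingConfig) -> dict[str, object]:
    """Config echo written as '#' header lines of the summary CSV."""
    return {
        "min_tubes": config.min_tubes,
        "draw_size": config.draw_size,
        "reps": config.reps,
        "seed": config.seed,
        "mean_traits": config.mean_traits,
        "z_scope": config.z_scope,
        "sampling": "without_replacement",
        "top_measure": "d_dimensional_hull_volume",
    }
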