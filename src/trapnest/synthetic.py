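"""Synthetic trap-nest datasets with the statistical structure the
analysis assumes.

The generator emulates a three-season trap-nest survey across four urban
green space (UGS) types:

* per-site environment: a Dirichlet split of the buffer into open green /
  impervious / other cover (UGS-conditional, e.g. green roofs draw high
  impervious and parks high open green) plus a gamma edge density;
* per-site occupancy: a negative-binomial number of occupied tubes per
  taxon (mean ~20, range reaching ~8-64, so the eligibility filter is
  exercised);
* per-tube brood size: a zero-truncated negative binomial whose truncated
  mean equals ``mu_total``, optionally linked to the environment on the
  log scale (linear, quadratic-impervious, and UGS-interaction terms);
* per-cell fates: one trinomial draw per brood cell (emerged / parasitized
  / non-emerged), with optional logit-scale environment links, so the
  count invariants hold exactly by construction.

Default taxon parameters echo the observed study-wide summary values
(bees: mean 6.68 cells per nest, 6.8% of cells parasitized, 25.7%
non-emerged; wasps: 4.16 / 9.8% / 30.7%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import nbinom

from .io import Dataset, NestRecord, SiteRecord, Taxon, UGSType
from .landscape import COVER_CLASSES, CoverGrid

__all__ = [
    "EnvLinks",
    "TaxonParams",
    "GeneratorConfig",
    "generate_sites",
    "generate_nests",
    "generate_dataset",
    "generate_raster",
]

# species pools (label, relative share) loosely shaped on the study's
# community tables; labels only, never used by the statistics
_BEE_SPECIES = (
    ("Osmia caerulescens", 0.23),
    ("Osmia pumila", 0.22),
    ("Megachile rotundata", 0.16),
    ("Megachile campanulae", 0.12),
    ("Heriades carinata", 0.08),
    ("Megachile centuncularis", 0.10),
    ("Hylaeus modestus", 0.05),
    ("Osmia lignaria", 0.04),
)
_WASP_SPECIES = (
    ("Trypoxylon frigidum", 0.26),
    ("Trypoxylon collinum", 0.20),
    ("Psenulus pallipes", 0.08),
    ("Isodontia mexicana", 0.13),
    ("Symmorphus canadensis", 0.09),
    ("Trypoxylon lactitarse", 0.08),
    ("Ancistrocerus antilope", 0.08),
    ("Euodynerus foraminatus", 0.08),
)

#: Dirichlet concentration for (open_green, impervious, other) per UGS type.
_ENV_ALPHAS = {
    UGSType.PARK: (6.0, 2.0, 2.0),
    UGSType.HOME_GARDEN: (4.0, 4.0, 2.0),
    UGSType.COMMUNITY_GARDEN: (4.5, 3.5, 2.0),
    UGSType.GREEN_ROOF: (1.5, 7.0, 1.5),
}
#: Gamma mean edge density (m/m2) per UGS type; home gardens most fine-grained.
_EDGE_MEANS = {
    UGSType.PARK: 0.030,
    UGSType.HOME_GARDEN: 0.060,
    UGSType.COMMUNITY_GARDEN: 0.050,
    UGSType.GREEN_ROOF: 0.040,
}
_EDGE_SHAPE = 6.0


@dataclass(frozen=True)
class EnvLinks:
    """Environment effects on brood size (log link) and fates (logit link).

    All coefficients apply to the raw gradient values; zero means no link
    (the null generator). ``delta_ugs`` adds a UGS-specific impervious
    slope on brood size, creating a true interaction.
    """

    beta_green: float = 0.0
    beta_imperv: float = 0.0
    beta_edge: float = 0.0
    gamma_imperv: float = 0.0  # coefficient on (impervious - 0.5)^2
    delta_ugs: dict[str, float] = field(default_factory=dict)
    par_beta_imperv: float = 0.0
    fail_beta_imperv: float = 0.0


@dataclass(frozen=True)
class TaxonParams:
    """Brood-size and fate parameters for one taxon."""

    mu_total: float
    p_par: float
    p_fail: float
    dispersion: float = 2.0  # negative-binomial shape r (smaller = heavier tail)
    links: EnvLinks = field(default_factory=EnvLinks)

    def __post_init__(self):
        if not (0 < self.p_par < 1 and 0 < self.p_fail < 1):
            raise ValueError("fate probabilities must lie in (0, 1)")
        if self.p_par + self.p_fail >= 1:
            raise ValueError("p_par + p_fail must be < 1")
        if self.mu_total < 1:
            raise ValueError("mu_total must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic survey."""

    n_sites: dict[str, int] = field(
        default_factory=lambda: {
            UGSType.COMMUNITY_GARDEN.value: 15,
            UGSType.HOME_GARDEN.value: 70,
            UGSType.PARK.value: 48,
            UGSType.GREEN_ROOF.value: 20,
        }
    )
    tubes_mean: float = 20.0
    tubes_dispersion: float = 6.0
    tubes_max: int = 64
    bee: TaxonParams = field(
        default_factory=lambda: TaxonParams(mu_total=6.68, p_par=0.068, p_fail=0.257)
    )
    wasp: TaxonParams = field(
        default_factory=lambda: TaxonParams(mu_total=4.16, p_par=0.098, p_fail=0.307)
    )
    #: couples trait spacing to offspring production (see generate_nests)
    evenness_coupling: bool = False
    seed: int = 0

    def params_for(self, taxon: Taxon) -> TaxonParams:
        return self.bee if taxon == Taxon.BEE else self.wasp


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    key = sum(ord(c) << (8 * i % 32) for i, c in enumerate(stage)) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def generate_sites(config: GeneratorConfig) -> list[SiteRecord]:
    """Draw UGS-conditional site environments, reproducible by seed."""
    rng = _stage_rng(config.seed, "sites")
    records: list[SiteRecord] = []
    idx = 1
    for ugs_value, count in config.n_sites.items():
        ugs = UGSType(ugs_value)
        alphas = _ENV_ALPHAS[ugs]
        for _ in range(count):
            og, imp, _other = rng.dirichlet(alphas)
            edge = rng.gamma(_EDGE_SHAPE, _EDGE_MEANS[ugs] / _EDGE_SHAPE)
            records.append(
                SiteRecord(
                    site_id=f"S{idx:03d}",
                    ugs_type=ugs,
                    open_green=float(og),
                    impervious=float(imp),
                    edge_density=float(edge),
                )
            )
            idx += 1
    return records


def _truncated_nbinom_params(mu_trunc: float, r: float) -> float:
    """Untruncated NB mean whose zero-truncated mean equals mu_trunc."""

    def gap(m):
        p = r / (r + m)
        p0 = nbinom.pmf(0, r, p)
        return m / (1 - p0) - mu_trunc

    # the truncated mean always exceeds the untruncated one
    return brentq(gap, 1e-9, mu_trunc, xtol=1e-12)


def _sample_ztnb(mu_trunc: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated negative-binomial draws by inverse CDF."""
    out = np.empty(mu_trunc.shape, dtype=int)
    for mu in np.unique(mu_trunc):
        sel = mu_trunc == mu
        m = _truncated_nbinom_params(float(mu), r)
        p = r / (r + m)
        p0 = nbinom.pmf(0, r, p)
        u = rng.uniform(p0, 1.0, size=int(sel.sum()))
        out[sel] = nbinom.ppf(u, r, p).astype(int)
    return out


def _linked_mu(site: SiteRecord, params: TaxonParams) -> float:
    ln = params.links
    log_mu = (
        np.log(params.mu_total)
        + ln.beta_green * site.open_green
        + ln.beta_imperv * site.impervious
        + ln.gamma_imperv * (site.impervious - 0.5) ** 2
        + ln.beta_edge * site.edge_density
        + ln.delta_ugs.get(site.ugs_type.value, 0.0) * site.impervious
    )
    return float(np.clip(np.exp(log_mu), 1.0, 40.0))


def _logit(p: float) -> float:
    return np.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _linked_fates(site: SiteRecord, params: TaxonParams) -> tuple[float, float]:
    ln = params.links
    p_par = _expit(_logit(params.p_par) + ln.par_beta_imperv * site.impervious)
    p_fail = _expit(_logit(params.p_fail) + ln.fail_beta_imperv * site.impervious)
    if p_par + p_fail >= 1:  # keep the trinomial valid under extreme links
        scale = 0.99 / (p_par + p_fail)
        p_par, p_fail = p_par * scale, p_fail * scale
    return p_par, p_fail


def _species_pool(taxon: Taxon):
    pool = _BEE_SPECIES if taxon == Taxon.BEE else _WASP_SPECIES
    names = [n for n, _ in pool]
    w = np.array([w for _, w in pool])
    return names, w / w.sum()


def generate_nests(sites: list[SiteRecord], config: GeneratorConfig) -> list[NestRecord]:
    """Draw occupied tubes and per-cell fates for every site and taxon.

    Every emitted record satisfies the nest invariants by construction:
    fates are one trinomial draw over the tube's brood cells.

    With ``evenness_coupling`` enabled, each site gets a latent quality
    q ~ U(0,1): high-q sites draw brood sizes from a compact mid-range
    band and lose few cells (evenly spaced traits, many emerged), low-q
    sites draw from two extreme bands and lose many (clumped traits with
    outliers, few emerged). This induces the positive evenness / negative
    richness-divergence coupling with offspring production.
    """
    rng = _stage_rng(config.seed, "nests")
    records: list[NestRecord] = []
    for site in sites:
        quality = rng.uniform() if config.evenness_coupling else None
        for taxon in (Taxon.BEE, Taxon.WASP):
            params = config.params_for(taxon)
            n_tubes = int(
                min(
                    config.tubes_max,
                    rng.negative_binomial(
                        config.tubes_dispersion,
                        config.tubes_dispersion / (config.tubes_dispersion + config.tubes_mean),
                    ),
                )
            )
            if n_tubes == 0:
                continue
            names, weights = _species_pool(taxon)
            species = rng.choice(names, size=n_tubes, p=weights)
            if quality is None:
                mu = _linked_mu(site, params)
                totals = _sample_ztnb(np.full(n_tubes, mu), params.dispersion, rng)
                p_par, p_fail = _linked_fates(site, params)
                p_par_tube = np.full(n_tubes, p_par)
                p_fail_tube = np.full(n_tubes, p_fail)
            else:
                # each tube interpolates between a clumped position (one of
                # two tight blobs: extreme brood sizes with blob-specific
                # parasitism) and an evenly spread position (distinct
                # mid-band brood sizes, wide fate bands), with weight q =
                # site quality; q=0 gives two separated blobs, q=1 an even
                # scatter over all three trait axes
                q = quality
                blob = rng.uniform(size=n_tubes) < 0.5
                blob_total = np.where(
                    blob, rng.integers(1, 3, size=n_tubes), rng.integers(21, 25, size=n_tubes)
                )
                # mid band mean (12) matches the blob mixture mean so brood
                # size does not leak a regime signal into offspring counts
                band = np.arange(5, 20)
                even_total = rng.choice(band, size=n_tubes, replace=n_tubes > band.size)
                totals = np.maximum(
                    1, np.rint((1 - q) * blob_total + q * even_total).astype(int)
                )
                blob_par = np.where(blob, 0.30, 0.01)
                p_par_tube = (1 - q) * blob_par + q * rng.uniform(0.0, 0.30, size=n_tubes)
                c = 0.55 - 0.40 * q
                p_fail_tube = np.clip(
                    c + q * rng.uniform(-0.15, 0.15, size=n_tubes), 0.02, 0.9
                )
            for t in range(n_tubes):
                total = int(totals[t])
                pp, pf = float(p_par_tube[t]), float(p_fail_tube[t])
                emerged, par, fail = rng.multinomial(total, [1 - pp - pf, pp, pf])
                records.append(
                    NestRecord(
                        nest_id=f"{site.site_id}-{taxon.value[0]}{t + 1:02d}",
                        site_id=site.site_id,
                        taxon=taxon,
                        species=str(species[t]),
                        total_cells=total,
                        parasitized_cells=int(par),
                        non_emerged_cells=int(fail),
                    )
                )
    return records


def generate_dataset(config: GeneratorConfig | None = None, seed: int | None = None) -> Dataset:
    """Sites plus nests as one validated Dataset."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    sites = generate_sites(config)
    nests = generate_nests(sites, config)
    return Dataset(nests=tuple(nests), sites=tuple(sites))


def generate_raster(
    shape: tuple[int, int] = (200, 200),
    cell_size: float = 5.0,
    patch_size: int = 8,
    class_weights: dict[int, float] | None = None,
    seed: int = 0,
) -> CoverGrid:
    """Blocky multi-class cover grid; patch_size tunes edge density.

    Patches are square blocks of ``patch_size`` cells drawn independently
    from ``class_weights`` (uniform over the legend by default);
    patch_size=1 approaches the checkerboard edge-density limit.
    """
    rng = np.random.default_rng(seed)
    if class_weights is None:
        class_weights = {code: 1.0 for code in COVER_CLASSES}
    codes = np.array(list(class_weights), dtype=int)
    w = np.array(list(class_weights.values()), dtype=float)
    w = w / w.sum()
    coarse_shape = (-(-shape[0] // patch_size), -(-shape[1] // patch_size))
    coarse = rng.choice(codes, size=coarse_shape, p=w)
    cells = np.kron(coarse, np.ones((patch_size, patch_size), dtype=int))
    cells = cells[: shape[0], : shape[1]]
    return CoverGrid(cells=cells, cell_size=cell_size)
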