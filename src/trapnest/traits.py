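"""Per-nest reproductive traits, offspring production, and z-scaling.

Three traits describe the reproductive phenotype of one nesting tube:

* ``total_cells`` — brood cells provisioned (a fecundity proxy);
* ``prop_parasite_free`` — fraction of cells not attacked by parasites;
* ``prop_non_emerged`` — fraction of cells that failed to emerge for
  reasons other than parasitism.

The number of emerged offspring per tube satisfies the exact identity

    emerged = total * (prop_parasite_free - prop_non_emerged)
            = total - parasitized - non_emerged

which holds in rational arithmetic; counts are the primary representation
so the identity is never degraded by floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .io import NestRecord, Taxon

__all__ = [
    "TraitVector",
    "TraitMatrix",
    "TRAIT_NAMES",
    "nest_traits",
    "emerged_identity_holds",
    "site_offspring_production",
    "z_transform",
    "correlation_screen",
]

#: Canonical trait order used by every downstream matrix.
TRAIT_NAMES = ("total_cells", "prop_parasite_free", "prop_non_emerged")


@dataclass(frozen=True)
class TraitVector:
    """The three reproductive traits of one nesting tube, plus its emerged count."""

    total_cells: int
    prop_parasite_free: float
    prop_non_emerged: float
    emerged_cells: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.total_cells, self.prop_parasite_free, self.prop_non_emerged],
            dtype=float,
        )


@dataclass(frozen=True)
class TraitMatrix:
    """z-scored trait vectors for a set of nests within one scope.

    Each column has mean 0 and sample standard deviation 1 over the scope
    (all nests of one taxon in the full dataset, by default). The centering
    and scaling constants are retained so the transform is invertible.
    """

    values: np.ndarray  # shape (n, 3)
    scope: str
    means: np.ndarray  # shape (3,)
    sds: np.ndarray  # shape (3,)
    columns: tuple[str, ...] = TRAIT_NAMES

    def inverse(self) -> np.ndarray:
        """Recover the raw trait values."""
        return self.values * self.sds + self.means


def nest_traits(nest: NestRecord) -> TraitVector:
    """Compute the trait vector of one nest.

    Proportions use the tube's own cell total as denominator; the emerged
    count is the exact integer ``total - parasitized - non_emerged``.
    """
    total = nest.total_cells
    return TraitVector(
        total_cells=total,
        prop_parasite_free=(total - nest.parasitized_cells) / total,
        prop_non_emerged=nest.non_emerged_cells / total,
        emerged_cells=nest.emerged_cells,
    )


def emerged_identity_holds(nest: NestRecord) -> bool:
    """Check total*(pf - ne) == total - parasitized - non_emerged exactly.

    Evaluated in rational arithmetic, so it is a true identity check rather
    than a floating-point comparison.
    """
    total = Fraction(nest.total_cells)
    pf = Fraction(nest.total_cells - nest.parasitized_cells, nest.total_cells)
    ne = Fraction(nest.non_emerged_cells, nest.total_cells)
    return total * (pf - ne) == nest.emerged_cells


def site_offspring_production(traits: Sequence[TraitVector]) -> float:
    """Mean number of emerged brood cells per tube at one site."""
    if len(traits) == 0:
        raise ValueError("offspring production of an empty nest collection")
    return float(np.mean([t.emerged_cells for t in traits]))


def z_transform(
    vectors: Sequence[TraitVector], scope: str | Taxon = "all"
) -> TraitMatrix:
    """Center and scale each trait to mean 0, sd 1 (sample sd, n-1).

    z-scaling gives the three traits equal weight in the multidimensional
    diversity indices. Raises if any trait has zero spread (a NaN column
    would silently poison every downstream index).
    """
    if len(vectors) < 2:
        raise ValueError("z_transform needs at least 2 trait vectors")
    raw = np.array([v.as_array() for v in vectors])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    for name, sd in zip(TRAIT_NAMES, sds):
        if sd == 0:
            raise ValueError(f"trait {name!r} has zero spread within scope; cannot z-scale")
    scope_label = scope.value if isinstance(scope, Taxon) else str(scope)
    return TraitMatrix(values=(raw - means) / sds, scope=scope_label, means=means, sds=sds)


def correlation_screen(matrix) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlations between columns.

    Accepts a TraitMatrix or a plain (n, p) array. Returns the symmetric
    correlation matrix and the maximum absolute off-diagonal entry — the
    screen used to confirm the traits (or the environmental gradients) are
    weakly enough correlated to be treated as separate axes.
    """
    values = matrix.values if isinstance(matrix, TraitMatrix) else np.asarray(matrix, float)
    if values.shape[0] < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    if np.any(values.std(axis=0) == 0):
        raise ValueError("correlation screen: zero-variance column")
    corr = np.corrcoef(values, rowvar=False)
    off = np.abs(corr - np.eye(corr.shape[0]))
    return corr, float(off.max())


def traits_for(nests: Iterable[NestRecord]) -> list[TraitVector]:
    """Convenience: trait vectors for a nest collection, order preserved."""
    return [nest_traits(n) for n in nests]
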