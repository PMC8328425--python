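"""Core record types and tabular I/O.

The pipeline's interchange format is CSV throughout: one table of occupied
nesting tubes (one row per tube, integer brood-cell fate counts) and one
table of trap-nest sites (urban-green-space category plus the three
environmental gradients). Counts are stored, proportions are always derived,
so no rounding inconsistency can creep in between the two.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Taxon",
    "UGSType",
    "NestRecord",
    "SiteRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_nests",
    "read_sites",
    "read_dataset",
    "write_table",
    "nests_to_frame",
    "sites_to_frame",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Taxon(str, enum.Enum):
    BEE = "bee"
    WASP = "wasp"


class UGSType(str, enum.Enum):
    """The four urban green space categories covered by the study design."""

    COMMUNITY_GARDEN = "community_garden"
    HOME_GARDEN = "home_garden"
    PARK = "park"
    GREEN_ROOF = "green_roof"


#: Accepted spellings for UGS labels, normalised to the canonical enum.
_UGS_ALIASES: Mapping[str, UGSType] = {
    "community_garden": UGSType.COMMUNITY_GARDEN,
    "community garden": UGSType.COMMUNITY_GARDEN,
    "community": UGSType.COMMUNITY_GARDEN,
    "home_garden": UGSType.HOME_GARDEN,
    "home garden": UGSType.HOME_GARDEN,
    "home": UGSType.HOME_GARDEN,
    "park": UGSType.PARK,
    "urban_park": UGSType.PARK,
    "urban park": UGSType.PARK,
    "green_roof": UGSType.GREEN_ROOF,
    "green roof": UGSType.GREEN_ROOF,
    "roof": UGSType.GREEN_ROOF,
}


@dataclass(frozen=True)
class NestRecord:
    """One occupied nesting tube: the unit of individual-level traits.

    A tube holds a linear series of brood cells, each of which either
    emerged, was attacked by parasites, or failed to emerge for other
    (parasite-free) reasons.
    """

    nest_id: str
    site_id: str
    taxon: Taxon
    species: str
    total_cells: int
    parasitized_cells: int
    non_emerged_cells: int
    year: int | None = None

    def __post_init__(self) -> None:
        if self.total_cells < 1:
            raise ValidationError(
                f"nest {self.nest_id!r}: total_cells must be >= 1 "
                f"(got {self.total_cells}); only occupied tubes are records"
            )
        if self.parasitized_cells < 0 or self.non_emerged_cells < 0:
            raise ValidationError(
                f"nest {self.nest_id!r}: fate counts must be non-negative"
            )
        if self.parasitized_cells + self.non_emerged_cells > self.total_cells:
            raise ValidationError(
                f"nest {self.nest_id!r}: parasitized_cells + non_emerged_cells "
                f"({self.parasitized_cells} + {self.non_emerged_cells}) exceeds "
                f"total_cells ({self.total_cells})"
            )

    @property
    def emerged_cells(self) -> int:
        """Brood cells that yielded an offspring (derived, never stored)."""
        return self.total_cells - self.parasitized_cells - self.non_emerged_cells


@dataclass(frozen=True)
class SiteRecord:
    """One trap-nest site: UGS category and three environmental gradients.

    ``open_green`` and ``impervious`` are proportions of the same circular
    buffer, so their sum cannot exceed one. ``edge_density`` is boundary
    length per buffer area (m/m2).
    """

    site_id: str
    ugs_type: UGSType
    open_green: float
    impervious: float
    edge_density: float

    def __post_init__(self) -> None:
        for name in ("open_green", "impervious"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"site {self.site_id!r}: {name} must lie in [0, 1] (got {v})"
                )
        if self.open_green + self.impervious > 1.0 + 1e-12:
            raise ValidationError(
                f"site {self.site_id!r}: open_green + impervious > 1 "
                f"({self.open_green} + {self.impervious})"
            )
        if self.edge_density < 0:
            raise ValidationError(
                f"site {self.site_id!r}: edge_density must be >= 0"
            )


@dataclass(frozen=True)
class Dataset:
    """A validated pair of nest and site tables."""

    nests: tuple[NestRecord, ...]
    sites: tuple[SiteRecord, ...]

    def __post_init__(self) -> None:
        known = {s.site_id for s in self.sites}
        if len(known) != len(self.sites):
            raise ValidationError("duplicate site_id in site table")
        orphans = sorted({n.site_id for n in self.nests} - known)
        if orphans:
            raise ValidationError(
                f"nest site_id(s) {orphans} do not resolve to any SiteRecord"
            )

    def site(self, site_id: str) -> SiteRecord:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def nests_for(self, site_id: str, taxon: Taxon | None = None) -> tuple[NestRecord, ...]:
        return tuple(
            n
            for n in self.nests
            if n.site_id == site_id and (taxon is None or n.taxon == taxon)
        )


_NEST_COLUMNS = (
    "nest_id",
    "site_id",
    "taxon",
    "species",
    "total_cells",
    "parasitized_cells",
    "non_emerged_cells",
)

_SITE_COLUMNS = ("site_id", "ugs_type", "open_green", "impervious", "edge_density")


def _read_csv(path: str | Path) -> pd.DataFrame:
    # "#"-prefixed lines are metadata headers written by this package.
    return pd.read_csv(path, comment="#")


def _require(df: pd.DataFrame, columns: Sequence[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def normalize_ugs(label: str) -> UGSType:
    key = str(label).strip().lower().replace("-", " ")
    key_us = key.replace(" ", "_")
    for candidate in (key, key_us):
        if candidate in _UGS_ALIASES:
            return _UGS_ALIASES[candidate]
    raise ValidationError(
        f"unknown UGS label {label!r}; expected one of "
        f"{sorted({u.value for u in UGSType})}"
    )


def read_nests(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[NestRecord]:
    """Read and validate a nest table.

    Parameters
    ----------
    path:
        CSV with columns nest_id, site_id, taxon, species, total_cells,
        parasitized_cells, non_emerged_cells and optionally year.
    dialect:
        Optional mapping from the file's column names to the canonical ones,
        e.g. ``{"tube": "nest_id"}``, so supplementary tables exported under
        other headings can be ingested without editing the file.
    """
    df = _read_csv(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    _require(df, _NEST_COLUMNS, path)
    has_year = "year" in df.columns
    records: list[NestRecord] = []
    for row in df.itertuples(index=False):
        taxon = Taxon(str(getattr(row, "taxon")).strip().lower())
        year = getattr(row, "year") if has_year else None
        records.append(
            NestRecord(
                nest_id=str(getattr(row, "nest_id")),
                site_id=str(getattr(row, "site_id")),
                taxon=taxon,
                species=str(getattr(row, "species")),
                total_cells=int(getattr(row, "total_cells")),
                parasitized_cells=int(getattr(row, "parasitized_cells")),
                non_emerged_cells=int(getattr(row, "non_emerged_cells")),
                year=None if year is None or pd.isna(year) else int(year),
            )
        )
    return records


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read and validate a site table (see :class:`SiteRecord`)."""
    df = _read_csv(path)
    _require(df, _SITE_COLUMNS, path)
    return [
        SiteRecord(
            site_id=str(row.site_id),
            ugs_type=normalize_ugs(row.ugs_type),
            open_green=float(row.open_green),
            impervious=float(row.impervious),
            edge_density=float(row.edge_density),
        )
        for row in df.itertuples(index=False)
    ]


def read_dataset(
    nest_path: str | Path,
    site_path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> Dataset:
    return Dataset(
        nests=tuple(read_nests(nest_path, dialect)),
        sites=tuple(read_sites(site_path)),
    )


def nests_to_frame(nests: Iterable[NestRecord]) -> pd.DataFrame:
    rows = []
    for n in nests:
        d = dataclasses.asdict(n)
        d["taxon"] = n.taxon.value
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(_NEST_COLUMNS) + ["year"])
    if df["year"].isna().all():
        df = df.drop(columns=["year"])
    return df


def sites_to_frame(sites: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = []
    for s in sites:
        d = dataclasses.asdict(s)
        d["ugs_type"] = s.ugs_type.value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(_SITE_COLUMNS))


def write_table(
    records,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Write any tabular result to CSV.

    Accepts a DataFrame, a sequence of dataclass records, or a sequence of
    dicts. Reals are written with 12 significant digits so a round-trip read
    reproduces them to that precision; integers round-trip bit-exactly.
    ``metadata`` key/value pairs are emitted as ``# key: value`` header lines.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty table")
        if dataclasses.is_dataclass(records[0]):
            if isinstance(records[0], NestRecord):
                df = nests_to_frame(records)
            elif isinstance(records[0], SiteRecord):
                df = sites_to_frame(records)
            else:
                df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path
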