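"""Leaf-assemblage data model, tabular I/O, and the nested dataset cascade.

One row of the specimen table is one fossil dicot leaf.  The analysis
proceeds through nested subsets of the assemblage:

* **Dataset 1** — all scored leaves (at least 50 % of the lamina preserved);
* **Dataset 2** — leaves at least 70 % preserved, eligible for outline
  reconstruction;
* **Dataset 3** — a fixed-size random subsample per site (400 leaves in the
  original study) carrying quantitative trait measurements;
* **Dataset 4** — Dataset 3 cleaned for multivariate analysis: complete
  cases only, Tukey-fence outliers on leaf size and leaf mass per area
  removed, and rare fossil-species / rare TCTs (fewer than five leaves)
  dropped;
* **Dataset 5** — Dataset 4 plus specimens whose missing LM_A could be
  imputed (see :mod:`ilta.lma_impute`).

The tabular dialect is plain UTF-8 CSV with one row per specimen; damage
types are stored either as a compact list column (``"2;12;78"``, optionally
``"2:3.5;12"`` with per-observation damaged areas in mm²) or as wide 0/1
incidence columns ``X1``…``X280``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tct import UNKNOWN, TraitQuartet

__all__ = [
    "DamageObservation",
    "LeafSpecimen",
    "Assemblage",
    "SchemaError",
    "read_assemblage",
    "write_assemblage",
    "filter_dataset2",
    "sample_dataset3",
    "build_dataset4",
    "tukey_fences",
    "write_incidence_matrix",
    "read_incidence_matrix",
]


class SchemaError(ValueError):
    """Raised when a specimen table violates the documented column contract."""


@dataclass(frozen=True)
class DamageObservation:
    """One damage type (DT) observed on one leaf.

    ``dt`` is the catalog number of the damage type, or one of the
    sentinels ``"unknown-gall"`` / ``"unknown-mine"`` for morphotypes that
    could not be matched to a catalog entry.  ``damaged_area_mm2`` is the
    measured damaged lamina area, when available.
    """

    dt: int | str
    damaged_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.dt, int):
            if self.dt < 1:
                raise ValueError(f"DT number must be >= 1, got {self.dt}")
        elif self.dt not in ("unknown-gall", "unknown-mine"):
            raise ValueError(f"invalid DT sentinel {self.dt!r}")
        if self.damaged_area_mm2 is not None and self.damaged_area_mm2 < 0:
            raise ValueError("damaged area must be >= 0")

    @property
    def label(self) -> str:
        """Column label in the wide incidence dialect (``X<dt>``)."""
        return f"X{self.dt}" if isinstance(self.dt, int) else self.dt


# specimen-level trait fields that are strictly positive when present
_POSITIVE_TRAITS = ("leaf_length_mm", "leaf_width_mm", "leaf_area_mm2",
                    "petiole_width_mm", "lma_gm2")


@dataclass
class LeafSpecimen:
    """One fossil leaf with its identifiers, characters, traits and damage."""

    specimen_id: str
    site: str
    family: str | None = None
    fossil_species: str | None = None
    growth_form: str = UNKNOWN
    phenology_modern: str = UNKNOWN
    lobation: str = UNKNOWN
    margin: str = UNKNOWN
    primary_venation: str = UNKNOWN
    secondary_venation: str = UNKNOWN
    tct_specimen: str | None = None
    tct_taxonomy: str | None = None
    tct_combined: str | None = None
    preserved_fraction: float | None = None
    area_index: float | None = None
    leaf_length_mm: float | None = None
    leaf_width_mm: float | None = None
    leaf_area_mm2: float | None = None
    petiole_width_mm: float | None = None
    lma_gm2: float | None = None
    lma_source: str = "missing"
    damage: list[DamageObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("preserved_fraction", "area_index"):
            value = getattr(self, name)
            if value is not None and not (0.0 < value <= 1.0):
                raise ValueError(
                    f"{name} must lie in (0, 1], got {value} "
                    f"(specimen {self.specimen_id})"
                )
        for name in _POSITIVE_TRAITS:
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(
                    f"{name} must be > 0, got {value} "
                    f"(specimen {self.specimen_id})"
                )
        if self.lma_gm2 is not None and self.lma_source not in (
            "measured", "imputed",
        ):
            raise ValueError(
                f"lma_gm2 present but lma_source={self.lma_source!r} "
                f"(specimen {self.specimen_id})"
            )
        if self.leaf_area_mm2 is not None:
            for obs in self.damage:
                if (obs.damaged_area_mm2 is not None
                        and obs.damaged_area_mm2 > self.leaf_area_mm2):
                    raise ValueError(
                        f"damaged area {obs.damaged_area_mm2} exceeds leaf "
                        f"area {self.leaf_area_mm2} "
                        f"(specimen {self.specimen_id})"
                    )

    @property
    def quartet(self) -> TraitQuartet:
        return TraitQuartet(
            self.lobation, self.margin,
            self.primary_venation, self.secondary_venation,
        )

    @property
    def damaged(self) -> bool:
        return len(self.damage) > 0

    @property
    def dt_numbers(self) -> list[int | str]:
        return [obs.dt for obs in self.damage]

    @property
    def total_damaged_area_mm2(self) -> float | None:
        areas = [o.damaged_area_mm2 for o in self.damage
                 if o.damaged_area_mm2 is not None]
        return float(sum(areas)) if areas else None

    @property
    def length_width_ratio(self) -> float | None:
        if self.leaf_length_mm is None or self.leaf_width_mm is None:
            return None
        return self.leaf_length_mm / self.leaf_width_mm


@dataclass
class Assemblage:
    """A named collection of leaf specimens (typically one per fossil site,
    or a pooled multi-site dataset at a given cascade level)."""

    name: str
    specimens: list[LeafSpecimen] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(ids) != len(set(ids)):
            seen, dupes = set(), []
            for i in ids:
                if i in seen:
                    dupes.append(i)
                seen.add(i)
            raise SchemaError(
                f"duplicated specimen_id(s) in {self.name!r}: "
                f"{sorted(set(dupes))}"
            )

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    @property
    def sites(self) -> list[str]:
        out: list[str] = []
        for s in self.specimens:
            if s.site not in out:
                out.append(s.site)
        return out

    def subset(self, predicate, name: str | None = None) -> "Assemblage":
        return Assemblage(
            name or self.name,
            [s for s in self.specimens if predicate(s)],
        )

    def by_site(self) -> dict[str, "Assemblage"]:
        return {
            site: self.subset(lambda s, site=site: s.site == site,
                              name=f"{self.name}:{site}")
            for site in self.sites
        }

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per specimen (damage as list column ``dts``)."""
        rows = []
        for s in self.specimens:
            row = {
                "specimen_id": s.specimen_id,
                "site": s.site,
                "family": s.family,
                "fossil_species": s.fossil_species,
                "growth_form": s.growth_form,
                "phenology_modern": s.phenology_modern,
                "lobation": s.lobation,
                "margin": s.margin,
                "primary_venation": s.primary_venation,
                "secondary_venation": s.secondary_venation,
                "tct_specimen": s.tct_specimen,
                "tct_taxonomy": s.tct_taxonomy,
                "tct_combined": s.tct_combined,
                "preserved_fraction": s.preserved_fraction,
                "area_index": s.area_index,
                "leaf_length_mm": s.leaf_length_mm,
                "leaf_width_mm": s.leaf_width_mm,
                "leaf_area_mm2": s.leaf_area_mm2,
                "petiole_width_mm": s.petiole_width_mm,
                "lma_gm2": s.lma_gm2,
                "lma_source": s.lma_source,
                "length_width_ratio": s.length_width_ratio,
                "dts": _format_damage(s.damage),
                "n_dts": len(s.damage),
                "damaged": s.damaged,
                "damaged_area_mm2": s.total_damaged_area_mm2,
            }
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# damage list column dialect: "2;12" or "2:3.5;12" (area after colon)

def _format_damage(damage: Sequence[DamageObservation]) -> str:
    parts = []
    for obs in damage:
        if obs.damaged_area_mm2 is not None:
            parts.append(f"{obs.dt}:{obs.damaged_area_mm2:.9g}")
        else:
            parts.append(str(obs.dt))
    return ";".join(parts)


def _parse_damage(text: str) -> list[DamageObservation]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return []
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" in chunk:
            dt_part, area_part = chunk.split(":", 1)
            area = float(area_part)
        else:
            dt_part, area = chunk, None
        dt_part = dt_part.strip()
        try:  # "2" or "2.0" (a numeric column read as float)
            dt: int | str = int(float(dt_part))
        except ValueError:
            dt = dt_part
        out.append(DamageObservation(dt, area))
    return out


_MANDATORY = ("specimen_id", "site")
_REAL_COLUMNS = (
    "preserved_fraction", "area_index", "leaf_length_mm", "leaf_width_mm",
    "leaf_area_mm2", "petiole_width_mm", "lma_gm2",
)
_TEXT_COLUMNS = (
    "family", "fossil_species", "growth_form", "phenology_modern",
    "lobation", "margin", "primary_venation", "secondary_venation",
    "tct_specimen", "tct_taxonomy", "tct_combined",
)
_WIDE_DT = re.compile(r"^X(\d+)$")


def read_assemblage(
    path,
    name: str | None = None,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
) -> Assemblage:
    """Read a specimen table (CSV/TSV) into an :class:`Assemblage`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row and one row per specimen.
    name
        Assemblage name; defaults to the file stem.
    dialect
        Optional ``{file column -> canonical column}`` rename map for
        tables using other headers.
    sep
        Field separator (``"\\t"`` for TSV).

    Damage types may come as a ``dts`` list column and/or wide ``X<dt>``
    0/1 columns; both are parsed.  Unknown categorical values map to
    ``"unknown"``.  Row count is preserved exactly.
    """
    frame = pd.read_csv(path, sep=sep, dtype={"specimen_id": str})
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    wide_cols = [c for c in frame.columns if _WIDE_DT.match(str(c))]
    specimens = []
    for _, row in frame.iterrows():
        sid = str(row["specimen_id"])
        kwargs: dict = {"specimen_id": sid, "site": str(row["site"])}
        for col in _TEXT_COLUMNS:
            if col in frame.columns:
                value = row[col]
                if pd.isna(value) or str(value).strip() == "":
                    value = None if col.startswith(("family", "fossil",
                                                    "tct")) else UNKNOWN
                else:
                    value = str(value).strip()
                kwargs[col] = value
        for col in _REAL_COLUMNS:
            if col in frame.columns and pd.notna(row[col]):
                try:
                    kwargs[col] = float(row[col])
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"non-numeric value {row[col]!r} in column {col} "
                        f"for specimen {sid}"
                    ) from exc
        if "lma_source" in frame.columns and pd.notna(row["lma_source"]):
            kwargs["lma_source"] = str(row["lma_source"])
        elif kwargs.get("lma_gm2") is not None:
            kwargs["lma_source"] = "measured"

        damage = _parse_damage(row["dts"]) if "dts" in frame.columns else []
        present = {obs.dt for obs in damage}
        for col in wide_cols:
            if pd.notna(row[col]) and float(row[col]) > 0:
                dt = int(_WIDE_DT.match(col).group(1))
                if dt not in present:
                    damage.append(DamageObservation(dt))
        kwargs["damage"] = damage
        try:
            specimens.append(LeafSpecimen(**kwargs))
        except ValueError as exc:
            raise SchemaError(f"invalid row for specimen {sid}: {exc}") from exc

    if name is None:
        name = getattr(path, "stem", None) or str(path)
    return Assemblage(name, specimens)


def write_assemblage(a: Assemblage, path, sep: str = ",") -> None:
    """Write the specimen table in the list-column dialect (round-trips
    through :func:`read_assemblage` to 1e-9 on reals, bit-exact on text)."""
    frame = a.to_frame().drop(columns=["n_dts", "damaged", "damaged_area_mm2",
                                       "length_width_ratio"])
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# the dataset cascade


def filter_dataset2(a: Assemblage, min_preserved: float = 0.70) -> Assemblage:
    """Dataset 2: keep leaves with at least 70 % of the lamina preserved.

    The threshold is inclusive ("at least 70 %").  Specimens lacking a
    preservation estimate are dropped with a warning; input order is kept,
    so the operation is idempotent.
    """
    lacking = [s.specimen_id for s in a
               if s.preserved_fraction is None]
    if lacking:
        warnings.warn(
            f"{len(lacking)} specimen(s) without preserved_fraction dropped",
            stacklevel=2,
        )
    return a.subset(
        lambda s: s.preserved_fraction is not None
        and s.preserved_fraction >= min_preserved,
        name=f"{a.name}/D2",
    )


def sample_dataset3(
    a: Assemblage, n_per_site: int, seed: int,
) -> Assemblage:
    """Dataset 3: simple random sample of ``n_per_site`` leaves per site.

    Sampling is without replacement and reproducible for a fixed seed.
    A site with fewer than ``n_per_site`` specimens contributes all of
    them, with a warning.
    """
    if n_per_site <= 0:
        raise ValueError(f"n_per_site must be positive, got {n_per_site}")
    rng = np.random.default_rng(seed)
    chosen: list[LeafSpecimen] = []
    for site in a.sites:
        pool = [s for s in a if s.site == site]
        if len(pool) < n_per_site:
            warnings.warn(
                f"site {site!r} has only {len(pool)} specimens "
                f"(< {n_per_site}); taking all",
                stacklevel=2,
            )
            chosen.extend(pool)
        else:
            idx = rng.choice(len(pool), size=n_per_site, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
    return Assemblage(f"{a.name}/D3", chosen)


def tukey_fences(values: Sequence[float]) -> tuple[float, float]:
    """Tukey's outlier fences ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` with
    linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


#: columns a specimen must have observed to enter the multivariate set
MULTIVARIATE_VARIABLES = (
    "leaf_area_mm2", "leaf_length_mm", "leaf_width_mm", "lma_gm2",
    "tct_combined", "area_index", "phenology_modern",
)


def build_dataset4(
    a: Assemblage,
    min_group: int = 5,
    variables: Sequence[str] = MULTIVARIATE_VARIABLES,
    per_site: bool = True,
    merge_rare_tcts: bool = False,
) -> tuple[Assemblage, dict[str, int]]:
    """Dataset 4: the cleaned complete-case set for multivariate analysis.

    Removal rules, applied in this order so that rarity is evaluated on the
    already-cleaned set:

    1. incomplete cases for the multivariate variable set;
    2. leaf-size or LM_A values outside the Tukey fences (1.5 × IQR beyond
       the quartiles), computed per site when ``per_site`` (the default);
    3. specimens of fossil-species with fewer than ``min_group`` remaining
       leaves;
    4. specimens of TCTs with fewer than ``min_group`` remaining leaves
       (deleted, or merged into a composite ``"other"`` class when
       ``merge_rare_tcts``).

    Returns the filtered assemblage and a removal ledger whose counts sum
    to ``len(input) - len(output)``.
    """
    ledger = {"incomplete": 0, "outlier": 0, "rare_species": 0,
              "rare_tct": 0}

    def complete(s: LeafSpecimen) -> bool:
        for var in variables:
            value = getattr(s, var)
            if value is None or value == UNKNOWN:
                return False
        return True

    current = [s for s in a if complete(s)]
    ledger["incomplete"] = len(a) - len(current)

    # Tukey fences on leaf size and LM_A, per site or pooled
    keep: list[LeafSpecimen] = []
    groups = (
        {site: [s for s in current if s.site == site]
         for site in dict.fromkeys(s.site for s in current)}
        if per_site
        else {"all": current}
    )
    fences = {
        key: (
            tukey_fences([s.leaf_area_mm2 for s in grp]),
            tukey_fences([s.lma_gm2 for s in grp]),
        )
        for key, grp in groups.items()
        if grp
    }
    for s in current:
        key = s.site if per_site else "all"
        (alo, ahi), (llo, lhi) = fences[key]
        if alo <= s.leaf_area_mm2 <= ahi and llo <= s.lma_gm2 <= lhi:
            keep.append(s)
    ledger["outlier"] = len(current) - len(keep)
    current = keep

    species_counts = pd.Series(
        [s.fossil_species for s in current], dtype="object",
    ).value_counts()
    keep = [
        s for s in current
        if s.fossil_species is not None
        and species_counts.get(s.fossil_species, 0) >= min_group
    ]
    ledger["rare_species"] = len(current) - len(keep)
    current = keep

    tct_counts = pd.Series(
        [s.tct_combined for s in current], dtype="object",
    ).value_counts()
    if merge_rare_tcts:
        merged = []
        for s in current:
            if tct_counts.get(s.tct_combined, 0) < min_group:
                merged.append(replace(s, tct_combined="other"))
            else:
                merged.append(s)
        current = merged
        ledger["rare_tct"] = 0
    else:
        keep = [
            s for s in current
            if tct_counts.get(s.tct_combined, 0) >= min_group
        ]
        ledger["rare_tct"] = len(current) - len(keep)
        current = keep

    return Assemblage(f"{a.name}/D4", current), ledger


# ---------------------------------------------------------------------------
# incidence matrices (the rarefaction input dialect)


def write_incidence_matrix(a: Assemblage, path=None) -> pd.DataFrame:
    """Leaves × damage-types 0/1 matrix in the wide ``X<dt>`` dialect.

    Row order equals specimen order; the first column is ``specimen_id``.
    An assemblage without damage yields a matrix with zero DT columns.
    When ``path`` is given the matrix is also written as CSV.
    """
    labels: list[str] = []
    for s in a:
        for obs in s.damage:
            if obs.label not in labels:
                labels.append(obs.label)

    def sort_key(label: str):
        m = _WIDE_DT.match(label)
        return (0, int(m.group(1))) if m else (1, label)

    labels = sorted(labels, key=sort_key)
    data = np.zeros((len(a), len(labels)), dtype=int)
    index = {lab: j for j, lab in enumerate(labels)}
    for i, s in enumerate(a):
        for obs in s.damage:
            data[i, index[obs.label]] = 1
    matrix = pd.DataFrame(data, columns=labels)
    matrix.insert(0, "specimen_id", [s.specimen_id for s in a])
    if path is not None:
        matrix.to_csv(path, index=False)
    return matrix


def read_incidence_matrix(path) -> pd.DataFrame:
    """Read an incidence-matrix CSV written by :func:`write_incidence_matrix`
    (or any table whose DT columns match ``X<number>``)."""
    frame = pd.read_csv(path, dtype={"specimen_id": str})
    dt_cols = [c for c in frame.columns if c != "specimen_id"]
    frame[dt_cols] = (frame[dt_cols].fillna(0) > 0).astype(int)
    return frame
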