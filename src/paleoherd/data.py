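"""Domain types and plain-text I/O.

Age is measured in months throughout. Age classes are half-open intervals
``[lower, upper)`` so that contiguity is unambiguous; the terminal
(open-ended) class of an archaeological schema is closed by an explicit
``terminal_cap``.

File formats:

* schema — YAML with a ``classes`` list of ``{label, lower, upper}`` mappings
  (``upper`` may be omitted on the last class) and an optional
  ``terminal_cap`` in months;
* modern herd table — CSV with columns
  ``herd_id,sex,age_class,survivors,population``;
* kill-off profile — CSV with columns ``site_id,age_class,count`` plus an
  optional ambiguity CSV ``site_id,individual_id,candidate_classes`` where
  ``candidate_classes`` is a ``|``-separated list of adjacent class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DEFAULT_TERMINAL_CAP = 144.0  # months; closes an open-ended last class

SEX_FEMALE = 0
SEX_MALE = 1


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class AgeClassSchema:
    """Ordered, contiguous age classes with boundaries in months."""

    labels: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    terminal_cap: float = DEFAULT_TERMINAL_CAP

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValidationError("schema needs at least 2 age classes")
        if len(self.lower) != n or len(self.upper) != n:
            raise ValidationError("labels/lower/upper lengths differ")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate age-class labels")
        if self.lower[0] != 0:
            raise ValidationError("first class must start at 0 months")
        for j in range(n):
            if not self.upper[j] > self.lower[j]:
                raise ValidationError(
                    f"class {self.labels[j]!r}: upper {self.upper[j]} "
                    f"not greater than lower {self.lower[j]}"
                )
        for j in range(1, n):
            if self.lower[j] != self.upper[j - 1]:
                kind = "overlap" if self.lower[j] < self.upper[j - 1] else "gap"
                raise ValidationError(
                    f"classes {self.labels[j - 1]!r} and {self.labels[j]!r}: "
                    f"{kind} between upper {self.upper[j - 1]} and lower {self.lower[j]}"
                )
        if self.upper[-1] != self.terminal_cap:
            raise ValidationError("terminal_cap must equal the last class upper bound")

    @classmethod
    def from_bounds(
        cls,
        classes: list[tuple[str, float, float | None]],
        terminal_cap: float | None = None,
    ) -> "AgeClassSchema":
        """Build from (label, lower, upper) triples; the last ``upper`` may be
        None, in which case ``terminal_cap`` (default 144) closes the class."""
        labels = tuple(str(c[0]) for c in classes)
        lower = tuple(float(c[1]) for c in classes)
        upper = [c[2] for c in classes]
        if upper[-1] is None:
            upper[-1] = terminal_cap if terminal_cap is not None else DEFAULT_TERMINAL_CAP
        upper_t = tuple(float(u) for u in upper)  # type: ignore[arg-type]
        cap = float(terminal_cap) if terminal_cap is not None else float(upper_t[-1])
        return cls(labels=labels, lower=lower, upper=upper_t, terminal_cap=cap)

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def midpoints(self) -> np.ndarray:
        """Class midpoints t_j = (lower_j + upper_j) / 2, in months."""
        return (np.asarray(self.lower) + np.asarray(self.upper)) / 2.0

    @property
    def boundaries(self) -> np.ndarray:
        """Class boundaries 0 = b_0 < b_1 < ... < b_T = terminal_cap."""
        return np.concatenate([[0.0], np.asarray(self.upper)])

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"age class {label!r} not in schema") from None


@dataclass(frozen=True)
class ModernHerdTable:
    """Sex-by-age census counts for modern unimproved herds.

    ``survivors[h, s, j]`` is the number of animals of sex ``s`` (0 = female,
    1 = male) alive at the midpoint of age class ``j`` in herd ``h``;
    ``population[h, j]`` is the herd population-size offset for that cell.
    """

    herd_ids: tuple[str, ...]
    survivors: np.ndarray  # (n_herds, 2, n_classes) int
    population: np.ndarray  # (n_herds, n_classes) int
    schema: AgeClassSchema

    def __post_init__(self) -> None:
        n_h, n_s, n_j = self.survivors.shape
        if n_s != 2 or n_j != self.schema.n_classes or n_h != len(self.herd_ids):
            raise ValidationError("survivors array shape does not match herds/schema")
        if self.population.shape != (n_h, n_j):
            raise ValidationError("population array shape does not match herds/schema")
        if np.any(self.survivors < 0):
            raise ValidationError("negative survivor count")
        if np.any(self.population <= 0):
            raise ValidationError("population sizes must be positive")
        if np.any(self.survivors > self.population[:, None, :]):
            raise ValidationError("survivor count exceeds population size")

    @property
    def n_herds(self) -> int:
        return len(self.herd_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h, hid in enumerate(self.herd_ids):
            for s in (SEX_FEMALE, SEX_MALE):
                for j, lab in enumerate(self.schema.labels):
                    rows.append(
                        dict(
                            herd_id=hid,
                            sex=s,
                            age_class=lab,
                            survivors=int(self.survivors[h, s, j]),
                            population=int(self.population[h, j]),
                        )
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True, eq=False)
class KillOffProfile:
    """Unsexed death counts per age class for one archaeological site.

    Individuals whose age class is uncertain are carried as per-individual
    candidate sets (contiguous runs of class indices) and imputed during
    MCMC rather than split fractionally.
    """

    site_id: str
    schema: AgeClassSchema
    fixed_counts: np.ndarray  # (n_classes,) int
    ambiguous: tuple[tuple[int, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        counts = np.asarray(self.fixed_counts)
        if counts.shape != (self.schema.n_classes,):
            raise ValidationError("fixed_counts length does not match schema")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("fixed_counts must be non-negative integers")
        for cand in self.ambiguous:
            if len(cand) < 2:
                raise ValidationError("candidate set must list at least 2 classes")
            idx = sorted(cand)
            if idx[0] < 0 or idx[-1] >= self.schema.n_classes:
                raise ValidationError("candidate class index out of range")
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ValidationError(f"candidate set {tuple(sorted(cand))} is not a contiguous run")
        if self.total < 1:
            raise ValidationError("profile contains no individuals")

    @property
    def total(self) -> int:
        """N_k. — fixed individuals plus ambiguously assigned ones."""
        return int(np.sum(self.fixed_counts)) + len(self.ambiguous)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KillOffProfile):
            return NotImplemented
        return (
            self.site_id == other.site_id
            and self.schema == other.schema
            and np.array_equal(self.fixed_counts, other.fixed_counts)
            and tuple(tuple(sorted(c)) for c in self.ambiguous)
            == tuple(tuple(sorted(c)) for c in other.ambiguous)
        )


@dataclass(frozen=True)
class ProductivityConstants:
    """Ethnographic productivity constants for unimproved cattle.

    Defaults are averages for modern unimproved African herds: milk while
    suckling (kg/month), suckling period and calving interval (months), age
    at first calving (months), the fraction of milk consumed by calves, the
    meat-and-offal (MOW) fraction of live weight, daily dry-matter feed
    intake as a fraction of live weight, and per-kg macronutrient/energy
    densities of milk and MOW.
    """

    milk_suckling: float = 42.3  # kg/month while a calf is suckling
    suckling_months: float = 9.18
    calving_interval: float = 18.36  # months
    age_first_calving: float = 42.0  # months
    calf_milk_fraction: float = 0.684
    mow_fraction_of_liveweight: float = 0.4995
    feed_daily_fraction: float = 0.02475  # of live weight per day
    milk_protein: float = 0.0333  # kg/kg
    milk_fat: float = 0.0375  # kg/kg
    milk_kcal: float = 670.0  # kcal/kg
    mow_protein: float = 0.1942  # kg/kg
    mow_fat: float = 0.1273  # kg/kg
    mow_kcal: float = 1980.0  # kcal/kg

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValidationError(f"constant {name} must be strictly positive")
        for name in ("calf_milk_fraction", "mow_fraction_of_liveweight", "feed_daily_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"constant {name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "ProductivityConstants":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown productivity constants: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: float(getattr(self, k)) for k in self.__dataclass_fields__},
                fh,
                sort_keys=False,
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_schema(path: str | Path) -> AgeClassSchema:
    """Read an age-class schema from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "classes" not in data:
        raise ValidationError(f"{path}: schema file needs a 'classes' list")
    classes = []
    for entry in data["classes"]:
        upper = entry.get("upper", None)
        classes.append((entry["label"], float(entry["lower"]), None if upper is None else float(upper)))
    cap = data.get("terminal_cap", None)
    return AgeClassSchema.from_bounds(classes, terminal_cap=None if cap is None else float(cap))


def write_schema(schema: AgeClassSchema, path: str | Path) -> None:
    data = {
        "classes": [
            {"label": lab, "lower": float(lo), "upper": float(up)}
            for lab, lo, up in zip(schema.labels, schema.lower, schema.upper)
        ],
        "terminal_cap": float(schema.terminal_cap),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_modern_table(path: str | Path, schema: AgeClassSchema) -> ModernHerdTable:
    """Read a modern herd census CSV (one row per herd x sex x class)."""
    df = pd.read_csv(path, comment="#")
    required = {"herd_id", "sex", "age_class", "survivors", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return modern_table_from_frame(df, schema)


def modern_table_from_frame(df: pd.DataFrame, schema: AgeClassSchema) -> ModernHerdTable:
    if df.duplicated(["herd_id", "sex", "age_class"]).any():
        dup = df[df.duplicated(["herd_id", "sex", "age_class"])].iloc[0]
        raise ValidationError(
            f"duplicate row for herd {dup['herd_id']!r}, sex {dup['sex']}, class {dup['age_class']!r}"
        )
    herd_ids = tuple(dict.fromkeys(df["herd_id"].astype(str)))
    n_h, n_j = len(herd_ids), schema.n_classes
    if len(df) != n_h * 2 * n_j:
        raise ValidationError(
            f"expected {n_h * 2 * n_j} rows (complete herd x sex x class grid), got {len(df)}"
        )
    surv = np.zeros((n_h, 2, n_j), dtype=np.int64)
    pop = np.zeros((n_h, n_j), dtype=np.int64)
    seen_pop = np.zeros((n_h, n_j), dtype=bool)
    h_index = {hid: h for h, hid in enumerate(herd_ids)}
    for row in df.itertuples(index=False):
        s = int(row.sex)
        if s not in (SEX_FEMALE, SEX_MALE):
            raise ValidationError(f"sex must be 0 (female) or 1 (male), got {row.sex!r}")
        h = h_index[str(row.herd_id)]
        j = schema.index_of(str(row.age_class))
        surv[h, s, j] = int(row.survivors)
        if seen_pop[h, j] and pop[h, j] != int(row.population):
            raise ValidationError(
                f"inconsistent population for herd {row.herd_id!r}, class {row.age_class!r}"
            )
        pop[h, j] = int(row.population)
        seen_pop[h, j] = True
    return ModernHerdTable(herd_ids=herd_ids, survivors=surv, population=pop, schema=schema)


def write_modern_table(table: ModernHerdTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_killoff(
    path: str | Path,
    schema: AgeClassSchema,
    ambiguity_path: str | Path | None = None,
) -> list[KillOffProfile]:
    """Read kill-off profiles (one or more sites) from CSV.

    ``ambiguity_path`` optionally adds individuals assigned to several
    adjacent classes (``candidate_classes`` column, labels separated by ``|``).
    """
    df = pd.read_csv(path, comment="#")
    required = {"site_id", "age_class", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    amb: dict[str, list[tuple[int, ...]]] = {}
    if ambiguity_path is not None:
        adf = pd.read_csv(ambiguity_path, comment="#")
        for row in adf.itertuples(index=False):
            labels = [lab.strip() for lab in str(row.candidate_classes).split("|")]
            cand = tuple(schema.index_of(lab) for lab in labels)
            amb.setdefault(str(row.site_id), []).append(cand)
    profiles = []
    for site_id, grp in df.groupby("site_id", sort=False):
        if grp.duplicated("age_class").any():
            raise ValidationError(f"site {site_id!r}: duplicate age-class rows")
        counts = np.zeros(schema.n_classes, dtype=np.int64)
        for row in grp.itertuples(index=False):
            counts[schema.index_of(str(row.age_class))] = int(row.count)
        profiles.append(
            KillOffProfile(
                site_id=str(site_id),
                schema=schema,
                fixed_counts=counts,
                ambiguous=tuple(amb.get(str(site_id), [])),
            )
        )
    return profiles


def write_killoff(
    profiles: list[KillOffProfile],
    path: str | Path,
    ambiguity_path: str | Path | None = None,
) -> None:
    rows = []
    amb_rows = []
    for prof in profiles:
        for j, lab in enumerate(prof.schema.labels):
            rows.append(dict(site_id=prof.site_id, age_class=lab, count=int(prof.fixed_counts[j])))
        for i, cand in enumerate(prof.ambiguous):
            labels = "|".join(prof.schema.labels[j] for j in sorted(cand))
            amb_rows.append(dict(site_id=prof.site_id, individual_id=i, candidate_classes=labels))
    pd.DataFrame(rows).to_csv(path, index=False)
    if ambiguity_path is not None:
        pd.DataFrame(amb_rows, columns=["site_id", "individual_id", "candidate_classes"]).to_csv(
            ambiguity_path, index=False
        )


def legge_schema(terminal_cap: float = DEFAULT_TERMINAL_CAP) -> AgeClassSchema:
    """The 9-class tooth eruption/wear schema with boundaries (in months)
    0, 1, 8, 18, 30, 36, 48, 78, 108 and an open-ended adult class."""
    bounds = [0.0, 1.0, 8.0, 18.0, 30.0, 36.0, 48.0, 78.0, 108.0, terminal_cap]
    classes = [
        (f"C{j + 1}", bounds[j], bounds[j + 1]) for j in range(len(bounds) - 1)
    ]
    return AgeClassSchema.from_bounds(classes, terminal_cap=terminal_cap)
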