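"""Cohort data model, trait registry, file I/O, validation and TIPI scoring.

The unit of every analysis is a long-format partner table: one row per
(respondent, partner), a father flag, and one column per registered trait.
Traits come in three families — demographic, physical (ordinal image scales),
and personality (TIPI domain scores) — and every trait carries an explicit
scale so out-of-range entries are caught at load time. Missing cells are kept
missing; nothing is ever imputed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Reserved (non-trait) columns of the long-format cohort CSV.
ID_COLUMNS = ("respondent_id", "partner_ordinal", "is_father")
OPTIONAL_COLUMNS = ("relationship_length_years",)

TRAIT_FAMILIES = ("demographic", "physical", "personality")


@dataclass(frozen=True)
class TraitSpec:
    """Registry entry for one partner trait.

    ``scale_min``/``scale_max`` bound admissible values (e.g. eye colour is
    coded 1–5 in the order gray, blue, green, brown, black; hair colour 1–9
    light to dark; TIPI domains 2–14). ``integer_valued`` marks ordinal
    image/Likert scales that only take whole-number codes.
    """

    name: str
    family: str
    scale_min: float
    scale_max: float
    integer_valued: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in TRAIT_FAMILIES:
            raise ValueError(f"unknown trait family {self.family!r}")
        if not self.scale_min < self.scale_max:
            raise ValueError(
                f"trait {self.name!r}: scale_min must be < scale_max "
                f"({self.scale_min} >= {self.scale_max})"
            )


class TraitRegistry(Mapping[str, TraitSpec]):
    """Ordered mapping of trait name -> TraitSpec; each trait appears once."""

    def __init__(self, specs: Iterable[TraitSpec]):
        self._specs: dict[str, TraitSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate trait {spec.name!r} in registry")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> TraitSpec:
        return self._specs[name]

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_entries(raw["traits"])

    @classmethod
    def _from_entries(cls, entries: Sequence[Mapping]) -> "TraitRegistry":
        return cls(
            TraitSpec(
                name=e["name"],
                family=e["family"],
                scale_min=float(e["scale_min"]),
                scale_max=float(e["scale_max"]),
                integer_valued=bool(e.get("integer_valued", True)),
                description=str(e.get("description", "")),
            )
            for e in entries
        )

    def to_yaml(self, path: str | Path) -> None:
        entries = [
            {
                "name": s.name,
                "family": s.family,
                "scale_min": s.scale_min,
                "scale_max": s.scale_max,
                "integer_valued": s.integer_valued,
                "description": s.description,
            }
            for s in self._specs.values()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"traits": entries}, fh, sort_keys=False)


def default_registry() -> TraitRegistry:
    """The standard 21-trait registry: 3 demographic, 13 physical, 5 TIPI domains."""
    path = importlib.resources.files("mateperm") / "_data" / "registry_default.yaml"
    with importlib.resources.as_file(path) as p:
        return TraitRegistry.from_yaml(p)


def tipi_domain_score(direct_item: float, reversed_item: float) -> float:
    """Score one TIPI Big Five domain from its direct and reverse-keyed items.

    Both items are 7-point Likert responses; the domain score is
    ``direct + (8 - reversed)``, ranging 2–14.
    """
    for v, label in ((direct_item, "direct_item"), (reversed_item, "reversed_item")):
        if not 1 <= v <= 7:
            raise ValueError(f"{label}={v} outside the 1-7 Likert range")
    return direct_item + (8 - reversed_item)


@dataclass(frozen=True)
class PartnerRecord:
    """One partner of one respondent: trait values, father flag, listing order."""

    respondent_id: str
    partner_ordinal: int
    is_father: bool
    traits: Mapping[str, float | None] = field(default_factory=dict)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    #: per-trait (n informative respondents, n informative partners)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass(frozen=True)
class TraitSlots:
    """Per-trait 'slot' view of a cohort used by all permutation machinery.

    Only informative respondents (>= 2 non-missing partner values for the
    trait) contribute. Partners appear as flat slots grouped contiguously by
    respondent; pair index arrays enumerate all within-respondent unordered
    pairs so the consistency index and its permutations vectorise.
    """

    values: np.ndarray          # float, shape (n_slots,), or (n_slots, k) for multi-trait
    group_sizes: np.ndarray     # int, per informative respondent
    group_offsets: np.ndarray   # int, start slot of each group
    respondent_ids: np.ndarray  # object, per group
    row_index: np.ndarray       # original cohort row position per slot
    is_father: np.ndarray       # bool, per slot
    pair_a: np.ndarray          # int, global slot index of first pair member
    pair_b: np.ndarray          # int, second pair member
    pair_group: np.ndarray      # int, group index of each pair
    pairs_per_group: np.ndarray # int, p_i * (p_i - 1) / 2

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_slots(self) -> int:
        return int(self.group_sizes.sum())


def _build_slots(df: pd.DataFrame, value_cols: Sequence[str]) -> TraitSlots:
    sub = df.dropna(subset=list(value_cols))
    sizes = sub.groupby("respondent_id", sort=True).size()
    keep = sizes[sizes >= 2].index
    sub = sub[sub["respondent_id"].isin(keep)].sort_values(
        ["respondent_id", "partner_ordinal"], kind="stable"
    )
    group_sizes = sub.groupby("respondent_id", sort=True).size().to_numpy()
    offsets = np.concatenate([[0], np.cumsum(group_sizes)[:-1]]).astype(np.int64)
    pair_a, pair_b, pair_group = [], [], []
    for g, (off, p) in enumerate(zip(offsets, group_sizes)):
        idx = np.arange(off, off + p)
        ja, jb = np.triu_indices(p, k=1)
        pair_a.append(idx[ja])
        pair_b.append(idx[jb])
        pair_group.append(np.full(len(ja), g, dtype=np.int64))
    values = sub[list(value_cols)].to_numpy(dtype=float)
    if len(value_cols) == 1:
        values = values[:, 0]
    return TraitSlots(
        values=values,
        group_sizes=group_sizes.astype(np.int64),
        group_offsets=offsets,
        respondent_ids=sub.groupby("respondent_id", sort=True).size().index.to_numpy(),
        row_index=sub.index.to_numpy(),
        is_father=sub["is_father"].to_numpy(dtype=bool),
        pair_a=np.concatenate(pair_a) if pair_a else np.empty(0, dtype=np.int64),
        pair_b=np.concatenate(pair_b) if pair_b else np.empty(0, dtype=np.int64),
        pair_group=np.concatenate(pair_group) if pair_group else np.empty(0, dtype=np.int64),
        pairs_per_group=(group_sizes * (group_sizes - 1) // 2).astype(np.int64),
    )


class CohortTable:
    """All respondents' partner records plus the trait registry.

    Thin wrapper over a long-format :class:`pandas.DataFrame` (one row per
    partner) that exposes the per-trait informative-slot views every
    downstream analysis consumes.
    """

    def __init__(self, df: pd.DataFrame, registry: TraitRegistry, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.registry = registry
        if validate:
            report = self.validate()
            if not report.ok:
                msgs = "; ".join(f"{loc}: {rule}" for loc, rule in report.errors[:10])
                raise ValueError(f"cohort failed validation: {msgs}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[PartnerRecord], registry: TraitRegistry, validate: bool = True
    ) -> "CohortTable":
        rows = []
        for r in records:
            row = {
                "respondent_id": r.respondent_id,
                "partner_ordinal": r.partner_ordinal,
                "is_father": int(r.is_father),
            }
            for t in registry.names:
                row[t] = r.traits.get(t, np.nan)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(ID_COLUMNS) + registry.names)
        return cls(df, registry, validate=validate)

    # -- basic properties --------------------------------------------------

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_partners(self) -> int:
        return len(self.df)

    @property
    def partner_counts(self) -> pd.Series:
        return self.df.groupby("respondent_id", sort=True).size()

    # -- validation --------------------------------------------------------

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        df = self.df
        for col in ID_COLUMNS:
            if col not in df.columns:
                report.errors.append(("<table>", f"missing required column {col!r}"))
                return report
        counts = df.groupby("respondent_id").size()
        for rid, c in counts.items():
            if c < 2:
                report.errors.append(
                    (f"respondent {rid}", "respondent below minimum partner count (2)")
                )
        dup = df.duplicated(subset=["respondent_id", "partner_ordinal"])
        for i in df.index[dup]:
            report.errors.append(
                (f"row {i}", "partner_ordinal not unique within respondent")
            )
        for trait, spec in self.registry.items():
            if trait not in df.columns:
                report.errors.append(("<table>", f"registered trait {trait!r} missing from table"))
                continue
            vals = df[trait]
            bad = vals.notna() & ((vals < spec.scale_min) | (vals > spec.scale_max))
            for i in df.index[bad]:
                report.errors.append(
                    (
                        f"row {i}",
                        f"trait {trait!r} value {vals[i]} outside "
                        f"[{spec.scale_min}, {spec.scale_max}]",
                    )
                )
            slots = _build_slots(df, [trait]) if not report.errors else None
            if slots is not None:
                report.counts[trait] = (slots.n_groups, slots.n_slots)
        extra = set(df.columns) - set(ID_COLUMNS) - set(OPTIONAL_COLUMNS) - set(self.registry.names)
        for col in sorted(extra):
            report.warnings.append(f"unregistered column {col!r} ignored")
        return report

    # -- slot views --------------------------------------------------------

    def trait_slots(self, trait: str) -> TraitSlots:
        """Informative-slot view for one trait (respondents with >=2 values)."""
        if trait not in self.registry:
            raise KeyError(f"unknown trait {trait!r}")
        return _build_slots(self.df, [trait])

    def multi_trait_slots(self, traits: Sequence[str]) -> TraitSlots:
        """Slot view on the pairwise/listwise-complete partner subset for several traits."""
        for t in traits:
            if t not in self.registry:
                raise KeyError(f"unknown trait {t!r}")
        return _build_slots(self.df, list(traits))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = list(ID_COLUMNS) + [
            c for c in OPTIONAL_COLUMNS if c in self.df.columns
        ] + self.registry.names
        self.df.to_csv(path, index=False, columns=cols)


def load_cohort(path: str | Path, registry_path: str | Path | None = None,
                registry: TraitRegistry | None = None) -> CohortTable:
    """Read and validate a long-format partner CSV.

    Empty cells are kept as missing. Raises ``ValueError`` on unknown trait
    columns, out-of-scale values, or respondents with fewer than two partners
    (the cohort inclusion rule).
    """
    if registry is None:
        registry = (
            TraitRegistry.from_yaml(registry_path) if registry_path else default_registry()
        )
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    unknown = set(df.columns) - set(ID_COLUMNS) - set(OPTIONAL_COLUMNS) - set(registry.names)
    if unknown:
        raise ValueError(f"unknown trait columns in cohort CSV: {sorted(unknown)}")
    absent = [t for t in registry.names if t not in df.columns]
    if absent:
        raise ValueError(f"registered traits missing from cohort CSV: {absent}")
    return CohortTable(df, registry)


# -- results tables --------------------------------------------------------

#: Fixed column orders of the result CSVs (analogues of the study's Tables 1-4).
TABLE_SCHEMAS: dict[str, list[str]] = {
    "table1_consistency.csv": [
        "trait", "observed_delta", "expected_delta", "expected_sd", "p", "p_adj",
        "p_formatted", "effect_pct", "ci_lo", "ci_hi", "icc_pct", "pearson_r",
        "n_respondents_informative", "n_partners_informative",
    ],
    "table2_shared_effects.csv": None,  # square trait x trait layout, set at write time
    "table3_father_exclusion.csv": [
        "trait", "observed_change", "expected_change_mean", "expected_change_sd",
        "p", "p_adj", "p_formatted",
    ],
    "table4_father_models.csv": [
        "trait", "mean_intercept_nonfather", "mean_effect_father", "mean_se",
        "mean_p", "mean_p_adj", "var_intercept_nonfather", "var_effect_father",
        "var_se", "var_p", "var_p_adj",
    ],
}


def format_p(p: float) -> str:
    """Presentation string for a p-value; numeric values stay in their own column."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_results_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result DataFrames as CSVs with fixed, documented column order.

    ``results`` maps a known table file name (see ``TABLE_SCHEMAS``) to a
    DataFrame; empty frames produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        if name not in TABLE_SCHEMAS:
            raise KeyError(f"unknown results table {name!r}")
        schema = TABLE_SCHEMAS[name]
        path = out_dir / name
        if schema is None:
            df.to_csv(path)
        else:
            out = df.reindex(columns=schema) if len(df) else pd.DataFrame(columns=schema)
            out.to_csv(path, index=False)
        written.append(path)
    return written
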