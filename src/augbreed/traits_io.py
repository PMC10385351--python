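"""Trial data model, fruit-level trait derivation and tabular I/O.

The central container is :class:`TrialTable`, one row per genotype x block
plot of an augmented block trial: a small set of replicated *check*
cultivars appears once in every block, while each unreplicated *test*
genotype appears in exactly one block.  Plot-level traits are either read
directly from a CSV table or derived from fruit-level records (mass,
diameter, firmness, CIELab colour) with :func:`aggregate_plot`.

Colorimetry follows the CIELab convention: the hue angle is the angle of
the (a, b) chromaticity vector, in degrees, and chroma is its length.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ID_COLUMNS = ("genotype_id", "population_id", "role", "block")
ROLE_CHECK = "check"
ROLE_TEST = "test"

#: Role spellings accepted on input and their canonical form.
DEFAULT_ROLE_ALIASES: Mapping[str, str] = {
    "check": ROLE_CHECK,
    "control": ROLE_CHECK,
    "standard": ROLE_CHECK,
    "test": ROLE_TEST,
    "regular": ROLE_TEST,
    "new": ROLE_TEST,
}

#: Traits that can be derived from fruit-level records.  TSS is measured on
#: homogenized pulp and therefore arrives at plot level, not per fruit.
FRUIT_DERIVED_TRAITS = (
    "TFM", "TFN", "AFM", "CFM", "CFN", "ACFM", "F", "L", "Hue", "C",
)

DEFAULT_MARKETABLE_MIN_DIAMETER = 35.0  # mm; fruits strictly larger count


class TrialValidationError(ValueError):
    """A trial table violates the augmented-block layout invariants."""


class UndefinedHueError(ValueError):
    """Hue angle requested for a fruit with a = b = 0 (achromatic point)."""


# ---------------------------------------------------------------------------
# colorimetry
# ---------------------------------------------------------------------------

def hue_angle(a, b):
    """Hue angle (degrees in [0, 360)) of CIELab chromaticity (a, b).

    Uses the two-argument arctangent so all four quadrants are resolved;
    for a > 0, b > 0 this equals ``degrees(arctan(b / a))``.  Accepts
    scalars or arrays.

    Raises
    ------
    UndefinedHueError
        If any (a, b) pair is exactly (0, 0), where hue is undefined.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any((a_arr == 0.0) & (b_arr == 0.0)):
        raise UndefinedHueError("hue angle is undefined at a = b = 0")
    deg = np.degrees(np.arctan2(b_arr, a_arr)) % 360.0
    if np.isscalar(a) and np.isscalar(b):
        return float(deg)
    return deg


def chroma(a, b):
    """Chroma ``sqrt(a**2 + b**2)``: colour purity/intensity. Array-safe."""
    c = np.hypot(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    if np.isscalar(a) and np.isscalar(b):
        return float(c)
    return c


# ---------------------------------------------------------------------------
# fruit records and plot aggregation
# ---------------------------------------------------------------------------

@dataclass
class FruitRecord:
    """A single fruit measurement within a plot.

    ``firmness_readings`` holds the penetrometer readings taken on this
    fruit (typically two, at points equidistant from the centre); ``L``,
    ``a``, ``b`` are the CIELab coordinates averaged over the colorimeter
    points on the fruit surface.
    """

    genotype_id: str
    block: str
    mass: float          # g
    diameter: float      # mm
    firmness_readings: Sequence[float] = field(default_factory=tuple)
    L: float = math.nan
    a: float = math.nan
    b: float = math.nan
    harvest_date: str | None = None

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"fruit mass must be positive, got {self.mass}")
        if not self.diameter > 0:
            raise ValueError(
                f"fruit diameter must be positive, got {self.diameter}")
        if any(f < 0 for f in self.firmness_readings):
            raise ValueError("firmness readings must be non-negative")
        if not math.isnan(self.L) and not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L must be within [0, 100], got {self.L}")


def aggregate_plot(
    records: Sequence[FruitRecord],
    marketable_min_diameter: float = DEFAULT_MARKETABLE_MIN_DIAMETER,
) -> dict[str, float]:
    """Collapse the fruit records of one plot into plot-level traits.

    Production traits: TFM (total fruit mass, g), TFN (count), AFM
    (TFM/TFN); their commercial counterparts CFM/CFN/ACFM are restricted
    to fruits with diameter strictly greater than
    ``marketable_min_diameter`` (35 mm by default).  Post-harvest traits:
    F is the mean of all firmness readings pooled over fruits; L, Hue and
    C are per-fruit values (hue/chroma computed from each fruit's own
    a, b) averaged over fruits.

    A plot with no marketable fruit gets CFM = CFN = 0 and ACFM missing
    (NaN).  An empty record list is an error.
    """
    if not records:
        raise ValueError("aggregate_plot requires at least one fruit record")

    masses = np.array([r.mass for r in records], dtype=float)
    diameters = np.array([r.diameter for r in records], dtype=float)

    traits: dict[str, float] = {}
    traits["TFM"] = float(masses.sum())
    traits["TFN"] = float(len(records))
    traits["AFM"] = traits["TFM"] / traits["TFN"]

    marketable = diameters > marketable_min_diameter
    traits["CFN"] = float(marketable.sum())
    traits["CFM"] = float(masses[marketable].sum())
    if traits["CFN"] > 0:
        traits["ACFM"] = traits["CFM"] / traits["CFN"]
    else:
        traits["ACFM"] = math.nan
        logger.warning(
            "plot (%s, block %s): no marketable fruit > %g mm; ACFM missing",
            records[0].genotype_id, records[0].block, marketable_min_diameter)

    firmness = [f for r in records for f in r.firmness_readings]
    traits["F"] = float(np.mean(firmness)) if firmness else math.nan

    lightness = np.array([r.L for r in records], dtype=float)
    traits["L"] = float(np.nanmean(lightness)) if not np.all(
        np.isnan(lightness)) else math.nan

    hues, chromas = [], []
    for r in records:
        if math.isnan(r.a) or math.isnan(r.b):
            continue
        hues.append(hue_angle(r.a, r.b))
        chromas.append(chroma(r.a, r.b))
    traits["Hue"] = float(np.mean(hues)) if hues else math.nan
    traits["C"] = float(np.mean(chromas)) if chromas else math.nan
    return traits


def plots_from_fruit_table(
    fruit_table: pd.DataFrame | str | Path,
    marketable_min_diameter: float = DEFAULT_MARKETABLE_MIN_DIAMETER,
) -> pd.DataFrame:
    """Aggregate a fruit-level CSV/DataFrame into a plot-level trait table.

    Expects columns ``genotype_id``, ``block``, ``mass``, ``diameter`` and
    optionally ``population_id``, ``role``, ``L``, ``a``, ``b`` plus any
    number of columns starting with ``firmness`` (one per reading).
    """
    if not isinstance(fruit_table, pd.DataFrame):
        fruit_table = pd.read_csv(fruit_table)
    firmness_cols = [c for c in fruit_table.columns if c.startswith("firmness")]

    rows = []
    keys = ["genotype_id", "block"]
    for (genotype, block), grp in fruit_table.groupby(keys, sort=False):
        records = []
        for _, r in grp.iterrows():
            readings = tuple(
                float(r[c]) for c in firmness_cols if pd.notna(r[c]))
            records.append(FruitRecord(
                genotype_id=str(genotype), block=str(block),
                mass=float(r["mass"]), diameter=float(r["diameter"]),
                firmness_readings=readings,
                L=float(r.get("L", math.nan)),
                a=float(r.get("a", math.nan)),
                b=float(r.get("b", math.nan)),
            ))
        row = {"genotype_id": str(genotype), "block": str(block)}
        for extra in ("population_id", "role"):
            if extra in grp.columns:
                row[extra] = grp[extra].iloc[0]
        row.update(aggregate_plot(records, marketable_min_diameter))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """A registered trait: its name, direction of improvement and units.

    ``direction`` is +1 when larger values are favourable (mass, counts,
    soluble solids...) and -1 when smaller values are favourable.
    """

    name: str
    direction: int = +1
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(
                f"trait {self.name!r}: direction must be +1 or -1, "
                f"got {self.direction}")


def read_trait_config(path: str | Path) -> list[TraitSpec]:
    """Read a YAML trait configuration.

    Format::

        traits:
          TFM: {direction: 1, units: g}
          Hue: {direction: 1, units: degrees}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    entries = raw["traits"] if isinstance(raw, Mapping) and "traits" in raw else raw
    specs = []
    for name, cfg in entries.items():
        cfg = cfg or {}
        specs.append(TraitSpec(
            name=str(name),
            direction=int(cfg.get("direction", +1)),
            units=str(cfg.get("units", ""))))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise TrialValidationError("duplicate trait names in configuration")
    return specs


def write_trait_config(specs: Sequence[TraitSpec], path: str | Path) -> None:
    payload = {"traits": {
        s.name: {"direction": s.direction, "units": s.units} for s in specs}}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSummary:
    """Shape of the augmented block design."""

    n_blocks: int
    n_checks: int
    n_tests: int
    check_ids: tuple[str, ...]
    tests_per_block: Mapping[str, int]


class TrialTable:
    """Plot-level observations of an augmented block trial.

    Wraps a :class:`pandas.DataFrame` with identifier columns
    ``genotype_id, population_id, role, block`` and one column per
    registered trait.  Validation enforces the augmented-block layout:
    every check appears exactly once in every block; every test genotype
    appears in exactly one block; all trait values are finite or missing.
    """

    def __init__(self, data: pd.DataFrame, traits: Sequence[TraitSpec],
                 validate: bool = True) -> None:
        self.data = data.reset_index(drop=True).copy()
        self.traits: dict[str, TraitSpec] = {t.name: t for t in traits}
        if len(self.traits) != len(traits):
            raise TrialValidationError("duplicate trait names in registry")
        if validate:
            self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    @property
    def blocks(self) -> list[str]:
        return sorted(self.data["block"].astype(str).unique())

    @property
    def checks(self) -> pd.DataFrame:
        return self.data[self.data["role"] == ROLE_CHECK]

    @property
    def tests(self) -> pd.DataFrame:
        return self.data[self.data["role"] == ROLE_TEST]

    @property
    def check_ids(self) -> list[str]:
        return sorted(self.checks["genotype_id"].astype(str).unique())

    @property
    def test_ids(self) -> list[str]:
        return sorted(self.tests["genotype_id"].astype(str).unique())

    def design_summary(self) -> DesignSummary:
        per_block = self.tests.groupby("block")["genotype_id"].size()
        return DesignSummary(
            n_blocks=len(self.blocks),
            n_checks=len(self.check_ids),
            n_tests=len(self.test_ids),
            check_ids=tuple(self.check_ids),
            tests_per_block=per_block.to_dict(),
        )

    def test_values(self, trait: str) -> pd.DataFrame:
        """Non-missing test plots for one trait: genotype_id, block, value."""
        self._require_trait(trait)
        sub = self.tests[["genotype_id", "block", trait]].copy()
        return sub[sub[trait].notna()]

    def check_matrix(self, trait: str) -> pd.DataFrame:
        """Checks x blocks value matrix for one trait (complete required).

        Raises :class:`TrialValidationError` naming the first missing
        (check, block) cell: the error estimate depends on the complete
        check layout and no imputation is attempted.
        """
        self._require_trait(trait)
        pivot = self.checks.pivot_table(
            index="genotype_id", columns="block", values=trait,
            aggfunc="first", dropna=False)
        pivot = pivot.reindex(index=self.check_ids, columns=self.blocks)
        if pivot.isna().any().any():
            check, block = next(
                (i, c) for i in pivot.index for c in pivot.columns
                if pd.isna(pivot.at[i, c]))
            raise TrialValidationError(
                f"trait {trait!r}: check {check!r} has no observation in "
                f"block {block!r}; the check layout must be complete")
        return pivot

    def _require_trait(self, trait: str) -> None:
        if trait not in self.traits:
            raise TrialValidationError(f"trait {trait!r} is not registered")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        missing_cols = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise TrialValidationError(
                f"missing required columns: {missing_cols}")

        bad_roles = set(self.data["role"].unique()) - {ROLE_CHECK, ROLE_TEST}
        if bad_roles:
            raise TrialValidationError(
                f"unknown role labels {sorted(bad_roles)}; expected "
                f"{ROLE_CHECK!r} or {ROLE_TEST!r} (configure aliases on read)")

        extra = [c for c in self.data.columns
                 if c not in ID_COLUMNS and c not in self.traits]
        if extra:
            raise TrialValidationError(
                f"unregistered trait columns: {extra}")

        for trait in self.traits:
            if trait not in self.data.columns:
                raise TrialValidationError(
                    f"registered trait {trait!r} has no data column")
            values = self.data[trait]
            finite = np.isfinite(values.astype(float)) | values.isna()
            if not finite.all():
                raise TrialValidationError(
                    f"trait {trait!r} contains non-finite values")

        # layout: checks complete and unique per block
        checks = self.checks
        counts = checks.groupby(["genotype_id", "block"]).size()
        dup = counts[counts > 1]
        if not dup.empty:
            g, b = dup.index[0]
            raise TrialValidationError(
                f"check {g!r} appears {dup.iloc[0]} times in block {b!r}; "
                "checks must appear exactly once per block")
        blocks = self.blocks
        for check in self.check_ids:
            present = set(checks.loc[
                checks["genotype_id"] == check, "block"].astype(str))
            absent = [b for b in blocks if b not in present]
            if absent:
                raise TrialValidationError(
                    f"check {check!r} is missing from block {absent[0]!r}; "
                    "checks must appear in every block")

        # layout: each test genotype in exactly one block
        test_blocks = self.tests.groupby("genotype_id")["block"].nunique()
        multi = test_blocks[test_blocks > 1]
        if not multi.empty:
            raise TrialValidationError(
                f"test genotype {multi.index[0]!r} appears in "
                f"{multi.iloc[0]} blocks; tests are unreplicated")
        test_counts = self.tests.groupby(["genotype_id", "block"]).size()
        dup_t = test_counts[test_counts > 1]
        if not dup_t.empty:
            g, b = dup_t.index[0]
            raise TrialValidationError(
                f"test genotype {g!r} has {dup_t.iloc[0]} rows in block {b!r}")

        overlap = set(self.check_ids) & set(self.test_ids)
        if overlap:
            raise TrialValidationError(
                f"genotypes with both roles: {sorted(overlap)[:3]}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trial(
    path: str | Path,
    trait_config_path: str | Path | None = None,
    role_aliases: Mapping[str, str] | None = None,
) -> TrialTable:
    """Read a plot-level CSV into a validated :class:`TrialTable`.

    The CSV must carry the identifier columns ``genotype_id,
    population_id, role, block``; every other column is a trait.  When
    ``trait_config_path`` is given, trait columns must match the
    registered names and take their directions from the config; otherwise
    traits are auto-registered with direction +1.
    """
    df = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS})
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(
            f"{path}: missing required columns {missing}")

    aliases = dict(DEFAULT_ROLE_ALIASES)
    if role_aliases:
        aliases.update({k.lower(): v for k, v in role_aliases.items()})
    df["role"] = df["role"].str.lower().map(lambda r: aliases.get(r, r))

    trait_cols = [c for c in df.columns if c not in ID_COLUMNS]
    df[trait_cols] = df[trait_cols].astype(float)
    if trait_config_path is not None:
        specs = read_trait_config(trait_config_path)
        registered = {s.name for s in specs}
        unknown = [c for c in trait_cols if c not in registered]
        if unknown:
            raise TrialValidationError(
                f"{path}: unregistered trait columns {unknown}")
        specs = [s for s in specs if s.name in trait_cols]
    else:
        specs = [TraitSpec(name=c) for c in trait_cols]
    return TrialTable(df, specs)


def write_table(table: "TrialTable | pd.DataFrame", path: str | Path) -> None:
    """Write a trial table or any result DataFrame to CSV (UTF-8, '.')."""
    df = table.data if isinstance(table, TrialTable) else table
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex)
              or df.index.name is not None)
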