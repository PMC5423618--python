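"""Reading, validation and standardization of height and trait tables.

On-disk formats are plain UTF-8 CSV with a header row:

* heights:  ``individual_id, species, ecosystem, age_yrs, height_cm``
* traits:   ``species, ecosystem, sla, wood_density, seed_mass, leaf_n``

Validation reports offending rows by file line number (header = line 1) and
never repairs or drops them silently.  Trait standardization (z-scoring) is
always performed with *training* means and sds, so that species from a new
ecosystem are placed on the training scale — extrapolated z-scores are
allowed and not clipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

HEIGHT_COLUMNS = ("individual_id", "species", "ecosystem", "age_yrs", "height_cm")
TRAIT_COLUMNS = ("species", "ecosystem", "sla", "wood_density", "seed_mass", "leaf_n")
TRAIT_NAMES = ("sla", "wood_density", "seed_mass", "leaf_n")

__all__ = [
    "HEIGHT_COLUMNS",
    "TRAIT_COLUMNS",
    "TRAIT_NAMES",
    "FormatError",
    "ValidationError",
    "Dataset",
    "StandardizationStats",
    "read_heights",
    "read_traits",
    "write_heights",
    "write_traits",
    "validate_heights",
    "validate_traits",
    "standardize_traits",
    "load_config",
]


class FormatError(ValueError):
    """A file does not have the expected columns/shape."""


class ValidationError(ValueError):
    """Rows violate the data invariants; message lists the offenders."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _line(df_index: int) -> int:
    # file line number: +1 for the header, +1 for 1-based counting
    return int(df_index) + 2


def validate_heights(df: pd.DataFrame) -> list[str]:
    """Return invariant violations (empty list = valid). Does not mutate."""
    problems: list[str] = []
    age = pd.to_numeric(df["age_yrs"], errors="coerce")
    height = pd.to_numeric(df["height_cm"], errors="coerce")
    for idx in df.index[age.isna() | ~np.isfinite(age.fillna(np.inf))]:
        problems.append(f"line {_line(idx)}: age_yrs is not a finite number")
    for idx in df.index[height.isna()]:
        problems.append(f"line {_line(idx)}: height_cm is not a number")
    for idx in df.index[age < 0]:
        problems.append(f"line {_line(idx)}: age_yrs must be >= 0, got {age[idx]}")
    for idx in df.index[height <= 0]:
        problems.append(f"line {_line(idx)}: height_cm must be > 0, got {height[idx]}")
    dup = df.duplicated(subset=["individual_id", "ecosystem"], keep=False)
    for idx in df.index[dup & ~df.duplicated(subset=["individual_id", "ecosystem"])]:
        problems.append(
            f"line {_line(idx)}: duplicate (individual_id, ecosystem) "
            f"({df.at[idx, 'individual_id']!r}, {df.at[idx, 'ecosystem']!r})"
        )
    return problems


def validate_traits(df: pd.DataFrame) -> list[str]:
    """Return invariant violations for a trait table. Does not mutate."""
    problems: list[str] = []
    for trait in TRAIT_NAMES:
        vals = pd.to_numeric(df[trait], errors="coerce")
        for idx in df.index[vals.isna()]:
            problems.append(
                f"line {_line(idx)}: species {df.at[idx, 'species']!r} has missing/"
                f"non-numeric {trait}"
            )
        for idx in df.index[vals <= 0]:
            problems.append(
                f"line {_line(idx)}: species {df.at[idx, 'species']!r} has "
                f"non-positive {trait} ({vals[idx]})"
            )
        for idx in df.index[np.isinf(vals.fillna(0.0))]:
            problems.append(
                f"line {_line(idx)}: species {df.at[idx, 'species']!r} has "
                f"non-finite {trait}"
            )
    dup = df.duplicated(subset=["species", "ecosystem"], keep=False)
    for idx in df.index[dup & ~df.duplicated(subset=["species", "ecosystem"])]:
        problems.append(
            f"line {_line(idx)}: duplicate trait record for species "
            f"{df.at[idx, 'species']!r} in ecosystem {df.at[idx, 'ecosystem']!r}"
        )
    return problems


def read_heights(path) -> pd.DataFrame:
    """Read and validate a height-observation CSV."""
    df = pd.read_csv(path)
    _check_columns(df, HEIGHT_COLUMNS, path)
    problems = validate_heights(df)
    if problems:
        raise ValidationError(f"{path}: invalid height rows:\n" + "\n".join(problems))
    if df.empty:
        logger.warning("%s: height file contains a header but no rows", path)
    df = df[list(HEIGHT_COLUMNS)].copy()
    df["age_yrs"] = df["age_yrs"].astype(float)
    df["height_cm"] = df["height_cm"].astype(float)
    for col in ("individual_id", "species", "ecosystem"):
        df[col] = df[col].astype(str)
    return df


def read_traits(path) -> pd.DataFrame:
    """Read and validate a species trait CSV (one row per species/ecosystem)."""
    df = pd.read_csv(path)
    _check_columns(df, TRAIT_COLUMNS, path)
    problems = validate_traits(df)
    if problems:
        raise ValidationError(f"{path}: invalid trait rows:\n" + "\n".join(problems))
    if df.empty:
        logger.warning("%s: trait file contains a header but no rows", path)
    df = df[list(TRAIT_COLUMNS)].copy()
    for trait in TRAIT_NAMES:
        df[trait] = df[trait].astype(float)
    for col in ("species", "ecosystem"):
        df[col] = df[col].astype(str)
    return df


def write_heights(df: pd.DataFrame, path) -> None:
    df[list(HEIGHT_COLUMNS)].to_csv(path, index=False)


def write_traits(df: pd.DataFrame, path) -> None:
    df[list(TRAIT_COLUMNS)].to_csv(path, index=False)


@dataclass
class Dataset:
    """Joined height observations and species traits for >= 1 ecosystems."""

    heights: pd.DataFrame
    traits: pd.DataFrame

    @property
    def ecosystems(self) -> list[str]:
        return sorted(set(self.heights["ecosystem"]))

    @property
    def species(self) -> list[str]:
        return sorted(set(self.heights["species"]))

    def validate(self) -> None:
        """Raise ValidationError on any cross-table invariant violation."""
        problems = validate_heights(self.heights) + validate_traits(self.traits)
        trait_keys = set(zip(self.traits["species"], self.traits["ecosystem"]))
        for sp, eco in sorted(set(zip(self.heights["species"], self.heights["ecosystem"]))):
            if (sp, eco) not in trait_keys:
                problems.append(f"species {sp!r} in ecosystem {eco!r} has no trait record")
        for (sp, eco), grp in self.heights.groupby(["species", "ecosystem"]):
            if grp["age_yrs"].nunique() < 2:
                problems.append(
                    f"species {sp!r} in ecosystem {eco!r} has < 2 distinct ages; "
                    "the sigmoid is unidentifiable"
                )
        if problems:
            raise ValidationError("dataset invariant violations:\n" + "\n".join(problems))

    def subset(self, ecosystems) -> "Dataset":
        if isinstance(ecosystems, str):
            ecosystems = [ecosystems]
        keep = set(ecosystems)
        return Dataset(
            heights=self.heights[self.heights["ecosystem"].isin(keep)].reset_index(drop=True),
            traits=self.traits[self.traits["ecosystem"].isin(keep)].reset_index(drop=True),
        )

    @classmethod
    def from_files(cls, heights_path, traits_path, validate: bool = True) -> "Dataset":
        ds = cls(heights=read_heights(heights_path), traits=read_traits(traits_path))
        if validate:
            ds.validate()
        return ds

    def to_files(self, heights_path, traits_path) -> None:
        write_heights(self.heights, heights_path)
        write_traits(self.traits, traits_path)


@dataclass
class StandardizationStats:
    """Training means/sds used to z-score traits (per trait, raw or log scale).

    New-ecosystem traits must be standardized with *these* statistics, never
    their own; out-of-range values yield z-scores beyond the training range,
    which is intentional extrapolation and is not clipped.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    ecosystem: str = ""
    log_traits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t, s in self.sd.items():
            if not np.isfinite(s) or s <= 0:
                raise ValidationError(f"degenerate training trait {t!r}: sd = {s}")

    @classmethod
    def from_traits(
        cls,
        traits: pd.DataFrame,
        traits_used=TRAIT_NAMES,
        ecosystem: str = "",
        log_traits: tuple[str, ...] = (),
    ) -> "StandardizationStats":
        mean, sd = {}, {}
        for t in traits_used:
            x = traits[t].to_numpy(dtype=float)
            if t in log_traits:
                x = np.log(x)
            mean[t] = float(np.mean(x))
            sd[t] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return cls(mean=mean, sd=sd, ecosystem=ecosystem, log_traits=tuple(log_traits))

    def standardize_value(self, trait: str, x):
        x = np.asarray(x, dtype=float)
        if trait in self.log_traits:
            x = np.log(x)
        return (x - self.mean[trait]) / self.sd[trait]

    def unstandardize_value(self, trait: str, z):
        x = np.asarray(z, dtype=float) * self.sd[trait] + self.mean[trait]
        if trait in self.log_traits:
            x = np.exp(x)
        return x

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ecosystem": self.ecosystem,
            "log_traits": list(self.log_traits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationStats":
        return cls(
            mean=dict(d["mean"]),
            sd=dict(d["sd"]),
            ecosystem=d.get("ecosystem", ""),
            log_traits=tuple(d.get("log_traits", ())),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StandardizationStats":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def standardize_traits(traits: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    """Z-score every trait in ``stats`` using the training means/sds.

    Returns a new frame (species, ecosystem, z_<trait> ...); input is not
    mutated.
    """
    out = traits[["species", "ecosystem"]].copy()
    for trait in stats.mean:
        if trait not in traits.columns:
            raise FormatError(f"trait table lacks column {trait!r}")
        out[f"z_{trait}"] = stats.standardize_value(trait, traits[trait].to_numpy())
    return out


def load_config(path) -> dict:
    """Load a YAML (or JSON — a YAML subset) run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping at top level")
    return cfg
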