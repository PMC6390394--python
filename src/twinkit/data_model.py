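"""Core data types, validation, and CSV I/O for five-group twin data.

A dataset is a collection of twin *pairs* (families). Each family carries a
zygosity group label (``MZm``, ``DZm``, ``MZf``, ``DZf``, ``DOS``), the sex of
each twin, a shared age, and a ``2 x T`` matrix of trait scores (``NaN`` for
missing cells). Pairs are never listwise-deleted: missing cells are preserved
so that full-information likelihood methods can use partial pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Zygosity",
    "Sex",
    "ZygosityCoefficients",
    "Family",
    "TwinDataset",
    "TwinDataError",
    "zygosity_coefficients",
    "read_twin_csv",
    "write_twin_csv",
    "group_counts",
]


class TwinDataError(ValueError):
    """Raised when twin records violate structural invariants."""


class Zygosity(str, Enum):
    MZM = "MZm"
    DZM = "DZm"
    MZF = "MZf"
    DZF = "DZf"
    DOS = "DOS"


class Sex(str, Enum):
    M = "M"
    F = "F"


# sexes implied by each same-sex group label
_GROUP_SEXES: dict[Zygosity, tuple[Sex, Sex] | None] = {
    Zygosity.MZM: (Sex.M, Sex.M),
    Zygosity.DZM: (Sex.M, Sex.M),
    Zygosity.MZF: (Sex.F, Sex.F),
    Zygosity.DZF: (Sex.F, Sex.F),
    Zygosity.DOS: None,  # opposite-sex: twin 1 is male by convention
}


@dataclass(frozen=True)
class ZygosityCoefficients:
    """Cross-twin correlation coefficients for the A, D and C components.

    MZ pairs share all genes (alpha_A = alpha_D = 1); same-sex DZ pairs share
    on average half of additive effects (alpha_A = 0.5) and a quarter of
    dominance effects (alpha_D = 0.25); shared environment is fully shared in
    all rearing groups (alpha_C = 1).
    """

    alpha_A: float
    alpha_D: float
    alpha_C: float


def zygosity_coefficients(group: Zygosity) -> ZygosityCoefficients:
    """Default cross-twin coefficients for a zygosity group.

    Opposite-sex DZ pairs default to the same-sex DZ values; a freely
    estimated opposite-sex genetic correlation (if any) is handled by the
    model layer, not here.
    """
    if group in (Zygosity.MZM, Zygosity.MZF):
        return ZygosityCoefficients(1.0, 1.0, 1.0)
    return ZygosityCoefficients(0.5, 0.25, 1.0)


@dataclass
class Family:
    family_id: str
    zygosity: Zygosity
    sex1: Sex
    sex2: Sex
    age: float
    traits: np.ndarray  # shape (2, T), NaN = missing

    def validate(self, n_traits: int) -> None:
        t = np.asarray(self.traits, dtype=float)
        if t.shape != (2, n_traits):
            raise TwinDataError(
                f"family {self.family_id!r}: trait matrix shape {t.shape}, "
                f"expected (2, {n_traits})"
            )
        expected = _GROUP_SEXES[self.zygosity]
        if expected is not None:
            if (self.sex1, self.sex2) != expected:
                raise TwinDataError(
                    f"family {self.family_id!r}: zygosity {self.zygosity.value} "
                    f"requires sexes {expected[0].value}/{expected[1].value}, "
                    f"got {self.sex1.value}/{self.sex2.value}"
                )
        else:
            if self.sex1 == self.sex2:
                raise TwinDataError(
                    f"family {self.family_id!r}: DOS pair must be opposite-sex, "
                    f"got {self.sex1.value}/{self.sex2.value}"
                )
            if self.sex1 != Sex.M:
                raise TwinDataError(
                    f"family {self.family_id!r}: DOS twin 1 must be the male "
                    "(fixed ordering convention)"
                )
        if not math.isfinite(self.age):
            raise TwinDataError(f"family {self.family_id!r}: non-finite age")


@dataclass
class TwinDataset:
    """Validated collection of twin pairs with a shared trait list."""

    families: list[Family]
    trait_names: tuple[str, ...]
    age_range: tuple[float, float] | None = None
    bounded_traits: bool = False  # enforce raw scores in [0, 1]

    def __post_init__(self) -> None:
        self.trait_names = tuple(self.trait_names)
        self.validate()

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def __len__(self) -> int:
        return len(self.families)

    def validate(self) -> None:
        T = self.n_traits
        for fam in self.families:
            fam.validate(T)
            if self.age_range is not None:
                lo, hi = self.age_range
                if not (lo <= fam.age <= hi):
                    raise TwinDataError(
                        f"family {fam.family_id!r}: age {fam.age} outside "
                        f"declared range [{lo}, {hi}]"
                    )
            if self.bounded_traits:
                t = fam.traits
                bad = ~np.isnan(t) & ((t < 0) | (t > 1))
                if bad.any():
                    raise TwinDataError(
                        f"family {fam.family_id!r}: trait value outside [0, 1]"
                    )

    def trait_index(self, name: str) -> int:
        return self.trait_names.index(name)

    def group_families(self, group: Zygosity) -> list[Family]:
        return [f for f in self.families if f.zygosity == group]

    def pair_matrix(self, group: Zygosity | None = None) -> np.ndarray:
        """Stacked pair observations, shape ``(n_pairs, 2*T)``.

        Columns are twin 1's T traits followed by twin 2's T traits.
        """
        fams = self.families if group is None else self.group_families(group)
        if not fams:
            return np.empty((0, 2 * self.n_traits))
        return np.vstack([f.traits.reshape(-1) for f in fams])

    def individual_table(self) -> pd.DataFrame:
        """Long-format per-individual table (two rows per family)."""
        rows = []
        for fam in self.families:
            for k, sex in enumerate((fam.sex1, fam.sex2)):
                row: dict = {
                    "family_id": fam.family_id,
                    "zyg": fam.zygosity.value,
                    "member": k + 1,
                    "sex": sex.value,
                    "age": fam.age,
                }
                for j, name in enumerate(self.trait_names):
                    row[name] = fam.traits[k, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def with_traits(self, new_traits: Mapping[str, np.ndarray]) -> "TwinDataset":
        """Copy of the dataset with replaced trait values.

        ``new_traits[name]`` must have shape ``(n_families, 2)``.
        """
        fams = []
        for i, fam in enumerate(self.families):
            t = np.column_stack(
                [np.asarray(new_traits[name], dtype=float)[i] for name in self.trait_names]
            )  # (2, T)
            fams.append(
                Family(fam.family_id, fam.zygosity, fam.sex1, fam.sex2, fam.age, t)
            )
        return TwinDataset(fams, self.trait_names, age_range=self.age_range)


def group_counts(data: TwinDataset) -> dict[Zygosity, int]:
    """Number of pairs per zygosity group (all five groups always present)."""
    counts = Counter(f.zygosity for f in data.families)
    return {g: counts.get(g, 0) for g in Zygosity}


def _parse_enum(cls, raw: str, what: str, family_id: str):
    try:
        return cls(raw)
    except ValueError:
        valid = ", ".join(e.value for e in cls)
        raise TwinDataError(
            f"family {family_id!r}: malformed {what} {raw!r} (expected one of {valid})"
        ) from None


def read_twin_csv(
    path,
    trait_names: Sequence[str] | None = None,
    schema: Mapping[str, str] | None = None,
    age_range: tuple[float, float] | None = None,
) -> TwinDataset:
    """Read a wide one-row-per-family twin CSV.

    Expected columns (renameable through ``schema``, a mapping from canonical
    name to actual column name): ``family_id``, ``zyg``, ``sex1``, ``sex2``,
    ``age``, plus ``<trait>_1`` / ``<trait>_2`` per trait. When
    ``trait_names`` is omitted, traits are inferred from the paired
    ``*_1``/``*_2`` columns. Missing trait cells (empty strings) become NaN.
    Opposite-sex pairs are reordered male-first if needed.
    """
    schema = dict(schema or {})
    col = lambda name: schema.get(name, name)
    df = pd.read_csv(path, dtype={col("family_id"): str})

    for required in ("family_id", "zyg", "sex1", "sex2", "age"):
        if col(required) not in df.columns:
            raise TwinDataError(f"missing required column {col(required)!r}")

    if trait_names is None:
        trait_names = []
        for c in df.columns:
            if c.endswith("_1") and (c[:-2] + "_2") in df.columns:
                trait_names.append(c[:-2])
        if not trait_names:
            raise TwinDataError("no <trait>_1/<trait>_2 column pairs found")
    for t in trait_names:
        for suffix in ("_1", "_2"):
            if col(t + suffix) not in df.columns:
                raise TwinDataError(f"missing trait column {col(t + suffix)!r}")

    families = []
    for _, row in df.iterrows():
        fid = str(row[col("family_id")])
        zyg = _parse_enum(Zygosity, str(row[col("zyg")]), "zygosity label", fid)
        sex1 = _parse_enum(Sex, str(row[col("sex1")]), "sex", fid)
        sex2 = _parse_enum(Sex, str(row[col("sex2")]), "sex", fid)
        t1 = [pd.to_numeric(row[col(t + "_1")], errors="coerce") for t in trait_names]
        t2 = [pd.to_numeric(row[col(t + "_2")], errors="coerce") for t in trait_names]
        if zyg == Zygosity.DOS and sex1 == Sex.F and sex2 == Sex.M:
            sex1, sex2 = sex2, sex1
            t1, t2 = t2, t1
        traits = np.array([t1, t2], dtype=float)
        families.append(Family(fid, zyg, sex1, sex2, float(row[col("age")]), traits))
    return TwinDataset(families, tuple(trait_names), age_range=age_range)


def write_twin_csv(data: TwinDataset, path) -> None:
    """Write a dataset in the standard wide CSV layout (inverse of read)."""
    rows = []
    for fam in data.families:
        row: dict = {
            "family_id": fam.family_id,
            "zyg": fam.zygosity.value,
            "sex1": fam.sex1.value,
            "sex2": fam.sex2.value,
            "age": fam.age,
        }
        for j, name in enumerate(data.trait_names):
            row[f"{name}_1"] = fam.traits[0, j]
            row[f"{name}_2"] = fam.traits[1, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
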