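"""Synthetic family populations with the structure the analytic model assumes.

Families are generated independently. A family is schizotypal with
probability ``prop_schizotypal``; schizotypal families are low-fitness with
probability ``p_low`` and high-fitness otherwise. Each member of a
schizotypal family is diagnosed independently with probability
``p_diag_high`` (high-fitness) or ``r * p_diag_high`` (low-fitness);
members of non-schizotypal families with ``p_diag_nonschizotypal``
(default 0 — diagnosable conditions are treated as negligibly rare outside
schizotypal families). Offspring counts are Poisson with mean
``base_mean_offspring`` times the class relative fertility (``W_H``,
``W_L``, or 1 for non-schizotypal families).

Populations round-trip losslessly through a tab-separated text format with
the simulation parameters embedded in a JSON header line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .analytic import SSMParams

__all__ = [
    "SimulationParams",
    "FamilyRecord",
    "PopulationTable",
    "PopulationParseError",
    "simulate_population",
    "write_population",
    "read_population",
    "FITNESS_HIGH",
    "FITNESS_LOW",
    "FITNESS_NA",
]

FITNESS_HIGH = "high"
FITNESS_LOW = "low"
FITNESS_NA = "not_applicable"

_FORMAT_MAGIC = "# fertbias-population v1"
_COLUMNS = (
    "family_id",
    "schizotypal",
    "fitness_class",
    "n_members",
    "n_diagnosed",
    "offspring_counts",
)


@dataclass(frozen=True)
class SimulationParams:
    """Population-level knobs wrapped around the analytic parameters.

    ``diagnosed_fertility_factor`` optionally multiplies the expected
    offspring count of diagnosed members (default 1.0 = off): by default
    all fertility effects flow through class membership, since the
    class-mean difference ``d`` already subsumes the fertility cost of the
    disorder itself.
    """

    ssm: SSMParams
    n_families: int = 1000
    prop_schizotypal: float = 0.2
    family_size: int = 5
    p_diag_high: float = 0.01
    p_diag_nonschizotypal: float = 0.0
    base_mean_offspring: float = 2.0
    diagnosed_fertility_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError(f"n_families must be >= 1; got {self.n_families!r}")
        if self.family_size < 1:
            raise ValueError(f"family_size must be >= 1; got {self.family_size!r}")
        if not (0.0 <= self.prop_schizotypal <= 1.0):
            raise ValueError(f"prop_schizotypal must lie in [0, 1]; got {self.prop_schizotypal!r}")
        if not (self.p_diag_high > 0.0):
            raise ValueError(f"p_diag_high must be > 0; got {self.p_diag_high!r}")
        if self.ssm.r * self.p_diag_high > 1.0:
            raise ValueError(
                f"r * p_diag_high = {self.ssm.r * self.p_diag_high!r} exceeds 1; "
                "the low-fitness diagnosis probability must be a valid probability"
            )
        if not (0.0 <= self.p_diag_nonschizotypal < self.p_diag_high):
            raise ValueError(
                "p_diag_nonschizotypal must satisfy 0 <= p < p_diag_high; "
                f"got {self.p_diag_nonschizotypal!r}"
            )
        if not (self.base_mean_offspring > 0.0):
            raise ValueError(f"base_mean_offspring must be > 0; got {self.base_mean_offspring!r}")
        if not (self.diagnosed_fertility_factor > 0.0):
            raise ValueError(
                f"diagnosed_fertility_factor must be > 0; got {self.diagnosed_fertility_factor!r}"
            )
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError(f"seed must be an integer; got {self.seed!r}")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "ssm": self.ssm.to_dict(),
            "n_families": self.n_families,
            "prop_schizotypal": self.prop_schizotypal,
            "family_size": self.family_size,
            "p_diag_high": self.p_diag_high,
            "p_diag_nonschizotypal": self.p_diag_nonschizotypal,
            "base_mean_offspring": self.base_mean_offspring,
            "diagnosed_fertility_factor": self.diagnosed_fertility_factor,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParams":
        data = dict(data)
        data["ssm"] = SSMParams.from_dict(data["ssm"])
        return cls(**data)


@dataclass(frozen=True)
class FamilyRecord:
    """One simulated family: class labels, diagnosis and offspring counts."""

    family_id: int
    schizotypal: bool
    fitness_class: str
    n_members: int
    n_diagnosed: int
    offspring_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.fitness_class not in (FITNESS_HIGH, FITNESS_LOW, FITNESS_NA):
            raise ValueError(f"unknown fitness_class {self.fitness_class!r}")
        if self.schizotypal != (self.fitness_class in (FITNESS_HIGH, FITNESS_LOW)):
            raise ValueError(
                "fitness_class must be high/low exactly for schizotypal families; "
                f"got schizotypal={self.schizotypal!r}, fitness_class={self.fitness_class!r}"
            )
        if self.n_members < 1:
            raise ValueError(f"n_members must be >= 1; got {self.n_members!r}")
        if not (0 <= self.n_diagnosed <= self.n_members):
            raise ValueError(
                f"n_diagnosed must lie in [0, n_members]; got {self.n_diagnosed!r}"
            )
        if len(self.offspring_counts) != self.n_members:
            raise ValueError(
                f"offspring_counts has length {len(self.offspring_counts)}, "
                f"expected n_members = {self.n_members}"
            )
        if any(c < 0 for c in self.offspring_counts):
            raise ValueError(f"offspring counts must be non-negative; got {self.offspring_counts!r}")

    @property
    def offspring_total(self) -> int:
        return sum(self.offspring_counts)


@dataclass
class PopulationTable:
    """Ordered collection of simulated families plus the generating params."""

    params: SimulationParams
    families: list[FamilyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def to_dataframe(self):
        """Family-level view as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "family_id": [f.family_id for f in self.families],
                "schizotypal": [f.schizotypal for f in self.families],
                "fitness_class": [f.fitness_class for f in self.families],
                "n_members": [f.n_members for f in self.families],
                "n_diagnosed": [f.n_diagnosed for f in self.families],
                "offspring_total": [f.offspring_total for f in self.families],
            }
        )

    def aggregates(self) -> dict:
        """Family-level numpy arrays used by the estimators (cached)."""
        cached = getattr(self, "_aggregates", None)
        if cached is None:
            fams = self.families
            cached = {
                "schizotypal": np.fromiter(
                    (f.schizotypal for f in fams), dtype=bool, count=len(fams)
                ),
                "low_fitness": np.fromiter(
                    (f.fitness_class == FITNESS_LOW for f in fams), dtype=bool, count=len(fams)
                ),
                "n_members": np.fromiter(
                    (f.n_members for f in fams), dtype=np.int64, count=len(fams)
                ),
                "n_diagnosed": np.fromiter(
                    (f.n_diagnosed for f in fams), dtype=np.int64, count=len(fams)
                ),
                "offspring_total": np.fromiter(
                    (f.offspring_total for f in fams), dtype=np.int64, count=len(fams)
                ),
            }
            self._aggregates = cached
        return cached


def simulate_population(params: SimulationParams) -> PopulationTable:
    """Draw a population of families under the given parameters.

    Identical parameters (including the seed) reproduce an identical
    table, bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_families
    k = params.family_size
    ssm = params.ssm

    schizotypal = rng.random(n) < params.prop_schizotypal
    low_draw = rng.random(n) < ssm.p_low
    low = schizotypal & low_draw

    p_diag = np.where(
        schizotypal,
        np.where(low, ssm.r * params.p_diag_high, params.p_diag_high),
        params.p_diag_nonschizotypal,
    )
    diagnosed = rng.random((n, k)) < p_diag[:, None]

    class_fert = np.where(schizotypal, np.where(low, ssm.w_low, ssm.w_high), 1.0)
    mean_off = params.base_mean_offspring * class_fert[:, None] * np.where(
        diagnosed, params.diagnosed_fertility_factor, 1.0
    )
    offspring = rng.poisson(mean_off)

    n_diag = diagnosed.sum(axis=1)
    off_rows = offspring.tolist()
    families = [
        FamilyRecord(
            family_id=i,
            schizotypal=bool(schizotypal[i]),
            fitness_class=(
                (FITNESS_LOW if low[i] else FITNESS_HIGH) if schizotypal[i] else FITNESS_NA
            ),
            n_members=k,
            n_diagnosed=int(n_diag[i]),
            offspring_counts=tuple(off_rows[i]),
        )
        for i in range(n)
    ]
    return PopulationTable(params=params, families=families)


class PopulationParseError(ValueError):
    """Raised when a population file is malformed; names the offending row."""


def write_population(pop: PopulationTable, path) -> None:
    """Serialize a population to a tab-separated text file.

    The first two lines are a format magic and the JSON-encoded
    :class:`SimulationParams` (including the seed), so the round trip is
    lossless and byte-deterministic.
    """
    path = Path(path)
    lines = [
        _FORMAT_MAGIC,
        "# params=" + json.dumps(pop.params.to_dict(), sort_keys=True),
        "\t".join(_COLUMNS),
    ]
    for fam in pop.families:
        lines.append(
            "\t".join(
                (
                    str(fam.family_id),
                    "1" if fam.schizotypal else "0",
                    fam.fitness_class,
                    str(fam.n_members),
                    str(fam.n_diagnosed),
                    ",".join(str(c) for c in fam.offspring_counts),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_population(path) -> PopulationTable:
    """Parse a population file written by :func:`write_population`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _FORMAT_MAGIC:
        raise PopulationParseError(f"{path}: missing format header {_FORMAT_MAGIC!r}")
    if len(lines) < 3 or not lines[1].startswith("# params="):
        raise PopulationParseError(f"{path}: missing '# params=' header on line 2")
    try:
        params = SimulationParams.from_dict(json.loads(lines[1][len("# params=") :]))
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise PopulationParseError(f"{path}: invalid params header: {exc}") from exc
    if tuple(lines[2].split("\t")) != _COLUMNS:
        raise PopulationParseError(f"{path}: unexpected column header on line 3")

    families: list[FamilyRecord] = []
    for lineno, raw in enumerate(lines[3:], start=4):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(_COLUMNS):
            raise PopulationParseError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} tab-separated fields, got {len(fields)}"
            )
        try:
            counts = tuple(int(c) for c in fields[5].split(",")) if fields[5] else ()
            record = FamilyRecord(
                family_id=int(fields[0]),
                schizotypal=fields[1] == "1",
                fitness_class=fields[2],
                n_members=int(fields[3]),
                n_diagnosed=int(fields[4]),
                offspring_counts=counts,
            )
        except ValueError as exc:
            raise PopulationParseError(f"{path}:{lineno}: {exc}") from exc
        families.append(record)
    return PopulationTable(params=params, families=families)
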