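"""Shared/fixed/free parameter declarations for multi-profile fitting.

The parsimony strategy for comparing dispersion profiles across samples
and temperatures is expressed as a :class:`ConstraintMap`: for each of the
seven canonical model parameters and each profile, the slot is either

* ``free``   — its own value in that profile,
* ``fixed``  — clamped to a given value, excluded from optimization,
* ``shared`` — tied to one value across every member of a named group.

Serialized as JSON: ``{"profiles": [{"c_s_dd": "free",
"tau_s": {"fixed": 2.43e-6}, "c_i_dd": {"shared": "ci"}, ...}, ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import PARAM_NAMES

__all__ = ["Constraint", "ConstraintMap", "free", "fixed", "shared"]

#: Parameters that must be strictly positive when fixed.
_POSITIVE = {"tau_s", "tau_i", "tau_f"}
#: Parameters that must be non-negative when fixed.
_NON_NEGATIVE = {"c_s_dd", "c_i_dd", "c_f_dd", "a"}


@dataclass(frozen=True)
class Constraint:
    kind: str  # "free" | "fixed" | "shared"
    value: float | None = None
    group: str | None = None

    def __post_init__(self):
        if self.kind not in ("free", "fixed", "shared"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "fixed" and self.value is None:
            raise ValueError("fixed constraint requires a value")
        if self.kind == "shared" and not self.group:
            raise ValueError("shared constraint requires a group id")


def free() -> Constraint:
    return Constraint("free")


def fixed(value: float) -> Constraint:
    return Constraint("fixed", value=float(value))


def shared(group: str) -> Constraint:
    return Constraint("shared", group=str(group))


class ConstraintMap:
    """Per-profile constraint declaration over the canonical parameters.

    Parameters
    ----------
    per_profile : sequence of mappings
        One ``{param_name: Constraint}`` mapping per profile.  Missing
        parameters default to ``free``.
    """

    def __init__(self, per_profile: Sequence[Mapping[str, Constraint]]):
        if len(per_profile) == 0:
            raise ValueError("constraint map needs at least one profile")
        table = []
        for entry in per_profile:
            row = {}
            for name in PARAM_NAMES:
                con = entry.get(name, free())
                if not isinstance(con, Constraint):
                    raise TypeError(f"expected Constraint for {name!r}, got {con!r}")
                if con.kind == "fixed":
                    if name in _POSITIVE and con.value <= 0:
                        raise ValueError(f"fixed {name} must be > 0, got {con.value}")
                    if name in _NON_NEGATIVE and con.value < 0:
                        raise ValueError(f"fixed {name} must be >= 0, got {con.value}")
            table.append(row | {n: entry.get(n, free()) for n in PARAM_NAMES})
        self._table = table
        # groups only make sense with >= 2 members
        counts: dict = {}
        for row in table:
            for name, con in row.items():
                if con.kind == "shared":
                    counts[(name, con.group)] = counts.get((name, con.group), 0) + 1
        undersized = [g for g, c in counts.items() if c < 2]
        if undersized:
            raise ValueError(f"shared groups with fewer than 2 members: {undersized}")

    # -- accessors ---------------------------------------------------------
    @property
    def n_profiles(self) -> int:
        return len(self._table)

    def constraint(self, profile_index: int, name: str) -> Constraint:
        return self._table[profile_index][name]

    def status(self, profile_index: int, name: str) -> str:
        """Human-readable slot status: ``free``, ``fixed(v)`` or ``shared:g``."""
        con = self.constraint(profile_index, name)
        if con.kind == "fixed":
            return f"fixed({con.value:g})"
        if con.kind == "shared":
            return f"shared:{con.group}"
        return "free"

    @property
    def n_free_slots(self) -> int:
        """Number of independent optimizable values (shared groups count once)."""
        seen_groups = set()
        n = 0
        for row in self._table:
            for name, con in row.items():
                if con.kind == "free":
                    n += 1
                elif con.kind == "shared":
                    key = (name, con.group)
                    if key not in seen_groups:
                        seen_groups.add(key)
                        n += 1
        return n

    # -- constructors ------------------------------------------------------
    @classmethod
    def all_free(cls, n_profiles: int) -> "ConstraintMap":
        return cls([{} for _ in range(n_profiles)])

    @classmethod
    def fully_shared(cls, n_profiles: int) -> "ConstraintMap":
        """Every parameter shared across all profiles (one group per parameter)."""
        if n_profiles < 2:
            raise ValueError("sharing requires >= 2 profiles")
        entry = {name: shared(name) for name in PARAM_NAMES}
        return cls([dict(entry) for _ in range(n_profiles)])

    def with_free_block(self, names: Iterable[str]) -> "ConstraintMap":
        """Copy with the given parameters freed (per-profile) in every profile."""
        names = tuple(names)
        unknown = [n for n in names if n not in PARAM_NAMES]
        if unknown:
            raise KeyError(f"unknown parameters: {unknown}")
        return ConstraintMap([
            {n: (free() if n in names else con) for n, con in row.items()}
            for row in self._table
        ])

    def with_constraint(self, profile_index: int, name: str,
                        con: Constraint) -> "ConstraintMap":
        rows = [dict(row) for row in self._table]
        rows[profile_index][name] = con
        return ConstraintMap(rows)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = []
        for row in self._table:
            entry = {}
            for name, con in row.items():
                if con.kind == "free":
                    entry[name] = "free"
                elif con.kind == "fixed":
                    entry[name] = {"fixed": con.value}
                else:
                    entry[name] = {"shared": con.group}
            out.append(entry)
        return {"profiles": out}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ConstraintMap":
        rows = []
        for entry in doc["profiles"]:
            row = {}
            for name, spec in entry.items():
                if spec == "free":
                    row[name] = free()
                elif isinstance(spec, Mapping) and "fixed" in spec:
                    row[name] = fixed(spec["fixed"])
                elif isinstance(spec, Mapping) and "shared" in spec:
                    row[name] = shared(spec["shared"])
                else:
                    raise ValueError(f"bad constraint spec for {name!r}: {spec!r}")
            rows.append(row)
        return cls(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ConstraintMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        return isinstance(other, ConstraintMap) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"ConstraintMap(n_profiles={self.n_profiles}, n_free_slots={self.n_free_slots})"
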