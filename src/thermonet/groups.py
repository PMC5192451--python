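"""Group-contribution estimation of standard formation energies.

A compound's standard Gibbs energy of formation is estimated additively
from a functional-group decomposition:

    dfG0 = P_o + sum_j n_j * P_j

where P_o is an origin constant, P_j the contribution of group j and
n_j how many times the group occurs.  Ring and similar structural
corrections are ordinary named groups in the table (e.g. ">CH- (ring)"),
not special-cased code, so fuller published tables load from TSV without
code changes.  Two tables are bundled (an earlier and an updated
contribution set) together with the ring-form glucose decomposition they
are conventionally demonstrated on.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

from . import _data

__all__ = [
    "GroupTable",
    "GroupDecomposition",
    "estimate_dfg0",
    "compare_to_reference",
    "mavrovouniotis_table",
    "jankowski_table",
    "glucose_ring_decomposition",
]


@dataclass(frozen=True)
class GroupTable:
    """Origin constant P_o and per-group contributions P_j, all kJ/mol."""

    origin: float
    contributions: Mapping[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "contributions", dict(self.contributions))


@dataclass(frozen=True)
class GroupDecomposition:
    """Counted functional groups of one compound."""

    compound: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        for group, n in counts.items():
            if n < 1 or int(n) != n:
                raise ValueError(
                    f"{self.compound}: group {group!r} count must be a positive integer, got {n}"
                )
        object.__setattr__(self, "counts", {g: int(n) for g, n in counts.items()})


def estimate_dfg0(decomposition: GroupDecomposition, table: GroupTable) -> float:
    """Apply dfG0 = P_o + sum_j n_j P_j; unknown groups raise KeyError."""
    missing = sorted(set(decomposition.counts) - set(table.contributions))
    if missing:
        raise KeyError(
            f"{decomposition.compound}: groups not in table {table.source!r}: "
            + ", ".join(missing)
        )
    return table.origin + sum(
        n * table.contributions[g] for g, n in decomposition.counts.items()
    )


def compare_to_reference(estimate: float, reference: float) -> float:
    """Absolute percent difference of an estimate from a reference value."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * abs(estimate - reference) / abs(reference)


def _load_table(filename: str, source: str) -> GroupTable:
    rows = _data.read_tsv(filename)
    origin = None
    contributions: dict[str, float] = {}
    for row in rows:
        if row["group"] == "Ori":
            origin = float(row["contribution_kj_mol"])
        else:
            contributions[row["group"]] = float(row["contribution_kj_mol"])
    if origin is None:
        raise ValueError(f"{filename}: no origin ('Ori') row")
    return GroupTable(origin=origin, contributions=contributions, source=source)


def mavrovouniotis_table() -> GroupTable:
    """The earlier bundled contribution set (origin -103.4 kJ/mol)."""
    return _load_table("group_table_mavrovouniotis.tsv", "mavrovouniotis")


def jankowski_table() -> GroupTable:
    """The updated bundled contribution set (origin 0.0 kJ/mol)."""
    return _load_table("group_table_jankowski.tsv", "jankowski")


def glucose_ring_decomposition() -> GroupDecomposition:
    """Ring-form glucose: 4 secondary OH, ring -O-, >CH2, 5 ring >CH-, primary OH."""
    rows = _data.read_tsv("glucose_groups.tsv")
    return GroupDecomposition(
        compound="Glucose", counts={r["group"]: int(r["count"]) for r in rows}
    )


def load_group_table(path, source: str = "") -> GroupTable:
    """Read a group table from a TSV with columns group, contribution_kj_mol."""
    rows = _data.read_tsv_path(path)
    origin = 0.0
    contributions: dict[str, float] = {}
    for row in rows:
        if row["group"] == "Ori":
            origin = float(row["contribution_kj_mol"])
        else:
            if row["group"] in contributions:
                raise ValueError(f"duplicate group {row['group']!r} in {path}")
            contributions[row["group"]] = float(row["contribution_kj_mol"])
    return GroupTable(origin=origin, contributions=contributions, source=source or str(path))


def load_decomposition(path) -> list[GroupDecomposition]:
    """Read decompositions from a TSV with columns compound, group, count."""
    rows = _data.read_tsv_path(path)
    by_compound: dict[str, dict[str, int]] = {}
    for row in rows:
        by_compound.setdefault(row["compound"], {})[row["group"]] = int(row["count"])
    return [GroupDecomposition(compound=c, counts=counts) for c, counts in by_compound.items()]
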