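"""Readers and writers for the bespoke TSV/JSON interchange formats.

Species tables mirror the layout of published formation-energy tables:
one row per protonation state, with rows sharing a ``reactant`` value
forming one pseudoisomer group.  Reaction models are equation strings
("A + B = C + D"); "=" marks a reversible reaction, "->" forward-only
and "<-" backward-only.  Readers reject malformed input with the row
number rather than silently coercing; writers emit files the readers
accept unchanged.
"""

from __future__ import annotations

import json
import re
import warnings
from collections.abc import Iterable, Mapping

from ._data import normalize_minus, read_tsv_path
from .constants import PROTON_NAMES
from .core import Conditions, Directionality, Reactant, Reaction, Species

__all__ = [
    "read_species_table",
    "read_reaction_table",
    "read_concentration_bounds",
    "read_conditions",
    "parse_reaction_equation",
    "format_reaction_equation",
    "write_energy_table",
    "write_range_table",
]

_SPECIES_COLUMNS = ("name", "dfg0_kj_mol", "charge", "n_hydrogen", "reactant", "compartment")


class ModelWarning(UserWarning):
    """Non-fatal model curation notices (e.g. stripped proton tokens)."""


def _require_columns(rows: list[dict[str, str]], required: Iterable[str], what: str) -> None:
    if rows:
        missing = [c for c in required if c not in rows[0]]
    else:
        missing = []
    if missing:
        raise ValueError(f"{what}: missing required columns: {', '.join(missing)}")


def read_species_table(path) -> dict[str, Reactant]:
    """Read a species TSV into pseudoisomer groups keyed by reactant name.

    A header comment line ``# units: J/mol`` declares formation energies
    in J/mol; they are converted to kJ/mol on input.  Validation errors
    name the offending data row (1-based, excluding header/comments).
    """
    scale = 1.0
    if hasattr(path, "read"):
        text = path.read()
        import io as _io

        path = _io.StringIO(text)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        import io as _io

        path = _io.StringIO(text)
    for line in text.splitlines():
        if line.lstrip().startswith("#") and re.search(r"units\s*[:=]\s*J/mol", line):
            scale = 1e-3
        if line.strip() and not line.lstrip().startswith("#"):
            break
    rows = read_tsv_path(path)
    _require_columns(rows, _SPECIES_COLUMNS, "species table")
    groups: dict[str, list[Species]] = {}
    compartments: dict[str, str] = {}
    for i, row in enumerate(rows, start=1):
        try:
            species = Species(
                name=row["name"],
                dfg0=float(row["dfg0_kj_mol"]) * scale,
                charge=int(row["charge"]),
                n_hydrogen=int(row["n_hydrogen"]),
                reference_group=row.get("reference_group", ""),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"species table row {i} ({row.get('name', '?')!r}): {exc}") from exc
        reactant = row["reactant"] or row["name"]
        if any(s.name == species.name for s in groups.get(reactant, [])):
            raise ValueError(
                f"species table row {i}: duplicate species {species.name!r} "
                f"within reactant {reactant!r}"
            )
        groups.setdefault(reactant, []).append(species)
        compartments[reactant] = row["compartment"] or "cytosol"
    return {
        name: Reactant(name=name, species=tuple(species), compartment_id=compartments[name])
        for name, species in groups.items()
    }


_ARROWS = (("<->", Directionality.REVERSIBLE), ("->", Directionality.FORWARD_ONLY),
           ("<-", Directionality.BACKWARD_ONLY), ("=", Directionality.REVERSIBLE))

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(.+)$")


def _parse_side(side: str, sign: int, stoich: dict[str, float], equation: str) -> None:
    side = side.strip()
    if not side:
        raise ValueError(f"equation {equation!r}: empty reaction side")
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            raise ValueError(f"equation {equation!r}: empty term")
        match = _TERM_RE.match(term)
        coeff = float(match.group(1)) if match.group(1) else 1.0
        name = match.group(2).strip()
        if name in PROTON_NAMES:
            warnings.warn(
                f"equation {equation!r}: stripped proton token {name!r} "
                "(reactions are stored proton-free; pH is held constant)",
                ModelWarning,
                stacklevel=4,
            )
            continue
        stoich[name] = stoich.get(name, 0.0) + sign * coeff
    # fully cancelled name pairs (A = A) fall through to the Reaction validator


def parse_reaction_equation(text: str, reaction_id: str = "") -> Reaction:
    """Parse an equation string like ``"2 A + B = C"`` into a Reaction."""
    equation = normalize_minus(text.strip())
    if not equation:
        raise ValueError("empty reaction equation")
    for arrow, directionality in _ARROWS:
        if f" {arrow} " in equation:
            left, right = equation.split(f" {arrow} ", 1)
            break
    else:
        raise ValueError(
            f"equation {text!r}: no reaction arrow found (use '=', '->' or '<-')"
        )
    if any(f" {a} " in right for a, _ in _ARROWS):
        raise ValueError(f"equation {text!r}: more than one reaction arrow")
    stoich: dict[str, float] = {}
    _parse_side(left, -1, stoich, equation)
    _parse_side(right, +1, stoich, equation)
    return Reaction(
        id=reaction_id or equation,
        stoichiometry=stoich,
        directionality=directionality,
    )


def format_reaction_equation(reaction: Reaction) -> str:
    """Canonical equation string; inverse of :func:`parse_reaction_equation`."""
    arrow = {
        Directionality.REVERSIBLE: "=",
        Directionality.FORWARD_ONLY: "->",
        Directionality.BACKWARD_ONLY: "<-",
    }[reaction.directionality]

    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for name, coeff in items:
            coeff = abs(coeff)
            prefix = "" if coeff == 1 else f"{coeff:g} "
            parts.append(f"{prefix}{name}")
        return " + ".join(parts)

    subs = sorted((n, c) for n, c in reaction.stoichiometry.items() if c < 0)
    prods = sorted((n, c) for n, c in reaction.stoichiometry.items() if c > 0)
    return f"{side(subs)} {arrow} {side(prods)}"


def read_reaction_table(path) -> list[Reaction]:
    """Read a model TSV with columns ``id`` and ``equation``."""
    rows = read_tsv_path(path)
    _require_columns(rows, ("id", "equation"), "reaction table")
    reactions = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        if row["id"] in seen:
            raise ValueError(f"reaction table row {i}: duplicate reaction id {row['id']!r}")
        seen.add(row["id"])
        try:
            reactions.append(parse_reaction_equation(row["equation"], reaction_id=row["id"]))
        except ValueError as exc:
            raise ValueError(f"reaction table row {i}: {exc}") from exc
    return reactions


def read_concentration_bounds(path) -> dict[str, tuple[float, float]]:
    """Read measured bounds from a TSV with columns reactant, c_min_M, c_max_M."""
    rows = read_tsv_path(path)
    _require_columns(rows, ("reactant", "c_min_M", "c_max_M"), "bounds table")
    bounds: dict[str, tuple[float, float]] = {}
    for i, row in enumerate(rows, start=1):
        try:
            lo, hi = float(row["c_min_M"]), float(row["c_max_M"])
        except ValueError as exc:
            raise ValueError(f"bounds table row {i} ({row['reactant']!r}): {exc}") from exc
        if not (0 < lo <= hi):
            raise ValueError(
                f"bounds table row {i}: need 0 < c_min <= c_max, got [{lo}, {hi}]"
            )
        bounds[row["reactant"]] = (lo, hi)
    return bounds


def read_conditions(path) -> dict[str, Conditions]:
    """Read per-compartment conditions from JSON keyed by compartment id."""
    if hasattr(path, "read"):
        payload = json.load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    out: dict[str, Conditions] = {}
    for compartment, spec in payload.items():
        try:
            out[compartment] = Conditions(
                ph=float(spec["ph"]),
                ionic_strength=float(spec["ionic_strength_M"]),
                temperature=float(spec.get("temperature_K", 298.15)),
                compartment_id=compartment,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"conditions for compartment {compartment!r}: {exc}") from exc
    return out


def write_energy_table(energies: Mapping[str, float], fh, value_column: str = "dfg0_prime_kj_mol") -> None:
    fh.write(f"reactant\t{value_column}\n")
    for name, value in energies.items():
        fh.write(f"{name}\t{value:.4f}\n")


def write_range_table(rows: Iterable[Mapping[str, object]], fh) -> None:
    rows = list(rows)
    if not rows:
        fh.write("\n")
        return
    columns = list(rows[0].keys())
    fh.write("\t".join(columns) + "\n")
    for row in rows:
        fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
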