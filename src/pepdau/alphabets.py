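"""Reduced amino-acid alphabets (grouping schemes).

A grouping scheme partitions the 20 standard amino acids into groups of
similar physicochemical property, each rendered as one degenerate symbol —
e.g. charge gives {H,K,R} "+", {D,E} "-" and everything else "0".  Testing
differential usage on the collapsed alphabet pools counts across group
members, which raises power for subtle group-level preferences that single
residues do not show.

Built-in schemes ship for identity (no grouping), 3-class hydrophobicity,
3-class charge at physiological pH, and 5-class side-chain size.  Custom
schemes can be registered programmatically or loaded from JSON; published
groupings by isoelectric point, polarity, bulkiness, volume, consensus
similarity or substitutability can be supplied the same way (their group
memberships are property-table choices, so they are user inputs here, not
hard-coded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .proteome import PAD, STANDARD_AA

_STANDARD = frozenset(STANDARD_AA)


class SchemeError(ValueError):
    """Raised when a grouping scheme is not a valid partition."""


#: residue char code -> 0..19 for standard AAs, -1 for padding/non-standard.
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _aa in enumerate(STANDARD_AA):
    _CODE_TABLE[ord(_aa)] = _i

AA_TO_CODE = {aa: i for i, aa in enumerate(STANDARD_AA)}


def encode_residues(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes: 0..19 for the standard amino acids
    (alphabetical order), -1 for padding and non-standard symbols."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Group:
    symbol: str
    members: frozenset[str]
    color: str
    label: str


@dataclass
class GroupingScheme:
    """A total partition of the 20 standard amino acids into symbol groups."""

    name: str
    groups: list[Group]
    _to_symbol: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        covered: dict[str, str] = {}
        symbols: set[str] = set()
        for g in self.groups:
            if len(g.symbol) != 1 or not g.symbol.isprintable():
                raise SchemeError(f"group symbol must be one printable char: "
                                  f"{g.symbol!r}")
            if g.symbol == PAD:
                raise SchemeError("symbol 'X' is reserved for padding")
            if g.symbol in symbols:
                raise SchemeError(f"duplicated group symbol {g.symbol!r}")
            symbols.add(g.symbol)
            for aa in g.members:
                if aa not in _STANDARD:
                    raise SchemeError(f"unknown amino acid {aa!r} in group "
                                      f"{g.symbol!r}")
                if aa in covered:
                    raise SchemeError(
                        f"amino acid {aa} assigned to both group "
                        f"{covered[aa]!r} and {g.symbol!r}"
                    )
                covered[aa] = g.symbol
        missing = _STANDARD - covered.keys()
        if missing:
            raise SchemeError(
                f"scheme {self.name!r} does not cover all amino acids; "
                f"missing: {', '.join(sorted(missing))}"
            )
        object.__setattr__(self, "_to_symbol", covered)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.groups]

    @property
    def colors(self) -> dict[str, str]:
        return {g.symbol: g.color for g in self.groups}

    @property
    def labels(self) -> dict[str, str]:
        return {g.label or g.symbol: g.symbol for g in self.groups}

    def symbol_of(self, aa: str) -> str:
        """Map one residue to its group symbol; padding maps to itself."""
        if aa == PAD:
            return PAD
        try:
            return self._to_symbol[aa]
        except KeyError:
            raise SchemeError(
                f"residue {aa!r} not covered by scheme {self.name!r}"
            ) from None

    def collapse_window(self, window: str) -> str:
        """Collapse a window string onto the degenerate alphabet."""
        return "".join(self.symbol_of(c) for c in window)

    def collapse_counts(self, counts: dict[str, float]) -> dict[str, float]:
        """Sum per-residue counts over group members."""
        out = {g.symbol: 0.0 for g in self.groups}
        for aa, c in counts.items():
            out[self.symbol_of(aa)] = out.get(self.symbol_of(aa), 0.0) + c
        return out

    def member_index(self, symbol_order: list[str] | None = None) -> np.ndarray:
        """Aggregation matrix M (20 x n_groups): M[i, j] = 1 iff the i-th
        standard residue belongs to group j.  counts @ M pools residue counts
        into group counts."""
        order = symbol_order or self.symbols
        M = np.zeros((len(STANDARD_AA), len(order)), dtype=np.int64)
        col = {s: j for j, s in enumerate(order)}
        for i, aa in enumerate(STANDARD_AA):
            M[i, col[self._to_symbol[aa]]] = 1
        return M

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "groups": [
                {
                    "symbol": g.symbol,
                    "members": sorted(g.members),
                    "color": g.color,
                    "label": g.label,
                }
                for g in self.groups
            ],
        }


def _scheme(name: str, spec: list[tuple[str, str, str, str]]) -> GroupingScheme:
    return GroupingScheme(
        name,
        [Group(sym, frozenset(members), color, label)
         for sym, members, color, label in spec],
    )


# Per-residue colors for the identity scheme follow the common
# chemistry-based convention (hydrophobic black, polar green, basic blue,
# acidic red, special-case purple/orange).
_IDENTITY_COLORS = {
    "A": "#000000", "V": "#000000", "L": "#000000", "I": "#000000",
    "M": "#000000", "F": "#000000", "W": "#000000", "C": "#ff8c00",
    "G": "#ff8c00", "P": "#9932cc", "S": "#228b22", "T": "#228b22",
    "Y": "#228b22", "N": "#228b22", "Q": "#228b22", "H": "#1e90ff",
    "K": "#1e90ff", "R": "#1e90ff", "D": "#d62728", "E": "#d62728",
}


def _builtin_registry() -> dict[str, GroupingScheme]:
    identity = GroupingScheme(
        "identity",
        [Group(aa, frozenset(aa), _IDENTITY_COLORS[aa], aa)
         for aa in STANDARD_AA],
    )
    hydro3 = _scheme("hydrophobicity3", [
        ("H", "WFYLIVMC", "#1b1b1b", "hydrophobic"),
        ("n", "HATPGNSQ", "#7f7f7f", "neutral"),
        ("p", "RKDE", "#2ca02c", "hydrophilic"),
    ])
    charge3 = _scheme("charge3", [
        ("+", "HKR", "#1e90ff", "positive"),
        ("0", "ACFGILMNPQSTVWY", "#7f7f7f", "neutral"),
        ("-", "DE", "#d62728", "negative"),
    ])
    size5 = _scheme("size5", [
        ("t", "GSA", "#9ecae1", "tiny"),
        ("s", "DNCEH", "#6baed6", "small"),
        ("m", "RQKT", "#4292c6", "medium"),
        ("L", "MPYF", "#2171b5", "large"),
        ("G", "ILVW", "#084594", "gigantic"),
    ])
    return {s.name: s for s in (identity, hydro3, charge3, size5)}


_REGISTRY: dict[str, GroupingScheme] = _builtin_registry()

BUILTIN_SCHEMES = tuple(sorted(_builtin_registry()))


def builtin_scheme(name: str) -> GroupingScheme:
    """Return a registered scheme by name (built-in or user-registered)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SchemeError(
            f"unknown scheme {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None


get_scheme = builtin_scheme


def register_scheme(scheme: GroupingScheme, overwrite: bool = False) -> str:
    """Register a custom scheme so it is retrievable by name."""
    if scheme.name in _builtin_registry() and not overwrite:
        raise SchemeError(f"cannot overwrite built-in scheme {scheme.name!r}")
    if scheme.name in _REGISTRY and not overwrite:
        raise SchemeError(f"scheme {scheme.name!r} already registered")
    _REGISTRY[scheme.name] = scheme
    return scheme.name


def reset_registry() -> None:
    """Drop user-registered schemes (used by tests and CLI startup)."""
    _REGISTRY.clear()
    _REGISTRY.update(_builtin_registry())


def scheme_from_dict(d: dict) -> GroupingScheme:
    """Build a scheme from a plain dict (strict: unknown keys rejected)."""
    extra = set(d) - {"name", "groups"}
    if extra:
        raise SchemeError(f"unknown keys in scheme definition: {sorted(extra)}")
    groups = []
    for g in d["groups"]:
        gextra = set(g) - {"symbol", "members", "color", "label"}
        if gextra:
            raise SchemeError(f"unknown keys in group definition: "
                              f"{sorted(gextra)}")
        groups.append(Group(
            g["symbol"],
            frozenset(aa.upper() for aa in g["members"]),
            g.get("color", "#444444"),
            g.get("label", g["symbol"]),
        ))
    return GroupingScheme(str(d["name"]), groups)


def load_scheme_json(path) -> GroupingScheme:
    """Load and validate a custom scheme from a JSON file."""
    with open(path) as fh:
        return scheme_from_dict(json.load(fh))
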