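"""Discrete morphological character matrices: model, validation and I/O.

A matrix is a taxon x character grid of state cells.  Symbols ``0``-``3`` are
determinate states, ``?`` is missing data, ``-`` is an inapplicable character
and a cell may be polymorphic/ambiguous over several states.  For parsimony
every cell is resolved to a non-empty *effective state set*; by default both
``?`` and ``-`` resolve to the full set of states observed in that column,
which is how PAUP* treats them for "standard" data.

Dialects:

* ``bespoke`` -- one taxon per line: name (underscores for spaces), whitespace,
  a contiguous symbol string; ``(01)`` marks an explicit polymorphism and a
  bare ``&`` a polymorphism whose member states were not recorded.
* ``nexus``   -- a ``DATA``/``CHARACTERS`` block (``SYMBOLS="0123"``,
  ``MISSING=?``, ``GAP=-``), read and written through dendropy.
* ``tnt``     -- an ``xread`` block; ``[01]`` marks polymorphism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "CellKind",
    "CharacterDef",
    "StateCell",
    "CharacterMatrix",
    "MatrixValidationError",
    "parse_matrix",
    "write_matrix",
    "informative_characters",
    "subset_matrix",
    "load_packaged_matrix",
    "packaged_character_defs",
    "taxon_groups",
    "taxon_aliases",
    "resolve_taxon_name",
]

MAX_STATES = 4
_DET = "0123"


class MatrixValidationError(ValueError):
    """Raised when matrix text or structure violates the format contract."""


class CellKind(Enum):
    DETERMINATE = "determinate"
    POLYMORPHIC = "polymorphic"
    MISSING = "missing"
    INAPPLICABLE = "inapplicable"


@dataclass(frozen=True)
class CharacterDef:
    """Metadata for one character: 1-based index, name and state labels."""

    index: int
    name: str
    states: tuple[str, ...]
    inapplicable_allowed: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.states) <= MAX_STATES:
            raise ValueError(f"character {self.index}: 1-{MAX_STATES} states required")


@dataclass(frozen=True)
class StateCell:
    """One cell: its kind, raw symbol(s) and declared state set.

    ``states`` is empty for missing/inapplicable cells; the effective set used
    by parsimony comes from :meth:`CharacterMatrix.state_sets` after policy
    resolution and is never empty.
    """

    kind: CellKind
    states: frozenset[int] = frozenset()
    raw: str = ""

    def __post_init__(self) -> None:
        if self.kind is CellKind.DETERMINATE and len(self.states) != 1:
            raise ValueError("determinate cell must hold exactly one state")
        if self.kind is CellKind.POLYMORPHIC and len(self.states) not in (0, 2, 3, 4):
            raise ValueError("polymorphic cell needs >= 2 states (or none recorded)")
        if self.kind in (CellKind.MISSING, CellKind.INAPPLICABLE) and self.states:
            raise ValueError(f"{self.kind.value} cell carries no declared states")

    @classmethod
    def determinate(cls, state: int, raw: str | None = None) -> "StateCell":
        return cls(CellKind.DETERMINATE, frozenset({state}), raw or str(state))

    @classmethod
    def from_symbol(cls, sym: str) -> "StateCell":
        if sym in _DET:
            return cls.determinate(int(sym), sym)
        if sym == "?":
            return cls(CellKind.MISSING, raw="?")
        if sym == "-":
            return cls(CellKind.INAPPLICABLE, raw="-")
        if sym == "&":
            # polymorphism whose member states were not recorded in the source
            return cls(CellKind.POLYMORPHIC, frozenset(), "&")
        raise MatrixValidationError(f"illegal symbol {sym!r}")

    def symbol(self) -> str:
        """Single-character bespoke symbol (polymorphisms use '(..)' or '&')."""
        if self.kind is CellKind.DETERMINATE:
            return str(next(iter(self.states)))
        if self.kind is CellKind.MISSING:
            return "?"
        if self.kind is CellKind.INAPPLICABLE:
            return "-"
        if not self.states:
            return "&"
        return "(" + "".join(str(s) for s in sorted(self.states)) + ")"


class CharacterMatrix:
    """Taxon x character grid of :class:`StateCell` with optional metadata."""

    def __init__(
        self,
        taxa: list[str],
        cells: list[list[StateCell]],
        defs: list[CharacterDef] | None = None,
        provenance: str = "",
    ) -> None:
        if not taxa:
            raise MatrixValidationError("matrix needs at least one taxon")
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon name(s): {', '.join(dup)}")
        n_char = len(cells[0])
        for name, row in zip(taxa, cells):
            if len(row) != n_char:
                raise MatrixValidationError(
                    f"ragged row for taxon {name!r}: {len(row)} cells, expected {n_char}"
                )
        if defs is not None and len(defs) != n_char:
            raise MatrixValidationError(
                f"{len(defs)} character definitions for {n_char} columns"
            )
        self.taxa = list(taxa)
        self.cells = cells
        self.defs = defs
        self.provenance = provenance

    # -- basic properties -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0])

    def row(self, taxon: str) -> list[StateCell]:
        return self.cells[self.taxa.index(taxon)]

    def row_string(self, taxon: str, raw: bool = False) -> str:
        """Symbol string for a row; ``raw=True`` reproduces source symbols."""
        return "".join(
            (c.raw if raw and c.raw else c.symbol()) for c in self.row(taxon)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.taxa == other.taxa and all(
            a.kind == b.kind and a.states == b.states
            for ra, rb in zip(self.cells, other.cells)
            for a, b in zip(ra, rb)
        )

    # -- parsimony-facing views ------------------------------------------
    def observed_states(self, col: int) -> frozenset[int]:
        """Determinate states observed in a 0-based column."""
        out: set[int] = set()
        for row in self.cells:
            if row[col].kind is CellKind.DETERMINATE:
                out |= row[col].states
        return frozenset(out)

    def state_sets(self, gap: str = "missing") -> np.ndarray:
        """Effective state sets as a uint8 bitmask array (n_taxa x n_char).

        ``gap='missing'`` resolves '-' (and '?', and empty polymorphisms) to
        the set of states observed in the column; ``gap='newstate'`` gives '-'
        its own extra state (bit above the observed ones).  Columns with no
        determinate observation resolve to state 0 so the set is never empty.
        """
        if gap not in ("missing", "newstate"):
            raise ValueError("gap policy must be 'missing' or 'newstate'")
        X = np.zeros((self.n_taxa, self.n_char), dtype=np.uint8)
        for j in range(self.n_char):
            obs = self.observed_states(j)
            full = sum(1 << s for s in obs) or 1
            gap_bit = 1 << (max(obs, default=0) + 1) if gap == "newstate" else full
            for i, row in enumerate(self.cells):
                cell = row[j]
                if cell.kind is CellKind.INAPPLICABLE:
                    X[i, j] = gap_bit
                elif cell.states:
                    X[i, j] = sum(1 << s for s in cell.states)
                else:  # missing, or polymorphism with unrecorded members
                    X[i, j] = full
        return X


# ---------------------------------------------------------------------------
# parsing


def _cells_from_symbols(symbols: list[str], taxon: str, n_expected: int | None):
    cells = []
    for k, sym in enumerate(symbols):
        try:
            if len(sym) > 1:
                cells.append(
                    StateCell(CellKind.POLYMORPHIC, frozenset(int(c) for c in sym), sym)
                )
            else:
                cells.append(StateCell.from_symbol(sym))
        except (MatrixValidationError, ValueError) as exc:
            raise MatrixValidationError(
                f"taxon {taxon!r}, character {k + 1}: {exc}"
            ) from None
    if n_expected is not None and len(cells) != n_expected:
        raise MatrixValidationError(
            f"ragged row for taxon {taxon!r}: {len(cells)} cells, expected {n_expected}"
        )
    return cells


def _tokenize_row(data: str, taxon: str) -> list[str]:
    """Split a symbol string into cell tokens, honouring (..)/[..]/{..} groups."""
    toks, i = [], 0
    closers = {"(": ")", "[": "]", "{": "}"}
    while i < len(data):
        ch = data[i]
        if ch in closers:
            j = data.find(closers[ch], i)
            if j < 0:
                raise MatrixValidationError(
                    f"taxon {taxon!r}: unclosed {ch!r} polymorphism group"
                )
            toks.append(data[i + 1 : j])
            i = j + 1
        else:
            toks.append(ch)
            i += 1
    return toks


def _parse_bespoke(text: str) -> tuple[list[str], list[list[StateCell]]]:
    taxa, rows = [], []
    n_expected = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixValidationError(f"cannot parse line: {line!r}")
        name, data = parts[0], parts[1].replace(" ", "")
        cells = _cells_from_symbols(_tokenize_row(data, name), name, n_expected)
        if n_expected is None:
            n_expected = len(cells)
        taxa.append(name)
        rows.append(cells)
    if not taxa:
        raise MatrixValidationError("no taxon rows found")
    return taxa, rows


def _parse_nexus(text: str) -> tuple[list[str], list[list[StateCell]]]:
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise MatrixValidationError(f"NEXUS parse failure: {exc}") from exc
    taxa, rows = [], []
    for taxon in dmat.taxon_namespace:
        name = taxon.label.replace(" ", "_")
        seq = dmat[taxon]
        cells = []
        for st in seq:
            sym = str(st.symbol)
            if sym == "?":
                cells.append(StateCell(CellKind.MISSING, raw="?"))
            elif sym == "-":
                cells.append(StateCell(CellKind.INAPPLICABLE, raw="-"))
            elif sym in _DET:
                cells.append(StateCell.determinate(int(sym)))
            else:  # dendropy multistate (polymorphic/ambiguous)
                members = frozenset(int(m.symbol) for m in st.member_states)
                cells.append(StateCell(CellKind.POLYMORPHIC, members, sym))
        taxa.append(name)
        rows.append(cells)
    return taxa, rows


_TNT_XREAD = re.compile(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);", re.S | re.I)


def _parse_tnt(text: str) -> tuple[list[str], list[list[StateCell]]]:
    m = _TNT_XREAD.search(text)
    if not m:
        raise MatrixValidationError("no xread block found in TNT input")
    n_char, n_taxa = int(m.group(1)), int(m.group(2))
    taxa, rows = [], []
    for line in m.group(3).splitlines():
        line = line.strip()
        if not line:
            continue
        name, data = line.split(None, 1)
        cells = _cells_from_symbols(
            _tokenize_row(data.replace(" ", ""), name), name, n_char
        )
        taxa.append(name)
        rows.append(cells)
    if len(taxa) != n_taxa:
        raise MatrixValidationError(
            f"xread declares {n_taxa} taxa but {len(taxa)} rows found"
        )
    return taxa, rows


def parse_matrix(
    text: str,
    dialect: str = "bespoke",
    defs: list[CharacterDef] | None = None,
    provenance: str = "",
) -> CharacterMatrix:
    """Parse matrix text in the given dialect into a validated matrix."""
    if not text.strip():
        raise MatrixValidationError("empty matrix text")
    parsers = {"bespoke": _parse_bespoke, "nexus": _parse_nexus, "tnt": _parse_tnt}
    if dialect not in parsers:
        raise ValueError(f"unsupported dialect {dialect!r}")
    taxa, rows = parsers[dialect](text)
    mat = CharacterMatrix(taxa, rows, defs=defs, provenance=provenance or dialect)
    # '&' marks a polymorphism whose member states were not recorded; resolve
    # it to the full set of states observed in the column (conservative
    # superset), or to missing if the column shows fewer than two states.
    for j in range(mat.n_char):
        obs = None
        for i, row in enumerate(mat.cells):
            cell = row[j]
            if cell.kind is CellKind.POLYMORPHIC and not cell.states:
                if obs is None:
                    obs = mat.observed_states(j)
                if len(obs) >= 2:
                    row[j] = StateCell(CellKind.POLYMORPHIC, obs, cell.raw)
                else:
                    row[j] = StateCell(CellKind.MISSING, raw=cell.raw)
    if defs is not None:
        for j, d in enumerate(defs):
            high = {s for s in mat.observed_states(j) if s >= len(d.states)}
            if high:
                raise MatrixValidationError(
                    f"character {d.index} ({d.name}): observed state(s) "
                    f"{sorted(high)} exceed the {len(d.states)} declared states"
                )
    return mat


# ---------------------------------------------------------------------------
# writing


def write_matrix(m: CharacterMatrix, dialect: str = "bespoke") -> str:
    """Serialize a matrix; ``parse_matrix(write_matrix(m), d)`` == ``m``."""
    if m.n_taxa == 0:
        raise MatrixValidationError("nothing to write: matrix has no taxa")
    if dialect == "bespoke":
        width = max(len(t) for t in m.taxa) + 2
        return "".join(
            f"{t:<{width}}{m.row_string(t)}\n" for t in m.taxa
        )
    if dialect == "tnt":
        lines = [f"xread {m.n_char} {m.n_taxa}"]
        for t in m.taxa:
            row = "".join(
                c.symbol().replace("(", "[").replace(")", "]") for c in m.row(t)
            )
            lines.append(f"{t} {row}")
        return "\n".join(lines) + "\n;\n"
    if dialect == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_char};",
            '  FORMAT DATATYPE=STANDARD SYMBOLS="0123" MISSING=? GAP=-;',
            "  MATRIX",
        ]
        width = max(len(t) for t in m.taxa) + 2
        for t in m.taxa:
            lines.append(f"    {t:<{width}}{m.row_string(t)}")
        lines += ["  ;", "END;"]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unsupported dialect {dialect!r}")


# ---------------------------------------------------------------------------
# derived views


def informative_characters(m: CharacterMatrix) -> list[int]:
    """1-based indices of parsimony-informative characters.

    A character is informative under unordered costs when at least two of its
    determinate states occur in at least two taxa each.
    """
    out = []
    for j in range(m.n_char):
        counts: dict[int, int] = {}
        for row in m.cells:
            if row[j].kind is CellKind.DETERMINATE:
                (s,) = row[j].states
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append(j + 1)
    return out


def subset_matrix(m: CharacterMatrix, taxa: list[str]) -> CharacterMatrix:
    """Row-subset preserving column order and metadata; aliases are resolved."""
    import difflib

    resolved = []
    for name in taxa:
        canonical = resolve_taxon_name(name)
        if canonical not in m.taxa:
            near = difflib.get_close_matches(name, m.taxa, n=3)
            hint = f" (did you mean: {', '.join(near)}?)" if near else ""
            raise KeyError(f"unknown taxon {name!r}{hint}")
        resolved.append(canonical)
    cells = [m.cells[m.taxa.index(t)] for t in resolved]
    return CharacterMatrix(resolved, cells, defs=m.defs, provenance=m.provenance)


# ---------------------------------------------------------------------------
# packaged fixture


def _data_text(fname: str) -> str:
    return (resources.files("parsiphy") / "data" / fname).read_text()


def packaged_character_defs() -> list[CharacterDef]:
    doc = yaml.safe_load(_data_text("characters.yaml"))
    return [
        CharacterDef(
            index=c["index"],
            name=c["name"],
            states=tuple(c["states"]),
            inapplicable_allowed=c["inapplicable_allowed"],
        )
        for c in doc["characters"]
    ]


def load_packaged_matrix() -> CharacterMatrix:
    """The packaged 78-taxon x 43-character arminid morphology matrix."""
    return parse_matrix(
        _data_text("table2_matrix.txt"),
        dialect="bespoke",
        defs=packaged_character_defs(),
        provenance="packaged arminid matrix",
    )


def taxon_groups() -> dict[str, list[str]]:
    doc = yaml.safe_load(_data_text("taxon_groups.yaml"))
    groups = dict(doc["groups"])
    groups["arminidae"] = (
        groups["armina"] + groups["dermatobranchus"] + groups["histiomena"]
    )
    return groups


def analysis_roots() -> dict[str, str]:
    return dict(yaml.safe_load(_data_text("taxon_groups.yaml"))["roots"])


def taxon_aliases() -> dict[str, str]:
    return dict(yaml.safe_load(_data_text("taxon_groups.yaml"))["aliases"])


def resolve_taxon_name(name: str) -> str:
    """Canonicalize a taxon name: underscores for spaces, known aliases fixed."""
    name = name.strip().replace(" ", "_")
    return taxon_aliases().get(name, name)
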