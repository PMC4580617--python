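"""Morphological character matrices: NEXUS / TNT input, NEXUS output, subsetting.

A matrix is a taxa x characters grid of :class:`StateSet` cells.  Cells are
either a set of observed integer states (singleton, or >=2 states for a
polymorphic scoring), MISSING (``?``, compatible with every state), or
INAPPLICABLE (``-``, scored exactly like MISSING but preserved on output).
Character indices are 1-based in every user-facing call, matching the way
morphologists number characters.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd


class MatrixError(ValueError):
    pass


class MatrixParseError(MatrixError):
    pass


@dataclass(frozen=True)
class StateSet:
    """States observed in one cell; empty set + kind flags missing data."""

    states: frozenset[int]
    kind: str = "observed"  # "observed" | "missing" | "gap"

    def __post_init__(self):
        if self.kind == "observed" and not self.states:
            raise MatrixError("an observed cell needs at least one state")
        if self.kind != "observed" and self.states:
            raise MatrixError("missing/gap cells carry no states")

    @property
    def is_uncertain(self) -> bool:
        """True when the cell constrains nothing (missing or inapplicable)."""
        return self.kind != "observed"

    @property
    def is_polymorphic(self) -> bool:
        return len(self.states) >= 2

    @classmethod
    def of(cls, *states: int) -> "StateSet":
        return cls(frozenset(states))

    def mask(self, n_states: int) -> int:
        if self.is_uncertain:
            return (1 << n_states) - 1
        m = 0
        for s in self.states:
            m |= 1 << s
        return m

    def symbol(self) -> str:
        if self.kind == "missing":
            return "?"
        if self.kind == "gap":
            return "-"
        if len(self.states) == 1:
            return str(next(iter(self.states)))
        return "{" + "".join(str(s) for s in sorted(self.states)) + "}"


MISSING = StateSet(frozenset(), "missing")
INAPPLICABLE = StateSet(frozenset(), "gap")


@dataclass
class CharacterMeta:
    index: int          # 1-based character number
    n_states: int
    ordered: bool = False
    active: bool = True


class CharacterMatrix:
    """Taxa x characters grid with per-character metadata."""

    def __init__(self, taxa: Sequence[str],
                 cells: Sequence[Sequence[StateSet]],
                 characters: Sequence[CharacterMeta] | None = None):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise MatrixError("taxon labels must be unique")
        if not taxa:
            raise MatrixError("a matrix needs at least one taxon")
        cells = [list(row) for row in cells]
        if len(cells) != len(taxa):
            raise MatrixError("one row of cells per taxon required")
        n_chars = len(cells[0])
        if n_chars < 1:
            raise MatrixError("a matrix needs at least one character")
        if any(len(row) != n_chars for row in cells):
            raise MatrixError("ragged rows: every taxon needs one cell per character")
        if characters is None:
            characters = [
                CharacterMeta(index=j + 1, n_states=self._observed_n_states(cells, j))
                for j in range(n_chars)
            ]
        characters = list(characters)
        if len(characters) != n_chars:
            raise MatrixError("one CharacterMeta per character required")
        for j, meta in enumerate(characters):
            hi = max((max(c.states) for row in [r[j] for r in cells]
                      for c in [row] if not c.is_uncertain), default=-1)
            if hi >= meta.n_states:
                raise MatrixError(
                    f"character {meta.index}: state {hi} exceeds declared "
                    f"n_states={meta.n_states}")
        self.taxa = taxa
        self.cells = cells
        self.characters = characters

    @staticmethod
    def _observed_n_states(cells, j) -> int:
        hi = max((max(c.states) for c in (row[j] for row in cells)
                  if not c.is_uncertain), default=0)
        return max(2, hi + 1)

    # -- basic views -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.characters)

    def column(self, index: int) -> list[StateSet]:
        """Column by 1-based character index."""
        j = self._char_pos(index)
        return [row[j] for row in self.cells]

    def _char_pos(self, index: int) -> int:
        for j, meta in enumerate(self.characters):
            if meta.index == index:
                return j
        raise MatrixError(f"no character with index {index}")

    def active_characters(self) -> list[CharacterMeta]:
        return [m for m in self.characters if m.active]

    def state_masks(self, respect_active: bool = True) -> tuple[np.ndarray, list[CharacterMeta]]:
        """Bitmask array (n_taxa, n_active_chars) for parsimony scoring."""
        metas = self.active_characters() if respect_active else list(self.characters)
        positions = [j for j, m in enumerate(self.characters)
                     if (m.active or not respect_active)]
        out = np.zeros((self.n_taxa, len(positions)), dtype=np.uint32)
        for col, j in enumerate(positions):
            n = self.characters[j].n_states
            for i in range(self.n_taxa):
                out[i, col] = self.cells[i][j].mask(n)
        return out, metas

    # -- editing -----------------------------------------------------

    def subset(self, drop_taxa: Iterable[str] = (),
               drop_characters: Iterable[int] = ()) -> "CharacterMatrix":
        """New matrix without the named taxa / 1-based character indices."""
        drop_taxa = list(drop_taxa)
        drop_characters = list(drop_characters)
        unknown = set(drop_taxa) - set(self.taxa)
        if unknown:
            raise MatrixError(f"unknown taxa: {sorted(unknown)}")
        have = {m.index for m in self.characters}
        bad = set(drop_characters) - have
        if bad:
            raise MatrixError(f"unknown character indices: {sorted(bad)}")
        keep_t = [i for i, t in enumerate(self.taxa) if t not in set(drop_taxa)]
        keep_c = [j for j, m in enumerate(self.characters)
                  if m.index not in set(drop_characters)]
        if len(keep_t) == 0 or len(keep_c) == 0:
            raise MatrixError("subset would leave an empty matrix")
        return CharacterMatrix(
            [self.taxa[i] for i in keep_t],
            [[self.cells[i][j] for j in keep_c] for i in keep_t],
            [replace(self.characters[j]) for j in keep_c],
        )

    def set_ordered(self, indices: Iterable[int], ordered: bool = True) -> None:
        for idx in indices:
            self.characters[self._char_pos(idx)].ordered = ordered

    # -- comparisons / export ----------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa and self.cells == other.cells
                and [m.index for m in self.characters] == [m.index for m in other.characters])

    def to_dataframe(self) -> pd.DataFrame:
        data = {m.index: [self.cells[i][j].symbol() for i in range(self.n_taxa)]
                for j, m in enumerate(self.characters)}
        return pd.DataFrame(data, index=self.taxa)

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_chars} characters>"


# ---------------------------------------------------------------------------
# NEXUS input (dendropy-backed) and output
# ---------------------------------------------------------------------------

def read_nexus(source) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    ``?`` maps to MISSING, ``-`` to INAPPLICABLE, and both ``{..}`` and
    ``(..)`` groups to polymorphic cells.  Interleaved blocks are accepted.
    """
    text = _as_text(source)
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        line = getattr(exc, "line_num", None)
        where = f" (line {line})" if line else ""
        raise MatrixParseError(f"malformed NEXUS{where}: {exc}") from exc
    taxa, cells = [], []
    for taxon in dm:
        taxa.append(taxon.label)
        row = []
        for cell in dm[taxon]:
            row.append(_convert_dendropy_cell(cell))
        cells.append(row)
    if not cells or not cells[0]:
        raise MatrixParseError("NEXUS matrix contains no characters")
    declared = _declared_dimensions(text)
    if declared is not None:
        ntax, nchar = declared
        if ntax != len(taxa) or nchar != len(cells[0]):
            raise MatrixParseError(
                f"DIMENSIONS declares {ntax} x {nchar} but matrix is "
                f"{len(taxa)} x {len(cells[0])}")
    return CharacterMatrix(taxa, cells)


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "#NEXUS" in text or "\n" in text:
        return text
    with open(text) as fh:
        return fh.read()


def _declared_dimensions(text: str) -> tuple[int, int] | None:
    m = re.search(r"DIMENSIONS[^;]*;", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    ntax = re.search(r"NTAX\s*=\s*(\d+)", m.group(0), re.IGNORECASE)
    nchar = re.search(r"NCHAR\s*=\s*(\d+)", m.group(0), re.IGNORECASE)
    if ntax and nchar:
        return int(ntax.group(1)), int(nchar.group(1))
    return None


def _convert_dendropy_cell(cell) -> StateSet:
    if getattr(cell, "is_gap_state", False):
        return INAPPLICABLE
    symbol = cell.symbol
    fundamentals = [s.symbol for s in cell.fundamental_states]
    if symbol == "?" or (symbol is None and "-" in fundamentals and len(fundamentals) > 1):
        return MISSING
    states = frozenset(int(s) for s in fundamentals if s.isdigit())
    if not states:
        raise MatrixParseError(f"cannot interpret NEXUS cell symbol {symbol!r}")
    return StateSet(states)


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialise to NEXUS; the output re-reads to an equal matrix."""
    max_state = max(m.n_states for m in matrix.characters) - 1
    symbols = "".join(str(s) for s in range(max_state + 1))
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};\n")
    out.write(f'  FORMAT SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    out.write("  MATRIX\n")
    width = max(len(_nexus_label(t)) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        label = _nexus_label(taxon)
        row = "".join(cell.symbol() for cell in matrix.cells[i])
        out.write(f"    {label:<{width}}{row}\n")
    out.write("  ;\nEND;\n")
    return out.getvalue()


def _nexus_label(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# Minimal TNT xread reader
# ---------------------------------------------------------------------------

def read_tnt(source) -> CharacterMatrix:
    """Read a minimal TNT ``xread`` file (non-interleaved, digit states,
    ``?`` missing, ``-`` gap, ``[ab]`` polymorphism)."""
    text = _as_text(source)
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);",
                  text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixParseError("no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa, cells = [], []
    for line in m.group(3).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixParseError(f"cannot parse xread row: {line!r}")
        label, seq = parts
        row = _parse_state_string(seq.replace(" ", ""), poly_open="[", poly_close="]")
        if len(row) != nchar:
            raise MatrixParseError(
                f"taxon {label!r}: {len(row)} characters, expected {nchar}")
        taxa.append(label)
        cells.append(row)
    if len(taxa) != ntax:
        raise MatrixParseError(f"{len(taxa)} taxa found, xread declares {ntax}")
    return CharacterMatrix(taxa, cells)


def _parse_state_string(seq: str, poly_open="{", poly_close="}") -> list[StateSet]:
    row: list[StateSet] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch == "?":
            row.append(MISSING)
        elif ch == "-":
            row.append(INAPPLICABLE)
        elif ch.isdigit():
            row.append(StateSet.of(int(ch)))
        elif ch == poly_open:
            j = seq.index(poly_close, i)
            row.append(StateSet(frozenset(int(c) for c in seq[i + 1:j])))
            i = j
        else:
            raise MatrixParseError(f"undeclared state symbol {ch!r}")
        i += 1
    return row
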