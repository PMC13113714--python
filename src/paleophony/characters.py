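"""Discrete morphological character matrices (NEXUS and TNT dialects).

A matrix cell is a set of admissible states: singletons for ordinary
observations, explicit subsets for polymorphisms (``{01}`` in NEXUS,
``[01]`` in TNT), and the full per-character alphabet for missing data
(``?`` and, by convention here, the gap/inapplicable symbol ``-``).

Per-character flags (ordered/unordered, active/inactive, integer weight)
are honored from NEXUS ``ASSUMPTIONS``/``TYPESET`` annotations and from TNT
``ccode`` directives.  Characters are unordered, active and weight 1 unless
annotated otherwise.

NEXUS parsing is delegated to dendropy; the TNT ``xread`` dialect has no
reader in the scientific Python stack, so a minimal one lives here.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .errors import MatrixFormatError

#: Sentinel cell meaning "missing: any state of this character's alphabet".
MISSING = None


def _sorted_symbols(symbols: Iterable[str]) -> tuple[str, ...]:
    syms = set(symbols)
    if all(s.isdigit() for s in syms):
        return tuple(sorted(syms, key=int))
    return tuple(sorted(syms))


@dataclass
class CharacterMatrix:
    """Taxa × characters matrix of discrete state sets.

    ``cells[i][j]`` is a frozenset of state symbols for taxon ``i`` at
    character ``j``, or :data:`MISSING`.
    """

    taxa: tuple[str, ...]
    cells: tuple[tuple[frozenset | None, ...], ...]
    ordered: tuple[bool, ...] = ()
    active: tuple[bool, ...] = ()
    weights: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixFormatError("duplicate taxon names")
        if not self.taxa or not self.cells:
            raise MatrixFormatError("empty matrix")
        nchar = {len(row) for row in self.cells}
        if len(nchar) != 1:
            raise MatrixFormatError(f"ragged matrix rows: lengths {sorted(nchar)}")
        n = next(iter(nchar))
        if n == 0:
            raise MatrixFormatError("matrix has zero characters")
        if len(self.cells) != len(self.taxa):
            raise MatrixFormatError("row count does not match taxon count")
        for row in self.cells:
            for cell in row:
                if cell is not MISSING and not cell:
                    raise MatrixFormatError("empty (non-missing) state set")
        if not self.ordered:
            self.ordered = (False,) * n
        if not self.active:
            self.active = (True,) * n
        if not self.weights:
            self.weights = (1,) * n
        for name, flags in (("ordered", self.ordered), ("active", self.active),
                            ("weights", self.weights)):
            if len(flags) != n:
                raise MatrixFormatError(f"{name} flags length != nchar ({n})")
        if any(w < 1 or int(w) != w for w in self.weights):
            raise MatrixFormatError("character weights must be positive integers")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0])

    def alphabet(self, j: int) -> tuple[str, ...]:
        """Observed alphabet of character ``j``: union of all non-missing
        cell sets (polymorphic members included), in numeric/lexical order."""
        syms: set[str] = set()
        for row in self.cells:
            if row[j] is not MISSING:
                syms |= row[j]
        return _sorted_symbols(syms)

    def state_sets(self, j: int) -> list[frozenset]:
        """Per-taxon resolved state sets for character ``j``; missing cells
        become the full observed alphabet (or ``{'0'}`` if nothing at all
        was observed)."""
        alpha = frozenset(self.alphabet(j)) or frozenset({"0"})
        return [alpha if row[j] is MISSING else row[j] for row in self.cells]

    def is_variable(self, j: int) -> bool:
        return len(self.alphabet(j)) > 1

    def is_informative(self, j: int) -> bool:
        """Parsimony-informative: ≥2 states each fixed in ≥2 taxa."""
        counts: dict[str, int] = {}
        for row in self.cells:
            cell = row[j]
            if cell is not MISSING and len(cell) == 1:
                (s,) = cell
                counts[s] = counts.get(s, 0) + 1
        return sum(1 for c in counts.values() if c >= 2) >= 2

    def subset(self, char_indices: Sequence[int]) -> "CharacterMatrix":
        idx = list(char_indices)
        return CharacterMatrix(
            taxa=self.taxa,
            cells=tuple(tuple(row[j] for j in idx) for row in self.cells),
            ordered=tuple(self.ordered[j] for j in idx),
            active=tuple(self.active[j] for j in idx),
            weights=tuple(self.weights[j] for j in idx),
        )


# ---------------------------------------------------------------------------
# NEXUS

def _parse_typeset_flags(text: str, nchar: int) -> tuple[bool, ...] | None:
    """Ordered/unordered flags from an ASSUMPTIONS TYPESET line, if any."""
    m = re.search(r"typeset[^=;]*=\s*([^;]+);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    ordered = [False] * nchar
    for part in m.group(1).split(","):
        if ":" not in part:
            continue
        kind, indices = part.split(":", 1)
        is_ord = kind.strip().lower() in ("ord", "ordered")
        for tok in indices.split():
            tok = tok.strip().rstrip(";")
            if not tok:
                continue
            if "-" in tok:
                a, b = tok.split("-", 1)
                rng = range(int(a) - 1, int(b))
            else:
                rng = range(int(tok) - 1, int(tok))
            for j in rng:
                if 0 <= j < nchar:
                    ordered[j] = is_ord
    return tuple(ordered)


def read_nexus_matrix(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block into a :class:`CharacterMatrix`."""
    text = Path(path).read_text()
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise MatrixFormatError(f"{path}: malformed NEXUS matrix: {exc}") from exc
    taxa: list[str] = []
    rows: list[tuple] = []
    nchar = None
    for taxon in dmat:
        taxa.append(taxon.label)
        row: list[frozenset | None] = []
        for state in dmat[taxon]:
            if state.symbol in ("?",):
                row.append(MISSING)
            elif state.symbol == "-":
                row.append(MISSING)  # gap/inapplicable treated as missing
            elif state.member_states is not None and state.symbol is None:
                # polymorphic/ambiguous composite
                members = {x.symbol for x in state.member_states} - {"-", "?"}
                row.append(MISSING if not members else frozenset(members))
            elif state.member_states is not None and state.symbol == "?":
                row.append(MISSING)
            else:
                row.append(frozenset({state.symbol}))
        if nchar is None:
            nchar = len(row)
        rows.append(tuple(row))
    if nchar is None:
        raise MatrixFormatError(f"{path}: no character rows found")
    ordered = _parse_typeset_flags(text, nchar)
    return CharacterMatrix(
        taxa=tuple(taxa), cells=tuple(rows),
        ordered=ordered or (), active=(), weights=(),
    )


# ---------------------------------------------------------------------------
# TNT xread

_TNT_COMMENT = re.compile(r"'[^']*'", re.DOTALL)


def _tnt_cells(seq: str, path, name) -> list[frozenset | None]:
    out: list[frozenset | None] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch in "?-":
            out.append(MISSING)
            i += 1
        elif ch in "[{(":
            close = {"[": "]", "{": "}", "(": ")"}[ch]
            j = seq.find(close, i)
            if j < 0:
                raise MatrixFormatError(
                    f"{path}: unterminated polymorphism in row {name!r}"
                )
            members = frozenset(seq[i + 1:j]) - {" "}
            if not members:
                raise MatrixFormatError(
                    f"{path}: empty polymorphism in row {name!r}"
                )
            out.append(members)
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            out.append(frozenset({ch}))
            i += 1
    return out


def _apply_ccode(directives: str, nchar: int,
                 ordered: list[bool], active: list[bool],
                 weights: list[int]) -> None:
    """Apply a TNT ccode directive body.

    Supported mode tokens: ``+`` ordered (additive), ``-`` unordered,
    ``[`` active, ``]`` inactive, ``/N`` weight N; followed by 0-based
    character indices or ``a.b`` ranges; ``.`` alone means all characters.
    """
    mode: dict[str, bool | int] = {}
    for tok in directives.replace(";", " ").split():
        if tok == "+":
            mode["ordered"] = True
        elif tok == "-":
            mode["ordered"] = False
        elif tok == "[":
            mode["active"] = True
        elif tok == "]":
            mode["active"] = False
        elif tok.startswith("/"):
            mode["weight"] = int(tok[1:])
        else:
            if tok == ".":
                rng = range(nchar)
            elif "." in tok:
                a, b = tok.split(".", 1)
                rng = range(int(a), int(b) + 1)
            else:
                rng = range(int(tok), int(tok) + 1)
            for j in rng:
                if not 0 <= j < nchar:
                    raise MatrixFormatError(
                        f"ccode index {j} outside 0..{nchar - 1}"
                    )
                if "ordered" in mode:
                    ordered[j] = bool(mode["ordered"])
                if "active" in mode:
                    active[j] = bool(mode["active"])
                if "weight" in mode:
                    weights[j] = int(mode["weight"])


def read_tnt_matrix(path: str | Path) -> CharacterMatrix:
    """Read a TNT ``xread`` file into a :class:`CharacterMatrix`."""
    text = _TNT_COMMENT.sub(" ", Path(path).read_text())
    m = re.search(r"\bxread\b\s+(\d+)\s+(\d+)(.*?);", text,
                  re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixFormatError(f"{path}: no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    body = m.group(3)
    taxa: list[str] = []
    cells: dict[str, list[frozenset | None]] = {}
    for line in body.splitlines():
        line = line.strip()
        if not line or line.startswith("&"):  # interleave section marker
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"{path}: malformed xread row {line!r}")
        name, seq = parts
        if name not in cells:
            taxa.append(name)
            cells[name] = []
        cells[name].extend(_tnt_cells(seq, path, name))
    if len(taxa) != ntax:
        raise MatrixFormatError(
            f"{path}: xread declares {ntax} taxa but {len(taxa)} rows found"
        )
    rows = []
    for name in taxa:
        row = cells[name]
        if len(row) != nchar:
            raise MatrixFormatError(
                f"{path}: taxon {name!r} has {len(row)} cells, expected {nchar}"
            )
        rows.append(tuple(row))
    ordered = [False] * nchar
    active = [True] * nchar
    weights = [1] * nchar
    for cm in re.finditer(r"\bccode\b([^;]*);", text, re.IGNORECASE | re.DOTALL):
        _apply_ccode(cm.group(1), nchar, ordered, active, weights)
    return CharacterMatrix(
        taxa=tuple(taxa), cells=tuple(rows),
        ordered=tuple(ordered), active=tuple(active), weights=tuple(weights),
    )


def read_matrix(path: str | Path) -> CharacterMatrix:
    """Read a character matrix, sniffing NEXUS vs. TNT from the content."""
    head = Path(path).read_text()[:4096].lstrip().lower()
    if head.startswith("#nexus"):
        return read_nexus_matrix(path)
    if "xread" in head:
        return read_tnt_matrix(path)
    raise MatrixFormatError(
        f"{path}: unrecognized matrix format (expected NEXUS or TNT xread)"
    )


# ---------------------------------------------------------------------------
# Writing (used by the synthetic-data generator)

def _format_cell(cell: frozenset | None) -> str:
    if cell is MISSING:
        return "?"
    if len(cell) == 1:
        return next(iter(cell))
    return "{" + "".join(_sorted_symbols(cell)) + "}"


def write_nexus_matrix(matrix: CharacterMatrix, path: str | Path,
                       header_comment: str | None = None) -> None:
    symbols = _sorted_symbols(
        s for j in range(matrix.n_char) for s in matrix.alphabet(j)
    ) or ("0",)
    name_w = max(len(t) for t in matrix.taxa)
    lines = ["#NEXUS"]
    if header_comment:
        lines.append(f"[{header_comment}]")
    lines += [
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa};",
        "  TAXLABELS " + " ".join(matrix.taxa) + ";",
        "END;",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NCHAR={matrix.n_char};",
        f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols)}\" "
        "MISSING=? GAP=-;",
        "  MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(_format_cell(c) for c in matrix.cells[i])
        lines.append(f"    {taxon:<{name_w}} {row}")
    lines += ["  ;", "END;"]
    if any(matrix.ordered):
        ords = " ".join(str(j + 1) for j, o in enumerate(matrix.ordered) if o)
        lines += [
            "BEGIN ASSUMPTIONS;",
            f"  TYPESET * default = ord: {ords};",
            "END;",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
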