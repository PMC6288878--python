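"""Readers and writers for count, probability, background and score tables.

Supported formats
-----------------
* Delimited tables (TSV/CSV, auto-detected from the header line; ``#``
  lines are comments).  Rows are symbols and columns are positions by
  default; the transposed orientation is accepted on request.  Empty cells
  mean "symbol not permitted at this position", which is how per-position
  alphabets round-trip through a rectangular file.
* JASPAR position frequency matrices (``>`` header, then ``A [ n n ... ]``
  rows for the four DNA bases).
* FASTA sequence sets, tokenized one symbol per column, counted into a
  :class:`~edlogo.matrices.CountMatrix`.

Score tables carry a two-line comment header recording the scoring mode
and centering rule, so downstream tools can interpret the signs and units.
"""

from __future__ import annotations

import io as _io
import re
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError
from .matrices import (
    Alphabet,
    Background,
    CountMatrix,
    PositionTable,
    ProbabilityMatrix,
    ScoreMatrix,
)

__all__ = [
    "read_count_table",
    "read_probability_table",
    "read_background",
    "read_jaspar_pfm",
    "counts_from_sequences",
    "read_score_table",
    "write_table",
    "write_score_table",
]


def _as_text(source: IO[str] | str) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _sniff_delimiter(text: str) -> str:
    for line in text.splitlines():
        if line.strip() and not line.lstrip().startswith("#"):
            return "\t" if "\t" in line else ","
    raise FormatError("empty table")


def _coerce_label(label: str):
    label = str(label).strip()
    try:
        return int(label)
    except ValueError:
        return label


def _parse_frame(text: str) -> pd.DataFrame:
    sep = _sniff_delimiter(text)
    try:
        frame = pd.read_csv(
            _io.StringIO(text), sep=sep, comment="#", index_col=0, header=0,
            skip_blank_lines=True, dtype=str,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed delimited table: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError("table has no data columns")
    return frame


def _frame_to_records(frame: pd.DataFrame, what: str):
    """Columns -> positions; rows -> symbols; blank cells -> absent symbol."""
    row_labels = [str(r).strip() for r in frame.index]
    if len(set(row_labels)) != len(row_labels):
        dupes = sorted({r for r in row_labels if row_labels.count(r) > 1})
        raise ValidationError(f"duplicate symbol label(s) {dupes} in {what} table")
    positions = [_coerce_label(c) for c in frame.columns]
    alphabets, vectors = [], []
    for col in frame.columns:
        syms, vals = [], []
        for sym, cell in zip(row_labels, frame[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell == "":
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"cell ({sym!r}, {col!r}) = {cell!r} does not parse as a number"
                ) from None
            syms.append(sym)
        if not syms:
            raise ValidationError(f"position {col!r} has no symbols")
        alphabets.append(Alphabet(syms))
        vectors.append(np.array(vals))
    return positions, alphabets, vectors


def read_count_table(
    source: IO[str] | str, orientation: str = "rows-are-symbols"
) -> CountMatrix:
    """Parse a delimited count table into a :class:`CountMatrix`.

    Cells must be non-negative and integral after rounding at 1e-9.
    ``orientation`` selects whether rows carry symbols (default) or
    positions.
    """
    frame = _parse_frame(_as_text(source))
    if orientation == "rows-are-positions":
        frame = frame.T
    elif orientation != "rows-are-symbols":
        raise ValidationError(f"unknown orientation {orientation!r}")
    positions, alphabets, vectors = _frame_to_records(frame, "count")
    for lab, v in zip(positions, vectors):
        if np.any(v < 0):
            raise ValidationError(f"negative count at position {lab!r}")
        if np.any(np.abs(v - np.round(v)) > 1e-9):
            raise ValidationError(f"non-integral count at position {lab!r}")
    return CountMatrix(positions, alphabets, [np.round(v) for v in vectors])


def read_probability_table(
    source: IO[str] | str,
    orientation: str = "rows-are-symbols",
    effective_count: float | None = None,
) -> ProbabilityMatrix:
    """Parse a delimited probability (or compositional-abundance) table.

    Each position's column is renormalized to sum to 1, so compositional
    data that is proportional to, but not exactly on, the simplex is
    accepted.  ``effective_count`` (default 1000) records the assumed
    precision of the values.
    """
    frame = _parse_frame(_as_text(source))
    if orientation == "rows-are-positions":
        frame = frame.T
    elif orientation != "rows-are-symbols":
        raise ValidationError(f"unknown orientation {orientation!r}")
    positions, alphabets, vectors = _frame_to_records(frame, "probability")
    vals = []
    for lab, v in zip(positions, vectors):
        if np.any(v < 0):
            raise ValidationError(f"negative probability at position {lab!r}")
        s = v.sum()
        if s <= 0:
            raise ValidationError(f"position {lab!r} sums to 0")
        vals.append(v / s)
    return ProbabilityMatrix(positions, alphabets, vals, effective_count=effective_count)


def read_background(source: IO[str] | str) -> Background:
    """Read a background distribution from a delimited table.

    A one-column table yields a shared vector applied at every position; a
    multi-column table yields a full per-position background matrix.
    """
    text = _as_text(source)
    pm = read_probability_table(text)
    if len(pm) == 1:
        return Background(vector=pm.values[0], alphabet=pm.alphabets[0])
    return Background(matrix=pm)


_JASPAR_ROW = re.compile(r"^\s*(\S+)\s*\[?\s*([-\d.\s]*?)\s*\]?\s*$")


def read_jaspar_pfm(source: IO[str] | str) -> CountMatrix:
    """Parse a JASPAR-dialect position frequency matrix.

    Expects a ``>`` header line followed by one row per base in file
    order, e.g. ``A [ 12  3  0 ]``.  Positions are labeled 1..L.
    """
    lines = [ln for ln in _as_text(source).splitlines() if ln.strip()]
    if not lines or not lines[0].lstrip().startswith(">"):
        raise FormatError("JASPAR PFM must start with a '>' header line")
    symbols, rows = [], []
    for ln in lines[1:]:
        m = _JASPAR_ROW.match(ln)
        if not m or not m.group(2).strip():
            raise FormatError(f"unparseable PFM row: {ln!r}")
        symbols.append(m.group(1))
        try:
            rows.append([float(x) for x in m.group(2).split()])
        except ValueError:
            raise FormatError(f"non-numeric count in PFM row: {ln!r}") from None
    if len(symbols) != 4:
        raise FormatError(f"expected 4 base rows in PFM, found {len(symbols)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"unequal PFM row lengths {sorted(lengths)}")
    L = lengths.pop()
    if L == 0:
        raise FormatError("PFM rows are empty")
    alph = Alphabet(symbols)
    mat = np.array(rows)  # symbols x positions
    return CountMatrix(list(range(1, L + 1)), [alph] * L, [mat[:, j] for j in range(L)])


def _tokenize(seq: str, tokenizer: str, delimiter: str) -> list[str]:
    if tokenizer == "single-char":
        return list(seq)
    if tokenizer == "delimiter":
        return [t for t in seq.split(delimiter)]
    raise ValidationError(f"unknown tokenizer {tokenizer!r}")


def counts_from_sequences(
    source: IO[str] | str,
    tokenizer: str = "single-char",
    delimiter: str = ",",
) -> CountMatrix:
    """Tokenize an aligned FASTA sequence set into per-position counts.

    All sequences must tokenize to the same length.  Each position's
    alphabet is the set of tokens observed there, in first-appearance
    order, so the per-position totals all equal the number of sequences.
    """
    handle = _io.StringIO(_as_text(source))
    token_rows = [
        _tokenize(str(rec.seq), tokenizer, delimiter)
        for rec in SeqIO.parse(handle, "fasta")
    ]
    if not token_rows:
        raise ValidationError("no sequences in FASTA input")
    lengths = {len(r) for r in token_rows}
    if len(lengths) != 1:
        raise ValidationError(f"sequences tokenize to unequal lengths {sorted(lengths)}")
    L = lengths.pop()
    if L == 0:
        raise ValidationError("sequences are empty")
    positions = list(range(1, L + 1))
    alphabets, vectors = [], []
    for j in range(L):
        counts: dict[str, int] = {}
        for row in token_rows:
            counts[row[j]] = counts.get(row[j], 0) + 1
        alphabets.append(Alphabet(counts.keys()))
        vectors.append(np.array(list(counts.values()), dtype=float))
    return CountMatrix(positions, alphabets, vectors)


def _format_cell(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _table_lines(table: PositionTable, delimiter: str) -> Iterable[str]:
    symbols = table.union_symbols()
    yield delimiter.join(["symbol"] + [str(p) for p in table.positions])
    for sym in symbols:
        cells = [sym]
        for alph, vec in zip(table.alphabets, table.values):
            if sym in alph:
                cells.append(_format_cell(vec[alph.index(sym)]))
            else:
                cells.append("")
        yield delimiter.join(cells)


def write_table(table: PositionTable, stream: IO[str], delimiter: str = "\t") -> None:
    """Serialize any position table as a delimited file (rows are symbols)."""
    for line in _table_lines(table, delimiter):
        stream.write(line + "\n")


def write_score_table(scores: ScoreMatrix, stream: IO[str], delimiter: str = "\t") -> None:
    """Serialize a score matrix with its mode/centering comment header."""
    stream.write(f"# mode = {scores.mode}\n")
    stream.write(f"# centering = {scores.centering}\n")
    write_table(scores, stream, delimiter)


def read_score_table(source: IO[str] | str) -> ScoreMatrix:
    """Parse a score table written by :func:`write_score_table`.

    Also accepts a bare delimited table of signed values (for example an
    externally computed PSSM); such input is tagged mode=raw.
    """
    text = _as_text(source)
    meta = {"mode": "raw", "centering": "none"}
    for ln in text.splitlines():
        m = re.match(r"^\s*#\s*(mode|centering)\s*=\s*(\S+)", ln)
        if m:
            meta[m.group(1)] = m.group(2)
    frame = _parse_frame(text)
    positions, alphabets, vectors = _frame_to_records(frame, "score")
    return ScoreMatrix(positions, alphabets, vectors, mode=meta["mode"], centering=meta["centering"])
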