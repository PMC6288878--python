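"""Position-indexed symbol matrices.

A logo describes, for each position along a sequence (or any other ordered
index set), a distribution over the symbols permitted at that position.
Symbols are arbitrary non-empty strings ("A", "C→T", "H3K4ME1"), and
different positions may carry different alphabets, so the fundamental
container here is a list of (position label, alphabet, value vector)
records rather than a rectangular array.  Rectangular inputs simply
populate identical alphabets at every position.

Containers
----------
:class:`Alphabet`
    Ordered, unique, non-empty symbol strings.
:class:`CountMatrix`
    Non-negative integer counts per (position, symbol).
:class:`ProbabilityMatrix`
    Per-position simplex vectors, with an *effective count* per position
    recording the precision of the estimates.
:class:`Background`
    A reference distribution, either one shared vector per alphabet or a
    full per-position :class:`ProbabilityMatrix`.
:class:`ScoreMatrix`
    Signed per-symbol heights with scoring-mode metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import SymbolLookupError, ValidationError

__all__ = [
    "Alphabet",
    "Background",
    "CountMatrix",
    "PositionTable",
    "ProbabilityMatrix",
    "ScoreMatrix",
    "normalize",
]

#: simplex tolerance for probability vectors
SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class Alphabet:
    """An ordered collection of unique, non-empty symbol strings.

    Symbol matching everywhere in the package is case-sensitive and
    exact-string: no DNA/RNA aliasing (``U`` is not ``T``), because symbols
    may be arbitrary strings where aliasing would be unsafe.

    Parameters
    ----------
    symbols:
        Symbols in display order (insertion order of the source).
    display:
        Optional per-symbol label overrides used only when rendering.
    """

    symbols: tuple[str, ...]
    display: Mapping[str, str] = field(default_factory=dict)

    def __init__(self, symbols: Iterable[str], display: Mapping[str, str] | None = None):
        symbols = tuple(symbols)
        seen = set()
        for s in symbols:
            if not isinstance(s, str) or not s.strip():
                raise ValidationError(f"alphabet symbol {s!r} is empty or whitespace-only")
            if s in seen:
                raise ValidationError(f"duplicate symbol {s!r} in alphabet")
            seen.add(s)
        if not symbols:
            raise ValidationError("alphabet must contain at least one symbol")
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "display", dict(display or {}))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise SymbolLookupError(f"symbol {symbol!r} not in alphabet {self.symbols}") from None

    def label(self, symbol: str) -> str:
        return self.display.get(symbol, symbol)


class PositionTable:
    """Base container: one value vector per position, each over its own alphabet."""

    def __init__(
        self,
        positions: Sequence[object],
        alphabets: Sequence[Alphabet],
        values: Sequence[np.ndarray],
    ):
        positions = list(positions)
        if len(set(map(str, positions))) != len(positions):
            raise ValidationError("duplicate position labels")
        if not (len(positions) == len(alphabets) == len(values)):
            raise ValidationError("positions, alphabets and values must have equal length")
        if not positions:
            raise ValidationError("matrix must contain at least one position")
        vals = []
        for lab, alph, v in zip(positions, alphabets, values):
            v = np.asarray(v, dtype=float)
            if v.shape != (len(alph),):
                raise ValidationError(
                    f"position {lab!r}: {len(alph)} symbols but {v.shape} values"
                )
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"position {lab!r}: non-finite values")
            vals.append(v)
        self.positions: list[object] = positions
        self.alphabets: list[Alphabet] = list(alphabets)
        self.values: list[np.ndarray] = vals

    # -- indexing ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.positions)

    def position_index(self, position: object) -> int:
        for i, lab in enumerate(self.positions):
            if lab == position or str(lab) == str(position):
                return i
        raise SymbolLookupError(f"unknown position {position!r}")

    def vector(self, position: object) -> np.ndarray:
        return self.values[self.position_index(position)]

    def alphabet(self, position: object) -> Alphabet:
        return self.alphabets[self.position_index(position)]

    def value(self, position: object, symbol: str) -> float:
        i = self.position_index(position)
        return float(self.values[i][self.alphabets[i].index(symbol)])

    # -- structure --------------------------------------------------------
    @property
    def is_rectangular(self) -> bool:
        first = self.alphabets[0].symbols
        return all(a.symbols == first for a in self.alphabets)

    def union_symbols(self) -> list[str]:
        """Symbols in first-appearance order across positions."""
        out: list[str] = []
        seen = set()
        for a in self.alphabets:
            for s in a.symbols:
                if s not in seen:
                    seen.add(s)
                    out.append(s)
        return out

    def same_axes(self, other: "PositionTable") -> bool:
        return len(self) == len(other) and all(
            a.symbols == b.symbols for a, b in zip(self.alphabets, other.alphabets)
        )

    def _eq_values(self, other: "PositionTable", atol: float = 0.0) -> bool:
        return (
            [str(p) for p in self.positions] == [str(p) for p in other.positions]
            and self.same_axes(other)
            and all(
                np.allclose(a, b, rtol=0.0, atol=atol)
                for a, b in zip(self.values, other.values)
            )
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionTable):
            return NotImplemented
        return type(self) is type(other) and self._eq_values(other)

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {len(self)} positions>"


class CountMatrix(PositionTable):
    """Non-negative integer counts per (position, symbol)."""

    def __init__(self, positions, alphabets, values):
        super().__init__(positions, alphabets, values)
        for lab, v in zip(self.positions, self.values):
            if np.any(v < 0):
                raise ValidationError(f"position {lab!r}: negative count")
            if np.any(np.abs(v - np.round(v)) > 1e-9):
                raise ValidationError(f"position {lab!r}: non-integral count")
        self.values = [np.round(v) for v in self.values]

    def totals(self) -> np.ndarray:
        """Per-position total count m."""
        return np.array([v.sum() for v in self.values])


class ProbabilityMatrix(PositionTable):
    """Per-position simplex vectors with an effective-count precision proxy.

    ``effective_count`` records, per position, the (pseudo) sample size the
    probabilities were estimated from; stabilizers use it to convert
    probability inputs back into counts.  Defaults to 1000, meaning the
    values are precise to no more than about 3 decimal places.
    """

    DEFAULT_EFFECTIVE_COUNT = 1000.0

    def __init__(self, positions, alphabets, values, effective_count=None):
        super().__init__(positions, alphabets, values)
        for lab, v in zip(self.positions, self.values):
            if np.any(v < 0):
                raise ValidationError(f"position {lab!r}: negative probability")
            if abs(v.sum() - 1.0) > SIMPLEX_TOL:
                raise ValidationError(
                    f"position {lab!r}: probabilities sum to {v.sum():.8f}, not 1"
                )
        if effective_count is None:
            effective_count = self.DEFAULT_EFFECTIVE_COUNT
        ec = np.broadcast_to(np.asarray(effective_count, dtype=float), (len(self),)).copy()
        if np.any(ec <= 0):
            raise ValidationError("effective_count must be positive")
        self.effective_count = ec

    def to_counts(self) -> CountMatrix:
        """Round ``p * effective_count`` into an integer CountMatrix."""
        vals = [np.round(v * ec) for v, ec in zip(self.values, self.effective_count)]
        return CountMatrix(self.positions, self.alphabets, vals)


class ScoreMatrix(PositionTable):
    """Signed per-symbol heights with scoring metadata.

    ``mode`` is one of ``edlogo`` (median-centered log2 enrichment, log2
    units), ``wkl`` (frequency-weighted log2 ratios), ``standard``
    (information-content logo, bits x probability, all values >= 0) or
    ``raw`` (uncentered log2 ratios).  ``centering`` records which median
    rule was applied (``none`` if the scores are uncentered).
    """

    MODES = ("edlogo", "wkl", "standard", "raw")
    CENTERINGS = ("smallest", "conventional", "largest", "none")

    def __init__(self, positions, alphabets, values, mode="raw", centering="none"):
        super().__init__(positions, alphabets, values)
        if mode not in self.MODES:
            raise ValidationError(f"unknown score mode {mode!r}")
        if centering not in self.CENTERINGS:
            raise ValidationError(f"unknown centering {centering!r}")
        if mode == "standard" and any(np.any(v < 0) for v in self.values):
            raise ValidationError("standard-mode scores must be non-negative")
        self.mode = mode
        self.centering = centering


class Background:
    """A reference distribution q against which enrichment is measured.

    Either one shared probability vector (applied to every position whose
    alphabet matches) or a full per-position :class:`ProbabilityMatrix`.
    Entries of q must be strictly positive at scoring time; zeros are
    rejected there with advice to stabilize first.
    """

    def __init__(
        self,
        vector: Sequence[float] | None = None,
        alphabet: Alphabet | None = None,
        matrix: ProbabilityMatrix | None = None,
        preset: str | None = None,
    ):
        if (vector is None) == (matrix is None):
            raise ValidationError("Background needs exactly one of vector or matrix")
        self.preset = preset
        self.matrix = matrix
        if vector is not None:
            if alphabet is None:
                raise ValidationError("shared background vector requires an alphabet")
            v = np.asarray(vector, dtype=float)
            if v.shape != (len(alphabet),):
                raise ValidationError("background vector length does not match alphabet")
            if np.any(v < 0):
                raise ValidationError("background probabilities must be non-negative")
            if abs(v.sum() - 1.0) > SIMPLEX_TOL:
                raise ValidationError(f"background sums to {v.sum():.8f}, not 1")
            self.vector = v
            self.vector_alphabet = alphabet
        else:
            self.vector = None
            self.vector_alphabet = None

    @classmethod
    def uniform(cls) -> "Background":
        """The 'uniform' preset: q_i = 1/n over whatever alphabet each position has."""
        bg = cls.__new__(cls)
        bg.preset = "uniform"
        bg.matrix = None
        bg.vector = None
        bg.vector_alphabet = None
        return bg

    def vector_for(self, position: object, alphabet: Alphabet) -> np.ndarray:
        """Resolve q for one position, aligned to ``alphabet``."""
        if self.preset == "uniform" and self.vector is None and self.matrix is None:
            n = len(alphabet)
            return np.full(n, 1.0 / n)
        if self.vector is not None:
            if self.vector_alphabet.symbols != alphabet.symbols:
                raise ValidationError(
                    f"background alphabet {self.vector_alphabet.symbols} does not match "
                    f"position {position!r} alphabet {alphabet.symbols}"
                )
            return self.vector
        i = self.matrix.position_index(position)
        if self.matrix.alphabets[i].symbols != alphabet.symbols:
            raise ValidationError(
                f"background alphabet mismatch at position {position!r}"
            )
        return self.matrix.values[i]

    def as_probability_matrix(self, like: PositionTable) -> ProbabilityMatrix:
        """Expand to a full matrix on the axes of ``like``."""
        vals = [
            self.vector_for(lab, alph).copy()
            for lab, alph in zip(like.positions, like.alphabets)
        ]
        ec = getattr(like, "effective_count", ProbabilityMatrix.DEFAULT_EFFECTIVE_COUNT)
        return ProbabilityMatrix(like.positions, like.alphabets, vals, effective_count=ec)


def normalize(counts: CountMatrix, effective_count_override: float | None = None) -> ProbabilityMatrix:
    """Maximum-likelihood probabilities p_i = m_i / m from counts.

    The per-position effective count is the observed total m unless
    overridden.  A position with total zero has no MLE and is rejected.
    """
    totals = counts.totals()
    for lab, m in zip(counts.positions, totals):
        if m <= 0:
            raise ValidationError(f"position {lab!r} has total count 0; cannot normalize")
    vals = [v / v.sum() for v in counts.values]
    ec = totals if effective_count_override is None else float(effective_count_override)
    if effective_count_override is not None and effective_count_override <= 0:
        raise ValidationError("effective_count_override must be positive")
    return ProbabilityMatrix(counts.positions, counts.alphabets, vals, effective_count=ec)
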