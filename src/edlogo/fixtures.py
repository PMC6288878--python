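"""Bundled worked-example matrices and a synthetic-data generator.

:func:`paper_fixtures` constructs, in memory, the small printed matrices
used throughout the documentation and tests: the four-base illustration
vector p = (0.33, 0.33, 0.33, 0.01), the even-n tie vector (0, 0, 1, 1),
the degenerate glycosylation center column (one amino acid observed 5422
times, nineteen never), and a mutational-signature-style center column
over six substitution-type strings.  The same matrices ship as delimited
files under ``edlogo/data/fixtures`` for CLI use; flanking positions and
backgrounds that the printed sources do not determine are synthetic
stand-ins and marked as such in the file headers.

:class:`SyntheticSpec` / :func:`generate` produce count matrices with a
known truth: designated symbols receive exact log2 enrichments over a
chosen background, remaining symbols share the leftover mass in
proportion to the background, and counts are drawn multinomially at a
chosen depth.  The true uncentered log ratios are returned alongside, so
estimator-recovery tests can measure error directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .matrices import (
    Alphabet,
    Background,
    CountMatrix,
    ProbabilityMatrix,
    ScoreMatrix,
)

__all__ = ["paper_fixtures", "fixture_path", "SyntheticSpec", "generate"]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
DNA = Alphabet(("A", "C", "G", "T"))
MUTATION_TYPES = Alphabet(("C→A", "C→G", "C→T", "T→A", "T→C", "T→G"))

# generic Swiss-Prot-style composition; synthetic stand-in for a real
# proteome background (percent, renormalized below)
_AA_PERCENT = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86, "G": 7.07,
    "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66, "M": 2.42, "N": 4.06,
    "P": 4.70, "Q": 3.93, "R": 5.53, "S": 6.56, "T": 5.34, "V": 6.87,
    "W": 1.08, "Y": 2.92,
}


def fixture_path(name: str):
    """Filesystem path of a bundled fixture file."""
    return resources.files("edlogo").joinpath("data", "fixtures", name)


def paper_fixtures() -> dict[str, object]:
    """The worked-example inputs, constructed programmatically."""
    fig1 = ProbabilityMatrix([1], [DNA], [np.array([0.33, 0.33, 0.33, 0.01])])
    tie = ScoreMatrix(
        [1], [Alphabet(("w", "x", "y", "z"))], [np.array([0.0, 0.0, 1.0, 1.0])],
        mode="raw", centering="none",
    )
    aa = Alphabet(AMINO_ACIDS)
    glyco = CountMatrix(
        [0], [aa], [np.array([5422.0 if s == "N" else 0.0 for s in AMINO_ACIDS])]
    )
    qv = np.array([_AA_PERCENT[s] for s in AMINO_ACIDS])
    aa_bg = Background(vector=qv / qv.sum(), alphabet=aa)
    # the four minor substitution types pad the printed 0.96/0.03 at 0.01/4
    sig_center = {"C→T": 0.96, "T→C": 0.03, "C→A": 0.0025, "C→G": 0.0025,
                  "T→A": 0.0025, "T→G": 0.0025}
    sig12 = ProbabilityMatrix(
        [0], [MUTATION_TYPES],
        [np.array([sig_center[s] for s in MUTATION_TYPES])],
    )
    return {
        "fig1_probs": fig1,
        "tie_tilde_r": tie,
        "glyco_center_counts": glyco,
        "aa_background": aa_bg,
        "sig12_center_probs": sig12,
    }


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic count matrix with known enrichment truth.

    Parameters
    ----------
    n_positions:
        Number of positions.
    alphabets:
        One :class:`Alphabet` per position, or a single alphabet shared by
        all; defaults to A/C/G/T everywhere.
    effects:
        Per position, a mapping symbol -> log2 enrichment over background.
        Designated symbols get p_i = q_i * 2**effect exactly; the rest
        share the leftover probability in proportion to q.  Positions
        without an entry draw p from a symmetric Dirichlet instead.
    concentration:
        Dirichlet concentration for positions without explicit effects
        (larger = closer to background-shaped noise).
    background:
        ``"uniform"`` or one probability vector per position.
    depth:
        Multinomial count total m per position.
    seed:
        Seed for the count draw (and any Dirichlet positions).
    """

    n_positions: int = 1
    alphabets: Sequence[Alphabet] | Alphabet | None = None
    effects: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    concentration: float = 5.0
    background: str | Sequence[Sequence[float]] = "uniform"
    depth: int = 1000
    seed: int = 0

    def resolved_alphabets(self) -> list[Alphabet]:
        if self.alphabets is None:
            return [DNA] * self.n_positions
        if isinstance(self.alphabets, Alphabet):
            return [self.alphabets] * self.n_positions
        alphs = list(self.alphabets)
        if len(alphs) != self.n_positions:
            raise ValidationError("need one alphabet per position")
        return alphs


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, Background, ScoreMatrix]:
    """Draw a synthetic count matrix; return (counts, background, true log ratios).

    Counts are multinomial at ``spec.depth`` per position (matching the
    sampling view of count-derived frequency estimates); the returned
    truth holds r̃ = log2(p/q), uncentered.
    """
    if spec.depth <= 0:
        raise ValidationError("depth m must be positive")
    if spec.n_positions <= 0:
        raise ValidationError("need at least one position")
    rng = np.random.default_rng(spec.seed)
    alphs = spec.resolved_alphabets()
    positions = list(range(1, spec.n_positions + 1))

    qvecs: list[np.ndarray] = []
    for j, alph in enumerate(alphs):
        if isinstance(spec.background, str):
            if spec.background != "uniform":
                raise ValidationError(f"unknown background preset {spec.background!r}")
            qvecs.append(np.full(len(alph), 1.0 / len(alph)))
        else:
            qv = np.asarray(spec.background[j], dtype=float)
            if qv.shape != (len(alph),) or np.any(qv <= 0):
                raise ValidationError(f"invalid background vector at position {j}")
            qvecs.append(qv / qv.sum())

    pvecs: list[np.ndarray] = []
    for j, (alph, qv) in enumerate(zip(alphs, qvecs)):
        eff = dict(spec.effects.get(j, {}))
        if eff:
            p = np.zeros(len(alph))
            fixed = np.zeros(len(alph), dtype=bool)
            for sym, e in eff.items():
                i = alph.index(sym)
                p[i] = qv[i] * 2.0 ** float(e)
                fixed[i] = True
            used = p[fixed].sum()
            if used >= 1.0:
                raise ValidationError(
                    f"effects at position {j} imply probability mass {used:.4f} >= 1"
                )
            if not np.all(~fixed) and (~fixed).sum() == 0 and abs(used - 1.0) > 1e-9:
                raise ValidationError(f"effects at position {j} fix all symbols but mass != 1")
            rest = qv[~fixed]
            p[~fixed] = (1.0 - used) * rest / rest.sum()
        else:
            p = rng.dirichlet(np.full(len(alph), spec.concentration))
            p = np.maximum(p, 1e-12)
            p = p / p.sum()
        pvecs.append(p)

    counts = [rng.multinomial(spec.depth, p).astype(float) for p in pvecs]
    fg = CountMatrix(positions, alphs, counts)
    if all(np.allclose(qv, qvecs[0]) and a.symbols == alphs[0].symbols
           for qv, a in zip(qvecs, alphs)):
        bg = Background(vector=qvecs[0], alphabet=alphs[0])
    else:
        bg = Background(matrix=ProbabilityMatrix(positions, alphs, qvecs))
    truth = ScoreMatrix(
        positions, alphs, [np.log2(p / q) for p, q in zip(pvecs, qvecs)],
        mode="raw", centering="none",
    )
    return fg, bg, truth
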