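"""Per-position height vectors for enrichment-depletion, standard and wKL logos.

The enrichment-depletion (ED) logo compares an observed symbol
distribution p with a background q by plotting, for each symbol i,

    r_i = log2(p_i / q_i) - c,

where c is a per-position median of the raw log2 ratios.  Subtracting the
median is a parsimony choice: among all height vectors of the form
log2(p_i/q_i) + k (the log scale of the multiplicative model
p_i ∝ λ_i q_i, where k is unidentifiable), the median-centered one has the
smallest total stack height Σ|r_i|.  Positive r_i is drawn above the axis
("enriched relative to the median symbol"), negative below ("depleted").

With an even number of symbols the minimizing offset is not unique: every
value in the closed interval between the two central order statistics
yields the same Σ|r_i|.  Three centering rules select an endpoint or the
midpoint of that interval:

``smallest``
    the lower central order statistic — favors an enrichment reading and
    is the default;
``conventional``
    the mean of the two central order statistics — the textbook median;
    the only rule under which swapping p and q exactly mirrors the logo
    about the x axis;
``largest``
    the upper central order statistic — favors a depletion reading.

For odd n all three coincide with the middle order statistic.

Differences of heights are centering-free:  r_a - r_b equals the log-odds
ratio log2((p_a/p_b)/(q_a/q_b)) under every rule.

Two comparison scorers are provided: the standard information-content
logo (heights p_i * IC, IC in bits against a uniform reference) and the
weighted Kullback-Leibler logo (heights p_i * log2(p_i/q_i), signed).
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, ValidationError
from .matrices import Background, ProbabilityMatrix, ScoreMatrix

__all__ = [
    "log_ratios",
    "median_center",
    "centering_constant",
    "edlogo_scores",
    "stack_height",
    "standard_logo_scores",
    "wkl_scores",
    "log_odds",
]

CENTERING_RULES = ("smallest", "conventional", "largest")


def log_ratios(p: ProbabilityMatrix, q: Background) -> ScoreMatrix:
    """Raw per-symbol log2 enrichment ratios log2(p_i / q_i), uncentered.

    Zeros in p or q make the ratio infinite and are rejected; stabilize
    the estimates first (pseudocounts or EB shrinkage) if the data contain
    unobserved symbols.
    """
    vals = []
    for lab, alph, pv in zip(p.positions, p.alphabets, p.values):
        qv = q.vector_for(lab, alph)
        for sym, pi, qi in zip(alph, pv, qv):
            if qi <= 0:
                raise DomainError(
                    f"background probability is {qi} at (position {lab!r}, symbol "
                    f"{sym!r}); log ratios need q > 0 — stabilize the background first"
                )
            if pi <= 0:
                raise DomainError(
                    f"probability is {pi} at (position {lab!r}, symbol {sym!r}); "
                    "log ratios need p > 0 — apply a stabilizer (pseudocount or eb)"
                )
        vals.append(np.log2(pv / qv))
    return ScoreMatrix(p.positions, p.alphabets, vals, mode="raw", centering="none")


def centering_constant(values: np.ndarray, rule: str) -> float:
    """The per-position offset subtracted by :func:`median_center`.

    Odd n: the middle order statistic (all rules coincide).  Even n: the
    lower central order statistic (``smallest``), their mean
    (``conventional``) or the upper one (``largest``) — the endpoints and
    midpoint of the interval of offsets minimizing the total stack height.
    """
    if rule not in CENTERING_RULES:
        raise ValidationError(f"unknown centering rule {rule!r}")
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValidationError("cannot center an empty position")
    if n % 2 == 1:
        return float(v[n // 2])
    lo, hi = float(v[n // 2 - 1]), float(v[n // 2])
    if rule == "smallest":
        return lo
    if rule == "largest":
        return hi
    return (lo + hi) / 2.0


def median_center(scores: ScoreMatrix, rule: str = "smallest") -> ScoreMatrix:
    """Subtract a per-position median from any score matrix.

    Works on raw log ratios and equally on externally derived quantities
    such as a PSSM, where the same adjustment reduces visual clutter.
    The result is tagged mode=edlogo.
    """
    vals = [v - centering_constant(v, rule) for v in scores.values]
    return ScoreMatrix(scores.positions, scores.alphabets, vals, mode="edlogo", centering=rule)


def edlogo_scores(p: ProbabilityMatrix, q: Background, rule: str = "smallest") -> ScoreMatrix:
    """Median-centered log2 enrichment scores (the ED logo heights).

    The default rule is ``smallest`` — the enrichment-favoring endpoint of
    the median interval; pass ``conventional`` to restore the mirror
    property under p/q exchange.
    """
    return median_center(log_ratios(p, q), rule)


def stack_height(scores: ScoreMatrix, position: object) -> float:
    """Total stacked-glyph height Σ_i |r_i| at one position."""
    return float(np.abs(scores.vector(position)).sum())


def standard_logo_scores(p: ProbabilityMatrix, n_ref: int | None = None) -> ScoreMatrix:
    """Classic information-content logo heights.

    height_i = p_i * IC with IC = log2(n_ref) + Σ p_i log2 p_i (bits,
    0*log2(0) = 0); n_ref defaults to each position's alphabet size.  The
    stack height equals the information content exactly.
    """
    if n_ref is not None and n_ref < 2:
        raise ValidationError("n_ref must be at least 2")
    vals = []
    for alph, pv in zip(p.alphabets, p.values):
        n = len(alph) if n_ref is None else n_ref
        if n < 2:
            raise ValidationError("alphabet size below 2 has no information content")
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pv > 0, pv * np.log2(np.where(pv > 0, pv, 1.0)), 0.0)
        ic = max(np.log2(n) + plogp.sum(), 0.0)
        vals.append(pv * ic)
    return ScoreMatrix(p.positions, p.alphabets, vals, mode="standard", centering="none")


def wkl_scores(p: ProbabilityMatrix, q: Background) -> ScoreMatrix:
    """Weighted Kullback-Leibler logo heights p_i * log2(p_i / q_i).

    Signed: depleted symbols get negative heights.  Zero probabilities map
    to height 0.  Provided for comparison with the ED logo; unlike it,
    these heights are frequency-weighted, so rare but strongly enriched
    symbols are visually suppressed.
    """
    vals = []
    for lab, alph, pv in zip(p.positions, p.alphabets, p.values):
        qv = q.vector_for(lab, alph)
        if np.any(qv <= 0):
            sym = alph.symbols[int(np.argmax(qv <= 0))]
            raise DomainError(
                f"background probability must be positive at (position {lab!r}, "
                f"symbol {sym!r})"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(pv > 0, pv * np.log2(np.where(pv > 0, pv, 1.0) / qv), 0.0)
        vals.append(h)
    return ScoreMatrix(p.positions, p.alphabets, vals, mode="wkl", centering="none")


def log_odds(scores: ScoreMatrix, position: object, symbol_a: str, symbol_b: str) -> float:
    """Height difference r_a - r_b at one position.

    For ED-logo scores this equals the log-odds ratio
    log2((p_a/p_b) / (q_a/q_b)), independent of the centering rule, since
    the per-position constant cancels.
    """
    i = scores.position_index(position)
    alph = scores.alphabets[i]
    v = scores.values[i]
    return float(v[alph.index(symbol_a)] - v[alph.index(symbol_b)])
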