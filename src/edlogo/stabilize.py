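"""Stabilized estimation of log2 enrichment ratios from count data.

Raw log2(p/q) estimates explode when symbols are rare or unobserved: a
zero count gives an infinite ratio, and low counts give wildly noisy
ones.  Two stabilizers are provided.

Pseudocounts
    p̂_i = (m_i + c) / (m + n c) with c = 0.5 by default, applied to every
    count-valued input.  Simple, but it inherits the background's
    structure: two symbols that are both entirely absent from the
    foreground still get different log-ratio estimates whenever their
    background rates differ, so an unobserved symbol can appear strongly
    "enriched" or "depleted" purely because of q.

Empirical Bayes shrinkage
    Stabilizes the log-ratio estimates directly.  Per (position, symbol)
    cell we form a point estimate of the log2 ratio with a half-count
    offset, attach a delta-method standard error, and fit a normal-means
    model across all cells jointly: the prior on the deviation of each
    cell from its position's median log ratio is a unimodal mixture of a
    point mass at zero and zero-centered normals on an adaptive variance
    grid, with mixture weights estimated by maximum marginal likelihood
    (EM).  Posterior means are returned.  Cells with little data have
    large standard errors and are pulled hard onto the position baseline,
    so unobserved symbols end up with nearly identical estimates
    regardless of their background rates — while cells backed by many
    counts keep their data-driven values (the estimates converge to the
    MLE log ratios as counts grow).

Probability-valued inputs are converted to counts by rounding against the
matrix's effective count (default 1000, i.e. values trusted to about 3
decimal places) before EB shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .matrices import (
    Background,
    CountMatrix,
    ProbabilityMatrix,
    ScoreMatrix,
    normalize,
)
from .scoring import edlogo_scores, median_center

__all__ = [
    "StabilizerConfig",
    "pseudocount_probs",
    "eb_shrink_log_ratios",
    "stabilized_edlogo",
]

LN2 = float(np.log(2.0))


@dataclass
class StabilizerConfig:
    """Configuration for the stabilization step.

    Parameters
    ----------
    method:
        ``none``, ``pseudocount`` or ``eb``.
    pseudocount:
        The constant c added to every count (default 0.5, half a count).
    effective_count:
        Pseudo sample size assumed when an input arrives as probabilities
        rather than counts (default 1000).
    prior:
        Tag for the EB prior family; only ``normal_mixture`` is defined.
    seed:
        Seed for any sampling step.  The EB fit itself is deterministic
        (EM from a fixed initialization), so the seed only matters for
        extensions that sample.
    """

    method: str = "eb"
    pseudocount: float = 0.5
    effective_count: float = 1000.0
    prior: str = "normal_mixture"
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("none", "pseudocount", "eb"):
            raise ValidationError(f"unknown stabilizer method {self.method!r}")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.effective_count < 1:
            raise ValidationError("effective_count must be >= 1")

    @classmethod
    def from_mapping(cls, mapping) -> "StabilizerConfig":
        known = {"method", "pseudocount", "effective_count", "prior", "seed"}
        kwargs = {}
        for key, val in dict(mapping).items():
            if key not in known:
                raise ValidationError(f"unknown stabilizer config key {key!r}")
            if key in ("pseudocount", "effective_count"):
                val = float(val)
            elif key == "seed":
                val = int(val)
            kwargs[key] = val
        return cls(**kwargs)


def pseudocount_probs(counts: CountMatrix, c: float = 0.5) -> ProbabilityMatrix:
    """Pseudocount-stabilized probabilities p̂_i = (m_i + c) / (m + n c).

    Strictly positive for any c > 0; the effective count is the inflated
    total m + n c.
    """
    if c <= 0:
        raise ValidationError("pseudocount must be positive")
    vals, ecs = [], []
    for alph, v in zip(counts.alphabets, counts.values):
        n = len(alph)
        total = v.sum() + n * c
        vals.append((v + c) / total)
        ecs.append(total)
    return ProbabilityMatrix(counts.positions, counts.alphabets, vals, effective_count=np.array(ecs))


def _background_counts(
    bg: CountMatrix | Background | ProbabilityMatrix,
    like: CountMatrix,
    effective_count: float,
) -> CountMatrix:
    """Coerce any background form into counts on the axes of ``like``."""
    if isinstance(bg, CountMatrix):
        if not bg.same_axes(like):
            raise ValidationError("foreground and background alphabets do not agree")
        return bg
    if isinstance(bg, Background):
        pm = bg.as_probability_matrix(like)
    elif isinstance(bg, ProbabilityMatrix):
        if not bg.same_axes(like):
            raise ValidationError("foreground and background alphabets do not agree")
        pm = bg
    else:
        raise ValidationError(f"unsupported background type {type(bg).__name__}")
    vals = [np.round(v * effective_count) for v in pm.values]
    return CountMatrix(like.positions, like.alphabets, vals)


def _point_estimates(fg: np.ndarray, bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-count log2-ratio point estimates and delta-method SEs for one position."""
    n = fg.size
    m, b = fg.sum(), bg.sum()
    fg_off, bg_off = fg + 0.5, bg + 0.5
    mt, bt = m + 0.5 * n, b + 0.5 * n
    x = (np.log(fg_off / mt) - np.log(bg_off / bt)) / LN2
    # var(log p̂) ≈ (1-p)/(m p) evaluated at the offset counts; zero-count
    # cells thus get the (large) SE of a half-count cell
    var = (
        np.clip(1.0 / fg_off - 1.0 / mt, 0.0, None)
        + np.clip(1.0 / bg_off - 1.0 / bt, 0.0, None)
    ) / LN2**2
    return x, np.sqrt(np.maximum(var, 1e-300))


def _mixture_grid(d: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Point mass plus a geometric grid of prior standard deviations."""
    span = max(float(np.max(np.abs(d))), 1e-3)
    lo = max(float(np.min(s)) / 10.0, 1e-6)
    hi = 2.0 * span
    if hi <= lo:
        hi = 2.0 * lo
    k = int(np.ceil(2.0 * np.log2(hi / lo))) + 1
    taus = lo * (np.sqrt(2.0) ** np.arange(k))
    taus = taus[taus <= hi * np.sqrt(2.0)]
    return np.concatenate([[0.0], taus])


def _fit_normal_mixture(
    d: np.ndarray, s: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """EM for mixture weights maximizing the marginal likelihood; returns posterior means.

    Observation model d_i ~ N(delta_i, s_i^2); prior
    delta ~ Σ_k π_k N(0, τ_k^2) with τ_0 = 0 a point mass.  Deterministic:
    uniform weight initialization, fixed grid, convergence at ``tol`` on
    the mean log-likelihood.
    """
    taus = _mixture_grid(d, s)
    sd = np.sqrt(s[:, None] ** 2 + taus[None, :] ** 2)  # cells x components
    lik = norm.pdf(d[:, None], loc=0.0, scale=sd)
    pi = np.full(taus.size, 1.0 / taus.size)
    last = -np.inf
    for _ in range(max_iter):
        weighted = lik * pi[None, :]
        total = weighted.sum(axis=1)
        total = np.maximum(total, 1e-300)
        resp = weighted / total[:, None]
        pi = resp.mean(axis=0)
        ll = float(np.mean(np.log(total)))
        if ll - last < tol:
            break
        last = ll
    weighted = lik * pi[None, :]
    total = np.maximum(weighted.sum(axis=1), 1e-300)
    resp = weighted / total[:, None]
    shrink = taus[None, :] ** 2 / (taus[None, :] ** 2 + s[:, None] ** 2)
    return (resp * shrink).sum(axis=1) * d


def eb_shrink_log_ratios(
    fg: CountMatrix,
    bg: CountMatrix | Background | ProbabilityMatrix,
    config: StabilizerConfig | None = None,
) -> ScoreMatrix:
    """Empirical-Bayes-shrunken estimates of the log2 ratios, uncentered.

    Finite for every symbol, including zero-count ones.  Shrinkage is fit
    jointly across all (position, symbol) cells, with each cell's prior
    centered at its position's median point estimate.
    """
    config = config or StabilizerConfig(method="eb")
    bgc = _background_counts(bg, fg, config.effective_count)
    xs, ss, mus, sizes = [], [], [], []
    for fv, bv in zip(fg.values, bgc.values):
        x, s = _point_estimates(fv, bv)
        xs.append(x)
        ss.append(s)
        mus.append(float(np.median(x)))
        sizes.append(x.size)
    d = np.concatenate([x - mu for x, mu in zip(xs, mus)])
    s = np.concatenate(ss)
    post = _fit_normal_mixture(d, s)
    vals, start = [], 0
    for mu, n in zip(mus, sizes):
        vals.append(mu + post[start : start + n])
        start += n
    return ScoreMatrix(fg.positions, fg.alphabets, vals, mode="raw", centering="none")


def stabilized_edlogo(
    fg: CountMatrix | ProbabilityMatrix,
    bg: Background | CountMatrix | ProbabilityMatrix,
    config: StabilizerConfig | None = None,
    rule: str = "smallest",
) -> ScoreMatrix:
    """End-to-end stabilized ED-logo scores from count (or probability) data.

    method=none
        MLE probabilities, then median-centered log ratios; errors on any
        zero probability.
    method=pseudocount
        Pseudocounts on every count-valued side.  A background supplied as
        probabilities is used as-is (it needs no zero-count repair); a
        count background is pseudocounted like the foreground.
    method=eb
        :func:`eb_shrink_log_ratios`, then median centering.
    """
    config = config or StabilizerConfig()
    if isinstance(fg, ProbabilityMatrix) and config.method in ("pseudocount", "eb"):
        fg = fg.to_counts()
    if config.method == "none":
        p = normalize(fg) if isinstance(fg, CountMatrix) else fg
        q = _as_background(bg, p, stabilize=False)
        return edlogo_scores(p, q, rule)
    if config.method == "pseudocount":
        p = pseudocount_probs(fg, config.pseudocount)
        q = _as_background(bg, p, stabilize=True, c=config.pseudocount)
        return edlogo_scores(p, q, rule)
    raw = eb_shrink_log_ratios(fg, bg, config)
    return median_center(raw, rule)


def _as_background(bg, like, stabilize: bool, c: float = 0.5) -> Background:
    if isinstance(bg, Background):
        return bg
    if isinstance(bg, CountMatrix):
        pm = pseudocount_probs(bg, c) if stabilize else normalize(bg)
        return Background(matrix=pm)
    if isinstance(bg, ProbabilityMatrix):
        return Background(matrix=bg)
    raise ValidationError(f"unsupported background type {type(bg).__name__}")
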