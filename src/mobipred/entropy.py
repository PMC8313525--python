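"""Entropy measures and the Fano predictability bound for symbolic sequences.

Three entropies, all in bits, characterise a location sequence with L
distinct symbols:

* random entropy  S_rand = log2(L) — every location equally likely;
* uncorrelated entropy  S_unc = -sum_k p_k log2 p_k — visit frequencies
  known, order ignored;
* actual entropy  S_est — the entropy *rate*, capturing temporal order,
  estimated with the Lempel-Ziv match-length estimator
  S_est = (mean_j Lambda_j)^(-1) log2 n,
  where Lambda_j is the length of the shortest substring starting at
  position j that does not occur (as a contiguous block) anywhere within the
  first j-1 positions.  When every substring starting at j already occurs in
  that prefix, Lambda_j = n - j + 2.  Lambda_1 = 1 (the empty prefix
  contains nothing); this convention is isolated in :func:`lz_match_lengths`.

Each entropy E maps to a maximum prediction accuracy Pi by solving Fano's
inequality
    E = -Pi log2 Pi - (1-Pi) log2(1-Pi) + (1-Pi) log2(L-1)
for the unique root Pi in [1/L, 1]; the logarithm base must match the one
used for the entropies (base 2 throughout).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import check_row_stochastic, stationary_distribution


@dataclass(frozen=True)
class EntropyResult:
    s_rand: float
    s_unc: float
    s_est: float
    n: int  # sequence length used
    L: int  # distinct symbols


@dataclass(frozen=True)
class PredictabilityResult:
    pi_rand: float
    pi_unc: float
    pi_max: float


def random_entropy(L: int) -> float:
    """log2 of the number of distinct locations."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return math.log2(L)


def uncorrelated_entropy(symbol_counts: Mapping) -> float:
    """Shannon entropy (bits) of empirical visit frequencies.

    Zero-count symbols are ignored (0 log 0 := 0).
    """
    counts = np.asarray([c for c in symbol_counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("no symbols with positive count")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _drop_nulls(symbols: Sequence) -> list:
    out = []
    for s in symbols:
        if s is None:
            continue
        if isinstance(s, float) and math.isnan(s):
            continue
        out.append(s)
    return out


def lz_match_lengths(symbols: Sequence) -> np.ndarray:
    """The Lambda vector of the Lempel-Ziv entropy estimator.

    Lambda_j (1-indexed) is the length of the shortest substring starting at
    j absent from the prefix of length j-1; if no such substring exists
    within the sequence, Lambda_j = n - j + 2.
    """
    n = len(symbols)
    if n == 0:
        return np.zeros(0, dtype=int)
    # map symbols to characters so the scan can use C-speed str.find
    codes: dict = {}
    s = "".join(chr(0x100 + codes.setdefault(sym, len(codes))) for sym in symbols)
    lam = np.empty(n, dtype=int)
    prev = 1
    for i in range(n):
        max_len = n - i
        length = max(1, prev - 1)
        while length <= max_len and s.find(s[i : i + length], 0, i) != -1:
            length += 1
        # length > max_len means even the full tail occurs in the prefix
        lam[i] = length if length <= max_len else max_len + 1  # = n - j + 2
        prev = lam[i]
    return lam


def lz_entropy_estimate(symbols: Sequence, drop_nulls: bool = True) -> float:
    """Lempel-Ziv estimate of the entropy rate, in bits per symbol.

    Nulls (None/NaN) are removed and the remainder concatenated before
    estimation when ``drop_nulls`` is set; correcting the resulting bias is
    the job of the missing-data estimators, not of this function.
    """
    syms = _drop_nulls(symbols) if drop_nulls else list(symbols)
    n = len(syms)
    if n < 2:
        raise ValueError("Lempel-Ziv estimator needs at least 2 symbols")
    lam = lz_match_lengths(syms)
    return float(n / lam.sum() * math.log2(n))


def _fano_value(pi: float, L: int) -> float:
    """The Fano right-hand side F(pi) for L >= 2."""

    def xlog2(v: float) -> float:
        return v * math.log2(v) if v > 0 else 0.0

    return -xlog2(pi) - xlog2(1.0 - pi) + (1.0 - pi) * math.log2(L - 1)


def solve_fano(E: float, L: int) -> float:
    """Invert Fano's inequality: the maximum accuracy Pi for entropy E (bits).

    F is strictly decreasing on [1/L, 1] with F(1/L) = log2 L and F(1) = 0,
    so bisection converges unconditionally; tolerance 1e-10 bits.  An E above
    log2 L (possible from estimator noise on short sequences) clamps to the
    floor 1/L with a warning.
    """
    if E < 0:
        raise ValueError("entropy must be non-negative")
    if L < 1:
        raise ValueError("L must be >= 1")
    if L == 1:
        return 1.0
    log2L = math.log2(L)
    if E >= log2L:
        if E > log2L + 1e-12:
            warnings.warn(
                f"entropy {E:.4f} bits exceeds log2(L)={log2L:.4f}; "
                "predictability clamped to 1/L",
                RuntimeWarning,
                stacklevel=2,
            )
        return 1.0 / L
    if E == 0.0:
        return 1.0
    lo, hi = 1.0 / L, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = _fano_value(mid, L)
        if abs(f - E) < 1e-10:
            return mid
        if f > E:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def predictability_profile(seq) -> tuple[EntropyResult, PredictabilityResult]:
    """All three entropies and predictabilities of a symbolic sequence.

    ``seq`` may be a TimeBinSequence, a PlaceSequence, or any sequence of
    symbols (None/NaN treated as nulls and dropped).  A sequence reduced to a
    single distinct symbol is completely predictable: all entropies are 0 and
    all predictabilities 1.
    """
    symbols = getattr(seq, "symbols", seq)
    syms = _drop_nulls(symbols)
    if not syms:
        raise ValueError("sequence has no non-null symbols")
    counts = Counter(syms)
    n, L = len(syms), len(counts)
    if L == 1:
        ent = EntropyResult(0.0, 0.0, 0.0, n, 1)
        return ent, PredictabilityResult(1.0, 1.0, 1.0)
    s_rand = random_entropy(L)
    s_unc = uncorrelated_entropy(counts)
    s_est = lz_entropy_estimate(syms, drop_nulls=False)
    ent = EntropyResult(s_rand, s_unc, s_est, n, L)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # short-sequence clamping
        pred = PredictabilityResult(
            pi_rand=solve_fano(s_rand, L),
            pi_unc=solve_fano(s_unc, L),
            pi_max=solve_fano(s_est, L),
        )
    return ent, pred


def markov_entropy_rate(transition_matrix) -> float:
    """Exact entropy rate H = -sum_i pi_i sum_j P_ij log2 P_ij of an
    irreducible Markov chain, in bits per step."""
    P = check_row_stochastic(transition_matrix)
    pi = stationary_distribution(P)  # raises on reducible chains
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    return float(-(pi[:, None] * plogp).sum())
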