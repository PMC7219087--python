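"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain Python
loops, string slicing and exact rational arithmetic only.
"""

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def window_score_loop(weights, window: str) -> float:
    """Sum of per-position weights by explicit iteration (weights: 4xL list)."""
    return sum(weights[_BASES.index(b)][j] for j, b in enumerate(window))


def brute_best_match(weights, seq: str):
    """Exhaustive best (score, offset, strand) over every offset x strand.

    Ties: smaller offset first, then '+' before '-'.  Returns None when no
    N-free window exists.  ``weights`` is a 4xL nested list.
    """
    L = len(weights[0])
    best = None
    for off in range(len(seq) - L + 1):
        fwd = seq[off : off + L]
        if "N" in fwd:
            continue
        for strand, window in (("+", fwd), ("-", revcomp(fwd))):
            s = window_score_loop(weights, window)
            key = (-s, off, 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, s, off, strand)
    if best is None:
        return None
    return best[1], best[2], best[3]


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact combinatorial sums."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def mixture_loglik_direct(x, model) -> float:
    """Direct evaluation of the two-component mixture log-likelihood."""
    from math import exp, log, pi, sqrt

    def phi(v, mu, sd):
        return exp(-((v - mu) ** 2) / (2 * sd**2)) / (sd * sqrt(2 * pi))

    return sum(
        log(
            model.pi_low * phi(v, model.mu_low, model.sigma_low)
            + model.pi_high * phi(v, model.mu_high, model.sigma_high)
        )
        for v in x
    )


def posterior_direct(model, score: float) -> float:
    """Two-term Bayes ratio for the high component, by plain arithmetic."""
    from math import exp, pi, sqrt

    def phi(v, mu, sd):
        return exp(-((v - mu) ** 2) / (2 * sd**2)) / (sd * sqrt(2 * pi))

    hi = model.pi_high * phi(score, model.mu_high, model.sigma_high)
    lo = model.pi_low * phi(score, model.mu_low, model.sigma_low)
    return hi / (hi + lo)
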