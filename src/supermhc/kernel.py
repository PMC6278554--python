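"""Substring string kernel and the pan-allele product kernel.

The similarity of two amino-acid sequences ``f`` and ``g`` is the sum,
over every pair of equal-length (contiguous) substrings ``u`` of ``f``
and ``v`` of ``g``, of the product of per-position substitution
odds-ratio factors::

    K3(f, g) = sum_{u in f, v in g, |u|=|v|=k, k>=1}
               prod_i (Q(u_i, v_i) / (p(u_i) p(v_i)))**beta

Sequences are similar when they share many high-scoring local
(ungapped) alignments.  The naive enumeration is quartic in sequence
length; the implementation uses the equivalent diagonal
dynamic program

    D(i, j) = s(f_i, g_j) * (1 + D(i+1, j+1)),    K3 = sum_{i,j} D(i, j)

which is O(|f||g|).  The brute-force enumerator is retained
(:func:`k3_brute_force`) as a reference implementation for validation.
Only the correlation-normalized form ``K3(f,g)/sqrt(K3(f,f) K3(g,g))``
is exposed to models; the pan-allele kernel is the product of the
normalized kernels over alpha chain, beta chain, and peptide, and is
therefore itself a positive semi-definite kernel with unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .substitution import SubstitutionModel, load_default_model

#: Calibrated kernel shape parameters: one exponent per sequence role.
#: Larger beta sharpens the substitution odds ratios; the peptide
#: kernel is the most specific, the nearly-conserved alpha chain the
#: flattest.
DEFAULT_BETA_PEPTIDE = 0.1137
DEFAULT_BETA_BETA_CHAIN = 0.06
DEFAULT_BETA_ALPHA = 0.02

_OVERFLOW_GUARD = 1e300


@dataclass(frozen=True)
class KernelParams:
    """Per-role exponents of the pan-allele kernel."""

    beta_peptide: float = DEFAULT_BETA_PEPTIDE
    beta_alpha: float = DEFAULT_BETA_ALPHA
    beta_beta_chain: float = DEFAULT_BETA_BETA_CHAIN

    def __post_init__(self):
        for name in ("beta_peptide", "beta_alpha", "beta_beta_chain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "beta_peptide": self.beta_peptide,
            "beta_alpha": self.beta_alpha,
            "beta_beta_chain": self.beta_beta_chain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelParams":
        return cls(**d)


@dataclass
class GramMatrix:
    """Symmetric kernel matrix over an ordered list of items."""

    items: list
    values: np.ndarray

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def _check_sequence(s: str, name: str) -> None:
    if not s:
        raise ValueError(f"{name} must be a non-empty amino-acid string")


def k3_raw(f: str, g: str, beta: float, model: SubstitutionModel) -> float:
    """Unnormalized substring kernel via the diagonal dynamic program.

    Falls back to a log-domain evaluation if the running sums leave
    double range (long sequences at large beta).
    """
    _check_sequence(f, "f")
    _check_sequence(g, "g")
    s = model.pair_score_matrix(beta)[np.ix_(model.encode(f), model.encode(g))]
    total = _k3_from_scores(s)
    if total < _OVERFLOW_GUARD and np.isfinite(total):
        return float(total)
    with np.errstate(over="ignore"):
        return float(np.exp(log_k3_raw(f, g, beta, model)))


def _k3_from_scores(s: np.ndarray) -> float:
    # P holds products of runs of length k along each diagonal, anchored
    # at (i, j); summing every P over k gives the kernel.
    n, m = s.shape
    p = s
    total = p.sum()
    for k in range(2, min(n, m) + 1):
        p = s[: n - k + 1, : m - k + 1] * p[1:, 1:]
        total += p.sum()
        if not total < _OVERFLOW_GUARD:
            return np.inf
    return total


def log_k3_raw(f: str, g: str, beta: float, model: SubstitutionModel) -> float:
    """log K3(f, g): the same diagonal recursion run in log space.

    Diagonal run products become sums of log pair scores (exact); only
    the final aggregation over anchors and lengths uses log-sum-exp.
    """
    _check_sequence(f, "f")
    _check_sequence(g, "g")
    ls = beta * model.log_odds[np.ix_(model.encode(f), model.encode(g))]
    n, m = ls.shape
    lp = ls
    parts = [logsumexp(lp)]
    for k in range(2, min(n, m) + 1):
        lp = ls[: n - k + 1, : m - k + 1] + lp[1:, 1:]
        parts.append(logsumexp(lp))
    return float(logsumexp(parts))


def k3_brute_force(f: str, g: str, beta: float,
                   model: SubstitutionModel) -> float:
    """Reference enumeration over all equal-length substring pairs.

    Exponentially slower than :func:`k3_raw` in spirit (quartic in the
    lengths); intended only for validating the dynamic program on
    short strings.
    """
    _check_sequence(f, "f")
    _check_sequence(g, "g")
    total = 0.0
    n, m = len(f), len(g)
    for k in range(1, min(n, m) + 1):
        for i in range(n - k + 1):
            for j in range(m - k + 1):
                prod = 1.0
                for t in range(k):
                    prod *= model.pair_score(f[i + t], g[j + t], beta)
                total += prod
    return total


def k3_normalized(f: str, g: str, beta: float,
                  model: SubstitutionModel) -> float:
    """Correlation-normalized kernel in (0, 1]; exactly 1 when f == g."""
    if f == g:
        _check_sequence(f, "f")
        return 1.0
    kfg = k3_raw(f, g, beta, model)
    kff = k3_raw(f, f, beta, model)
    kgg = k3_raw(g, g, beta, model)
    if all(np.isfinite(v) and v < _OVERFLOW_GUARD for v in (kfg, kff, kgg)):
        return float(kfg / np.sqrt(kff * kgg))
    lfg = log_k3_raw(f, g, beta, model)
    lff = log_k3_raw(f, f, beta, model)
    lgg = log_k3_raw(g, g, beta, model)
    return float(np.exp(lfg - 0.5 * (lff + lgg)))


class KernelEngine:
    """Pan-allele kernel evaluator with per-string and per-pair caches.

    Alleles repeat across thousands of peptides, so Gram construction
    is dominated by a modest number of distinct string pairs; the
    engine memoizes every normalized evaluation (per role, unordered
    pair) and reuses them across Gram/cross-Gram calls, folds, and
    cluster models.
    """

    def __init__(self, params: KernelParams | None = None,
                 model: SubstitutionModel | None = None):
        self.params = params or KernelParams()
        self.model = model or load_default_model()
        self._pair: dict[tuple[float, str, str], float] = {}
        self._log_self: dict[tuple[float, str], float] = {}

    def _self_log(self, f: str, beta: float) -> float:
        key = (beta, f)
        v = self._log_self.get(key)
        if v is None:
            v = log_k3_raw(f, f, beta, self.model)
            self._log_self[key] = v
        return v

    def normalized(self, f: str, g: str, beta: float) -> float:
        if f == g:
            _check_sequence(f, "f")
            return 1.0
        key = (beta, f, g) if f < g else (beta, g, f)
        v = self._pair.get(key)
        if v is None:
            kfg = k3_raw(f, g, beta, self.model)
            lfg = np.log(kfg) if np.isfinite(kfg) and kfg > 0 \
                else log_k3_raw(f, g, beta, self.model)
            v = float(np.exp(
                lfg - 0.5 * (self._self_log(f, beta) + self._self_log(g, beta))
            ))
            self._pair[key] = v
        return v

    def alpha_kernel(self, a: str, a2: str) -> float:
        return self.normalized(a, a2, self.params.beta_alpha)

    def beta_kernel(self, b: str, b2: str) -> float:
        return self.normalized(b, b2, self.params.beta_beta_chain)

    def peptide_kernel(self, p: str, p2: str) -> float:
        return self.normalized(p, p2, self.params.beta_peptide)

    def pan(self, x: tuple[str, str, str], x2: tuple[str, str, str]) -> float:
        """Product kernel over (alpha_region, beta_region, peptide)."""
        return (
            self.alpha_kernel(x[0], x2[0])
            * self.beta_kernel(x[1], x2[1])
            * self.peptide_kernel(x[2], x2[2])
        )

    def _role_matrix(self, strings_a: list[str], strings_b: list[str],
                     beta: float) -> np.ndarray:
        out = np.empty((len(strings_a), len(strings_b)))
        for i, f in enumerate(strings_a):
            for j, g in enumerate(strings_b):
                out[i, j] = self.normalized(f, g, beta)
        return out

    def _factor_matrices(self, points_a, points_b):
        betas = (self.params.beta_alpha, self.params.beta_beta_chain,
                 self.params.beta_peptide)
        total = None
        for role, beta in enumerate(betas):
            ua = sorted({x[role] for x in points_a})
            ub = sorted({x[role] for x in points_b})
            idx_a = {s: i for i, s in enumerate(ua)}
            idx_b = {s: i for i, s in enumerate(ub)}
            small = self._role_matrix(ua, ub, beta)
            ia = np.array([idx_a[x[role]] for x in points_a], dtype=np.intp)
            ib = np.array([idx_b[x[role]] for x in points_b], dtype=np.intp)
            expanded = small[np.ix_(ia, ib)]
            total = expanded if total is None else total * expanded
        return total

    def gram(self, points: list[tuple[str, str, str]]) -> GramMatrix:
        """Pan-allele Gram matrix on a list of (alpha, beta, peptide)."""
        if not points:
            raise ValueError("gram requires at least one point")
        values = self._factor_matrices(points, points)
        values = (values + values.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(values, 1.0)
        return GramMatrix(items=list(points), values=values)

    def cross(self, points: list[tuple[str, str, str]],
              queries: list[tuple[str, str, str]]) -> np.ndarray:
        """Rectangular kernel matrix, shape (len(queries), len(points))."""
        if not points or not queries:
            raise ValueError("cross requires non-empty points and queries")
        return self._factor_matrices(queries, points)


def pan_kernel(x: tuple[str, str, str], x2: tuple[str, str, str],
               params: KernelParams | None = None,
               model: SubstitutionModel | None = None) -> float:
    """One pan-allele kernel evaluation (convenience wrapper)."""
    return KernelEngine(params, model).pan(x, x2)


def gram(points: list[tuple[str, str, str]],
         params: KernelParams | None = None,
         model: SubstitutionModel | None = None) -> GramMatrix:
    """Pan-allele Gram matrix (convenience wrapper over KernelEngine)."""
    return KernelEngine(params, model).gram(points)
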