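"""Kernel regularized least squares (kernel ridge) on the pan-allele kernel.

Fitting minimizes ``sum_i (f(x_i) - y_i)^2 + lam * ||f||_K^2`` over the
reproducing kernel Hilbert space of the pan-allele kernel.  By the
representer theorem the minimizer is ``f(x) = sum_i c_i K(x_i, x)``
with coefficients solving the symmetric positive-definite system
``(K + lam I) c = y``; the loss is an unscaled sum of squares (no 1/m
factor), which fixes the meaning of ``lam``.  The default
``lam = e^-13`` is the calibrated operating point of the method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kernel import KernelEngine, KernelParams

#: Default ridge regularizer.
DEFAULT_LAMBDA = math.exp(-13)

Triple = tuple[str, str, str]


@dataclass
class RLSModel:
    """A fitted kernel RLS regressor.

    Attributes
    ----------
    train_points : list of (alpha_region, beta_region, peptide)
    coefficients : (m,) ndarray
        Representer coefficients, one per training point.
    lam : float
        Ridge regularizer used at fit time.
    params : KernelParams
        Kernel exponents used at fit time (and required at predict time).
    """

    train_points: list[Triple]
    coefficients: np.ndarray
    lam: float
    params: KernelParams

    def __post_init__(self):
        if len(self.coefficients) != len(self.train_points):
            raise ValueError("one coefficient per training point required")
        if self.lam <= 0:
            raise ValueError("lam must be strictly positive")

    def predict(self, points: list[Triple],
                engine: KernelEngine | None = None,
                clip: bool = False) -> np.ndarray:
        """Predicted affinities ``f(x*) = sum_i c_i K(x_i, x*)``.

        Outputs are not clipped by default: the regressor may slightly
        overshoot [0, 1].  Pass ``clip=True`` for reporting on the
        normalized affinity scale.
        """
        engine = _engine_for(self, engine)
        kx = engine.cross(self.train_points, list(points))
        out = kx @ self.coefficients
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def to_dict(self) -> dict:
        return {
            "train_points": [list(t) for t in self.train_points],
            "coefficients": [repr(c) for c in self.coefficients.tolist()],
            "lam": repr(self.lam),
            "params": self.params.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RLSModel":
        return cls(
            train_points=[tuple(t) for t in d["train_points"]],
            coefficients=np.array([float(c) for c in d["coefficients"]]),
            lam=float(d["lam"]),
            params=KernelParams.from_dict(d["params"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _engine_for(model: RLSModel, engine: KernelEngine | None) -> KernelEngine:
    if engine is None:
        return KernelEngine(model.params)
    if engine.params != model.params:
        raise ValueError("engine kernel parameters differ from the model's")
    return engine


def fit(points: list[Triple], targets, params: KernelParams | None = None,
        lam: float = DEFAULT_LAMBDA,
        engine: KernelEngine | None = None) -> RLSModel:
    """Fit kernel RLS: solve ``(K + lam I) c = y`` by Cholesky.

    ``K`` is the pan-allele Gram matrix on the training triples.  The
    system is positive definite for any ``lam > 0``, so a direct
    symmetric factorization is used; results are deterministic for a
    fixed input order and invariant (up to permutation of
    coefficients) under reordering.
    """
    y = np.asarray(targets, dtype=float)
    if y.ndim != 1 or len(y) != len(points):
        raise ValueError("targets must be a vector with one entry per point")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    if lam <= 0:
        raise ValueError("lam must be strictly positive")
    params = params or KernelParams()
    if engine is None:
        engine = KernelEngine(params)
    elif engine.params != params:
        raise ValueError("engine kernel parameters differ from params")
    k = engine.gram(list(points)).values
    a = k + lam * np.eye(len(y))
    c = cho_solve(cho_factor(a, lower=True), y)
    return RLSModel(train_points=list(points), coefficients=c,
                    lam=lam, params=params)


def objective(model: RLSModel, coefficients: np.ndarray,
              targets, engine: KernelEngine | None = None) -> float:
    """The regularized empirical risk at arbitrary coefficients.

    ``||K c - y||^2 + lam * c' K c`` — useful for verifying that the
    fitted coefficients minimize the quadratic objective.
    """
    engine = _engine_for(model, engine)
    k = engine.gram(model.train_points).values
    y = np.asarray(targets, dtype=float)
    r = k @ coefficients - y
    return float(r @ r + model.lam * coefficients @ k @ coefficients)
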