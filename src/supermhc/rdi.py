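"""Repertoire dissimilarity index (RDI) between MHC molecules.

Two molecules are compared through the peptides they have both been
measured against.  Direct comparison of shared-binder counts is
fragile: repertoire sizes differ by orders of magnitude and small
repertoires overlap little.  The RDI therefore works in three steps:

1. For every molecule pair (i, j), the mean absolute difference
   ``d_ij`` of their normalized affinities over shared peptides.
2. For a target pair (i, j), form the two vectors ``(d_ui)_u`` and
   ``(d_uj)_u`` over all reference molecules u, and compute Kendall's
   rank correlation tau between them (tau-a: tied differences
   contribute zero).  Only the ordering of the references matters, so
   the index is robust to outliers and scale.
3. ``RDI(i, j) = 1 - tau``, giving values in [0, 2]; 0 means the two
   molecules rank every reference identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BindingDataset


@dataclass
class Repertoire:
    """Measured peptide -> normalized affinity map for one molecule."""

    molecule: str
    affinities: dict[str, float]

    def __post_init__(self):
        if not self.affinities:
            raise ValueError(f"repertoire of {self.molecule} is empty")
        bad = {p: a for p, a in self.affinities.items()
               if not (0.0 <= a <= 1.0)}
        if bad:
            raise ValueError(
                f"repertoire of {self.molecule} has affinities outside "
                f"[0, 1]: {list(bad)[:3]}"
            )


def repertoires_from_dataset(dataset: BindingDataset) -> list[Repertoire]:
    by_mol: dict[str, dict[str, float]] = {}
    for r in dataset.records:
        by_mol.setdefault(r.allele_name, {})[r.peptide] = r.affinity
    return [Repertoire(m, aff) for m, aff in by_mol.items()]


def mean_abs_diff(rep_i: Repertoire, rep_j: Repertoire
                  ) -> tuple[float, int]:
    """Mean |f_p^i - f_p^j| over shared peptides, and the overlap size.

    Returns ``(nan, 0)`` when the repertoires share no peptide — an
    undefined (flagged) value, not an error.
    """
    shared = rep_i.affinities.keys() & rep_j.affinities.keys()
    if not shared:
        return float("nan"), 0
    d = sum(abs(rep_i.affinities[p] - rep_j.affinities[p]) for p in shared)
    return d / len(shared), len(shared)


def kendall_tau(u, v) -> float:
    """Kendall's tau-a between two equal-length real vectors.

    ``(2 / (n (n-1))) * sum_{k<k'} sign((u_k - u_k') (v_k - v_k'))``;
    tied pairs contribute zero to the sum but still count in the
    normalization, so the value lies in [-1, 1].  Depends only on the
    orderings of u and v.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length vectors")
    n = len(u)
    if n < 2:
        raise ValueError("kendall_tau needs at least two entries")
    su = np.sign(u[:, None] - u[None, :])
    sv = np.sign(v[:, None] - v[None, :])
    iu = np.triu_indices(n, k=1)
    return float((su[iu] * sv[iu]).sum() * 2.0 / (n * (n - 1)))


@dataclass
class DissimilarityMatrix:
    """Symmetric RDI matrix with per-pair shared-peptide counts."""

    molecules: list[str]
    values: np.ndarray
    shared_counts: np.ndarray = field(default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecules,
                            columns=self.molecules)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA",
                                   index_label="molecule")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(molecules=list(df.index),
                   values=df.to_numpy(dtype=float))


def rdi_matrix(repertoires: list[Repertoire], min_overlap: int = 1,
               include_self_references: bool = True) -> DissimilarityMatrix:
    """All-pairs RDI over a set of molecules.

    For each target pair, the reference vectors are restricted to
    molecules u for which both ``d_ui`` and ``d_uj`` are defined with
    at least ``min_overlap`` shared peptides; tau is normalized over
    the usable references.  By default the targets themselves serve as
    references too (``d_ii = 0``).  Pairs with fewer than two usable
    references are flagged as missing (NaN) with a warning.  The
    diagonal is 0 by construction.
    """
    m = len(repertoires)
    if m < 3:
        raise ValueError("the reference construction needs >= 3 molecules")
    names = [r.molecule for r in repertoires]
    if len(set(names)) != m:
        raise ValueError("duplicate molecule names in repertoires")

    d = np.full((m, m), np.nan)
    counts = np.zeros((m, m), dtype=int)
    np.fill_diagonal(d, 0.0)
    for i in range(m):
        counts[i, i] = len(repertoires[i].affinities)
        for j in range(i + 1, m):
            dij, nij = mean_abs_diff(repertoires[i], repertoires[j])
            d[i, j] = d[j, i] = dij
            counts[i, j] = counts[j, i] = nij

    usable = np.isfinite(d)
    if min_overlap > 1:
        usable &= counts >= min_overlap
        np.fill_diagonal(usable, True)

    rdi = np.full((m, m), np.nan)
    np.fill_diagonal(rdi, 0.0)
    n_missing = 0
    for i in range(m):
        for j in range(i + 1, m):
            refs = usable[:, i] & usable[:, j]
            if not include_self_references:
                refs[i] = refs[j] = False
            idx = np.flatnonzero(refs)
            if len(idx) < 2:
                n_missing += 1
                continue
            tau = kendall_tau(d[idx, i], d[idx, j])
            rdi[i, j] = rdi[j, i] = 1.0 - tau
    if n_missing:
        warnings.warn(
            f"{n_missing} molecule pairs have fewer than two usable "
            "references; their RDI is reported as missing (NA). Consider "
            "lowering min_overlap or dropping sparse molecules.",
            stacklevel=2,
        )
    return DissimilarityMatrix(molecules=names, values=rdi,
                               shared_counts=counts)
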