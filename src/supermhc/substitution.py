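"""BLOSUM62-derived substitution frequency model.

The string kernel scores a pair of aligned residues ``(x, y)`` by the
odds ratio ``Q(x, y) / (p(x) p(y))`` raised to a power ``beta``, where
``Q`` is the joint (target) frequency of observing ``x`` aligned to
``y`` in the clustered alignment blocks underlying BLOSUM62 and ``p``
is the marginal residue frequency.  The integer BLOSUM62 log-odds
matrix cannot be used directly: the kernel needs the frequencies
themselves.  The package therefore ships the clustered target
frequency table from the original BLOSUM construction as plain text
(``data/blosum62.qij``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: The 20 standard amino acids, in the row order of the shipped table.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"


class InvalidResidueError(ValueError):
    """A residue outside the 20-letter standard amino-acid alphabet."""


@dataclass(frozen=True)
class SubstitutionModel:
    """Pair frequencies Q(x, y) and marginals p(x) over 20 amino acids.

    Attributes
    ----------
    alphabet : str
        Residue order of the matrix rows/columns.
    q : (20, 20) ndarray
        Symmetric joint pair-frequency matrix, entries > 0, total mass 1.
    p : (20,) ndarray
        Marginals, ``p[x] = sum_y q[x, y]``.
    """

    alphabet: str
    q: np.ndarray
    p: np.ndarray
    log_odds: np.ndarray = field(repr=False, default=None)  # ln(q / (p p^T))
    index: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self.log_odds is None:
            lo = np.log(self.q) - np.add.outer(np.log(self.p), np.log(self.p))
            object.__setattr__(self, "log_odds", lo)
        if self.index is None:
            object.__setattr__(
                self, "index", {aa: i for i, aa in enumerate(self.alphabet)}
            )

    def encode(self, sequence: str) -> np.ndarray:
        """Map a residue string to integer indices into the matrix."""
        try:
            return np.array([self.index[aa] for aa in sequence], dtype=np.intp)
        except KeyError as exc:
            raise InvalidResidueError(
                f"residue {exc.args[0]!r} is not one of the 20 standard amino acids"
            ) from None

    def pair_score(self, x: str, y: str, beta: float) -> float:
        """Per-position kernel factor ``(Q(x,y) / (p(x) p(y)))**beta``.

        Computed as ``exp(beta * ln odds)`` so long substring products
        can be assembled stably in log space.
        """
        if beta <= 0:
            raise ValueError(f"beta must be positive, got {beta}")
        i = self.index.get(x)
        j = self.index.get(y)
        if i is None or j is None:
            bad = x if i is None else y
            raise InvalidResidueError(
                f"residue {bad!r} is not one of the 20 standard amino acids"
            )
        return math.exp(beta * self.log_odds[i, j])

    def pair_score_matrix(self, beta: float) -> np.ndarray:
        """Full 20x20 matrix of :meth:`pair_score` values at ``beta``."""
        if beta <= 0:
            raise ValueError(f"beta must be positive, got {beta}")
        return np.exp(beta * self.log_odds)


def _parse_qij(text: str) -> tuple[list[str], np.ndarray]:
    alphabet: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line[0].isalpha():
            alphabet = line.split()
            continue
        rows.append([float(tok) for tok in line.split()])
    n = len(alphabet)
    if n == 0 or len(rows) != n:
        raise ValueError("malformed substitution table: expected a header "
                         "row of residues and one triangular row per residue")
    q = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValueError(f"row {i} of the triangular table has {len(row)} "
                             f"entries, expected {i + 1}")
        for j, v in enumerate(row):
            q[i, j] = v
            q[j, i] = v
    return alphabet, q


def load_model(path: str | Path) -> SubstitutionModel:
    """Load a pair-frequency model from a plain-text triangular table.

    The format matches the shipped ``blosum62.qij``: a header line of
    residue one-letter codes, then one lower-triangular row per residue.
    Off-diagonal printed values are per ordered cell (the mirrored
    matrix sums to ~1).  The matrix is renormalized to total mass
    exactly 1 to absorb the rounding of the printed decimals.
    """
    alphabet, q = _parse_qij(Path(path).read_text())
    return _finalize(alphabet, q)


def _finalize(alphabet: list[str], q: np.ndarray) -> SubstitutionModel:
    if np.any(q <= 0):
        raise ValueError("all pair frequencies must be strictly positive")
    q = q / q.sum()
    p = q.sum(axis=1)
    return SubstitutionModel(alphabet="".join(alphabet), q=q, p=p)


def load_default_model() -> SubstitutionModel:
    """The embedded BLOSUM62 clustered target-frequency model."""
    text = (
        resources.files("supermhc").joinpath("data/blosum62.qij").read_text()
    )
    alphabet, q = _parse_qij(text)
    return _finalize(alphabet, q)
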