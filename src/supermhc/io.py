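"""Binding tables, allele names, chain sequences, and IC50 normalization.

Class II MHC binding data arrive as tab-separated records of
``(allele, peptide, IC50 [nM])``.  IC50 values are mapped onto a
normalized affinity scale in [0, 1] by

    psi(IC50) = 1 - log(IC50) / log(50000)

clamped to 1 below 1 nM and to 0 above 50,000 nM; stronger binding
(lower IC50) gives higher affinity.  Allele chain sequences are read
from FASTA and reduced to the polymorphic exon-2 region, located
between locus-specific three-residue start/end markers.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Upper bound of the informative IC50 range (nM).
IC50_MAX = 50_000.0
_LOG_IC50_MAX = math.log(IC50_MAX)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

#: Fixed alpha chain adopted for every HLA-DR molecule (DRA is
#: essentially monomorphic).
DR_ALPHA = "DRA10101"

# Three-residue markers delimiting the polymorphic exon-2 region of
# each chain locus.  Some loci admit alternative markers.
START_MARKERS = {
    "DPA": ("DHV",),
    "DQA": ("DHV",),
    "DRA": ("EHV",),
    "DPB": ("NYL", "NYV"),
    "DQB": ("DFV",),
    "DRB": ("RFL",),
}
END_MARKERS = {
    "DPA": ("AAN", "ATN"),
    "DQA": ("ATN",),
    "DRA": ("ITN",),
    "DPB": ("QRR",),
    "DQB": ("QRR",),
    "DRB": ("QRR",),
}


class ParseError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


def normalize_ic50(ic50: float) -> float:
    """Normalized binding affinity psi(IC50) in [0, 1].

    Piecewise: 0 for IC50 > 50,000 nM, 1 for IC50 < 1 nM, otherwise
    ``1 - ln(IC50)/ln(50000)`` (the ratio of logarithms makes the base
    irrelevant).  Monotone nonincreasing in IC50.
    """
    if not (isinstance(ic50, (int, float)) and math.isfinite(ic50)) or ic50 <= 0:
        raise ValueError(f"IC50 must be a positive finite number in nM, got {ic50!r}")
    if ic50 > IC50_MAX:
        return 0.0
    if ic50 < 1.0:
        return 1.0
    return 1.0 - math.log(ic50) / _LOG_IC50_MAX


def ic50_from_affinity(affinity: float) -> float:
    """Inverse of :func:`normalize_ic50` on the middle branch.

    Maps affinity ``a`` in [0, 1] to ``50000 ** (1 - a)`` nM, so the
    result always lies in [1, 50,000] and round-trips through
    :func:`normalize_ic50`.
    """
    if not (0.0 <= affinity <= 1.0):
        raise ValueError(f"affinity must lie in [0, 1], got {affinity!r}")
    return min(IC50_MAX, max(1.0, math.exp((1.0 - affinity) * _LOG_IC50_MAX)))


@dataclass(frozen=True)
class AlleleIdentity:
    """A parsed class II allele name: isotype plus alpha/beta chain names."""

    raw_name: str
    isotype: str  # one of {"DR", "DP", "DQ"}
    alpha_name: str  # canonical chain key, e.g. "DQA10501"
    beta_name: str  # e.g. "DQB10301"

    @property
    def canonical(self) -> str:
        """Canonical allele key: the beta chain for DR (alpha is fixed),
        ``alpha-beta`` for DP/DQ."""
        if self.isotype == "DR":
            return self.beta_name
        return f"{self.alpha_name}-{self.beta_name}"


@dataclass(frozen=True)
class AlleleSequence:
    """Polymorphic exon-2 regions of both chains of one molecule."""

    identity: AlleleIdentity
    alpha_region: str
    beta_region: str


@dataclass
class BindingRecord:
    allele_name: str  # canonical key
    peptide: str
    ic50: float
    affinity: float

    def __post_init__(self):
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(
                f"peptide {self.peptide!r} contains non-standard residues"
            )


@dataclass
class BindingDataset:
    """An ordered collection of binding records plus the chain catalog."""

    records: list[BindingRecord] = field(default_factory=list)
    catalog: dict[str, AlleleSequence] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def molecules(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.allele_name)
        return list(seen)

    def validate(self) -> None:
        """Check that every referenced allele resolves in the catalog."""
        missing = {r.allele_name for r in self.records} - set(self.catalog)
        if missing:
            raise ValueError(
                f"records reference alleles absent from the catalog: {sorted(missing)}"
            )

    def triples(self) -> list[tuple[str, str, str]]:
        """(alpha_region, beta_region, peptide) per record, catalog-resolved."""
        self.validate()
        return [
            (
                self.catalog[r.allele_name].alpha_region,
                self.catalog[r.allele_name].beta_region,
                r.peptide,
            )
            for r in self.records
        ]


_CHAIN_RE = re.compile(r"^(D[RPQ])([AB])(\d*)$")


def _canonical_chain(token: str) -> str:
    """Normalize one chain token: strip HLA- prefix, stars, colons.

    ``DQB1*03:01`` / ``DQB10301`` / ``DQB1_0301`` all map to ``DQB10301``.
    """
    t = token.strip().upper()
    if t.startswith("HLA-"):
        t = t[4:]
    t = t.replace("*", "").replace(":", "").replace("_", "")
    m = re.match(r"^(D[RPQ][AB]\d?)(\d{4,})$", t)
    if not m:
        raise ParseError(f"unrecognized chain token {token!r}")
    return m.group(1) + m.group(2)


def parse_allele_name(raw: str) -> AlleleIdentity:
    """Parse either allele-name dialect into an :class:`AlleleIdentity`.

    Recognizes the single-chain dialect used for DR molecules
    (``DRB1_0101``, ``DRB1*01:01``) and the paired-chain dialect used
    for DP/DQ (``HLA-DQA10501-DQB10301``).  DR names receive the fixed
    DRA*01:01 alpha chain.
    """
    if not raw or not raw.strip():
        raise ParseError("empty allele name")
    t = raw.strip().upper()
    if t.startswith("HLA-"):
        t = t[4:]
    # Paired-chain dialect: split at the dash between two chain tokens.
    if "-" in t:
        parts = [p for p in t.split("-") if p]
        if len(parts) != 2:
            raise ParseError(f"cannot parse paired-chain allele name {raw!r}")
        a, b = (_canonical_chain(p) for p in parts)
        if a[2] == "B" and b[2] == "A":
            a, b = b, a
        if a[2] != "A" or b[2] != "B" or a[1] != b[1]:
            raise ParseError(
                f"allele name {raw!r} does not pair an alpha with a beta "
                "chain of the same locus"
            )
        isotype = {"R": "DR", "P": "DP", "Q": "DQ"}[a[1]]
        return AlleleIdentity(raw, isotype, a, b)
    # Single-chain dialect: a beta chain; only DR has a fixed alpha.
    chain = _canonical_chain(t)
    locus, kind = chain[:2], chain[2]
    if kind != "B":
        raise ParseError(
            f"single-chain allele name {raw!r} must name a beta chain"
        )
    if locus != "DR":
        raise ParseError(
            f"allele name {raw!r}: {locus} molecules must specify both the "
            "alpha and beta chain (only DR has a fixed alpha, DRA*01:01)"
        )
    return AlleleIdentity(raw, "DR", DR_ALPHA, chain)


def canonical_allele_name(raw: str) -> str:
    return parse_allele_name(raw).canonical


def extract_polymorphic_region(full_chain: str, locus_chain: str) -> str:
    """Extract the exon-2 region between the locus start/end markers.

    The region runs from the FIRST occurrence of the start marker
    through the LAST occurrence of the end marker, inclusive of both
    three-residue markers.  For loci with alternative markers the
    earliest-occurring start and latest-occurring end alternative win.
    """
    locus_chain = locus_chain.upper()
    if locus_chain not in START_MARKERS:
        raise ExtractionError(
            f"unknown chain locus {locus_chain!r}; expected one of "
            f"{sorted(START_MARKERS)}"
        )
    starts = [full_chain.find(m) for m in START_MARKERS[locus_chain]]
    starts = [s for s in starts if s >= 0]
    if not starts:
        raise ExtractionError(
            f"start marker {'/'.join(START_MARKERS[locus_chain])} not found "
            f"in {locus_chain} chain"
        )
    start = min(starts)
    ends = [full_chain.rfind(m) for m in END_MARKERS[locus_chain]]
    ends = [e for e in ends if e >= start]
    if not ends:
        raise ExtractionError(
            f"end marker {'/'.join(END_MARKERS[locus_chain])} not found at or "
            f"after the start marker in {locus_chain} chain"
        )
    end = max(ends)
    return full_chain[start : end + 3]


def load_chain_fasta(path: str | Path) -> dict[str, str]:
    """Read chain sequences from FASTA, keyed by canonical chain name.

    The first whitespace-separated header token must contain the chain
    name in either dialect (e.g. ``DQA1*05:01`` or ``DQA10501``).
    """
    chains: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            key = _canonical_chain(rec.id)
        except ParseError:
            raise ParseError(
                f"FASTA header {rec.id!r} in {path} does not contain a "
                "recognizable chain name"
            ) from None
        chains[key] = str(rec.seq).upper()
    if not chains:
        raise ParseError(f"no sequences found in {path}")
    return chains


def build_catalog(
    allele_names: list[str],
    chains: dict[str, str],
    extract: bool = True,
) -> dict[str, AlleleSequence]:
    """Resolve each allele's chain pair and extract exon-2 regions.

    With ``extract=False`` the chain sequences are taken as already
    being the polymorphic regions.
    """
    catalog: dict[str, AlleleSequence] = {}
    for name in allele_names:
        ident = parse_allele_name(name)
        for chain_name in (ident.alpha_name, ident.beta_name):
            if chain_name not in chains:
                raise ParseError(
                    f"allele {name!r}: chain {chain_name} not found in the "
                    "supplied sequences"
                )
        alpha = chains[ident.alpha_name]
        beta = chains[ident.beta_name]
        if extract:
            alpha = extract_polymorphic_region(alpha, ident.alpha_name[:3])
            beta = extract_polymorphic_region(beta, ident.beta_name[:3])
        catalog[ident.canonical] = AlleleSequence(ident, alpha, beta)
    return catalog


def load_binding_table(
    path: str | Path,
    min_peptide_length: int = 9,
    min_peptides_per_allele: int = 1,
) -> BindingDataset:
    """Parse a TSV binding table into a :class:`BindingDataset`.

    Expects a header line with columns ``allele``, ``peptide``,
    ``ic50``; ``#`` comment lines are ignored.  Peptides shorter than
    ``min_peptide_length`` are dropped (class II predictors need at
    least a 9-mer binding core), as are alleles left with fewer than
    ``min_peptides_per_allele`` measurements.  Duplicate
    (allele, peptide) measurements are averaged on the normalized
    affinity scale, with a warning.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = {"allele", "peptide", "ic50"} - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: missing column(s) {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                allele = canonical_allele_name(row["allele"])
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            peptide = row["peptide"].strip().upper()
            if not _PEPTIDE_RE.match(peptide):
                raise ParseError(
                    f"{path}:{lineno}: peptide {peptide!r} contains "
                    "non-standard amino-acid letters"
                )
            try:
                ic50 = float(row["ic50"])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric ic50 {row['ic50']!r}"
                ) from None
            if not math.isfinite(ic50) or ic50 <= 0:
                raise ParseError(
                    f"{path}:{lineno}: ic50 must be positive and finite, "
                    f"got {row['ic50']!r}"
                )
            rows.append((allele, peptide, ic50))
    if header is None or not rows:
        raise ParseError(f"{path}: empty binding table")

    n_short = sum(1 for _, pep, _ in rows if len(pep) < min_peptide_length)
    if n_short:
        log.info("dropped %d rows with peptide length < %d",
                 n_short, min_peptide_length)
    rows = [r for r in rows if len(r[1]) >= min_peptide_length]
    if not rows:
        raise ParseError(
            f"{path}: no rows left after the minimum-peptide-length filter"
        )

    # Average duplicate (allele, peptide) measurements on the affinity scale.
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for allele, peptide, ic50 in rows:
        key = (allele, peptide)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(ic50)
    n_dup = sum(1 for v in grouped.values() if len(v) > 1)
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicated (allele, peptide) pairs averaged on the "
            "normalized affinity scale",
            stacklevel=2,
        )

    records: list[BindingRecord] = []
    for allele, peptide in order:
        ics = grouped[(allele, peptide)]
        if len(ics) == 1:
            ic50 = ics[0]
            affinity = normalize_ic50(ic50)
        else:
            mean_aff = sum(normalize_ic50(v) for v in ics) / len(ics)
            ic50 = ic50_from_affinity(mean_aff)
            # re-derive from the stored IC50 so write/reload round-trips
            affinity = normalize_ic50(ic50)
        records.append(BindingRecord(allele, peptide, ic50, affinity))

    counts: dict[str, int] = {}
    for r in records:
        counts[r.allele_name] = counts.get(r.allele_name, 0) + 1
    thin = {a for a, c in counts.items() if c < min_peptides_per_allele}
    if thin:
        log.info("dropped %d alleles with fewer than %d measured peptides",
                 len(thin), min_peptides_per_allele)
        records = [r for r in records if r.allele_name not in thin]
    if not records:
        raise ParseError(f"{path}: no records left after filtering")
    return BindingDataset(records=records)


def write_binding_table(dataset: BindingDataset, path: str | Path,
                        with_affinity: bool = True) -> None:
    """Write records as TSV; full float precision so reloads round-trip."""
    path = Path(path)
    with path.open("w") as fh:
        cols = ["allele", "peptide", "ic50"]
        if with_affinity:
            cols.append("affinity")
        fh.write("\t".join(cols) + "\n")
        for r in dataset.records:
            row = [r.allele_name, r.peptide, repr(r.ic50)]
            if with_affinity:
                row.append(repr(r.affinity))
            fh.write("\t".join(row) + "\n")
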