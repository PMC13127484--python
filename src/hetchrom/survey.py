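"""Taxon-wide survey of basic N-terminal extensions in a protein family.

The pipeline mirrors the workflow used to census Suv39h orthologs: filter
protein records by name, locate each record's N-terminal extension relative
to two reference proteins on a multiple sequence alignment (the extension
*start* anchored at residue 1 of a short reference such as mouse Suv39h1,
the extension *end* anchored at a boundary residue of a long reference such
as residue 81 of mouse Suv39h2), keep extensions longer than a length
cutoff, compute amino-acid composition and isoelectric point (pI), keep
basic domains (pI >= 10 by default), and cluster them by composition PCA
into reference-similar and reference-distinct groups.

The alignment is an input: it is computed externally (e.g. Clustal Omega)
or emitted, with ground truth, by :mod:`hetchrom.synth`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .errors import (
    ConfigError,
    DegenerateInputError,
    MissingAccessionError,
    ParseError,
    RangeError,
)

# --------------------------------------------------------------------------
# Alphabet and pKa constants
# --------------------------------------------------------------------------

#: The 20 canonical amino acids, in the fixed order used for composition
#: vectors and PCA loadings.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-canonical codes accepted on input but excluded from
#: composition and charge calculations.
AMBIGUOUS_AA = "BZXUO"

_ACCEPTED = set(CANONICAL_AA) | set(AMBIGUOUS_AA)

GAP = "-"

#: pKa scales for the Henderson-Hasselbalch charge model.  Keys: "nterm",
#: "cterm" and the ionizable side chains.  The EMBOSS constant table is the
#: default, matching the default of the widely used pI routines.
PKA_SCALES: dict[str, dict[str, float]] = {
    "EMBOSS": {
        "nterm": 8.6,
        "cterm": 3.6,
        "K": 10.8,
        "R": 12.5,
        "H": 6.5,
        "D": 3.9,
        "E": 4.1,
        "C": 8.5,
        "Y": 10.1,
    },
}

_BASIC_GROUPS = ("R", "K", "H")
_ACIDIC_GROUPS = ("D", "E", "C", "Y")


def get_pka_scale(name: str) -> dict[str, float]:
    try:
        return PKA_SCALES[name]
    except KeyError:
        raise ConfigError(
            f"unknown pKa scale {name!r}; available: {sorted(PKA_SCALES)}"
        ) from None


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein entry: accession, free-text name, organism, sequence."""

    accession: str
    protein_name: str
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.accession}: empty sequence")
        bad = set(self.sequence.upper()) - _ACCEPTED
        if bad:
            raise ParseError(
                f"{self.accession}: illegal residue codes {sorted(bad)}"
            )


@dataclasses.dataclass(frozen=True)
class AlignedSet:
    """A multiple sequence alignment as ordered (accession, row) pairs.

    Rows use ``-`` as the gap character and share a common length
    (``column_count``).  Column and residue coordinates are 1-based
    throughout this module.
    """

    records: tuple[tuple[str, str], ...]
    column_count: int

    def __post_init__(self) -> None:
        for acc, row in self.records:
            if len(row) != self.column_count:
                raise ParseError(
                    f"{acc}: aligned length {len(row)} != column count "
                    f"{self.column_count}"
                )

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "AlignedSet":
        rows = tuple((acc, row.upper()) for acc, row in rows)
        if not rows:
            raise ParseError("empty alignment")
        return cls(records=rows, column_count=len(rows[0][1]))

    def row(self, accession: str) -> str:
        for acc, row in self.records:
            if acc == accession:
                return row
        raise MissingAccessionError(accession)

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.records]


@dataclasses.dataclass(frozen=True)
class NTermExtension:
    """An extracted N-terminal extension with its physicochemistry."""

    accession: str
    sequence: str
    length: int
    pI: float
    composition: np.ndarray  # 20-vector over CANONICAL_AA, sums to 1


@dataclasses.dataclass(frozen=True)
class PcaResult:
    """Composition PCA: scores, orthonormal loadings, variance fractions."""

    accessions: tuple[str, ...]
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (20, k), orthonormal columns
    explained_variance_fraction: np.ndarray  # (k,)
    cluster_labels: tuple[str, ...] = ()  # filled by cluster_domains


# --------------------------------------------------------------------------
# Name filtering
# --------------------------------------------------------------------------


def filter_by_name(
    records: Sequence[ProteinRecord],
    include_token: str = "histone",
    exclude_tokens: Sequence[str] = ("prdm", "setmar"),
) -> list[ProteinRecord]:
    """Keep records whose protein name contains ``include_token`` and none
    of ``exclude_tokens``.  Matching is case-insensitive substring matching;
    input order is preserved.
    """
    if not include_token or any(not t for t in exclude_tokens):
        raise ValueError("tokens must be non-empty")
    inc = include_token.lower()
    exc = [t.lower() for t in exclude_tokens]
    out = []
    for rec in records:
        name = rec.protein_name.lower()
        if inc in name and not any(t in name for t in exc):
            out.append(rec)
    return out


# --------------------------------------------------------------------------
# Alignment coordinate mapping
# --------------------------------------------------------------------------


def reference_column(aln: AlignedSet, ref_accession: str, residue_index: int) -> int:
    """Map a 1-based residue index of a reference sequence to the 1-based
    alignment column holding that residue.
    """
    if residue_index < 1:
        raise RangeError(f"residue_index must be >= 1, got {residue_index}")
    row = aln.row(ref_accession)
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == residue_index:
                return col
    raise RangeError(
        f"{ref_accession}: residue index {residue_index} beyond ungapped "
        f"length {count}"
    )


def extends_beyond(aln: AlignedSet, accession: str, ref_start_column: int) -> bool:
    """True iff the sequence has at least one residue in a column strictly
    before ``ref_start_column`` (the column of the short reference's first
    residue) — i.e. its N terminus extends beyond the reference's.
    """
    if not 1 <= ref_start_column <= aln.column_count:
        raise RangeError(f"column {ref_start_column} outside alignment")
    row = aln.row(accession)
    return any(ch != GAP for ch in row[: ref_start_column - 1])


def truncate_extension(aln: AlignedSet, accession: str, boundary_column: int) -> str:
    """Ungapped residues of ``accession`` in columns 1..boundary_column
    inclusive — the record's N-terminal segment up to the anchored boundary.
    """
    if not 1 <= boundary_column <= aln.column_count:
        raise RangeError(f"column {boundary_column} outside alignment")
    row = aln.row(accession)
    return row[:boundary_column].replace(GAP, "")


# --------------------------------------------------------------------------
# Physicochemistry
# --------------------------------------------------------------------------


def aa_composition(sequence: str) -> np.ndarray:
    """Fraction of each canonical residue among the canonical residues of
    ``sequence`` (ambiguity codes excluded from numerator and denominator).

    Returns a 20-vector ordered as :data:`CANONICAL_AA`; entries sum to 1.
    """
    if not sequence:
        raise DegenerateInputError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _ACCEPTED
    if bad:
        raise ParseError(f"illegal residue codes {sorted(bad)}")
    counts = np.array([seq.count(aa) for aa in CANONICAL_AA], dtype=float)
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("sequence has no canonical residues")
    return counts / total


def _ionizable_counts(sequence: str) -> dict[str, int]:
    seq = sequence.upper()
    bad = set(seq) - _ACCEPTED
    if bad:
        raise ParseError(f"illegal residue codes {sorted(bad)}")
    return {aa: seq.count(aa) for aa in _BASIC_GROUPS + _ACIDIC_GROUPS}


def net_charge(sequence: str, pH: float, pka_set: str = "EMBOSS") -> float:
    """Henderson-Hasselbalch net charge Z(pH) of a peptide.

    Z = sum over basic groups g of n_g / (1 + 10^(pH - pKa_g))
      - sum over acidic groups g of n_g / (1 + 10^(pKa_g - pH))

    Basic groups: the free N terminus plus R, K, H side chains; acidic:
    the free C terminus plus D, E, C, Y.  Ambiguity codes are ignored.
    """
    if not 0 <= pH <= 14:
        raise ValueError(f"pH {pH} outside [0, 14]")
    pka = get_pka_scale(pka_set)
    counts = _ionizable_counts(sequence)
    z = 1.0 / (1.0 + 10.0 ** (pH - pka["nterm"]))
    z -= 1.0 / (1.0 + 10.0 ** (pka["cterm"] - pH))
    for aa in _BASIC_GROUPS:
        z += counts[aa] / (1.0 + 10.0 ** (pH - pka[aa]))
    for aa in _ACIDIC_GROUPS:
        z -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - pH))
    return z


def isoelectric_point(
    sequence: str, pka_set: str = "EMBOSS", tolerance: float = 0.001
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Z(pH) is strictly decreasing (every peptide has the two termini), so the
    root is unique; the result is within ``tolerance`` pH units of it.  If Z
    does not change sign on [0, 14] the closer bracket end is returned.
    """
    if not sequence:
        raise DegenerateInputError("empty sequence")
    lo, hi = 0.0, 14.0
    z_lo = net_charge(sequence, lo, pka_set)
    z_hi = net_charge(sequence, hi, pka_set)
    if z_lo <= 0:
        return lo
    if z_hi >= 0:
        return hi
    while hi - lo > 2 * tolerance:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_extension(
    accession: str, sequence: str, pka_set: str = "EMBOSS"
) -> NTermExtension:
    """Bundle an extracted extension with its length, composition and pI."""
    return NTermExtension(
        accession=accession,
        sequence=sequence,
        length=len(sequence),
        pI=isoelectric_point(sequence, pka_set),
        composition=aa_composition(sequence),
    )


# --------------------------------------------------------------------------
# Selection filters
# --------------------------------------------------------------------------


def length_filter(
    extensions: Iterable[NTermExtension], min_exclusive: int = 20
) -> list[NTermExtension]:
    """Keep extensions strictly longer than ``min_exclusive`` residues."""
    return [e for e in extensions if e.length > min_exclusive]


def pi_filter(
    extensions: Iterable[NTermExtension], threshold: float = 10.0
) -> list[NTermExtension]:
    """Keep extensions with pI >= ``threshold`` (inclusive)."""
    return [e for e in extensions if e.pI >= threshold]


# --------------------------------------------------------------------------
# Composition PCA and clustering
# --------------------------------------------------------------------------


def pca_composition(matrix: np.ndarray, accessions: Sequence[str] | None = None) -> PcaResult:
    """Exact PCA of an n x 20 composition matrix.

    Columns are mean-centered but not variance-scaled (composition fractions
    already share a scale).  Scores and loadings come from an SVD of the
    centered matrix; ``k = min(n - 1, 20)`` components are reported.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n = X.shape[0]
    if n < 3:
        raise DegenerateInputError(f"PCA needs n >= 3 rows, got {n}")
    if accessions is None:
        accessions = tuple(str(i) for i in range(n))
    centered = X - X.mean(axis=0)
    k = min(n - 1, X.shape[1])
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    scores = U * s
    total = float((s**2).sum())
    evf = (s**2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        accessions=tuple(accessions),
        scores=scores,
        loadings=Vt.T,
        explained_variance_fraction=evf,
    )


def cluster_domains(
    pca: PcaResult, reference_accession: str, k: int = 2, seed: int = 0
) -> PcaResult:
    """Partition domains on PC1-PC2 into ``k`` groups by k-means and label
    the group containing ``reference_accession`` "similar", the rest
    "distinct".

    The choice of k-means with k = 2 is this package's convention for the
    similar/distinct split; it is deterministic given ``seed``.
    """
    if reference_accession not in pca.accessions:
        raise MissingAccessionError(reference_accession)
    coords = pca.scores[:, : min(2, pca.scores.shape[1])]
    n = coords.shape[0]
    spread = float(np.ptp(coords, axis=0).max()) if n else 0.0
    if n <= k or spread == 0.0:
        # degenerate: too few points or all identical -> one cluster
        labels = np.zeros(n, dtype=int)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(coords)
    ref_label = labels[pca.accessions.index(reference_accession)]
    names = tuple("similar" if l == ref_label else "distinct" for l in labels)
    return dataclasses.replace(pca, cluster_labels=names)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SurveyResult:
    """All intermediates of a survey run plus the per-stage count table."""

    filtered: list[ProteinRecord]
    extended_accessions: list[str]
    extensions: list[NTermExtension]  # after length filter
    basic: list[NTermExtension]  # after pI filter
    pca: PcaResult | None
    counts: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Per-domain table for the basic (pI-filtered) set."""
        rows = []
        labels = dict(
            zip(self.pca.accessions, self.pca.cluster_labels)
        ) if self.pca is not None and self.pca.cluster_labels else {}
        for ext in self.basic:
            row = {
                "accession": ext.accession,
                "length": ext.length,
                "pI": ext.pI,
            }
            row.update(
                {f"frac_{aa}": ext.composition[i] for i, aa in enumerate(CANONICAL_AA)}
            )
            if self.pca is not None:
                i = self.pca.accessions.index(ext.accession)
                row["PC1"] = self.pca.scores[i, 0]
                if self.pca.scores.shape[1] > 1:
                    row["PC2"] = self.pca.scores[i, 1]
                row["cluster_label"] = labels.get(ext.accession, "")
            rows.append(row)
        return pd.DataFrame(rows)


def survey_counts(
    n_input: int, n_extended: int, n_long: int, n_basic: int
) -> pd.DataFrame:
    """Ordered stage-count table with survivor fractions.

    Stages: name-filtered input records; records with an N-terminal
    extension; extensions longer than the length cutoff; extensions at or
    above the pI threshold.
    """
    stages = ["input", "extended", "long_extension", "basic_pi"]
    counts = [n_input, n_extended, n_long, n_basic]
    frac_of_input = [100.0 * c / n_input if n_input else 0.0 for c in counts]
    return pd.DataFrame(
        {"stage": stages, "count": counts, "percent_of_input": frac_of_input}
    )


def run_survey(
    records: Sequence[ProteinRecord],
    aln: AlignedSet,
    ref_start: tuple[str, int],
    truncate_at: tuple[str, int],
    include_token: str = "histone",
    exclude_tokens: Sequence[str] = ("prdm", "setmar"),
    min_length: int = 20,
    pi_threshold: float = 10.0,
    pka_scale: str = "EMBOSS",
    seed: int = 0,
) -> SurveyResult:
    """Run the full survey.

    Parameters
    ----------
    ref_start : (accession, residue_index)
        Reference whose residue anchors the extension *start* (a record is
        "extended" iff it has residues before this column).  Default usage:
        residue 1 of the short paralog (e.g. mouse Suv39h1, O54864).
    truncate_at : (accession, residue_index)
        Reference whose residue anchors the truncation boundary, e.g.
        residue 81 of mouse Suv39h2 (Q9EQQ0).
    """
    filtered = filter_by_name(records, include_token, exclude_tokens)
    kept_accs = {r.accession for r in filtered}

    start_col = reference_column(aln, *ref_start)
    boundary_col = reference_column(aln, *truncate_at)

    extended = [
        acc
        for acc in aln.accessions
        if acc in kept_accs and extends_beyond(aln, acc, start_col)
    ]
    truncated = []
    for acc in extended:
        seq = truncate_extension(aln, acc, boundary_col)
        if seq:
            truncated.append(make_extension(acc, seq, pka_scale))
    long_ext = length_filter(truncated, min_length)
    basic = pi_filter(long_ext, pi_threshold)

    pca = None
    if len(basic) >= 3:
        M = np.vstack([e.composition for e in basic])
        pca = pca_composition(M, [e.accession for e in basic])
        ref_acc = truncate_at[0]
        if ref_acc in pca.accessions:
            pca = cluster_domains(pca, ref_acc, k=2, seed=seed)

    counts = survey_counts(len(filtered), len(extended), len(long_ext), len(basic))
    return SurveyResult(
        filtered=filtered,
        extended_accessions=extended,
        extensions=long_ext,
        basic=basic,
        pca=pca,
        counts=counts,
    )


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """(accession, sequence) pairs from a FASTA file; the accession is the
    middle field of UniProt-style ``db|ACC|NAME`` ids, else the whole id."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 2 else rec.id
        out.append((acc, str(rec.seq).upper()))
    return out


def read_alignment(path) -> AlignedSet:
    """Aligned FASTA (gap ``-``) to an :class:`AlignedSet`."""
    aln = AlignIO.read(str(path), "fasta")
    rows = []
    for rec in aln:
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 2 else rec.id
        rows.append((acc, str(rec.seq).upper()))
    return AlignedSet.from_rows(rows)


def read_metadata(path) -> pd.DataFrame:
    """Metadata TSV with columns accession, protein_name, organism."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"accession", "protein_name", "organism"} - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns {sorted(missing)}")
    return df


def records_from_inputs(
    sequences: Iterable[tuple[str, str]], metadata: pd.DataFrame
) -> list[ProteinRecord]:
    meta = metadata.set_index("accession")
    out = []
    for acc, seq in sequences:
        if acc in meta.index:
            row = meta.loc[acc]
            out.append(
                ProteinRecord(acc, str(row["protein_name"]), str(row["organism"]), seq)
            )
    return out
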