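"""Pedigree and genomic relationship matrices.

The pedigree numerator relationship matrix ``A`` holds the expected
additive-genetic correlations implied by a pedigree (tabular method); it is
the covariance kernel of the direct/social animal model.  The genomic
relationship matrix (GRM) is the marker-based analogue used as the kinship
of the genome scans (VanRaden's first, centred and frequency-scaled, method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0  # sentinel for an unknown parent in integer-coded pedigrees

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "numerator_relationship",
    "genomic_relationship",
    "read_pedigree_csv",
    "write_relationship_matrix",
    "read_relationship_matrix",
]


class PedigreeError(ValueError):
    """Raised for unordered, cyclic or dangling pedigrees."""


@dataclass
class Pedigree:
    """Ordered trio records (animal, sire, dam); parents precede offspring.

    ``records`` is a DataFrame with columns ``id``, ``sire``, ``dam``;
    missing parents are encoded as ``"0"`` / ``0`` / empty.  ``id_index``
    maps each animal id to its row position.
    """

    records: pd.DataFrame
    id_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"id", "sire", "dam"}
        if not req.issubset(self.records.columns):
            raise PedigreeError(f"pedigree needs columns {sorted(req)}")
        ids = list(self.records["id"])
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        self.id_index = {a: i for i, a in enumerate(ids)}
        for col in ("sire", "dam"):
            for row, parent in enumerate(self.records[col]):
                if _is_unknown(parent):
                    continue
                j = self.id_index.get(parent)
                if j is None:
                    raise PedigreeError(f"{col} {parent!r} of {ids[row]!r} is not in the pedigree")
                if j >= row:
                    raise PedigreeError(
                        f"{col} {parent!r} does not precede offspring {ids[row]!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list:
        return list(self.records["id"])

    def parent_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (sire, dam) per animal, -1 for unknown."""
        n = len(self)
        s = np.full(n, -1, dtype=np.int64)
        d = np.full(n, -1, dtype=np.int64)
        for i, (sire, dam) in enumerate(zip(self.records["sire"], self.records["dam"])):
            if not _is_unknown(sire):
                s[i] = self.id_index[sire]
            if not _is_unknown(dam):
                d[i] = self.id_index[dam]
        return s, d


def _is_unknown(parent) -> bool:
    if parent is None:
        return True
    if isinstance(parent, float) and np.isnan(parent):
        return True
    return str(parent).strip() in ("", "0", "nan", "NA", ".")


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with row/column labels."""

    values: np.ndarray
    ids: list
    kind: str  # "pedigree_numerator" | "genomic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("label count does not match matrix order")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.values = v

    def submatrix(self, ids) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            idx = np.array([pos[a] for a in ids])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} absent from relationship matrix") from None
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F = diag(A) - 1 (pedigree kind only)."""
        if self.kind != "pedigree_numerator":
            raise ValueError("inbreeding is defined for the pedigree numerator matrix")
        return np.diag(self.values) - 1.0


def numerator_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular recursion.

    A[i,i] = 1 + A[sire,dam]/2 and A[i,j] = (A[j,sire] + A[j,dam])/2 for
    j earlier than i, with unknown-parent terms contributing zero.
    """
    n = len(pedigree)
    sire, dam = pedigree.parent_rows()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(A, pedigree.ids, "pedigree_numerator")


def genomic_relationship(
    dosages: np.ndarray, sample_ids, allele_freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden centred GRM: G = M Mᵀ / Σ 2p(1-p), M = dosage - 2p.

    ``dosages`` is samples x loci in {0,1,2} with NaN for missing; missing
    entries are mean-imputed per locus.  Frequencies default to the sample
    alt-allele frequencies.  Monomorphic loci carry no information and are
    dropped; an all-monomorphic input is an error.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("GRM needs a 2-D dosage matrix with >= 2 samples")
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            allele_freqs = np.nanmean(X, axis=0) / 2.0
    p = np.asarray(allele_freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic locus: GRM undefined")
    X = X[:, poly]
    p = p[poly]
    col_mean = 2.0 * p
    miss = np.isnan(X)
    if miss.any():
        X = np.where(miss, np.broadcast_to(col_mean, X.shape), X)
    M = X - col_mean
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = (M @ M.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, list(sample_ids), "genomic")


# ---------------------------------------------------------------------------
# plain-text IO


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV with columns id,sire,dam (extra columns kept)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree(df)


def write_relationship_matrix(rm: RelationshipMatrix, path) -> None:
    pd.DataFrame(rm.values, index=rm.ids, columns=rm.ids).to_csv(path, float_format="%.10g")


def read_relationship_matrix(path, kind: str = "pedigree_numerator") -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(df.to_numpy(float), list(df.index.astype(str)), kind)
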