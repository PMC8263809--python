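"""Sparse local LD panels.

Stores SNP-SNP correlations c_jl for local (within a cM window),
significant pairs, estimated from a reference panel. The persisted binary
format spends exactly 8 bytes per unique pair: a 4-byte partner index and
a 4-byte IEEE-754 float correlation, preceded by a small self-describing
header (panel size, window, threshold and per-SNP pair counts).

Significance uses the exact likelihood-ratio test for a bivariate-normal
correlation: -n' ln(1 - c^2) ~ chi-squared(1) under c = 0.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.stats import chi2

from .formats import FormatError, GenotypeMatrix, SnpPanel

_MAGIC = b"PRSLD\x01\x00\x00"


@dataclass
class LdPairStore:
    """Symmetric CSR of off-diagonal local correlations.

    Unstored pairs read as 0; the diagonal reads as 1. ``indptr``,
    ``indices``, ``values`` describe a symmetric sparse matrix (each
    unique pair appears twice); ``n_pairs`` counts unique j < l pairs.
    """

    m: int
    n_ref: int
    window_cm: float
    p_threshold: float
    indptr: np.ndarray
    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int32)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.indptr) != self.m + 1:
            raise ValueError("indptr length must be m + 1")
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("|c_jl| must not exceed 1")

    @property
    def n_pairs(self) -> int:
        return len(self.indices) // 2

    def correlation(self, j: int, l: int) -> float:
        """c_jl with symmetric access; diagonal 1, unstored 0."""
        if j == l:
            return 1.0
        lo, hi = self.indptr[j], self.indptr[j + 1]
        pos = np.searchsorted(self.indices[lo:hi], l)
        if pos < hi - lo and self.indices[lo + pos] == l:
            return float(self.values[lo + pos])
        return 0.0

    def neighbors(self, j: int):
        lo, hi = self.indptr[j], self.indptr[j + 1]
        return self.indices[lo:hi], self.values[lo:hi]

    def to_sparse(self, squared: bool = False) -> sp.csr_matrix:
        vals = self.values**2 if squared else self.values
        return sp.csr_matrix(
            (vals, self.indices.astype(np.int64), self.indptr),
            shape=(self.m, self.m),
        )

    def dense(self) -> np.ndarray:
        """Dense correlation matrix with unit diagonal (small panels only)."""
        C = self.to_sparse().toarray()
        np.fill_diagonal(C, 1.0)
        return C


def c2_significance_threshold(n_ref: int, p_threshold: float) -> float:
    """Smallest c^2 significant at p_threshold under the LRT."""
    crit = chi2.isf(p_threshold, df=1)
    return -np.expm1(-crit / n_ref)


def compute_ld_pairs(G_ref: GenotypeMatrix, panel: SnpPanel,
                     window_cm: float = 3.0,
                     p_threshold: float = 0.01,
                     block: int = 512) -> LdPairStore:
    """Estimate and filter local SNP-SNP correlations from a reference panel.

    Pairs are kept iff their cM distance is at most ``window_cm`` and the
    two-sided LRT of c_jl = 0 has P < ``p_threshold``.
    """
    n_ref = G_ref.n
    if n_ref < 30:
        raise ValueError("reference panel too small (need n' >= 30)")
    m = panel.m
    if G_ref.m != m:
        raise ValueError("reference genotypes misaligned with panel")
    cm = panel.cm_position
    if np.any(np.diff(cm) < 0):
        raise ValueError("panel must be sorted by position")
    c2_min = c2_significance_threshold(n_ref, p_threshold)
    X = np.asarray(G_ref.standardized(), dtype=np.float32, order="F")

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for b0 in range(0, m, block):
        b1 = min(b0 + block, m)
        hi = int(np.searchsorted(cm, cm[b1 - 1] + window_cm, side="right"))
        C = (X[:, b0:b1].T @ X[:, b0:hi]) / np.float32(n_ref)
        np.clip(C, -1.0, 1.0, out=C)
        for j in range(b0, b1):
            l_hi = int(np.searchsorted(cm, cm[j] + window_cm, side="right"))
            if l_hi <= j + 1:
                continue
            c = C[j - b0, j + 1 - b0: l_hi - b0].astype(np.float64)
            keep = c * c > c2_min
            if keep.any():
                ls = np.arange(j + 1, l_hi, dtype=np.int32)[keep]
                rows.append(np.full(len(ls), j, dtype=np.int32))
                cols.append(ls)
                vals.append(c[keep])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
    else:
        r = np.empty(0, dtype=np.int32)
        c = np.empty(0, dtype=np.int32)
        v = np.empty(0, dtype=np.float64)
    return _from_upper_pairs(m, n_ref, window_cm, p_threshold, r, c, v)


def _from_upper_pairs(m, n_ref, window_cm, p_threshold, r, c, v) -> LdPairStore:
    """Build the symmetric CSR from unique j < l pairs."""
    rows = np.concatenate([r, c])
    cols = np.concatenate([c, r])
    vals = np.concatenate([v, v])
    order = np.lexsort((cols, rows))
    rows, cols, vals = rows[order], cols[order], vals[order]
    counts = np.bincount(rows, minlength=m)
    indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return LdPairStore(
        m=m, n_ref=n_ref, window_cm=window_cm, p_threshold=p_threshold,
        indptr=indptr, indices=cols.astype(np.int32), values=vals,
    )


def _upper_pairs(store: LdPairStore):
    """Unique j < l pairs in row-major order."""
    rows = np.repeat(
        np.arange(store.m, dtype=np.int32), np.diff(store.indptr)
    )
    upper = store.indices > rows
    return rows[upper], store.indices[upper], store.values[upper]


def save_store(store: LdPairStore, path: str | Path) -> None:
    """Persist: header + exactly 8 bytes (int32 index, float32 c) per pair."""
    r, c, v = _upper_pairs(store)
    counts = np.bincount(r, minlength=store.m).astype(np.int32)
    header = _MAGIC + struct.pack(
        "<iiddq", store.m, store.n_ref, store.window_cm, store.p_threshold,
        len(c),
    )
    payload = np.empty(len(c), dtype=[("l", "<i4"), ("c", "<f4")])
    payload["l"] = c
    payload["c"] = v.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(counts.tobytes())
        fh.write(payload.tobytes())


def header_size(m: int) -> int:
    return len(_MAGIC) + struct.calcsize("<iiddq") + 4 * m


def load_store(path: str | Path) -> LdPairStore:
    raw = Path(path).read_bytes()
    if raw[: len(_MAGIC)] != _MAGIC:
        raise FormatError("not an LD pair store (bad magic bytes)")
    off = len(_MAGIC)
    m, n_ref, window_cm, p_threshold, n_pairs = struct.unpack_from(
        "<iiddq", raw, off
    )
    off += struct.calcsize("<iiddq")
    counts = np.frombuffer(raw, dtype=np.int32, count=m, offset=off)
    off += 4 * m
    if (len(raw) - off) % 8 != 0 or (len(raw) - off) // 8 != n_pairs:
        raise FormatError("truncated LD pair store payload")
    payload = np.frombuffer(
        raw, dtype=[("l", "<i4"), ("c", "<f4")], count=n_pairs, offset=off
    )
    rows = np.repeat(np.arange(m, dtype=np.int32), counts)
    return _from_upper_pairs(
        m, n_ref, window_cm, p_threshold,
        rows, payload["l"].astype(np.int32), payload["c"].astype(np.float64),
    )


def ld_scores(store: LdPairStore, annotations: np.ndarray) -> np.ndarray:
    """Per-SNP annotation-weighted LD scores.

    Column k of the result is sum_l c2_jl a_lk over stored neighbours plus
    the self term a_jk (c2_jj = 1).
    """
    A = np.asarray(annotations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[0] != store.m:
        raise ValueError("annotations misaligned with panel")
    return A + store.to_sparse(squared=True) @ A
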