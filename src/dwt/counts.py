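"""Dirichlet-multinomial marginal likelihoods of alignment columns and column
pairs, and the pairwise dependency-evidence matrix R.

A motif of length ``l`` observed in ``n`` aligned sites is summarized by
single-nucleotide counts ``n[i, a]`` (letter ``a`` at position ``i``) and
dinucleotide counts ``n[i, j, a, b]`` (letters ``(a, b)`` at the position pair
``(i, j)``).  Integrating the multinomial likelihood of a column against a
symmetric Dirichlet prior with pseudocount ``lambda`` per letter gives a
closed-form marginal probability; the ratio of a pair's joint marginal to the
product of its two column marginals is the Bayesian evidence ``R_ij`` for a
direct dependency between positions ``i`` and ``j``.  For large ``n``,
``R_ij ~ exp(n * I_ij)`` with ``I_ij`` the empirical mutual information.

Everything is carried in natural-log space; counts may be fractional (EM soft
assignments produce non-integer counts and the log-gamma function handles them
natively).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

ALPHABET = "ACGT"
N_LETTERS = 4
#: integer codes: A=0, C=1, G=2, T=3, N=4 (missing/any)
N_CODE = 4

__all__ = [
    "ALPHABET",
    "N_CODE",
    "PriorSpec",
    "CountProfile",
    "PairCountTensor",
    "column_log_prob",
    "pair_log_prob",
    "dependency_log_ratio",
    "dependency_matrix",
    "mutual_information",
    "encode",
    "decode",
    "revcomp_codes",
]

_CODE_OF = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE_OF[ord(_c)] = _i
    _CODE_OF[ord(_c.lower())] = _i
_CODE_OF[ord("N")] = N_CODE
_CODE_OF[ord("n")] = N_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to integer codes (A,C,G,T,N -> 0..4).

    Raises ``ValueError`` on any other character.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[raw]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid nucleotide character {bad!r} in sequence")
    return codes.astype(np.int8)


def decode(codes: np.ndarray) -> str:
    return "".join((ALPHABET + "N")[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement in code space; N maps to N."""
    out = codes[::-1].copy()
    acgt = out < N_CODE
    out[acgt] = 3 - out[acgt]
    return out


@dataclass(frozen=True)
class PriorSpec:
    """Symmetric Dirichlet pseudocounts for mono- and di-nucleotide columns.

    Consistency between the mononucleotide prior (4 letters) and the
    dinucleotide prior (16 letter pairs) requires ``lambda_di =
    lambda_mono / 4``; the dinucleotide pseudocount is therefore derived, not
    free.  The default ``lambda_mono = 1/2`` is the Jeffreys prior; results
    are insensitive within ``0 < lambda_mono <= 1``.
    """

    lambda_mono: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_mono <= 1.0):
            raise ValueError(
                f"lambda_mono must be in (0, 1], got {self.lambda_mono}"
            )

    @property
    def lambda_di(self) -> float:
        return self.lambda_mono / 4.0


def column_log_prob(counts: np.ndarray, prior: PriorSpec = PriorSpec()) -> float:
    """Log marginal probability of one alignment column.

    ``log[ Gamma(4λ)/Gamma(n+4λ) * prod_a Gamma(n_a+λ)/Gamma(λ) ]`` for a
    4-vector of (possibly fractional) letter counts with total ``n``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_LETTERS,):
        raise ValueError(f"expected a 4-vector of counts, got shape {c.shape}")
    if (c < 0).any():
        raise ValueError("negative letter count")
    lam = prior.lambda_mono
    n = c.sum()
    return float(
        gammaln(4 * lam) - gammaln(n + 4 * lam)
        + (gammaln(c + lam) - gammaln(lam)).sum()
    )


def pair_log_prob(counts: np.ndarray, prior: PriorSpec = PriorSpec()) -> float:
    """Log marginal probability of a pair of columns from its 4x4 count table,
    under the dinucleotide Dirichlet prior ``λ' = λ/4``."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_LETTERS, N_LETTERS):
        raise ValueError(f"expected a 4x4 count table, got shape {c.shape}")
    if (c < 0).any():
        raise ValueError("negative pair count")
    lam = prior.lambda_di
    n = c.sum()
    return float(
        gammaln(16 * lam) - gammaln(n + 16 * lam)
        + (gammaln(c + lam) - gammaln(lam)).sum()
    )


@dataclass
class CountProfile:
    """Per-position letter counts ``n[i, a]`` over an aligned site set.

    Counts are real-valued (EM produces fractional soft counts); every
    position must carry the same total count ``n``.
    """

    counts: np.ndarray  # (l, 4)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_LETTERS:
            raise ValueError("counts must have shape (l, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        totals = self.counts.sum(axis=1)
        n = totals[0] if len(totals) else 0.0
        if n > 0 and not np.allclose(totals, n, rtol=1e-9, atol=1e-9):
            raise ValueError("per-position totals differ across positions")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> float:
        return float(self.counts.sum(axis=1)[0]) if self.length else 0.0

    @classmethod
    def from_sites(cls, sites: "list[str] | np.ndarray",
                   weights: np.ndarray | None = None) -> "CountProfile":
        codes = _as_code_matrix(sites)
        m, l = codes.shape
        w = np.ones(m) if weights is None else np.asarray(weights, float)
        counts = np.zeros((l, N_LETTERS))
        for a in range(N_LETTERS):
            counts[:, a] = (w[:, None] * (codes == a)).sum(axis=0)
        return cls(counts)


def _as_code_matrix(sites) -> np.ndarray:
    if isinstance(sites, np.ndarray) and sites.dtype.kind in "iu":
        return np.asarray(sites, dtype=np.int8)
    return np.stack([encode(s) for s in sites])


@dataclass
class PairCountTensor:
    """Dinucleotide counts ``n[i, j, a, b]`` for all ordered position pairs.

    The full (l, l, 4, 4) tensor is stored with the index-swap symmetry
    ``n[i, j, a, b] == n[j, i, b, a]``; the diagonal blocks are unused. This
    tensor is the complete specification of a DWT model (together with the
    prior).
    """

    tensor: np.ndarray  # (l, l, 4, 4)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        t = self.tensor
        if t.ndim != 4 or t.shape[2:] != (N_LETTERS, N_LETTERS) or t.shape[0] != t.shape[1]:
            raise ValueError("tensor must have shape (l, l, 4, 4)")
        if (t < 0).any():
            raise ValueError("negative pair counts")

    @property
    def length(self) -> int:
        return self.tensor.shape[0]

    @property
    def n(self) -> float:
        l = self.length
        if l < 2:
            return 0.0
        return float(self.tensor[0, 1].sum())

    @classmethod
    def from_sites(cls, sites, weights: np.ndarray | None = None) -> "PairCountTensor":
        """Accumulate (weighted) pair counts from fixed-length sites.

        Positions carrying N contribute nothing (zero one-hot row).
        """
        codes = _as_code_matrix(sites)
        m, l = codes.shape
        w = np.ones(m) if weights is None else np.asarray(weights, float)
        onehot = np.zeros((m, l, N_LETTERS))
        valid = codes < N_CODE
        mi, li = np.nonzero(valid)
        onehot[mi, li, codes[mi, li]] = 1.0
        tensor = np.einsum("m,mia,mjb->ijab", w, onehot, onehot, optimize=True)
        # diagonal blocks are meaningless; zero them for hygiene
        for i in range(l):
            tensor[i, i] = 0.0
        return cls(tensor)

    def pair(self, i: int, j: int) -> np.ndarray:
        """4x4 count table for positions (i, j), 0-based."""
        return self.tensor[i, j]

    def marginal_profile(self) -> CountProfile:
        """Marginalize pair counts to per-position letter counts."""
        l = self.length
        if l < 2:
            raise ValueError("need length >= 2 to marginalize pair counts")
        counts = np.empty((l, N_LETTERS))
        for i in range(l):
            j = 1 if i == 0 else 0
            counts[i] = self.tensor[i, j].sum(axis=1)
        return CountProfile(counts)

    def validate(self, rtol: float = 1e-6) -> None:
        """Check index-swap symmetry and marginal consistency across pairs."""
        t, l = self.tensor, self.length
        if not np.allclose(t, np.transpose(t, (1, 0, 3, 2)), rtol=rtol, atol=1e-9):
            raise ValueError("pair counts violate index-swap symmetry")
        scale = max(self.n, 1.0)
        for i in range(l):
            margs = [t[i, j].sum(axis=1) for j in range(l) if j != i]
            for m in margs[1:]:
                if not np.allclose(m, margs[0], rtol=rtol, atol=rtol * scale):
                    raise ValueError(
                        f"marginal counts at position {i + 1} are inconsistent "
                        "across pairs"
                    )


def dependency_log_ratio(pair: PairCountTensor, i: int, j: int,
                         prior: PriorSpec = PriorSpec()) -> float:
    """Log evidence ratio ``log R_ij`` for a dependency between positions i, j
    (0-based): joint pair marginal minus the two column marginals."""
    if i == j:
        raise ValueError("dependency ratio is undefined for i == j")
    table = pair.pair(i, j)
    return (
        pair_log_prob(table, prior)
        - column_log_prob(table.sum(axis=1), prior)
        - column_log_prob(table.sum(axis=0), prior)
    )


def dependency_matrix(pair: PairCountTensor,
                      prior: PriorSpec = PriorSpec()) -> np.ndarray:
    """Symmetric (l, l) matrix of log R_ij with zero diagonal."""
    l = pair.length
    logR = np.zeros((l, l))
    for i in range(l):
        for j in range(i + 1, l):
            logR[i, j] = logR[j, i] = dependency_log_ratio(pair, i, j, prior)
    return logR


def mutual_information(table: np.ndarray) -> float:
    """Empirical mutual information (nats) of a 4x4 pair count table.

    Diagnostic only: for large n, ``log R_ij ~ n * I_ij``.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        return 0.0
    p = t / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / (pa @ pb)[mask])).sum())
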