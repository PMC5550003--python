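"""Motif models and binding-energy scoring.

Three motif models share one interface:

* ``PswmModel`` — independent positions; predictive probability of letter
  ``a`` at position ``i`` is ``(n_ia + λ) / (n + 4λ)``.
* ``DwtModel`` — dinucleotide weight tensor; the predictive of a segment is
  the PSWM factor times a ratio of spanning-tree determinants,
  ``D(R(s, S)) / D(R(S))``, where ``R(s, S)`` augments the training counts
  with the scored segment at weight one.  When no pairwise evidence is
  present the ratio is 1 and the DWT reduces to the PSWM.
* ``AdjModel`` — dependencies restricted to adjacent positions; the chain is
  the unique spanning tree of the path graph, so the predictive factorizes
  as a first-order Markov chain of Dirichlet predictives.

The binding energy of a segment is its log-odds against a 0th-order
background, ``E(s) = log P(s|M) - log P(s|B)`` (units kT); the energy of a
longer sequence log-sum-exps ``E(s)`` over every segment on both strands.

Missing letters (N) are ratio-neutral: an N position contributes 0 to both
the model and background log-probabilities, and any pair term touching an N
position falls back to the marginal-only contribution (its R augmentation is
skipped).  An all-N segment therefore has energy exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import logsumexp

from .counts import (
    ALPHABET,
    N_CODE,
    N_LETTERS,
    CountProfile,
    PairCountTensor,
    PriorSpec,
    dependency_matrix,
    encode,
    revcomp_codes,
)
from .trees import batched_tree_log_sum, laplacian_minor_logdet

__all__ = [
    "BackgroundModel",
    "PswmModel",
    "AdjModel",
    "DwtModel",
    "EnergyProfile",
    "segment_energy",
    "sequence_energy",
    "pad_with_n",
]


def _as_codes(s) -> np.ndarray:
    return encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.int8)


def _code_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return X.astype(np.int8, copy=False)
    return np.stack([_as_codes(s) for s in X])


@dataclass(frozen=True)
class BackgroundModel:
    """0th-order background: overall letter frequencies ``b_a``."""

    freqs: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (N_LETTERS,):
            raise ValueError("background frequencies must be a 4-vector")
        if (f <= 0).any() or not np.isclose(f.sum(), 1.0, atol=1e-8):
            raise ValueError("background frequencies must be positive and sum to 1")
        object.__setattr__(self, "freqs", f / f.sum())

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(N_LETTERS, 0.25))

    @classmethod
    def from_sequences(cls, sequences) -> "BackgroundModel":
        """Letter frequencies pooled over the input set (N ignored)."""
        counts = np.zeros(N_LETTERS)
        for s in sequences:
            codes = _as_codes(s)
            counts += np.bincount(codes[codes < N_CODE], minlength=N_LETTERS)
        if counts.sum() == 0:
            raise ValueError("no ACGT letters in input sequences")
        # half-pseudocount guards against absent letters in tiny inputs
        counts = counts + 0.5
        return cls(counts / counts.sum())

    @cached_property
    def log_freqs5(self) -> np.ndarray:
        """log b_a extended with 0 at the N code (ratio-neutral)."""
        out = np.zeros(N_LETTERS + 1)
        out[:N_LETTERS] = np.log(self.freqs)
        return out


class _MotifModel:
    """Shared surface: length, prior, vectorized segment log-predictives."""

    prior: PriorSpec

    @property
    def length(self) -> int:
        raise NotImplementedError

    def log_predictive(self, segments) -> np.ndarray:
        """Log P(s|M) for a batch of length-l segments (code matrix or list
        of strings)."""
        raise NotImplementedError

    def log_predictive_one(self, s) -> float:
        return float(self.log_predictive([s] if isinstance(s, str) else
                                         _as_codes(s)[None, :])[0])

    def _check_segments(self, segments) -> np.ndarray:
        codes = _code_matrix(segments)
        if codes.shape[1] != self.length:
            raise ValueError(
                f"segment length {codes.shape[1]} != motif length {self.length}"
            )
        return codes


def _column_predictive_table(counts: np.ndarray, lam: float) -> np.ndarray:
    """(l, 5) table of log[(n_ia + λ)/(n + 4λ)], with 0 at the N column."""
    n = counts.sum(axis=1, keepdims=True)
    table = np.zeros((counts.shape[0], N_LETTERS + 1))
    table[:, :N_LETTERS] = np.log(counts + lam) - np.log(n + 4 * lam)
    return table


@dataclass
class PswmModel(_MotifModel):
    """Position-specific weight matrix with Dirichlet pseudocounts."""

    profile: CountProfile
    prior: PriorSpec = field(default_factory=PriorSpec)

    @classmethod
    def from_counts(cls, counts, prior: PriorSpec = PriorSpec()) -> "PswmModel":
        return cls(CountProfile(np.asarray(counts, dtype=float)), prior)

    @classmethod
    def from_sites(cls, sites, prior: PriorSpec = PriorSpec()) -> "PswmModel":
        return cls(CountProfile.from_sites(sites), prior)

    @property
    def length(self) -> int:
        return self.profile.length

    @cached_property
    def _colpred(self) -> np.ndarray:
        return _column_predictive_table(self.profile.counts, self.prior.lambda_mono)

    def predictive_probs(self) -> np.ndarray:
        """(l, 4) matrix of predictive letter probabilities (rows sum to 1)."""
        return np.exp(self._colpred[:, :N_LETTERS])

    def log_predictive(self, segments) -> np.ndarray:
        codes = self._check_segments(segments)
        l = self.length
        return self._colpred[np.arange(l)[None, :], codes].sum(axis=1)


class _PairModelBase(_MotifModel):
    """Common machinery for models specified by a PairCountTensor."""

    pairs: PairCountTensor
    prior: PriorSpec

    @property
    def length(self) -> int:
        return self.pairs.length

    @cached_property
    def marginals(self) -> CountProfile:
        return self.pairs.marginal_profile()

    @cached_property
    def _colpred(self) -> np.ndarray:
        return _column_predictive_table(self.marginals.counts,
                                        self.prior.lambda_mono)

    def to_pswm(self) -> PswmModel:
        return PswmModel(self.marginals, self.prior)

    def predictive_probs(self) -> np.ndarray:
        return np.exp(self._colpred[:, :N_LETTERS])


@dataclass
class AdjModel(_PairModelBase):
    """Adjacent-dependency motif model (first-order chain).

    The chain ``1 - 2 - ... - l`` is the only spanning tree once non-adjacent
    dependencies are forbidden, so ``P(s) = P(s_1) prod_i P(s_i | s_{i-1})``
    with ``P(s_i | s_{i-1})`` the ratio of the pair predictive to the column
    predictive at ``i - 1``.
    """

    pairs: PairCountTensor
    prior: PriorSpec = field(default_factory=PriorSpec)

    @classmethod
    def from_sites(cls, sites, weights=None,
                   prior: PriorSpec = PriorSpec()) -> "AdjModel":
        return cls(PairCountTensor.from_sites(sites, weights), prior)

    @cached_property
    def _pairpred(self) -> np.ndarray:
        """(l-1, 5, 5) log pair predictives for adjacent pairs; N rows/cols 0."""
        l, lam_di = self.length, self.prior.lambda_di
        n = self.pairs.n
        out = np.zeros((l - 1, N_LETTERS + 1, N_LETTERS + 1))
        for i in range(l - 1):
            out[i, :N_LETTERS, :N_LETTERS] = (
                np.log(self.pairs.pair(i, i + 1) + lam_di)
                - np.log(n + 16 * lam_di)
            )
        return out

    def log_predictive(self, segments) -> np.ndarray:
        codes = self._check_segments(segments)
        m, l = codes.shape
        cp = self._colpred
        idx = np.arange(l)
        col_terms = cp[idx[None, :], codes]            # (m, l)
        out = col_terms[:, 0].copy()
        for i in range(1, l):
            prev, cur = codes[:, i - 1], codes[:, i]
            both = (prev < N_CODE) & (cur < N_CODE)
            pair_term = self._pairpred[i - 1][prev, cur] - col_terms[:, i - 1]
            # parent N -> fall back to the marginal predictive of the child
            out += np.where(both, pair_term,
                            np.where(cur < N_CODE, col_terms[:, i], 0.0))
        return out


@dataclass
class DwtModel(_PairModelBase):
    """Dinucleotide weight tensor: all pairwise dependencies, marginalized
    over spanning-tree factorizations.

    Specified entirely by the 16 l(l-1)/2 pair counts plus the prior.  The
    dependency matrix ``logR`` and tree-sum ``log D(R)`` of the training
    counts are cached; per-segment scoring only needs the cheap predictive
    increments to each ``logR_ij`` plus one batched determinant.
    """

    pairs: PairCountTensor
    prior: PriorSpec = field(default_factory=PriorSpec)
    name: str = "dwt"

    @classmethod
    def from_sites(cls, sites, weights=None, prior: PriorSpec = PriorSpec(),
                   name: str = "dwt") -> "DwtModel":
        return cls(PairCountTensor.from_sites(sites, weights), prior, name)

    @cached_property
    def logR(self) -> np.ndarray:
        return dependency_matrix(self.pairs, self.prior)

    @cached_property
    def log_d(self) -> float:
        return laplacian_minor_logdet(self.logR).log_d

    @cached_property
    def _delta(self) -> np.ndarray:
        """(l, l, 5, 5) increments to logR_ij when a segment with letters
        (a, b) at (i, j) is added at weight one.

        delta[i,j,a,b] = log(n_ab + λ') - log(n + 4λ) - colpred[i,a]
                         - colpred[j,b]; zero when i == j or either letter
        is N (marginal-only contribution, R factor treated as 1).
        """
        l = self.length
        lam, lam_di = self.prior.lambda_mono, self.prior.lambda_di
        n = self.pairs.n
        cp = self._colpred
        out = np.zeros((l, l, N_LETTERS + 1, N_LETTERS + 1))
        log_denom = np.log(n + 4 * lam)  # == log(n + 16λ')
        for i in range(l):
            for j in range(l):
                if i == j:
                    continue
                out[i, j, :N_LETTERS, :N_LETTERS] = (
                    np.log(self.pairs.pair(i, j) + lam_di) - log_denom
                    - cp[i, :N_LETTERS, None] - cp[j, None, :N_LETTERS]
                )
        return out

    def log_predictive(self, segments) -> np.ndarray:
        codes = self._check_segments(segments)
        m, l = codes.shape
        idx = np.arange(l)
        base = self._colpred[idx[None, :], codes].sum(axis=1)
        if l == 1:
            return base
        ii = idx[None, :, None]
        jj = idx[None, None, :]
        log_d_aug = np.empty(m)
        for s in range(0, m, 16384):  # chunked: keeps the (m, l, l) stack small
            e = min(s + 16384, m)
            block = codes[s:e]
            logR_aug = self.logR[None, :, :] + self._delta[
                ii, jj, block[:, :, None], block[:, None, :]]
            log_d_aug[s:e] = batched_tree_log_sum(logR_aug)
        return base + log_d_aug - self.log_d

    def augmented_logR(self, s) -> np.ndarray:
        """Dependency matrix of the training counts plus segment ``s``."""
        codes = _as_codes(s)[None, :]
        self._check_segments(codes)
        l = self.length
        idx = np.arange(l)
        return self.logR + self._delta[
            idx[:, None], idx[None, :], codes[0][:, None], codes[0][None, :]
        ]

    def edge_posterior_matrix(self) -> np.ndarray:
        from .trees import edge_posteriors
        return edge_posteriors(self.logR)


@dataclass
class EnergyProfile:
    """Per-segment binding energies over both strands of one sequence.

    ``offsets`` are 1-based positions of the leftmost forward-strand base of
    each fixed-length site; ``strands`` is '+'/'-'.  ``total`` is
    ``E(S) = log sum_s exp(E(s))`` over all ``l_s`` segments.
    """

    offsets: np.ndarray
    strands: np.ndarray
    energies: np.ndarray
    total: float
    l_s: int

    def best(self) -> tuple[int, str, float]:
        k = int(np.argmax(self.energies))
        return int(self.offsets[k]), str(self.strands[k]), float(self.energies[k])


def pad_with_n(seq: str, k: int) -> str:
    return "N" * k + seq + "N" * k


def segment_energy(model: _MotifModel, background: BackgroundModel, s) -> float:
    """E(s) = log P(s|M) - log P(s|B) for one length-l segment (kT)."""
    codes = _as_codes(s)
    lp = model.log_predictive_one(codes)
    return lp - float(background.log_freqs5[codes].sum())


def _window_codes(codes: np.ndarray, l: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(codes, l)


def sequence_energy(model: _MotifModel, background: BackgroundModel, seq,
                    pad: bool = False) -> EnergyProfile:
    """Binding-energy profile of a longer sequence on both strands.

    Enumerates all ``|S| - l + 1`` offsets forward and reverse-complement
    (``L_S = 2 (|S| - l + 1)`` segments) and log-sum-exps their energies.
    Set ``pad=True`` to first pad with ``l // 2`` N's per side (SELEX reads
    shorter than the motif).
    """
    l = model.length
    if isinstance(seq, str) and pad:
        seq = pad_with_n(seq, l // 2)
    codes = _as_codes(seq)
    if codes.size < l:
        raise ValueError(
            f"sequence length {codes.size} < motif length {l}; "
            "pass pad=True to N-pad"
        )
    W = codes.size - l + 1
    fwd = _window_codes(codes, l)
    rc = _window_codes(revcomp_codes(codes), l)[::-1]  # rc[k] revcomps window k
    all_windows = np.concatenate([fwd, rc], axis=0)
    logb = background.log_freqs5
    energies = model.log_predictive(all_windows) - logb[all_windows].sum(axis=1)
    offsets = np.concatenate([np.arange(1, W + 1)] * 2)
    strands = np.array(["+"] * W + ["-"] * W)
    return EnergyProfile(
        offsets=offsets,
        strands=strands,
        energies=energies,
        total=float(logsumexp(energies)),
        l_s=2 * W,
    )
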