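"""EM inference of motif models from sets of bound sequences.

The likelihood pictures each input sequence as sampled from a large
background pool in proportion to its probability of being bound by the TF in
the low-concentration (unsaturated) limit.  Up to an additive constant,

    L(M, E0) = sum_S log[ (e^{E(S)} + L_S e^{E0}) / (1 + e^{E0}) ],

where ``E(S)`` log-sum-exps the segment energies over both strands, ``L_S``
is the segment count, and ``E0`` is the non-specific binding energy (the TF
concentration cancels).  Each iteration (i) scores every segment under the
current model, (ii) re-optimizes ``E0`` as the root of dL/dE0, (iii) turns
segment energies into binding posteriors, and (iv) accumulates the
posterior-weighted dinucleotide counts that define the next model.  The same
loop fits PSWM, ADJ, and DWT motifs so the three can be compared on equal
footing; only the segment scorer differs.

``MotifEM`` wraps the loop as a scikit-learn style estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .counts import (
    N_CODE,
    N_LETTERS,
    CountProfile,
    PairCountTensor,
    PriorSpec,
    encode,
    revcomp_codes,
)
from .models import (
    AdjModel,
    BackgroundModel,
    DwtModel,
    PswmModel,
    pad_with_n,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentIndex",
    "dataset_log_likelihood",
    "optimize_e0",
    "site_posteriors",
    "update_pair_counts",
    "run_em",
    "EmResult",
    "MotifEM",
]

MODEL_KINDS = ("pswm", "adj", "dwt")


class SegmentIndex:
    """All fixed-length segments of a sequence set, both strands, flattened.

    Reverse-strand segments are stored reverse-complemented (the letters the
    motif reads), so downstream scoring and soft-count accumulation need no
    strand logic.  Segments are grouped contiguously per sequence for
    reduceat-based per-sequence aggregation.
    """

    def __init__(self, sequences, l: int, pad: bool = False):
        if not sequences:
            raise ValueError("empty sequence set")
        seg_blocks, offs, strands, seq_ids, starts = [], [], [], [], []
        pos = 0
        for k, seq in enumerate(sequences):
            if isinstance(seq, str):
                if pad:
                    seq = pad_with_n(seq, l // 2)
                codes = encode(seq)
            else:
                codes = np.asarray(seq, dtype=np.int8)
            if codes.size < l:
                raise ValueError(
                    f"sequence {k} shorter than motif length {l} "
                    "(pass pad=True to N-pad)"
                )
            W = codes.size - l + 1
            fwd = np.lib.stride_tricks.sliding_window_view(codes, l)
            rc = np.lib.stride_tricks.sliding_window_view(
                revcomp_codes(codes), l)[::-1]
            seg_blocks.append(np.concatenate([fwd, rc], axis=0))
            offs.append(np.concatenate([np.arange(1, W + 1)] * 2))
            strands.append(np.array(["+"] * W + ["-"] * W))
            seq_ids.append(np.full(2 * W, k))
            starts.append(pos)
            pos += 2 * W
        self.l = l
        self.n_sequences = len(sequences)
        self.segments = np.concatenate(seg_blocks, axis=0)
        self.offsets = np.concatenate(offs)
        self.strands = np.concatenate(strands)
        self.seq_ids = np.concatenate(seq_ids)
        self.starts = np.asarray(starts)
        self.l_s = np.diff(np.append(self.starts, pos))  # segments per sequence

    def background_term(self, background: BackgroundModel) -> np.ndarray:
        return background.log_freqs5[self.segments].sum(axis=1)

    def energies(self, model, background: BackgroundModel
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Per-segment energies E(s) and per-sequence totals E(S)."""
        e_seg = model.log_predictive(self.segments) - self.background_term(background)
        return e_seg, self.grouped_logsumexp(e_seg)

    def grouped_logsumexp(self, values: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(values, self.starts)
        sums = np.add.reduceat(np.exp(values - mx[self.seq_ids]), self.starts)
        return mx + np.log(sums)

    def onehot(self) -> np.ndarray:
        """(M, l, 4) indicator of segment letters; N rows are all-zero."""
        M, l = self.segments.shape
        out = np.zeros((M, l, N_LETTERS))
        mi, li = np.nonzero(self.segments < N_CODE)
        out[mi, li, self.segments[mi, li]] = 1.0
        return out


def dataset_log_likelihood(e_total: np.ndarray, l_s: np.ndarray,
                           e0: float) -> float:
    """Sampling log-likelihood (additive constant dropped), log-sum-exp safe."""
    e_total = np.asarray(e_total, dtype=float)
    l_s = np.asarray(l_s, dtype=float)
    if e_total.size == 0:
        raise ValueError("empty dataset")
    num = np.logaddexp(e_total, np.log(l_s) + e0)
    return float((num - np.logaddexp(0.0, e0)).sum())


def optimize_e0(e_total: np.ndarray, l_s: np.ndarray,
                bracket: tuple[float, float] = (-50.0, 50.0)) -> float:
    """Root of dL/dE0 over the bracket.

    The derivative is ``e^{E0}`` times ``g(E0) = sum_S [L_S / (e^{E(S)} +
    L_S e^{E0}) - 1 / (1 + e^{E0})]``; the prefactor never vanishes, so we
    root-find ``g``.  If ``g`` has no sign change in the bracket the end
    with the higher likelihood is returned with a warning.
    """
    e_total = np.asarray(e_total, dtype=float)
    l_s = np.asarray(l_s, dtype=float)
    if e_total.size == 0:
        raise ValueError("empty dataset")
    if not np.isfinite(e_total).all():
        raise ValueError("non-finite sequence energies")
    log_l = np.log(l_s)

    def g(e0: float) -> float:
        t1 = np.exp(log_l - np.logaddexp(e_total, log_l + e0))
        t2 = np.exp(-np.logaddexp(0.0, e0))
        return float((t1 - t2).sum())

    # g decays to 0 at +inf and rounds to noise well inside the bracket, so
    # a naive endpoint sign test is unreliable: scan a grid, polish every
    # genuine sign change, and keep whichever stationary point (or bracket
    # end) attains the highest likelihood.
    grid = np.linspace(bracket[0], bracket[1], 201)
    gv = np.array([g(x) for x in grid])
    noise = 1e-12 * e_total.size
    if np.all(np.abs(gv) < noise):
        return 0.0  # degenerate: every E0 is a root (all E(S) = log L_S)
    candidates = [bracket[0], bracket[1]]
    interior = False
    for k in np.nonzero(np.diff(np.sign(gv)) != 0)[0]:
        if max(abs(gv[k]), abs(gv[k + 1])) <= noise:
            continue  # underflow-tail noise, not a real root
        candidates.append(
            float(brentq(g, grid[k], grid[k + 1], xtol=1e-12, rtol=1e-14)))
        interior = True
    if not interior:
        logger.warning(
            "dL/dE0 has no sign change in [%g, %g]; using the bracket end "
            "with higher likelihood", *bracket,
        )
    lls = [dataset_log_likelihood(e_total, l_s, e0) for e0 in candidates]
    return float(candidates[int(np.argmax(lls))])


def site_posteriors(e_seg: np.ndarray, e_total: np.ndarray,
                    l_s: np.ndarray, e0: float,
                    seq_ids: np.ndarray) -> np.ndarray:
    """P_b(s) = e^{E(s)} / (e^{E(S)} + L_S e^{E0}) per segment."""
    denom = np.logaddexp(e_total, np.log(np.asarray(l_s, float)) + e0)
    return np.exp(e_seg - denom[seq_ids])


def update_pair_counts(index: SegmentIndex, posteriors: np.ndarray,
                       onehot: np.ndarray | None = None) -> PairCountTensor:
    """Posterior-weighted dinucleotide soft counts over all segments.

    Marginal consistency holds by construction (each segment contributes a
    rank-one indicator tensor scaled by its posterior).
    """
    X = index.onehot() if onehot is None else onehot
    tensor = np.einsum("m,mia,mjb->ijab", posteriors, X, X, optimize=True)
    l = index.l
    for i in range(l):
        tensor[i, i] = 0.0
    return PairCountTensor(tensor)


def _model_from_tensor(kind: str, tensor: PairCountTensor, prior: PriorSpec):
    if kind == "pswm":
        return PswmModel(tensor.marginal_profile(), prior)
    if kind == "adj":
        return AdjModel(tensor, prior)
    if kind == "dwt":
        return DwtModel(tensor, prior)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


@dataclass
class EmResult:
    model: object
    e0: float
    log_likelihood: float
    trace: pd.DataFrame          # columns: iteration, log_likelihood, e0
    n_iter: int
    converged: bool
    restart: int = 0


def _run_em_once(index: SegmentIndex, init_counts: np.ndarray, kind: str,
                 prior: PriorSpec, background: BackgroundModel,
                 tol: float, max_iter: int,
                 e0_bracket: tuple[float, float]) -> EmResult:
    onehot = index.onehot()
    scorer = PswmModel(CountProfile(init_counts), prior)
    rows = []
    best = None
    prev_l = -np.inf
    converged = False
    n_iter = 0
    for it in range(max_iter + 1):
        e_seg, e_total = index.energies(scorer, background)
        e0 = optimize_e0(e_total, index.l_s, e0_bracket)
        ll = dataset_log_likelihood(e_total, index.l_s, e0)
        if it > 0 and ll < prev_l - 1e-9 * abs(prev_l):
            # The count update is a fixed-point heuristic, not a strict EM
            # bound; a likelihood decrease means it left the monotone
            # regime.  Reject the candidate and return the best state.
            logger.info("EM iter %d: candidate decreased L (%.6f -> %.6f); "
                        "stopping at the best state", it, prev_l, ll)
            converged = True
            break
        rows.append((it, ll, e0))
        logger.info("EM iter %d: L=%.6f E0=%.4f", it, ll, e0)
        n_iter = it
        if best is None or ll > best[0]:
            best = (ll, scorer, e0)
        if it > 0 and ll - prev_l < tol * abs(ll):
            converged = True
            break
        prev_l = ll
        if it == max_iter:
            break
        post = site_posteriors(e_seg, e_total, index.l_s, e0, index.seq_ids)
        total_mass = post.sum()
        if total_mass <= 1e-12:
            raise RuntimeError(
                "EM collapse: all binding posteriors vanished "
                f"(total mass {total_mass:.3e}); the initial motif may not "
                "match the data"
            )
        tensor = update_pair_counts(index, post, onehot)
        scorer = _model_from_tensor(kind, tensor, prior)
    ll, model, e0 = best
    if logger.isEnabledFor(logging.DEBUG) and hasattr(model, "logR"):
        from .trees import edge_posteriors
        P = edge_posteriors(model.logR)
        iu = np.triu_indices(model.length, 1)
        top = np.argsort(P[iu])[::-1][:3]
        logger.debug(
            "top edge posteriors: %s",
            ", ".join(f"({iu[0][k] + 1},{iu[1][k] + 1})={P[iu][k]:.3f}"
                      for k in top))
    trace = pd.DataFrame(rows, columns=["iteration", "log_likelihood", "e0"])
    return EmResult(model=model, e0=float(e0), log_likelihood=float(ll),
                    trace=trace, n_iter=n_iter, converged=converged)


def run_em(sequences, init_pswm_counts, model_kind: str = "dwt",
           prior: PriorSpec = PriorSpec(), background: BackgroundModel | None = None,
           tol: float = 1e-6, max_iter: int = 200, restarts: int = 1,
           random_state=None, pad: bool = False,
           e0_bracket: tuple[float, float] = (-50.0, 50.0)) -> EmResult:
    """Fit a motif of the requested kind by EM from an initial PSWM.

    Iteration 0 scores segments with the initial PSWM (a DWT with no pair
    evidence reduces to exactly this), so the first E-step needs no pair
    counts.  With ``restarts > 1``, additional runs start from
    Dirichlet-perturbed versions of the initial counts and the best final
    likelihood wins; perturbations draw from ``random_state``.
    """
    init_counts = np.asarray(init_pswm_counts, dtype=float)
    if init_counts.ndim != 2 or init_counts.shape[1] != N_LETTERS:
        raise ValueError("initial PSWM counts must have shape (l, 4)")
    l = init_counts.shape[0]
    if background is None:
        background = BackgroundModel.from_sequences(
            [s for s in sequences if isinstance(s, str)] or sequences)
    index = SegmentIndex(sequences, l, pad=pad)
    rng = np.random.default_rng(random_state)
    best = None
    for r in range(max(1, restarts)):
        counts = init_counts
        if r > 0:
            n = max(init_counts.sum(axis=1).max(), 1.0)
            probs = (init_counts + prior.lambda_mono)
            probs = probs / probs.sum(axis=1, keepdims=True)
            counts = np.stack([n * rng.dirichlet(5.0 * p) for p in probs])
        res = _run_em_once(index, counts, model_kind, prior, background,
                           tol, max_iter, e0_bracket)
        res.restart = r
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    return best


class MotifEM(BaseEstimator):
    """Scikit-learn style estimator for EM motif inference.

    Parameters
    ----------
    model : {"pswm", "adj", "dwt"}
        Motif model family to fit.
    init_pswm : array-like of shape (l, 4)
        Initial PSWM count matrix (letter order A, C, G, T); fixes the motif
        length.
    lambda_ : float
        Dirichlet pseudocount per letter (dinucleotide prior is
        ``lambda_ / 4``).
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        Maximum EM iterations per start.
    restarts : int
        Number of EM starts (first unperturbed, rest Dirichlet-perturbed).
    pad : bool
        N-pad sequences shorter than the motif (SELEX reads).
    random_state : int or None
        Seed for restart perturbations.

    Attributes
    ----------
    model_ : fitted motif model (PswmModel, AdjModel, or DwtModel)
    e0_ : fitted non-specific binding energy (kT)
    log_likelihood_ : best achieved data log-likelihood
    trace_ : per-iteration DataFrame (iteration, log_likelihood, e0)
    n_iter_ : iterations run in the winning start
    background_ : BackgroundModel used for energies
    """

    def __init__(self, model: str = "dwt", init_pswm=None, lambda_: float = 0.5,
                 tol: float = 1e-6, max_iter: int = 200, restarts: int = 1,
                 pad: bool = False, random_state=None,
                 e0_bracket: tuple[float, float] = (-50.0, 50.0)):
        self.model = model
        self.init_pswm = init_pswm
        self.lambda_ = lambda_
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.pad = pad
        self.random_state = random_state
        self.e0_bracket = e0_bracket

    def fit(self, X, y=None):
        """Fit the motif on a list of DNA sequences."""
        if self.init_pswm is None:
            raise ValueError("init_pswm (an (l, 4) count matrix) is required")
        if self.model not in MODEL_KINDS:
            raise ValueError(
                f"model must be one of {MODEL_KINDS}, got {self.model!r}")
        prior = PriorSpec(self.lambda_)
        self.background_ = BackgroundModel.from_sequences(X)
        res = run_em(
            X, self.init_pswm, model_kind=self.model, prior=prior,
            background=self.background_, tol=self.tol, max_iter=self.max_iter,
            restarts=self.restarts, random_state=self.random_state,
            pad=self.pad, e0_bracket=self.e0_bracket,
        )
        self.model_ = res.model
        self.e0_ = res.e0
        self.log_likelihood_ = res.log_likelihood
        self.trace_ = res.trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("MotifEM instance is not fitted yet")

    def score_samples(self, X) -> np.ndarray:
        """Total binding energies E(S) of sequences under the fitted model."""
        self._check_fitted()
        index = SegmentIndex(X, self.model_.length, pad=self.pad)
        _, e_total = index.energies(self.model_, self.background_)
        return e_total

    def score(self, X, y=None) -> float:
        """Dataset log-likelihood of X under the fitted model and E0."""
        self._check_fitted()
        index = SegmentIndex(X, self.model_.length, pad=self.pad)
        _, e_total = index.energies(self.model_, self.background_)
        return dataset_log_likelihood(e_total, index.l_s, self.e0_)

    def predict_sites(self, X, min_posterior: float = 0.0) -> pd.DataFrame:
        """Per-segment binding-site predictions.

        Returns a DataFrame with 1-based offsets, strand, energy, and
        binding posterior for every segment with posterior >= threshold.
        """
        self._check_fitted()
        index = SegmentIndex(X, self.model_.length, pad=self.pad)
        e_seg, e_total = index.energies(self.model_, self.background_)
        post = site_posteriors(e_seg, e_total, index.l_s, self.e0_,
                               index.seq_ids)
        df = pd.DataFrame({
            "seq_index": index.seq_ids,
            "offset": index.offsets,
            "strand": index.strands,
            "energy": e_seg,
            "posterior": post,
        })
        return df[df["posterior"] >= min_posterior].reset_index(drop=True)
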