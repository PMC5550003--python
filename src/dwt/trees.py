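"""Sums over spanning trees of a weighted complete graph.

The mixture over all factorizations of a motif's joint probability into
pairwise conditionals reduces to a sum, over all spanning trees of the
position graph, of the product of dependency weights ``R_ij`` along tree
edges.  By the weighted matrix-tree theorem this equals any principal minor
determinant of the graph Laplacian ``L = diag(row sums) - R``.

Numerical scheme.  ``R_ij = exp(logR_ij)`` can span hundreds of orders of
magnitude (strong dependencies scale like ``exp(n * I_ij)``), and plain LU
on the rescaled Laplacian minor suffers catastrophic cancellation: for a
strongly coupled pair the pivot update ``d_j - R_ij^2 / d_i`` subtracts two
nearly equal large numbers whose tiny difference carries the answer.  We
therefore evaluate the minor determinant by graph elimination (star-mesh
reduction), which never forms a diagonal by subtraction: eliminating node k
contributes the pivot ``d_k = sum of k's remaining edge weights`` to the
determinant and adds ``W_ki W_kj / d_k`` to every remaining weight.  All
quantities are sums, products and quotients of positive numbers, so every
pivot retains full relative precision regardless of dynamic range; the log
determinant accumulates ``log d_k``.  A uniform rescaling is applied up
front and re-applied adaptively before each elimination step (dividing the
remaining weights by f multiplies each of the ``r`` remaining pivots by
1/f, compensated exactly by ``r * log f``), so no intermediate can overflow.
In exact arithmetic the procedure is Gaussian elimination on the Laplacian
minor and reproduces the tree sum identically.

Edge posteriors use the contraction identity: the weighted fraction of
spanning trees containing edge (i, j) is ``R_ij * D(G/ij) / D(G)`` with
``G/ij`` the graph with i and j merged, again evaluated subtraction-free.

A brute-force oracle enumerates all ``l^(l-2)`` labelled trees through
their Pruefer sequences; it is used only for testing at small ``l``.
"""

from __future__ import annotations

import bisect
import itertools
from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TreeSumResult",
    "NumericalInstabilityError",
    "laplacian_minor_logdet",
    "batched_tree_log_sum",
    "brute_force_tree_sum",
    "pruefer_to_edges",
    "edge_posteriors",
]

_TINY = np.finfo(float).tiny


class NumericalInstabilityError(ArithmeticError):
    """Raised when the spanning-tree sum cannot be evaluated to full
    relative precision (effectively disconnected graph or non-finite
    weights)."""


class TreeSumResult(NamedTuple):
    log_d: float      # natural log of the spanning-tree sum D(R)
    log_scale: float  # total rescaling compensation folded into log_d
    l: int


def _check_logR(logR: np.ndarray) -> np.ndarray:
    logR = np.asarray(logR, dtype=float)
    if logR.ndim != 2 or logR.shape[0] != logR.shape[1]:
        raise ValueError("logR must be a square matrix")
    if not np.allclose(logR, logR.T, rtol=1e-12, atol=1e-12):
        raise ValueError("logR must be symmetric")
    return logR


_CHUNK = 16384


def _eliminate_chunk(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elimination core for one contiguous chunk (ground node last)."""
    m, l, _ = S.shape
    off = ~np.eye(l, dtype=bool)
    c = S[:, off].max(axis=1)
    if not np.isfinite(c).all():
        raise NumericalInstabilityError("non-finite dependency weights")
    W = np.exp(S - c[:, None, None])
    idx = np.arange(l)
    W[:, idx, idx] = 0.0
    n = l - 1
    A = np.ascontiguousarray(W[:, :n, :n])   # weights among non-ground nodes
    g = np.ascontiguousarray(W[:, :n, n])    # weights to the ground node
    log_scale = (l - 1) * c
    log_d = log_scale.copy()
    for k in range(n):
        r = n - k  # remaining nodes = pivots still to take
        f = np.maximum(A.reshape(m, -1).max(axis=1), g.max(axis=1))
        f = np.maximum(f, _TINY)
        lf = np.log(f)
        log_d += r * lf
        log_scale += r * lf
        inv = (1.0 / f)[:, None]
        g *= inv
        A *= inv[:, :, None]
        d = g[:, 0] + A[:, 0, 1:].sum(axis=1)
        if (d <= 0).any() or not np.isfinite(d).all():
            j = int(np.argmax(~((d > 0) & np.isfinite(d))))
            raise NumericalInstabilityError(
                f"zero or non-finite pivot at elimination step {k} "
                f"(batch element {j}): graph is numerically disconnected"
            )
        log_d += np.log(d)
        if r > 1:
            w = A[:, 0, 1:] / d[:, None]                    # (m, r-1)
            A = A[:, 1:, 1:] + w[:, :, None] * A[:, 0, None, 1:]
            rem = np.arange(r - 1)
            A[:, rem, rem] = 0.0
            g = g[:, 1:] + w * g[:, 0, None]
    return log_d, log_scale


def _eliminate(stack: np.ndarray, ground: int) -> tuple[np.ndarray, np.ndarray]:
    """Log spanning-tree sums of a (m, l, l) stack of symmetric log-weight
    matrices by subtraction-free node elimination with node ``ground``
    taken as the removed Laplacian row/column.

    Returns (log_d, log_scale) arrays of shape (m,).
    """
    m, l, _ = stack.shape
    if l == 1:
        return np.zeros(m), np.zeros(m)
    if ground != l - 1:
        perm = [i for i in range(l) if i != ground] + [ground]
        stack = stack[:, perm][:, :, perm]
    log_d = np.empty(m)
    log_scale = np.empty(m)
    for s in range(0, m, _CHUNK):
        e = min(s + _CHUNK, m)
        log_d[s:e], log_scale[s:e] = _eliminate_chunk(
            np.ascontiguousarray(stack[s:e]))
    return log_d, log_scale


def laplacian_minor_logdet(logR: np.ndarray, remove: int = 0) -> TreeSumResult:
    """Log of the sum over all spanning trees of ``prod exp(logR_ij)``.

    Any Laplacian row/column may be removed (``remove``); the result is
    identical up to floating-point error.
    """
    logR = _check_logR(logR)
    l = logR.shape[0]
    if l == 1:
        return TreeSumResult(0.0, 0.0, 1)
    if not 0 <= remove < l:
        raise ValueError(f"remove index {remove} out of range for l={l}")
    log_d, log_scale = _eliminate(logR[None, :, :], ground=remove)
    return TreeSumResult(float(log_d[0]), float(log_scale[0]), l)


def batched_tree_log_sum(logR_stack: np.ndarray) -> np.ndarray:
    """Vectorized tree log-sums for a stack of (m, l, l) symmetric matrices.

    Used by the DWT scorer, which evaluates one augmented dependency matrix
    per candidate binding-site segment.
    """
    stack = np.asarray(logR_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("expected a (m, l, l) stack")
    l = stack.shape[1]
    if l == 1:
        return np.zeros(stack.shape[0])
    if l == 2:
        return stack[:, 0, 1].copy()
    log_d, _ = _eliminate(stack, ground=l - 1)
    return log_d


def pruefer_to_edges(seq: tuple[int, ...], l: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence over {0..l-1} into the l-1 edges of its
    labelled tree."""
    degree = [1] * l
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(l) if degree[i] == 1)
    for v in seq:
        u = leaves.pop(0)
        edges.append((min(u, v), max(u, v)))
        degree[v] -= 1
        if degree[v] == 1:
            bisect.insort(leaves, v)
    u, v = leaves
    edges.append((min(u, v), max(u, v)))
    return edges


def brute_force_tree_sum(logR: np.ndarray) -> float:
    """Exact log spanning-tree sum by full enumeration (test oracle).

    Refuses l > 7 (the number of trees is ``l^(l-2)``).
    """
    logR = _check_logR(logR)
    l = logR.shape[0]
    if l > 7:
        raise ValueError("brute-force enumeration limited to l <= 7")
    if l == 1:
        return 0.0
    if l == 2:
        return float(logR[0, 1])
    log_weights = []
    for seq in itertools.product(range(l), repeat=l - 2):
        edges = pruefer_to_edges(seq, l)
        log_weights.append(sum(logR[i, j] for i, j in edges))
    return float(logsumexp(log_weights))


def _contract(logR: np.ndarray, i: int, j: int) -> np.ndarray:
    """Log-weight matrix of the graph with nodes i and j merged (i < j).

    Parallel edges add in linear space; the merged node takes slot i and
    slot j is deleted.
    """
    l = logR.shape[0]
    keep = [k for k in range(l) if k != j]
    out = logR[np.ix_(keep, keep)].copy()
    merged = np.logaddexp(logR[i, :], logR[j, :])
    merged = merged[keep]
    pos_i = keep.index(i)
    out[pos_i, :] = merged
    out[:, pos_i] = merged
    out[pos_i, pos_i] = 0.0
    return out


def edge_posteriors(logR: np.ndarray) -> np.ndarray:
    """Posterior probability P(i, j) that the tree mixture's factorization
    contains a direct dependence between positions i and j.

    Equals the weighted fraction of spanning trees containing edge (i, j),
    computed through the contraction identity ``P(i,j) = R_ij * D(G/ij) /
    D(G)``; each determinant is evaluated by the subtraction-free
    elimination, so the ratio stays accurate even when ``R`` spans hundreds
    of orders of magnitude.

    Returns a symmetric (l, l) matrix with zero diagonal; the upper
    triangle sums to l - 1 (every spanning tree has l - 1 edges).
    """
    logR = _check_logR(logR)
    l = logR.shape[0]
    if l < 2:
        raise ValueError("edge posteriors require l >= 2")
    if l == 2:
        return np.array([[0.0, 1.0], [1.0, 0.0]])
    log_d = laplacian_minor_logdet(logR).log_d
    pairs = [(i, j) for i in range(l) for j in range(i + 1, l)]
    contracted = np.stack([_contract(logR, i, j) for i, j in pairs])
    log_dc = batched_tree_log_sum(contracted)
    P = np.zeros((l, l))
    for (i, j), ldc in zip(pairs, log_dc):
        P[i, j] = P[j, i] = np.exp(logR[i, j] + ldc - log_d)
    if (P < -1e-9).any() or (P > 1 + 1e-9).any():
        raise NumericalInstabilityError("edge posteriors left [0, 1]")
    return np.clip(P, 0.0, 1.0)
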