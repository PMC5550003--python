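"""Benchmarking: decoy sequences, precision-recall, and dependency controls.

The discrimination benchmark scores held-out bound sequences ("peaks")
against composition-matched random "decoys" with a fitted motif model and
summarizes the separation of the two energy distributions by the area under
the precision-recall curve, which equals the average precision.

The randomized-dependency control rebuilds a motif from sites resampled
independently per position out of a model's marginal letter frequencies:
any apparent pairwise dependencies in the rebuilt model are sampling
artifacts, giving a null distribution for edge posteriors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts import N_CODE, N_LETTERS, PairCountTensor, decode, encode
from .models import BackgroundModel, DwtModel
from .trees import edge_posteriors

__all__ = [
    "generate_decoys",
    "precision_recall",
    "average_precision",
    "randomized_dependency_control",
    "benchmark_split",
]


def _dinucleotide_counts(sequences) -> tuple[np.ndarray, np.ndarray]:
    """Pooled first/transition counts over ACGT (N breaks the chain)."""
    start = np.zeros(N_LETTERS)
    trans = np.zeros((N_LETTERS, N_LETTERS))
    for s in sequences:
        codes = encode(s) if isinstance(s, str) else np.asarray(s, np.int8)
        ok = codes < N_CODE
        if ok.any():
            start[codes[ok][0]] += 1
        a, b = codes[:-1], codes[1:]
        pair_ok = ok[:-1] & ok[1:]
        np.add.at(trans, (a[pair_ok], b[pair_ok]), 1.0)
    return start, trans


def generate_decoys(sequences, multiplicity: int = 4, seed=None,
                    mode: str = "markov") -> list[str]:
    """Random decoys with the source lengths and dinucleotide composition.

    ``markov`` (default) samples each decoy from a first-order Markov chain
    fitted to the pooled dinucleotide frequencies of the sources, matching
    composition in expectation.  ``shuffle`` performs a per-sequence
    dinucleotide-preserving shuffle (random Euler path through the exact
    dinucleotide multigraph of each source).  Both are seed-deterministic.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    seqs = list(sequences)
    if any(len(s) < 2 for s in seqs):
        raise ValueError("source sequences must be at least 2 bp")
    rng = np.random.default_rng(seed)
    if mode == "markov":
        return _markov_decoys(seqs, multiplicity, rng)
    if mode == "shuffle":
        return [d for s in seqs
                for d in (_dinucleotide_shuffle(s, rng)
                          for _ in range(multiplicity))]
    raise ValueError(f"unknown decoy mode {mode!r}")


def _markov_decoys(seqs, multiplicity, rng) -> list[str]:
    start, trans = _dinucleotide_counts(seqs)
    p0 = trans.sum(axis=1)
    if p0.sum() == 0:
        raise ValueError("no dinucleotides in source sequences")
    p0 = p0 / p0.sum()
    # observed rows are used exactly (a homopolymer source must yield
    # homopolymer decoys); only never-visited states fall back to uniform
    P = trans.copy()
    empty = P.sum(axis=1) == 0
    P[empty] = 1.0
    P /= P.sum(axis=1, keepdims=True)
    cum0 = np.cumsum(p0)
    cumP = np.cumsum(P, axis=1)
    out = []
    for s in seqs:
        L = len(s)
        for _ in range(multiplicity):
            u = rng.random(L)
            codes = np.empty(L, dtype=np.int8)
            codes[0] = np.searchsorted(cum0, u[0])
            for t in range(1, L):
                codes[t] = np.searchsorted(cumP[codes[t - 1]], u[t])
            out.append(decode(codes))
    return out


def _dinucleotide_shuffle(seq: str, rng) -> str:
    """Exact per-sequence dinucleotide-preserving shuffle (random Euler
    path: shuffle each letter's successor list, keeping the last edge of
    every non-terminal letter on a random arborescence into the final
    letter so the walk cannot strand)."""
    codes = encode(seq)
    if (codes >= N_CODE).any():
        # N breaks dinucleotide bookkeeping; shuffle ACGT stretches only
        raise ValueError("shuffle mode requires N-free sequences")
    L = len(codes)
    if L <= 2:
        return seq
    succ = {a: [] for a in range(N_LETTERS)}
    for a, b in zip(codes[:-1], codes[1:]):
        succ[int(a)].append(int(b))
    last = int(codes[-1])
    present = [a for a in range(N_LETTERS) if succ[a] or a == last]
    # draw arborescences until every non-terminal vertex reaches `last`
    while True:
        tail = {}
        for a in present:
            if a != last and succ[a]:
                tail[a] = succ[a][rng.integers(len(succ[a]))]
        ok = True
        for a in tail:
            seen, v = {a}, tail[a]
            while v != last and v in tail:
                if v in seen:
                    break
                seen.add(v)
                v = tail[v]
            if v != last:
                ok = False
                break
        if ok:
            break
    shuffled = {}
    for a in present:
        lst = [b for b in succ[a]]
        if a in tail:
            lst.remove(tail[a])
        rng.shuffle(lst)
        if a in tail:
            lst.append(tail[a])
        shuffled[a] = lst
    walk = [int(codes[0])]
    ptr = {a: 0 for a in present}
    v = walk[0]
    for _ in range(L - 1):
        nxt = shuffled[v][ptr[v]]
        ptr[v] += 1
        walk.append(nxt)
        v = nxt
    return decode(np.array(walk, dtype=np.int8))


def precision_recall(scores, labels) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve over all distinct score cut-offs.

    ``labels`` are boolean (True = true binding peak).  At each cut-off
    ``E_c`` the predicted-positive set is ``score > E_c`` (ties enter and
    leave together).  Returns the curve (threshold, precision, recall) and
    the average precision, integrated step-wise: ``sum_k dRecall_k *
    Precision_k`` over recall increments, which equals the mean precision
    at the positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    if labels.all() or (~labels).all():
        raise ValueError("precision-recall needs both classes")
    order = np.argsort(scores)[::-1]
    s, y = scores[order], labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    block_ends = np.append(distinct, len(s) - 1)  # inclusive end of tie blocks
    tp = np.cumsum(y)[block_ends]
    pp = block_ends + 1.0
    n_pos = labels.sum()
    precision = tp / pp
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    ap = float((d_recall * precision).sum())
    curve = pd.DataFrame({
        "threshold": s[block_ends],
        "precision": precision,
        "recall": recall,
    })
    return curve, ap


def average_precision(scores, labels) -> float:
    return precision_recall(scores, labels)[1]


def randomized_dependency_control(model: DwtModel, seed=None) -> dict:
    """Rebuild the model from sites resampled out of its own marginals.

    The model's pair counts are marginalized to a PSWM; the same (rounded)
    number of sites is sampled independently per position from the
    marginal frequencies; a new DWT is built from these synthetic sites.
    Returns the edge-posterior matrix of the rebuilt model plus posteriors
    stratified by adjacency (|i-j| == 1 versus > 1).
    """
    n = int(round(model.pairs.n))
    if n < 2:
        raise ValueError("need at least 2 effective sites to resample")
    marg = model.marginals.counts
    probs = marg / marg.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    l = model.length
    u = rng.random((n, l))
    cdf = np.cumsum(probs, axis=1)
    codes = (u[:, :, None] < cdf[None, :, :]).argmax(axis=2).astype(np.int8)
    control = DwtModel(PairCountTensor.from_sites(codes), model.prior)
    P = edge_posteriors(control.logR)
    iu, ju = np.triu_indices(l, 1)
    adjacent = (ju - iu) == 1
    return {
        "control_model": control,
        "posteriors": P,
        "adjacent": P[iu[adjacent], ju[adjacent]],
        "distal": P[iu[~adjacent], ju[~adjacent]],
    }


def planted_recovery_study(planted, seed: int, n_train: int = 500,
                           peak_length: int = 200, n_test: int = 200,
                           decoys_per_seq: int = 4, tol: float = 1e-4,
                           max_iter: int = 25) -> dict:
    """One replicate of the synthetic discrimination benchmark.

    Sites sampled from the planted model are embedded in background peaks;
    DWT and PSWM motifs are fitted by the same EM on the training peaks
    (initialized from the marginal counts of 100 training sites); both are
    scored on held-out peaks against composition-matched decoys.  Returns
    average precisions, the fitted DWT's edge ranking (posterior with
    dependency-evidence tie-break, since posteriors saturate at 1 for
    near-certain edges), and the fraction of training sites whose
    top-posterior segment matches the embedded truth.
    """
    from .counts import CountProfile
    from .em import MotifEM
    from .simulate import embed_in_background, sample_sites

    bg = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]))
    sites = sample_sites(planted, n_train, seed)
    seqs, truth = embed_in_background(sites, peak_length, bg, seed + 1000)
    init = CountProfile.from_sites(sites[:100]).counts
    fits = {
        kind: MotifEM(model=kind, init_pswm=init, tol=tol,
                      max_iter=max_iter).fit(seqs)
        for kind in ("dwt", "pswm")
    }
    test_sites = sample_sites(planted, n_test, seed + 2000)
    test_seqs, _ = embed_in_background(test_sites, peak_length, bg,
                                       seed + 3000)
    decoys = generate_decoys(test_seqs, decoys_per_seq, seed + 4000)
    labels = np.concatenate([np.ones(len(test_seqs), bool),
                             np.zeros(len(decoys), bool)])
    aps = {kind: average_precision(est.score_samples(test_seqs + decoys),
                                   labels)
           for kind, est in fits.items()}
    model = fits["dwt"].model_
    P = model.edge_posterior_matrix()
    R = model.logR
    l = model.length
    iu = np.triu_indices(l, 1)
    order = np.lexsort((-R[iu], -P[iu]))
    ranked = [(int(iu[0][k]), int(iu[1][k])) for k in order]
    pred = fits["dwt"].predict_sites(seqs)
    best = pred.loc[pred.groupby("seq_index")["posterior"].idxmax()]
    best = best.reset_index(drop=True)
    tt = truth.reset_index(drop=True)
    align = float(((best["offset"].values == tt["offset"].values)
                   & (best["strand"].values == tt["strand"].values)).mean())
    return {
        "ap_dwt": aps["dwt"],
        "ap_pswm": aps["pswm"],
        "ranked_edges": ranked,
        "posteriors": P,
        "alignment_fraction": align,
        "traces": {k: est.trace_ for k, est in fits.items()},
    }


def benchmark_split(sequences, seed=None) -> tuple[list, list]:
    """Uniform random 50/50 train/test split, seed-deterministic."""
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    half = len(seqs) // 2
    train = [seqs[i] for i in perm[:half]]
    test = [seqs[i] for i in perm[half:]]
    return train, test
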