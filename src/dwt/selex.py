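"""Likelihoods of HT-SELEX round data under an energy model.

HT-SELEX iterates selection of short DNA reads for binding to a protein,
sequencing each round.  Under ideal energy-proportional selection, the
probability that a selected sequence is ``S`` is ``f_t(S) e^{E(S)} /
sum_S' f_t(S') e^{E(S')}`` with ``f_t`` the round-t frequencies; the data
log-likelihood sums ``n_{t+1}(S)`` times that log-probability over
consecutive round pairs, and is compared against random sampling (``L0``,
the same expression with the selection factor dropped).

Observed round-to-round enrichment is usually shallower than the model
energies predict, so selection is tempered by a "temperature" ``beta``
(selection weight ``e^{beta E(S)}``).  The likelihood gain over random
sampling is then

    dL(E, beta) = sum_t N(t+1) * ( beta <E>_{t+1} - log <e^{beta E}>_t ),

a concave function of beta (log-convexity of the moment generating
function); its maximizer and the per-sequence gain ``dL/N`` with
``N = sum_{t>=2} N(t)`` are the performance measures.

Reads shorter than the motif are N-padded with ``l // 2`` N's per side
before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .models import BackgroundModel, sequence_energy

__all__ = [
    "SelexDataset",
    "TemperatureFit",
    "pad_and_score",
    "selection_log_likelihood",
    "temperature_dL",
    "fit_temperature",
    "energy_bin_enrichment",
]


@dataclass
class SelexDataset:
    """Per-round sequence count tables for T >= 2 consecutive rounds.

    ``sequences`` is the union of distinct reads; ``counts[t, k]`` is the
    occurrence count of read k in round t (0-based round index).
    """

    sequences: list[str]
    counts: np.ndarray  # (T, n_unique) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.sequences):
            raise ValueError("counts must have shape (T, n_sequences)")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 rounds")
        if (self.counts < 0).any() or not np.issubdtype(
                self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_rounds(self) -> int:
        return self.counts.shape[0]

    @property
    def round_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_selected(self) -> float:
        """N = total sequences over rounds 2..T (the selected draws)."""
        return float(self.round_totals[1:].sum())

    @classmethod
    def from_matrix(cls, sequences, counts) -> "SelexDataset":
        return cls(list(sequences), np.asarray(counts))

    @classmethod
    def from_round_tables(cls, tables: "list[pd.DataFrame]") -> "SelexDataset":
        """Build from per-round two-column (sequence, count) tables."""
        seqs: dict[str, int] = {}
        for tab in tables:
            for s in tab.iloc[:, 0]:
                seqs.setdefault(s, len(seqs))
        counts = np.zeros((len(tables), len(seqs)), dtype=np.int64)
        for t, tab in enumerate(tables):
            for s, c in zip(tab.iloc[:, 0], tab.iloc[:, 1]):
                counts[t, seqs[s]] += int(c)
        return cls(list(seqs), counts)

    @classmethod
    def from_manifest(cls, manifest_path) -> "SelexDataset":
        """Load rounds listed in a manifest file (one TSV path per line,
        consecutive rounds in order; paths relative to the manifest)."""
        mpath = Path(manifest_path)
        tables = []
        for line in mpath.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tables.append(pd.read_csv(mpath.parent / line, sep="\t",
                                      header=None, comment="#"))
        return cls.from_round_tables(tables)


@dataclass(frozen=True)
class TemperatureFit:
    beta: float
    dL: float
    dL_per_seq: float
    n: float


def pad_and_score(model, background: BackgroundModel, sequences) -> np.ndarray:
    """Total energies E(S) of SELEX reads, N-padded with l//2 per side."""
    out = np.empty(len(sequences))
    for k, s in enumerate(sequences):
        if len(s) == 0:
            raise ValueError(f"empty sequence at index {k}")
        out[k] = sequence_energy(model, background, s, pad=True).total
    return out


def selection_log_likelihood(energies: np.ndarray, dataset: SelexDataset
                             ) -> tuple[float, float]:
    """(L(E), L0): the selection and random-sampling log-likelihoods.

    Reads observed at round t+1 but absent at round t receive the
    pseudo-frequency ``1 / (N(t) + U)`` with U the number of distinct
    reads, keeping the likelihood finite without distorting abundant
    terms.
    """
    E = np.asarray(energies, dtype=float)
    n = dataset.counts
    T, U = n.shape
    if E.shape != (U,):
        raise ValueError("energies must align with dataset sequences")
    totals = dataset.round_totals
    L = 0.0
    L0 = 0.0
    for t in range(T - 1):
        if totals[t] == 0:
            raise ValueError(f"round {t + 1} has zero total count")
        f = n[t] / totals[t]
        logf = np.full(U, -np.log(float(totals[t] + U)))
        obs = f > 0
        logf[obs] = np.log(f[obs])
        lognorm = logsumexp(logf + E)
        nt1 = n[t + 1]
        L += float((nt1 * (E + logf - lognorm)).sum())
        L0 += float((nt1 * logf).sum())
    return L, L0


def temperature_dL(energies: np.ndarray, dataset: SelexDataset,
                   beta: float) -> float:
    """Likelihood gain over random sampling at inverse temperature beta.

    ``sum_t N(t+1) (beta <E>_{t+1} - log <e^{beta E}>_t)`` with the
    averages weighted by the respective rounds' counts; exact and
    log-sum-exp safe.  Only round-t-observed reads enter ``<e^{beta E}>_t``,
    so no zero-frequency handling is needed.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    E = np.asarray(energies, dtype=float)
    n = dataset.counts
    totals = dataset.round_totals
    out = 0.0
    for t in range(n.shape[0] - 1):
        nt, nt1 = n[t], n[t + 1]
        mean_next = (nt1 * E).sum() / totals[t + 1]
        obs = nt > 0
        log_mean_sel = logsumexp(
            beta * E[obs], b=nt[obs] / totals[t])
        out += float(totals[t + 1]) * (beta * mean_next - log_mean_sel)
    return float(out)


def fit_temperature(energies: np.ndarray, dataset: SelexDataset,
                    beta_max: float = 5.0) -> TemperatureFit:
    """Maximize the concave dL(E, beta) over [0, beta_max].

    Golden-section (bounded Brent) to 1e-8; constant energies give dL = 0
    everywhere and return beta = 0 by convention.
    """
    E = np.asarray(energies, dtype=float)
    obs = dataset.counts.sum(axis=0) > 0
    if np.ptp(E[obs]) < 1e-12:
        return TemperatureFit(0.0, 0.0, 0.0, dataset.n_selected)
    res = minimize_scalar(
        lambda b: -temperature_dL(E, dataset, b),
        bounds=(0.0, beta_max), method="bounded",
        options={"xatol": 1e-8},
    )
    beta = float(res.x)
    if beta_max - beta < 1e-6:
        import logging
        logging.getLogger(__name__).warning(
            "dL still increasing at beta_max=%g; returning the bound", beta_max)
        beta = beta_max
    dl = temperature_dL(E, dataset, beta)
    if dl < 0:  # beta = 0 always attains 0
        beta, dl = 0.0, 0.0
    n = dataset.n_selected
    return TemperatureFit(beta, float(dl), float(dl / n), n)


def energy_bin_enrichment(energies: np.ndarray, dataset: SelexDataset,
                          bin_width: float = 1.0,
                          rounds: tuple[int, int] | None = None
                          ) -> pd.DataFrame:
    """Log-enrichment of energy strata between two consecutive rounds.

    Under ideal tempered selection, ``log[f_{t+1}(E) / f_t(E)]`` is linear
    in E with slope beta.  Bins empty in either round are dropped.
    """
    E = np.asarray(energies, dtype=float)
    t0, t1 = rounds if rounds is not None else (0, 1)
    if t1 != t0 + 1:
        raise ValueError("rounds must be consecutive")
    n = dataset.counts
    edges = np.arange(E.min(), E.max() + 2 * bin_width, bin_width)
    idx = np.digitize(E, edges)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        c0, c1 = n[t0, sel].sum(), n[t1, sel].sum()
        if c0 == 0 or c1 == 0:
            continue
        f0 = c0 / dataset.round_totals[t0]
        f1 = c1 / dataset.round_totals[t1]
        rows.append(((E[sel] * n[t0, sel]).sum() / c0, np.log(f1 / f0)))
    return pd.DataFrame(rows, columns=["energy", "log_enrichment"])
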