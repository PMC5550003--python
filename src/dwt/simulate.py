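"""Seed-deterministic generators for synthetic study data.

``PlantedModel`` realizes the tree-structured generative model the motif
machinery assumes: a forest over motif positions where each root position
draws from its own marginal and each child draws from a conditional table
indexed by its parent's letter.  Sampling is ancestral down the forest.

``embed_in_background`` plants sampled sites at random offsets and strands
inside background-composed sequences, emulating ChIP-seq peak sequences
(typically 100-300 bp) with a known truth table for recovery scoring.

``simulate_selex`` draws successive selection rounds with per-sequence
probabilities proportional to ``f_t(S) * exp(beta0 * E(S))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import ALPHABET, N_LETTERS, decode, encode, revcomp_codes
from .models import BackgroundModel

__all__ = [
    "PlantedModel",
    "sample_sites",
    "embed_in_background",
    "simulate_selex",
    "null_motif",
    "one_edge_motif",
    "two_edge_distal_motif",
    "chain_motif",
    "fixture_suite",
]


@dataclass
class PlantedModel:
    """Tree-structured site generator.

    ``marginals[i]`` is the letter distribution of position ``i`` when it is
    a root; ``edges`` maps each child position to ``(parent, table)`` where
    ``table[p, c]`` = P(child letter c | parent letter p). Edges must form a
    forest (each child has one parent, no cycles).
    """

    length: int
    marginals: np.ndarray                       # (l, 4)
    edges: dict[int, tuple[int, np.ndarray]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        self.marginals = np.asarray(self.marginals, dtype=float)
        if self.marginals.shape != (self.length, N_LETTERS):
            raise ValueError("marginals must have shape (l, 4)")
        if not np.allclose(self.marginals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("marginal rows must sum to 1")
        for child, (parent, table) in self.edges.items():
            t = np.asarray(table, dtype=float)
            if t.shape != (N_LETTERS, N_LETTERS) or not np.allclose(
                    t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"edge {parent}->{child}: invalid conditional")
            self.edges[child] = (parent, t)
        self._check_forest()

    def _check_forest(self) -> None:
        for child in self.edges:
            seen = {child}
            node = child
            while node in self.edges:
                node = self.edges[node][0]
                if node in seen:
                    raise ValueError("planted edges contain a cycle")
                seen.add(node)

    @property
    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected (i, j) pairs with i < j, 0-based."""
        return sorted(
            (min(p, c), max(p, c)) for c, (p, _) in self.edges.items()
        )

    def topological_order(self) -> list[int]:
        order, placed = [], set()
        def place(i: int) -> None:
            if i in placed:
                return
            if i in self.edges:
                place(self.edges[i][0])
            order.append(i)
            placed.add(i)
        for i in range(self.length):
            place(i)
        return order

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestral sampling of n sites; returns an (n, l) code matrix."""
        codes = np.empty((n, self.length), dtype=np.int8)
        u = rng.random((n, self.length))
        for i in self.topological_order():
            if i in self.edges:
                parent, table = self.edges[i]
                cdf = np.cumsum(table, axis=1)
                codes[:, i] = (u[:, i, None] < cdf[codes[:, parent]]).argmax(axis=1)
            else:
                cdf = np.cumsum(self.marginals[i])
                codes[:, i] = (u[:, i, None] < cdf[None, :]).argmax(axis=1)
        return codes


def sample_sites(planted: PlantedModel, n: int, seed) -> list[str]:
    """Sample n sites as strings (seed-deterministic)."""
    rng = np.random.default_rng(seed)
    return [decode(c) for c in planted.sample(n, rng)]


def embed_in_background(sites, peak_length: int,
                        background: BackgroundModel, seed
                        ) -> tuple[list[str], pd.DataFrame]:
    """Embed each site at a uniform random offset/strand in a background
    sequence of ``peak_length``.

    Returns the sequences and a truth table (id, offset 1-based, strand);
    on the '-' strand the embedded subsequence is the reverse complement of
    the site.
    """
    rng = np.random.default_rng(seed)
    site_codes = [encode(s) if isinstance(s, str) else np.asarray(s, np.int8)
                  for s in sites]
    l = site_codes[0].size
    if peak_length < l:
        raise ValueError("peak_length shorter than site length")
    seqs, rows = [], []
    for k, sc in enumerate(site_codes):
        bg = rng.choice(N_LETTERS, size=peak_length,
                        p=background.freqs).astype(np.int8)
        off = int(rng.integers(0, peak_length - l + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        insert = sc if strand == "+" else revcomp_codes(sc)
        bg[off:off + l] = insert
        seqs.append(decode(bg))
        rows.append((f"peak_{k}", off + 1, strand))
    truth = pd.DataFrame(rows, columns=["id", "offset", "strand"])
    return seqs, truth


@dataclass
class SimulatedSelex:
    """Thin carrier for simulated round data; convertible to SelexDataset."""
    sequences: list[str]
    counts: np.ndarray  # (T, n_unique)

    def to_dataset(self):
        from .selex import SelexDataset
        return SelexDataset.from_matrix(self.sequences, self.counts)


def simulate_selex(sequences, energies, beta0: float, rounds: int,
                   draws: int, seed, initial_frequencies=None) -> SimulatedSelex:
    """Simulate multi-round selection over a fixed pool of sequences.

    Round 1 is a multinomial draw from the pool frequencies; each later
    round draws with probability proportional to ``f_t(S) exp(beta0 E(S))``
    where ``f_t`` are the previous round's observed frequencies.
    """
    if rounds < 2:
        raise ValueError("need at least 2 rounds")
    rng = np.random.default_rng(seed)
    E = np.asarray(energies, dtype=float)
    m = len(sequences)
    if E.shape != (m,):
        raise ValueError("energies must align with sequences")
    f = (np.full(m, 1.0 / m) if initial_frequencies is None
         else np.asarray(initial_frequencies, float))
    f = f / f.sum()
    counts = np.empty((rounds, m), dtype=np.int64)
    counts[0] = rng.multinomial(draws, f)
    for t in range(1, rounds):
        ft = counts[t - 1] / counts[t - 1].sum()
        logw = np.full(m, -np.inf)
        obs = ft > 0
        logw[obs] = np.log(ft[obs]) + beta0 * E[obs]
        w = np.exp(logw - logw.max())
        counts[t] = rng.multinomial(draws, w / w.sum())
    return SimulatedSelex(list(sequences), counts)


# ---------------------------------------------------------------------------
# default fixture suite: planted motifs separating DWT vs ADJ vs PSWM
# ---------------------------------------------------------------------------

def _consensus_marginals(l: int, consensus: str, strength: float) -> np.ndarray:
    m = np.full((l, N_LETTERS), (1 - strength) / 3)
    for i, c in enumerate(consensus):
        m[i, ALPHABET.index(c)] = strength
    return m


def _coupling_table(letters: tuple[int, int], agree: float) -> np.ndarray:
    """Conditional table concentrated on two letters: the child repeats the
    parent's letter with probability ``agree``, else takes the other letter
    of the pair (tiny mass elsewhere keeps the table strictly positive)."""
    eps = 1e-3
    a, b = letters
    t = np.full((N_LETTERS, N_LETTERS), eps)
    for p in range(N_LETTERS):
        t[p, a] = t[p, b] = (1 - 2 * eps) / 2
    t[a, a], t[a, b] = agree, 1 - agree - 2 * eps
    t[b, b], t[b, a] = agree, 1 - agree - 2 * eps
    return t / t.sum(axis=1, keepdims=True)


def _two_state_marginal() -> np.ndarray:
    eps = 1e-3
    return np.array([0.5 - eps, 0.5 - eps, eps, eps])


def null_motif(l: int = 10, strength: float = 0.85) -> PlantedModel:
    """Independent positions; moderate consensus (no dependencies)."""
    consensus = ("ACGTACGTAC" * 2)[:l]
    return PlantedModel(l, _consensus_marginals(l, consensus, strength),
                        {}, description=f"null consensus strength {strength}")


def one_edge_motif(l: int = 10, agree: float = 0.9,
                   strength: float = 0.85) -> PlantedModel:
    """One coupled pair at distal positions (3, 8) [1-based (4, 9)]."""
    m = _consensus_marginals(l, ("ACGTACGTAC" * 2)[:l], strength)
    m[3] = _two_state_marginal()  # A/C
    m[8] = _two_state_marginal()
    return PlantedModel(
        l, m, {8: (3, _coupling_table((0, 1), agree))},
        description=f"one distal edge (4,9), agreement {agree}",
    )


def two_edge_distal_motif(l: int = 10, agree: float = 0.95,
                          strength: float = 0.85) -> PlantedModel:
    """Coupled pairs at 1-based (2, 9) and (3, 4): one distal, one adjacent.

    Coupled positions are two-letter 50/50 (A/C and G/T), so a PSWM sees
    only one bit there while the pair carries the agreement signal.  The
    default 0.95 agreement (~0.71 bits of mutual information per pair)
    places the discrimination benchmark inside the strong-coupling regime.
    """
    m = _consensus_marginals(l, ("ACGTACGTAC" * 2)[:l], strength)
    for i in (1, 8):
        m[i] = _two_state_marginal()                      # A/C pair
    gt = np.array([1e-3, 1e-3, 0.5 - 1e-3, 0.5 - 1e-3])  # G/T pair
    for i in (2, 3):
        m[i] = gt
    return PlantedModel(
        l, m,
        {8: (1, _coupling_table((0, 1), agree)),
         3: (2, _coupling_table((2, 3), agree))},
        description=f"edges (2,9) distal and (3,4) adjacent, agreement {agree}",
    )


def chain_motif(l: int = 6, agree: float = 0.9) -> PlantedModel:
    """First-order chain 1->2->...->l over letters A/C."""
    m = np.tile(_two_state_marginal(), (l, 1))
    table = _coupling_table((0, 1), agree)
    edges = {i: (i - 1, table) for i in range(1, l)}
    return PlantedModel(l, m, edges, description=f"chain, agreement {agree}")


def fixture_suite() -> dict[str, PlantedModel]:
    return {
        "null": null_motif(),
        "one_edge": one_edge_motif(),
        "two_edge_distal": two_edge_distal_motif(),
        "chain": chain_motif(),
    }
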