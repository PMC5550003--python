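"""Dilogos: graphical representation of pairwise-dependency motif models.

A dilogo extends the familiar sequence logo with the dependency structure a
DWT model carries: (top) the marginal logo with letter stacks scaled by
information content; (middle) arrows for the selected acyclic set of
dependencies; (bottom) a lower-triangle lattice shading every pairwise
posterior P(i, j); and, per dependent position, four conditional logos
P(child letter | parent letter), one row per parent letter.

Edge selection walks the pairwise posteriors from highest to lowest,
keeping each edge unless it closes a loop (greedy Kruskal forest over all
pairs).  Arrows are oriented away from the position with the highest
marginal information content in each forest component, so conserved anchor
positions act as parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .counts import ALPHABET, N_LETTERS
from .models import DwtModel
from .trees import edge_posteriors

__all__ = ["DilogoSpec", "build_dilogo", "render_dilogo", "write_spec_tsv"]

_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


@dataclass
class DilogoSpec:
    """All quantities a dilogo renders; pure data, renderer-independent."""

    length: int
    marginals: np.ndarray                 # (l, 4) probability rows
    lattice: np.ndarray                   # (l, l) symmetric posteriors
    edges: list[tuple[int, int]]          # (child, parent), 0-based
    conditionals: dict[tuple[int, int], np.ndarray]  # (child, parent) -> (4, 4)
    min_posterior: float = 0.5

    def information_bits(self) -> np.ndarray:
        w = self.marginals
        h = -(w * np.log2(w, where=w > 0, out=np.zeros_like(w))).sum(axis=1)
        return 2.0 - h


def _greedy_forest(P: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal-style loop-free edge selection in posterior order."""
    l = P.shape[0]
    iu, ju = np.triu_indices(l, 1)
    order = np.argsort(P[iu, ju], kind="stable")[::-1]
    parent = list(range(l))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
    return edges


def build_dilogo(model: DwtModel, min_posterior: float = 0.5) -> DilogoSpec:
    """Derive the dilogo data from a fitted DWT model.

    Marginals are the predictive column probabilities; the lattice holds
    all edge posteriors; edges are the greedy loop-free selection, oriented
    away from the most informative position of each component; conditional
    tables are Dirichlet predictives ``P(s_i | s_j) = (n_ij + λ') /
    (n_j + 4λ')``.  ``min_posterior`` only gates which arrows are drawn.
    """
    l = model.length
    if l < 2:
        raise ValueError("dilogos require a motif of length >= 2")
    marginals = model.predictive_probs()
    P = edge_posteriors(model.logR)
    forest = _greedy_forest(P)

    info = (2.0 + (marginals * np.log2(marginals)).sum(axis=1))
    adj: dict[int, list[int]] = {i: [] for i in range(l)}
    for i, j in forest:
        adj[i].append(j)
        adj[j].append(i)
    oriented: list[tuple[int, int]] = []  # (child, parent)
    visited = set()
    for comp_nodes in _components(adj, l):
        root = max(comp_nodes, key=lambda i: info[i])
        stack = [root]
        visited.add(root)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in visited:
                    visited.add(v)
                    oriented.append((v, u))  # v depends on u
                    stack.append(v)
    # keep the greedy (posterior-sorted) ordering for display
    rank = {tuple(sorted(e)): k for k, e in enumerate(forest)}
    oriented.sort(key=lambda e: rank[tuple(sorted(e))])

    lam, lam_di = model.prior.lambda_mono, model.prior.lambda_di
    conditionals = {}
    for child, par in oriented:
        i, j = (child, par)
        pair = model.pairs.tensor[j, i]        # rows: parent letter
        marg = pair.sum(axis=1)
        cond = (pair + lam_di) / (marg + 4 * lam_di)[:, None]
        conditionals[(child, par)] = cond
    return DilogoSpec(l, marginals, P, oriented, conditionals, min_posterior)


def _components(adj, l):
    seen = set()
    for s in range(l):
        if s in seen:
            continue
        comp, stack = [], [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        yield comp


# ---------------------------------------------------------------------------
# SVG rendering (pure function of the spec)
# ---------------------------------------------------------------------------

_CELL = 28.0
_LOGO_H = 64.0


def _letter_stack(x, y_base, probs, height_bits, cell=_CELL, max_bits=2.0):
    """SVG elements for one information-scaled letter stack."""
    out = []
    order = np.argsort(probs)  # smallest drawn first (bottom)
    total_h = _LOGO_H * height_bits / max_bits
    y = y_base
    for a in order:
        h = float(probs[a]) * total_h
        if h < 0.1:
            continue
        letter = ALPHABET[a]
        # glyph box ~ (0.6 x 0.66)*font-size; scale to cell x h
        out.append(
            f'<text x="0" y="0" font-family="DejaVu Sans Mono, monospace" '
            f'font-weight="bold" font-size="20" fill="{_COLORS[letter]}" '
            f'transform="translate({x + 2:.2f},{y:.2f}) '
            f'scale({(cell - 4) / 12.2:.4f},{h / 14.7:.4f})">{letter}</text>'
        )
        y -= h
    return out


def render_dilogo(spec: DilogoSpec, path) -> None:
    """Render the dilogo as a standalone SVG file."""
    l = spec.length
    cell = _CELL
    width = max(l * cell + 160, 360)
    cond_rows = len(spec.edges)
    lattice_y = _LOGO_H + 70
    cond_y = lattice_y + l * 0.55 * cell + 40
    height = cond_y + cond_rows * (4 * 16 + 26) + 30
    e = []
    e.append(f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
             f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">')
    e.append(f'<rect width="{width:.0f}" height="{height:.0f}" fill="white"/>')

    # --- marginal logo ---
    bits = spec.information_bits()
    for i in range(l):
        e.extend(_letter_stack(20 + i * cell, _LOGO_H + 6, spec.marginals[i],
                               bits[i]))
        e.append(f'<text x="{20 + i * cell + cell / 2:.1f}" y="{_LOGO_H + 22}" '
                 f'font-size="9" text-anchor="middle" fill="#444">{i + 1}</text>')

    # --- dependency arrows (above the lattice) ---
    arrow_y = _LOGO_H + 34
    e.append('<defs><marker id="arr" viewBox="0 0 8 8" refX="7" refY="4" '
             'markerWidth="6" markerHeight="6" orient="auto">'
             '<path d="M0,0 L8,4 L0,8 z" fill="#333"/></marker></defs>')
    for child, par in spec.edges:
        if spec.lattice[child, par] < spec.min_posterior:
            continue
        x1 = 20 + par * cell + cell / 2
        x2 = 20 + child * cell + cell / 2
        mid = (x1 + x2) / 2
        rise = min(26, 6 + abs(child - par) * 3)
        e.append(
            f'<path d="M{x1:.1f},{arrow_y} Q{mid:.1f},{arrow_y - rise:.1f} '
            f'{x2:.1f},{arrow_y}" fill="none" stroke="#333" '
            f'stroke-width="1.2" marker-end="url(#arr)"/>'
        )

    # --- posterior lattice (lower triangle) ---
    s = 0.55 * cell
    for i in range(l):
        for j in range(i + 1, l):
            p = float(spec.lattice[i, j])
            shade = int(255 - 215 * p)
            x = 20 + i * s
            y = lattice_y + (j - 1) * s
            e.append(
                f'<rect class="lattice" x="{x:.1f}" y="{y:.1f}" '
                f'width="{s:.1f}" height="{s:.1f}" '
                f'fill="rgb(255,{shade},{shade})" stroke="#999" '
                f'stroke-width="0.4"><title>P({i + 1},{j + 1})='
                f'{p:.3f}</title></rect>'
            )

    # --- conditional logos ---
    y = cond_y
    for child, par in spec.edges:
        cond = spec.conditionals[(child, par)]
        e.append(f'<text x="20" y="{y:.1f}" font-size="11" fill="#222">'
                 f'position {child + 1} | position {par + 1}</text>')
        for p_letter in range(N_LETTERS):
            yy = y + 14 + p_letter * 16
            e.append(f'<text x="26" y="{yy + 10:.1f}" font-size="10" '
                     f'fill="{_COLORS[ALPHABET[p_letter]]}" font-weight="bold">'
                     f'{ALPHABET[p_letter]}</text>')
            x = 44.0
            for c_letter in np.argsort(cond[p_letter])[::-1]:
                w = 30 * float(cond[p_letter, c_letter])
                if w < 0.4:
                    continue
                e.append(
                    f'<text x="0" y="0" font-size="12" font-weight="bold" '
                    f'font-family="DejaVu Sans Mono, monospace" '
                    f'fill="{_COLORS[ALPHABET[c_letter]]}" '
                    f'transform="translate({x:.1f},{yy + 10:.1f}) '
                    f'scale({w / 7.3:.3f},1)">{ALPHABET[c_letter]}</text>'
                )
                x += w
        y += 4 * 16 + 26
    e.append("</svg>")
    Path(path).write_text("\n".join(e) + "\n")


def write_spec_tsv(spec: DilogoSpec, path) -> None:
    """Structured text sidecar: marginals, lattice, edges, conditionals."""
    lines = [f"#DILOGO length={spec.length}"]
    lines.append("#block marginals\t" + "\t".join(ALPHABET))
    for i, row in enumerate(spec.marginals):
        lines.append(f"{i + 1}\t" + "\t".join(f"{v:.6g}" for v in row))
    lines.append("#block lattice\ti\tj\tposterior")
    l = spec.length
    for i in range(l):
        for j in range(i + 1, l):
            lines.append(f"{i + 1}\t{j + 1}\t{spec.lattice[i, j]:.6g}")
    lines.append("#block edges\tchild\tparent\tposterior")
    for child, par in spec.edges:
        lines.append(f"{child + 1}\t{par + 1}\t{spec.lattice[child, par]:.6g}")
    lines.append("#block conditionals\tchild\tparent\tparent_letter\t"
                 + "\t".join(ALPHABET))
    for (child, par), cond in spec.conditionals.items():
        for p_letter in range(N_LETTERS):
            lines.append(
                f"{child + 1}\t{par + 1}\t{ALPHABET[p_letter]}\t"
                + "\t".join(f"{v:.6g}" for v in cond[p_letter]))
    Path(path).write_text("\n".join(lines) + "\n")
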