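"""Newman spectral modularity maximization with Kernighan-Lin refinement.

Implements the weighted generalization of Newman's (2006) leading-eigenvector
method: the modularity of a partition with affiliation m is

    Q = (1/2W) * sum_ij (w_ij - s_i s_j / 2W) * delta(m_i, m_j)

with s_i the node strengths and 2W the total weight (twice the sum over
unordered edges).  For a binary graph this reduces to the usual form with
degrees and edge count.  Q of the trivial one-module partition is exactly 0.

The maximizer proceeds by recursive spectral bisection on the (generalized)
modularity matrix, a Kernighan-Lin sweep after each bisection, and a final
global refinement that moves single nodes between (or out into new) modules
and merges module pairs while any move improves Q.  All tie-breaks are by
lowest node index, so results are deterministic for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class ModularityResult:
    Q: float
    affiliation: np.ndarray   # module id per node, 0-based, relabeled by first node
    n_modules: int


def partition_modularity(weights: np.ndarray, affiliation: np.ndarray) -> float:
    """Weighted Newman Q of an explicit partition."""
    W = np.asarray(weights, dtype=float)
    aff = np.asarray(affiliation)
    total2 = W.sum()
    if total2 <= 0:
        return 0.0
    s = W.sum(axis=1)
    same = aff[:, None] == aff[None, :]
    B = W - np.outer(s, s) / total2
    return float(B[same].sum() / total2)


def _kl_bisection_refine(Bg: np.ndarray, sides: np.ndarray) -> np.ndarray:
    """Kernighan-Lin sweep on a +-1 bisection of the group matrix Bg.

    Bg must be the generalized modularity matrix of the group (rows summing
    to zero), so the bisection quality is q = s^T Bg s (up to constants).
    Each pass moves every node exactly once in best-gain order and keeps the
    best intermediate state; passes repeat until no improvement.
    """
    n = len(sides)
    sides = sides.astype(float).copy()
    for _ in range(n):  # bounded number of passes
        best_q = sides @ Bg @ sides
        start_q = best_q
        state = sides.copy()
        moved = np.zeros(n, dtype=bool)
        best_state = sides.copy()
        for _step in range(n):
            # gain of flipping node i: delta q = -4 s_i * (Bg s)_i + 4 Bg_ii
            field = Bg @ state
            gains = -4.0 * state * field + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            state[i] = -state[i]
            moved[i] = True
            q = state @ Bg @ state
            if q > best_q + _EPS:
                best_q = q
                best_state = state.copy()
        sides = best_state
        if best_q <= start_q + _EPS:
            break
    return sides


def _spectral_bisect(B: np.ndarray, group: np.ndarray,
                     total2: float) -> tuple[np.ndarray, np.ndarray] | None:
    """Split ``group`` in two if that increases Q, else return None."""
    Bg = B[np.ix_(group, group)].copy()
    Bg -= np.diag(Bg.sum(axis=1))       # generalized modularity matrix
    Bg = (Bg + Bg.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(Bg)
    lead = eigvecs[:, -1]
    if eigvals[-1] <= _EPS:
        return None
    sides = np.where(lead >= 0, 1.0, -1.0)
    sides = _kl_bisection_refine(Bg, sides)
    dq = (sides @ Bg @ sides) / (2.0 * total2)
    if dq <= _EPS or np.all(sides == sides[0]):
        return None
    return group[sides > 0], group[sides < 0]


def _move_refine(B: np.ndarray, total2: float, aff: np.ndarray) -> np.ndarray:
    """Greedy node-move and module-merge refinement until convergence."""
    aff = aff.copy()
    n = len(aff)
    for _ in range(200):
        improved = False
        # single-node moves (including into a fresh singleton module)
        for i in range(n):
            current = aff[i]
            labels = np.unique(aff)
            free = int(labels.max()) + 1
            base = B[i] @ (aff == current) - B[i, i]
            best_gain, best_target = _EPS, None
            for target in list(labels) + [free]:
                if target == current:
                    continue
                gain = (B[i] @ (aff == target)) - base
                if gain > best_gain:
                    best_gain, best_target = gain, target
            if best_target is not None:
                aff[i] = best_target
                improved = True
        # module merges
        labels = list(np.unique(aff))
        merged = True
        while merged:
            merged = False
            best_gain, best_pair = _EPS, None
            for ai in range(len(labels)):
                for bi in range(ai + 1, len(labels)):
                    a, b = labels[ai], labels[bi]
                    gain = B[np.ix_(aff == a, aff == b)].sum()
                    if gain > best_gain:
                        best_gain, best_pair = gain, (a, b)
            if best_pair is not None:
                a, b = best_pair
                aff[aff == b] = a
                labels = list(np.unique(aff))
                improved = merged = True
        if not improved:
            break
    return aff


def _pair_move_refine(B: np.ndarray, total2: float,
                      aff: np.ndarray) -> np.ndarray:
    """Joint two-node moves: both to a common target (new module allowed)
    or an exchange of modules; catches barriers single moves cannot."""
    aff = aff.copy()
    n = len(aff)

    def move_gain(state, i, target):
        base = B[i] @ (state == state[i]) - B[i, i]
        return (B[i] @ (state == target)) - base

    for _ in range(n):
        improved = False
        labels = list(np.unique(aff))
        free = int(max(labels)) + 1
        best_gain, best_apply = _EPS, None
        for i in range(n):
            for j in range(i + 1, n):
                # joint move to a common target
                for target in labels + [free]:
                    if target == aff[i] and target == aff[j]:
                        continue
                    state = aff.copy()
                    gain = move_gain(state, i, target)
                    state[i] = target
                    gain += move_gain(state, j, target)
                    if gain > best_gain:
                        best_gain, best_apply = gain, (i, j, target, target)
                # exchange modules
                if aff[i] != aff[j]:
                    state = aff.copy()
                    gain = move_gain(state, i, aff[j])
                    state[i] = aff[j]
                    gain += move_gain(state, j, aff[i])
                    if gain > best_gain:
                        best_gain, best_apply = gain, (i, j, aff[j], aff[i])
        if best_apply is None:
            break
        i, j, ti, tj = best_apply
        aff[i], aff[j] = ti, tj
        improved = True
        if not improved:
            break
    return aff


def _global_kl(B: np.ndarray, total2: float, aff: np.ndarray) -> np.ndarray:
    """Multi-module Kernighan-Lin: cross small Q barriers.

    One pass moves every node exactly once (to its best alternative module,
    new singleton allowed, even at a loss) and keeps the best intermediate
    partition seen; passes repeat while Q improves.
    """
    aff = aff.copy()
    n = len(aff)
    for _ in range(n):
        state = aff.copy()
        best_state = aff.copy()
        best_gain, running = 0.0, 0.0
        moved = np.zeros(n, dtype=bool)
        for _step in range(n):
            step_best, choice = -np.inf, None
            labels = np.unique(state)
            free = int(labels.max()) + 1
            for i in range(n):
                if moved[i]:
                    continue
                base = B[i] @ (state == state[i]) - B[i, i]
                for target in list(labels) + [free]:
                    if target == state[i]:
                        continue
                    gain = (B[i] @ (state == target)) - base
                    if gain > step_best + _EPS:
                        step_best, choice = gain, (i, target)
            if choice is None:
                break
            i, target = choice
            state[i] = target
            moved[i] = True
            running += step_best
            if running > best_gain + _EPS:
                best_gain = running
                best_state = state.copy()
        if best_gain <= _EPS:
            break
        aff = best_state
    return aff


def _canonical_labels(aff: np.ndarray) -> np.ndarray:
    out = np.empty_like(aff)
    mapping: dict[int, int] = {}
    for i, a in enumerate(aff):
        if a not in mapping:
            mapping[a] = len(mapping)
        out[i] = mapping[a]
    return out


def newman_modularity(weights: np.ndarray) -> ModularityResult:
    """Maximize weighted Newman modularity; deterministic for fixed input."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    total2 = W.sum()
    if n == 0:
        raise ValueError("empty graph")
    if total2 <= 0:
        return ModularityResult(0.0, np.zeros(n, dtype=int), 1)
    s = W.sum(axis=1)
    B = W - np.outer(s, s) / total2
    np.fill_diagonal(B, np.diag(W) - s * s / total2)

    modules: list[np.ndarray] = []
    stack = [np.arange(n)]
    while stack:
        group = stack.pop()
        if len(group) == 1:
            modules.append(group)
            continue
        split = _spectral_bisect(B, group, total2)
        if split is None:
            modules.append(group)
        else:
            stack.extend(split)

    spectral = np.empty(n, dtype=int)
    for label, group in enumerate(modules):
        spectral[group] = label

    # refine from several deterministic starting partitions (the spectral
    # tree, all singletons, one module) and keep the best; the extra starts
    # cross Q barriers the bisection basin cannot
    best_aff, best_q = None, -np.inf
    starts = [spectral, np.arange(n), np.zeros(n, dtype=int)]
    for aff in starts:
        aff = aff.copy()
        for _ in range(50):
            aff = _move_refine(B, total2, aff)
            aff = _global_kl(B, total2, aff)
            aff = _pair_move_refine(B, total2, aff)
            aff = _move_refine(B, total2, aff)
            split_any = False
            for label in np.unique(aff):
                group = np.flatnonzero(aff == label)
                if len(group) < 2:
                    continue
                split = _spectral_bisect(B, group, total2)
                if split is not None:
                    aff[split[1]] = int(aff.max()) + 1
                    split_any = True
            if not split_any:
                break
        q = partition_modularity(W, aff)
        if q > best_q + _EPS:
            best_q, best_aff = q, aff
    aff = _canonical_labels(best_aff)
    return ModularityResult(Q=best_q, affiliation=aff,
                            n_modules=int(aff.max()) + 1)
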