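"""Exhaustive search for the optimal valid ordering.

``best_valid_orderings`` runs a depth-first backtracking search over
partial orderings. A prefix is abandoned as soon as appending a sample
would break successor dominance for an earlier position, or when an
admissible optimistic bound (remaining steps times the largest
off-diagonal similarity) cannot reach the best total found so far, so
the search is exact. ``enumerate_all`` is the unpruned cross-check: it
scores every permutation (vectorised, so 10! is still a few seconds)
and is used to certify the pruned search on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .similarity import Ordering, SimilarityMatrix, is_valid_ordering, overall_similarity

__all__ = [
    "OracleResult",
    "best_valid_orderings",
    "enumerate_all",
    "enumerate_best_valid",
]

_TIE_TOL = 1e-9


@dataclass
class OracleResult:
    """Outcome of the exhaustive search.

    ``optimal_orderings`` is empty when no valid ordering exists (then
    ``best_similarity`` is None); every listed ordering is valid and
    attains ``best_similarity`` within 1e-9.
    """

    best_similarity: float | None
    optimal_orderings: list[Ordering]
    explored_nodes: int


def best_valid_orderings(S: SimilarityMatrix, max_n: int = 12) -> OracleResult:
    """Exact maximisers of the overall similarity over valid orderings."""
    n = S.n
    if n > max_n:
        raise InputError(
            f"refusing exhaustive search for n={n} > max_n={max_n}; "
            "raise max_n explicitly if you accept the runtime"
        )
    sim = S.sim
    max_off = S.max_offdiagonal()
    best: list[float] = [-np.inf]
    optima: list[Ordering] = []
    explored = 0

    prefix: list[int] = []
    used = [False] * n

    def extend() -> None:
        nonlocal explored, optima
        depth = len(prefix)
        if depth == n:
            total = sum(sim[prefix[k], prefix[k + 1]] for k in range(n - 1))
            if total > best[0] + _TIE_TOL:
                best[0] = total
                optima = [tuple(prefix)]
            elif abs(total - best[0]) <= _TIE_TOL:
                tup = tuple(prefix)
                if tup not in optima:
                    optima.append(tup)
            return
        for a in range(n):
            if used[a]:
                continue
            # successor dominance: each earlier position with a fixed
            # successor must not prefer the new sample
            ok = all(
                sim[prefix[i], prefix[i + 1]] >= sim[prefix[i], a] - _TIE_TOL
                for i in range(depth - 1)
            )
            if not ok:
                continue
            partial = sum(sim[prefix[k], prefix[k + 1]] for k in range(depth - 1))
            if depth >= 1:
                partial += sim[prefix[-1], a]
            remaining = n - depth - 1
            if partial + remaining * max_off < best[0] - _TIE_TOL:
                continue  # admissible bound cannot reach the incumbent
            explored += 1
            prefix.append(a)
            used[a] = True
            extend()
            prefix.pop()
            used[a] = False

    extend()
    if not optima:
        return OracleResult(None, [], explored)
    # re-score exactly and drop any tie-tolerance stragglers
    scored = [(overall_similarity(o, S), o) for o in optima]
    top = max(s for s, _ in scored)
    winners = [o for s, o in scored if abs(s - top) <= _TIE_TOL and is_valid_ordering(o, S)]
    return OracleResult(float(top), winners, explored)


def enumerate_all(
    S: SimilarityMatrix, max_n: int = 9
) -> list[tuple[Ordering, float, bool]]:
    """Score and validity-flag every permutation (unpruned cross-check)."""
    n = S.n
    if n > max_n:
        raise InputError(
            f"refusing full enumeration for n={n} > max_n={max_n} "
            f"({n}! permutations); raise max_n explicitly if you accept the cost"
        )
    sim = S.sim
    total = 1
    for k in range(2, n + 1):
        total *= k
    perms = np.empty((total, n), dtype=np.int8)
    for row, p in enumerate(itertools.permutations(range(n))):
        perms[row] = p

    out: list[tuple[Ordering, float, bool]] = []
    chunk = 200_000
    for lo in range(0, total, chunk):
        block = perms[lo : lo + chunk].astype(np.intp)
        sims = np.zeros(block.shape[0])
        for k in range(n - 1):
            sims += sim[block[:, k], block[:, k + 1]]
        valid = np.ones(block.shape[0], dtype=bool)
        for i in range(n - 2):
            succ = sim[block[:, i], block[:, i + 1]]
            for j in range(i + 2, n):
                valid &= succ >= sim[block[:, i], block[:, j]] - _TIE_TOL
        out.extend(
            (tuple(int(x) for x in block[r]), float(sims[r]), bool(valid[r]))
            for r in range(block.shape[0])
        )
    return out


def _perm_blocks(n: int, chunk: int):
    """Yield permutations of range(n) as integer-index arrays, chunked."""
    buf = np.empty((chunk, n), dtype=np.int8)
    fill = 0
    for p in itertools.permutations(range(n)):
        buf[fill] = p
        fill += 1
        if fill == chunk:
            yield buf.astype(np.intp)
            fill = 0
    if fill:
        yield buf[:fill].astype(np.intp)


def enumerate_best_valid(
    S: SimilarityMatrix, max_n: int = 10, require_valid: bool = True
) -> OracleResult:
    """Unpruned optimum over valid orderings, streamed in chunks.

    Same contract as :func:`best_valid_orderings` but found by brute
    force over all n! permutations, never keeping more than one chunk in
    memory; intended purely as an independent certificate of the pruned
    search. With ``require_valid=False`` the validity constraint is
    dropped, giving the unconstrained maximum over every permutation
    (useful to certify how many orderings attain the global optimum —
    the objective is reversal-invariant while validity is not).
    """
    n = S.n
    if n > max_n:
        raise InputError(f"refusing full enumeration for n={n} > max_n={max_n}")
    sim = S.sim
    best = -np.inf
    optima: list[Ordering] = []
    explored = 0
    for block in _perm_blocks(n, 200_000):
        explored += block.shape[0]
        sims = np.zeros(block.shape[0])
        for k in range(n - 1):
            sims += sim[block[:, k], block[:, k + 1]]
        if require_valid:
            valid = np.ones(block.shape[0], dtype=bool)
            for i in range(n - 2):
                succ = sim[block[:, i], block[:, i + 1]]
                for j in range(i + 2, n):
                    valid &= succ >= sim[block[:, i], block[:, j]] - _TIE_TOL
            sims[~valid] = -np.inf
            any_hit = bool(valid.any())
        else:
            any_hit = True
        block_best = float(sims.max()) if any_hit else -np.inf
        if block_best > best + _TIE_TOL:
            best = block_best
            optima = []
        if block_best > -np.inf and block_best >= best - _TIE_TOL:
            hits = np.nonzero(sims >= best - _TIE_TOL)[0]
            optima.extend(tuple(int(x) for x in block[r]) for r in hits)
    if not optima:
        return OracleResult(None, [], explored)
    scored = [(overall_similarity(o, S), o) for o in set(optima)]
    top = max(s for s, _ in scored)
    winners = sorted(o for s, o in scored if abs(s - top) <= _TIE_TOL)
    return OracleResult(float(top), winners, explored)
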