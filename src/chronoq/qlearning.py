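"""Tabular Q-learning over the ordering tree.

The environment is a tree: a state is the prefix of samples placed so
far (the root is the empty prefix), every non-terminal state offers one
action per sample, and a root-to-leaf path of length ``n`` spells out a
candidate ordering (its *action configuration*). Placing a fresh sample
is rewarded with its similarity to the previous one, so the undiscounted
reward sum along a repeat-free path telescopes to the overall similarity
of the ordering; repeated samples and terminal sequences that break the
validity constraint draw a penalty. Maximising return therefore
maximises the overall similarity over valid orderings.

Action selection mixes two deterministic greedy rules: with probability
``epsilon`` the action whose successor state has the largest Q-value,
otherwise a one-step look-ahead picking the action that maximises the
total similarity of the extended prefix. Exploration comes entirely from
tie-breaking: during training ties are broken uniformly at random from
the seeded generator. This matters at the root, where the look-ahead
scores of all first samples tie at zero, so the look-ahead branch keeps
sampling first actions uniformly forever; with a deterministic tie-break
the agent would fixate on one starting sample and could never discover
an optimum that starts elsewhere. Solution extraction is deterministic
(highest Q, ties to the lowest sample index).

Q-values are stored sparsely, keyed by prefix, since the full tree has
on the order of ``n^n`` states and an episode touches only ``n`` of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError
from .similarity import (
    Ordering,
    SimilarityMatrix,
    is_valid_ordering,
    overall_similarity,
    similarity_from_expression,
)

__all__ = [
    "PathState",
    "QTable",
    "RLConfig",
    "TrainingLog",
    "successors",
    "step_reward",
    "select_action",
    "q_update",
    "train",
    "extract_solution",
    "solve",
]

#: A state is the sequence of actions taken from the root.
PathState = tuple[int, ...]


@dataclass
class RLConfig:
    """Training hyper-parameters.

    ``gamma=1`` keeps the return undiscounted so it telescopes exactly to
    the overall similarity; ``epsilon`` is the probability of the
    Q-greedy branch (the complement takes the look-ahead branch);
    ``invalid_penalty=None`` resolves to twice the largest pairwise
    similarity of the instance at training time.
    """

    gamma: float = 1.0
    alpha: float = 0.8
    episodes: int = 13_000
    epsilon: float = 0.8
    invalid_penalty: float | None = None
    seed: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise InputError("gamma must lie in (0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError("alpha must lie in [0, 1]")
        if self.episodes < 0:
            raise InputError("episodes must be nonnegative")
        if not 0.0 <= self.epsilon <= 1.0:
            raise InputError("epsilon must lie in [0, 1]")
        if self.invalid_penalty is not None and self.invalid_penalty <= 0:
            raise InputError("invalid_penalty must be positive")
        if self.log_every < 1:
            raise InputError("log_every must be positive")

    def resolved_penalty(self, S: SimilarityMatrix) -> float:
        if self.invalid_penalty is not None:
            return float(self.invalid_penalty)
        return 2.0 * S.max_offdiagonal()


class QTable:
    """Sparse (state, action) -> value map with a default for unseen pairs."""

    def __init__(self, n_actions: int, default: float = 0.0) -> None:
        self.n_actions = int(n_actions)
        self.default = float(default)
        self._rows: dict[PathState, np.ndarray] = {}

    def row(self, state: PathState) -> np.ndarray:
        """Action values of ``state`` (a fresh default row if unseen)."""
        row = self._rows.get(state)
        if row is None:
            return np.full(self.n_actions, self.default)
        return row

    def get(self, state: PathState, action: int) -> float:
        row = self._rows.get(state)
        return self.default if row is None else float(row[action])

    def set(self, state: PathState, action: int, value: float) -> None:
        row = self._rows.get(state)
        if row is None:
            row = np.full(self.n_actions, self.default)
            self._rows[state] = row
        row[action] = value

    def max_value(self, state: PathState) -> float:
        row = self._rows.get(state)
        return self.default if row is None else float(row.max())

    def __len__(self) -> int:
        return len(self._rows)


@dataclass
class TrainingLog:
    """Greedy-solution quality sampled along training.

    ``entries`` holds ``(episode, overall similarity of the current
    greedy solution)`` pairs with strictly increasing episode numbers;
    ``candidate_evaluations`` counts similarity/Q candidate scans, the
    quantity whose per-episode growth is quadratic in ``n``.
    """

    entries: list[tuple[int, float]] = field(default_factory=list)
    candidate_evaluations: int = 0

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def similarities(self) -> list[float]:
        return [s for _, s in self.entries]


def successors(state: PathState, n: int) -> list[int]:
    """All actions available from ``state`` (empty when terminal).

    Every one of the ``n`` samples is a physically possible move —
    repeats are discouraged by the reward, not forbidden by the
    dynamics — and blind sampling would pick each with probability 1/n.
    """
    if len(state) >= n:
        return []
    return list(range(n))


def step_reward(
    state: PathState, action: int, S: SimilarityMatrix, config: RLConfig
) -> float:
    """Reward for appending ``action`` to ``state``.

    A repeated sample costs the invalid penalty; a fresh sample earns its
    similarity to the previous one (0 at the root). Completing a terminal
    sequence that is not a valid ordering costs one extra penalty, so
    valid orderings are the only sequences whose return equals their
    overall similarity.
    """
    n = S.n
    if len(state) >= n:
        raise InputError("no reward from a terminal state")
    penalty = config.resolved_penalty(S)
    if action in state:
        reward = -penalty
    elif state:
        reward = S.value(state[-1], action)
    else:
        reward = 0.0
    full = state + (int(action),)
    if len(full) == n:
        distinct = len(set(full)) == n
        if not distinct or not is_valid_ordering(full, S):
            reward -= penalty
    return float(reward)


def _pick(candidates: np.ndarray, scores: np.ndarray, rng) -> int:
    """Arg-max with tie-breaking: seeded-uniform when ``rng`` is given,
    lowest sample index otherwise."""
    best = scores.max()
    ties = candidates[scores == best]
    if rng is None or len(ties) == 1:
        return int(ties[0])
    return int(ties[rng.integers(len(ties))])


def select_action(
    state: PathState,
    q: QTable,
    S: SimilarityMatrix,
    config: RLConfig,
    rng: np.random.Generator,
    log: TrainingLog | None = None,
) -> int:
    """One training-time action choice from ``state``.

    With probability ``epsilon`` the Q-greedy branch picks the action
    whose successor has the largest Q-value; otherwise the look-ahead
    branch picks the action maximising the total similarity of the
    extended prefix (for a fixed prefix this is the similarity of the
    new adjacent pair, zero at the root). Already-used actions are
    excluded whenever an unused one exists; ties go to a uniform draw
    from ``rng``.
    """
    n = S.n
    if len(state) >= n:
        raise InputError("cannot select an action from a terminal state")
    used = set(state)
    candidates = np.array([a for a in range(n) if a not in used] or list(range(n)))
    if log is not None:
        log.candidate_evaluations += len(candidates)
    if rng.random() < config.epsilon:
        scores = q.row(state)[candidates]
    else:
        if state:
            scores = S.sim[state[-1], candidates]
        else:
            scores = np.zeros(len(candidates))
    return _pick(candidates, scores, rng)


def q_update(
    q: QTable,
    state: PathState,
    action: int,
    reward: float,
    next_state: PathState,
    config: RLConfig,
    n: int | None = None,
) -> None:
    """One temporal-difference backup:
    ``Q(s,a) += alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))``.

    The max over the successors of a terminal state is 0.
    """
    if next_state != state + (int(action),):
        raise InputError("next_state must extend state by action")
    n = q.n_actions if n is None else n
    terminal = len(next_state) >= n
    future = 0.0 if terminal else config.gamma * q.max_value(next_state)
    old = q.get(state, action)
    q.set(state, action, old + config.alpha * (reward + future - old))


def train(
    S: SimilarityMatrix, config: RLConfig | None = None
) -> tuple[QTable, TrainingLog]:
    """Run episodic Q-learning on the ordering tree of ``S``.

    Each episode walks root-to-terminal with :func:`select_action`,
    backing up every transition with :func:`q_update`. Every
    ``log_every`` episodes the current greedy solution is extracted and
    its overall similarity recorded, giving the convergence trace of the
    learner.
    """
    if S.n < 2:
        raise InputError("training needs at least 2 samples")
    config = config or RLConfig()
    rng = np.random.default_rng(config.seed)
    q = QTable(S.n)
    log = TrainingLog()
    n = S.n
    for episode in range(1, config.episodes + 1):
        state: PathState = ()
        for _ in range(n):
            action = select_action(state, q, S, config, rng, log=log)
            reward = step_reward(state, action, S, config)
            next_state = state + (action,)
            q_update(q, state, action, reward, next_state, config, n=n)
            state = next_state
        if episode % config.log_every == 0:
            greedy = extract_solution(q, S)
            log.entries.append((episode, overall_similarity(greedy, S)))
    return q, log


def extract_solution(q: QTable, S: SimilarityMatrix) -> Ordering:
    """Greedy root-to-leaf walk: highest-Q unused action at every step,
    ties to the lowest sample index; always yields a permutation."""
    n = S.n
    state: PathState = ()
    used: set[int] = set()
    for _ in range(n):
        candidates = np.array([a for a in range(n) if a not in used])
        scores = q.row(state)[candidates]
        action = _pick(candidates, scores, rng=None)
        state = state + (action,)
        used.add(action)
    return state


def solve(
    data,
    times=None,
    config: RLConfig | None = None,
    threshold: float = 0.6,
    constant="auto",
    direction: str = "increasing",
) -> tuple[Ordering, dict]:
    """End-to-end ordering of an expression matrix or similarity matrix.

    With an expression matrix and times, genes are filtered (missing
    removal + correlation filter at ``threshold``) before the similarity
    matrix is built with the large-constant rule; the agent is then
    trained and the greedy solution extracted. When times are known the
    result is oriented along them (``direction`` picks the convention)
    and its misplacement degree is reported.

    Returns the ordering (0-based sample indices) and a summary dict
    with the overall similarity, validity flag (of the learned
    direction, before any orientation flip), training log and, when
    available, SMD and the filtering report.
    """
    from . import evaluation, preprocessing

    config = config or RLConfig()
    summary: dict = {}
    if isinstance(data, SimilarityMatrix):
        S = data
    else:
        matrix = data
        if matrix.n_samples < 2:
            raise InputError("need at least 2 samples to order")
        if times is not None:
            matrix, report = preprocessing.preprocess(matrix, times, threshold)
            summary["filter"] = {
                "threshold": report.threshold,
                "kept_genes": report.n_kept,
                "dropped_missing": report.dropped_missing,
                "dropped_low_correlation": report.dropped_low_correlation,
            }
        elif matrix.has_missing():
            matrix = preprocessing.remove_incomplete_genes(matrix)
        S = similarity_from_expression(matrix, constant=constant)
    if S.n < 2:
        raise InputError("need at least 2 samples to order")

    q, log = train(S, config)
    ordering = extract_solution(q, S)
    # score the solution in its learned direction: the objective is
    # reversal-invariant but the validity constraint is not, and
    # orientation below may flip the reported direction
    summary.update(
        overall_similarity=overall_similarity(ordering, S),
        valid=is_valid_ordering(ordering, S),
    )

    if times is not None:
        ids = [S.sample_ids[i] for i in ordering]
        oriented_ids = evaluation.orient(ids, times, direction=direction)
        index_of = {s: i for i, s in enumerate(S.sample_ids)}
        ordering = tuple(index_of[s] for s in oriented_ids)
        res = evaluation.smd(oriented_ids, times)
        summary["smd"] = res.smd
        left, right = evaluation.half_averages(oriented_ids, times)
        summary["half_averages"] = (left, right)

    summary.update(
        training_log=log,
        episodes=config.episodes,
        seed=config.seed,
    )
    return ordering, summary
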