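"""Ordering quality: the samples-misplacement degree (SMD), orientation
and half-average reporting.

SMD counts samples whose known time falls outside the closed interval
spanned by the times of their two neighbours in the candidate ordering.
For an interior position ``i`` the sample is misplaced iff
``sgn(t_i - t_{i-1}) * sgn(t_{i+1} - t_i) < 0``; the first and last
samples are misplaced iff their time is neither the global minimum nor
the global maximum. SMD is 0 for the correctly time-sorted ordering and,
because the objective is direction-blind, also 0 for its exact reverse.
Only the relative order of the time values matters, so SMD is invariant
under any strictly increasing transformation of the times.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .dataset_io import SampleTimes
from .errors import InputError

__all__ = ["SMDResult", "smd", "orient", "half_averages"]


@dataclass
class SMDResult:
    """Misplacement count plus the per-position flags behind it."""

    smd: int
    misplaced: list[bool]

    def __post_init__(self) -> None:
        assert self.smd == sum(self.misplaced)


def _times_along(ordering: Sequence, times) -> np.ndarray:
    """Time value of each position of ``ordering``; ids may be any key."""
    if isinstance(times, SampleTimes):
        return times.vector_for([str(s) for s in ordering])
    try:
        return np.asarray([float(times[s]) for s in ordering])
    except KeyError as exc:
        raise InputError(f"no time recorded for sample {exc}") from exc


def smd(ordering: Sequence, times) -> SMDResult:
    """Samples-misplacement degree of ``ordering`` under known ``times``.

    ``ordering`` is a sequence of sample identifiers (any hashable key of
    ``times``); ``times`` is a :class:`SampleTimes` or a plain mapping.
    """
    if len(set(ordering)) != len(ordering):
        raise InputError("ordering contains repeated samples")
    t = _times_along(ordering, times)
    n = len(t)
    if n < 2:
        raise InputError("SMD needs at least 2 samples")
    tmin, tmax = float(t.min()), float(t.max())
    flags = [False] * n
    flags[0] = t[0] not in (tmin, tmax)
    flags[-1] = t[-1] not in (tmin, tmax)
    for i in range(1, n - 1):
        flags[i] = np.sign(t[i] - t[i - 1]) * np.sign(t[i + 1] - t[i]) < 0
    return SMDResult(smd=int(sum(flags)), misplaced=[bool(f) for f in flags])


def orient(ordering: Sequence, times, direction: str = "increasing"):
    """Pick the ordering or its reverse using the time annotation.

    The objective cannot tell an ordering from its reverse, so the
    reported direction is fixed with the auxiliary times: the returned
    sequence is whichever of the two has the larger Spearman rank
    correlation between position and time (``direction="increasing"``),
    or the smaller one (``direction="decreasing"``, the convention for
    survival data where later disease stages mean shorter survival).
    Ties leave the input unchanged.
    """
    if direction not in {"increasing", "decreasing"}:
        raise InputError("direction must be 'increasing' or 'decreasing'")
    t = _times_along(ordering, times)
    rho = spearmanr(np.arange(len(t)), t).statistic
    if np.isnan(rho) or rho == 0.0:
        return type(ordering)(ordering) if not isinstance(ordering, tuple) else tuple(ordering)
    flip = rho < 0 if direction == "increasing" else rho > 0
    seq = list(ordering)[::-1] if flip else list(ordering)
    return tuple(seq) if isinstance(ordering, tuple) else type(ordering)(seq)


def half_averages(ordering: Sequence, times) -> tuple[float, float]:
    """Mean time of the first ``ceil(n/2)`` positions and of the rest."""
    t = _times_along(ordering, times)
    if len(t) < 2:
        raise InputError("half averages need at least 2 samples")
    cut = ceil(len(t) / 2)
    return float(t[:cut].mean()), float(t[cut:].mean())
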