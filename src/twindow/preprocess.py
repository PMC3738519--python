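"""Trial-level filters and the kill-the-twin catch-trial correction.

The published dataset ships already filtered, so these operations matter
when raw logs are supplied or when data are simulated: exclusion of trials
with stimulus-timing uncertainty above 5 ms, exclusion of TOJ responses
faster than 100 ms from first onset (false alarms), and the kill-the-twin
procedure, which removes, for each fast guess observed on catch trials, a
response of similar latency from the visual-only distribution and replaces
it with an infinitely long reaction time.
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict

import numpy as np

from .datasets import INFINITE, ConditionRTs, TOJTable

__all__ = [
    "KillTwinMode",
    "exclude_uncertain_trials",
    "filter_toj_false_alarms",
    "kill_the_twin",
]


class KillTwinMode(enum.Enum):
    """Twin-selection policy.

    CONSERVATIVE (used on observed data) prefers, for each catch-trial
    guess, the nearest finite visual latency that does not exceed the guess
    latency, falling back to the overall nearest when none is <=.
    PROGRESSIVE (used on resampled null data) removes the overall nearest
    finite latency.
    """

    CONSERVATIVE = "conservative"
    PROGRESSIVE = "progressive"


def exclude_uncertain_trials(trials, threshold: float = 5.0):
    """Drop trials whose timing uncertainty strictly exceeds ``threshold`` ms.

    Parameters
    ----------
    trials : iterable of (latency, uncertainty)
    threshold : float
        Maximum tolerated timing uncertainty in ms (default 5).

    Returns
    -------
    kept : list of (latency, uncertainty)
    n_excluded : int
    """
    kept = []
    n_excluded = 0
    for latency, uncertainty in trials:
        if uncertainty < 0:
            raise ValueError("timing uncertainty must be nonnegative")
        if uncertainty > threshold:
            n_excluded += 1
        else:
            kept.append((latency, uncertainty))
    return kept, n_excluded


def filter_toj_false_alarms(trials, min_latency: float = 100.0):
    """Aggregate raw TOJ trials into a count table, dropping false alarms.

    Responses given earlier than ``min_latency`` ms after the onset of the
    first stimulus are excluded.  Remaining trials are aggregated into
    (visual-first count, total) per SOA; SOAs whose trials were all
    excluded keep a row with total 0 (a zero-trial row contributes a
    factor of one to the binomial likelihood downstream).

    Parameters
    ----------
    trials : iterable of (soa, response_latency_from_first_onset, visual_first)
        ``visual_first`` is truthy when the response was "visual first".

    Returns
    -------
    table : TOJTable
    n_false_alarms : int
    """
    counts: dict[int, int] = defaultdict(int)
    totals: dict[int, int] = defaultdict(int)
    n_fa = 0
    for soa, latency, visual_first in trials:
        soa = int(soa)
        totals.setdefault(soa, 0)
        counts.setdefault(soa, 0)
        if latency < min_latency:
            n_fa += 1
            continue
        totals[soa] += 1
        counts[soa] += int(bool(visual_first))
    soas = sorted(totals)
    table = TOJTable(
        np.array(soas, dtype=int),
        np.array([counts[s] for s in soas], dtype=int),
        np.array([totals[s] for s in soas], dtype=int),
    )
    return table, n_fa


def _pick_twin(finite_sorted: np.ndarray, guess: float, mode: KillTwinMode) -> int:
    """Index (into ``finite_sorted``) of the latency to kill for one guess.

    Ties at equal absolute distance break toward the lower latency.
    """
    if mode is KillTwinMode.CONSERVATIVE:
        below = np.nonzero(finite_sorted <= guess)[0]
        if below.size:
            return int(below[-1])  # nearest latency <= guess
    # overall nearest; searchsorted gives the insertion point
    j = int(np.searchsorted(finite_sorted, guess))
    if j == 0:
        return 0
    if j == finite_sorted.size:
        return j - 1
    lo, hi = finite_sorted[j - 1], finite_sorted[j]
    return j - 1 if guess - lo <= hi - guess else j


def kill_the_twin(
    target: ConditionRTs, catch: ConditionRTs, mode: KillTwinMode
) -> ConditionRTs:
    """Replace, per catch-trial response, one matched target latency by inf.

    Catch responses are processed in ascending latency order so the result
    is deterministic.  The multiset size of ``target`` is preserved.  If the
    target runs out of finite latencies, remaining catch responses are
    ignored with a warning.
    """
    if target.n_total == 0:
        raise ValueError("kill_the_twin: target distribution is empty")
    guesses = np.sort(catch.finite)
    lat = np.array(target.latencies, dtype=float, copy=True)
    for g in guesses:
        finite_idx = np.nonzero(np.isfinite(lat))[0]
        if finite_idx.size == 0:
            warnings.warn(
                "kill_the_twin: no finite latencies left; ignoring remaining "
                "catch responses",
                stacklevel=2,
            )
            break
        order = finite_idx[np.argsort(lat[finite_idx], kind="stable")]
        k = _pick_twin(lat[order], float(g), mode)
        lat[order[k]] = INFINITE
    return ConditionRTs(target.condition_label, target.soa, lat)
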