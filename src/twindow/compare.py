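"""Cross-task comparison of the temporal window of integration.

A participant shows task-driven recalibration ("malleability") when some
SOA simultaneously (a) sits inside the RT-defined window with a significant
race-model violation — the stimuli were integrated when speed was the goal —
and (b) lies strictly outside the TOJ-defined window — their order was
discriminated above chance when segregation was the goal.  The reverse
pattern (chance TOJ without RT violation) is never counted, because absence
of evidence for violation is not evidence of its absence.

Group statistics compare window widths and boundaries between malleable and
non-malleable participants with pooled-variance t tests and a two-factor
between-subjects ANOVA (task x group) on the widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import TOJTable
from .psychometric import TojTWI
from .race import RtTWI

__all__ = [
    "ParticipantClassification",
    "detect_dissociation",
    "compare_groups",
]


@dataclass(frozen=True)
class ParticipantClassification:
    """Per-participant dissociation verdict and supporting numbers."""

    id: str
    rt_twi: RtTWI | None
    toj_twi: TojTWI
    dissociation_soas: tuple[int, ...]
    mean_toj_accuracy_at_dissociation: float | None

    @property
    def malleable(self) -> bool:
        return len(self.dissociation_soas) > 0


def _toj_accuracy(table: TOJTable, soa: int) -> float:
    """Proportion of correct order reports at one SOA.

    Correct means "visual first" for positive SOAs and "auditory first" for
    negative ones; at SOA 0 (no correct answer) the majority response rate
    is used.
    """
    i = int(np.nonzero(table.soas == soa)[0][0])
    c, n = int(table.counts[i]), int(table.totals[i])
    if n == 0:
        return float("nan")
    if soa > 0:
        return c / n
    if soa < 0:
        return (n - c) / n
    return max(c, n - c) / n


def detect_dissociation(
    participant_id: str,
    rt_results,
    rt_window: RtTWI | None,
    toj_window: TojTWI,
    toj_table: TOJTable,
) -> ParticipantClassification:
    """Find SOAs integrated in the RT task yet segregated in the TOJ task.

    Dissociation SOAs are the significantly race-violating SOAs inside the
    RT window that fall strictly outside [threshold_A, threshold_V].
    """
    soas: list[int] = []
    if rt_window is not None:
        for r in rt_results:
            if not r.significant or r.untestable:
                continue
            if not (rt_window.lower <= r.soa <= rt_window.upper):
                continue
            if toj_window.contains(r.soa):
                continue
            soas.append(int(r.soa))
    soas.sort()
    if soas:
        acc = float(np.nanmean([_toj_accuracy(toj_table, s) for s in soas]))
    else:
        acc = None
    return ParticipantClassification(
        participant_id, rt_window, toj_window, tuple(soas), acc
    )


def _group_t(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Pooled-variance two-sample t test, reported as mean (SD), t, p."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        return {"applicable": False, "reason": "fewer than 2 per group"}
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        t, p = 0.0, 1.0  # both groups constant and equal: no difference
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "applicable": True,
        "mean_malleable": float(a.mean()),
        "sd_malleable": float(a.std(ddof=1)),
        "mean_other": float(b.mean()),
        "sd_other": float(b.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "n": [int(a.size), int(b.size)],
    }


def compare_groups(classifications) -> dict:
    """Group statistics: malleable vs non-malleable windows.

    t tests on TOJ width, RT width and all four boundaries; two-factor
    between-subjects ANOVA on widths with factors task (RT/TOJ) x group,
    Type II sums of squares (the design may be unbalanced).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    classifications = list(classifications)
    mall = [c for c in classifications if c.malleable]
    other = [c for c in classifications if not c.malleable]
    report: dict = {
        "n_malleable": len(mall),
        "n_other": len(other),
        "malleable_ids": sorted(c.id for c in mall),
    }
    if not mall or not other:
        report["applicable"] = False
        report["reason"] = "one of the groups is empty"
        return report
    report["applicable"] = True

    def widths_toj(group):
        return np.array([c.toj_twi.width for c in group])

    def widths_rt(group):
        return np.array([c.rt_twi.width for c in group if c.rt_twi is not None])

    report["t_tests"] = {
        "toj_width": _group_t(widths_toj(mall), widths_toj(other)),
        "rt_width": _group_t(widths_rt(mall), widths_rt(other)),
        "toj_boundary_visual": _group_t(
            np.array([c.toj_twi.threshold_v for c in mall]),
            np.array([c.toj_twi.threshold_v for c in other]),
        ),
        "toj_boundary_auditory": _group_t(
            np.array([c.toj_twi.threshold_a for c in mall]),
            np.array([c.toj_twi.threshold_a for c in other]),
        ),
        "rt_boundary_upper": _group_t(
            np.array([c.rt_twi.upper for c in mall if c.rt_twi is not None]),
            np.array([c.rt_twi.upper for c in other if c.rt_twi is not None]),
        ),
        "rt_boundary_lower": _group_t(
            np.array([c.rt_twi.lower for c in mall if c.rt_twi is not None]),
            np.array([c.rt_twi.lower for c in other if c.rt_twi is not None]),
        ),
    }

    rows = []
    for c in classifications:
        group = "malleable" if c.malleable else "other"
        rows.append({"width": c.toj_twi.width, "task": "TOJ", "group": group})
        if c.rt_twi is not None:
            rows.append({"width": c.rt_twi.width, "task": "RT", "group": group})
    frame = pd.DataFrame(rows)
    model = smf.ols("width ~ C(task) * C(group)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = {}
    key_map = {
        "C(task)": "task",
        "C(group)": "group",
        "C(task):C(group)": "interaction",
    }
    for raw, name in key_map.items():
        anova[name] = {
            "F": float(table.loc[raw, "F"]),
            "p": float(table.loc[raw, "PR(>F)"]),
        }
    by_task = frame.groupby("task")["width"]
    by_group = frame.groupby("group")["width"]
    anova["task_means"] = {
        k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        for k, v in by_task
    }
    anova["group_means"] = {
        k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        for k, v in by_group
    }
    report["anova_widths"] = anova
    return report
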