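"""End-to-end orchestration: preprocess -> race tests -> TOJ fits -> compare.

``run_study`` walks every participant through the race-model analysis (one
resampling test per SOA plus the contiguity rule for the RT-defined
window), the Bayesian psychometric fit (slice sampling, thresholds,
widest-boundary window, non-performer exclusion), and the cross-task
dissociation classification, then assembles group-level summaries: the
sign-permutation test on D per SOA, the group psychometric curve, and the
malleable-vs-other comparison statistics.  Group-level analyses are
illustrative; the substantive claims rest on the per-participant results.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
substreams keyed by participant and stage, so a report is reproducible
bit-for-bit from its provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .compare import ParticipantClassification, compare_groups, detect_dissociation
from .datasets import SOA_GRID, StudyDataset
from .preprocess import KillTwinMode, kill_the_twin
from .psychometric import (
    PriorSpec,
    exclude_nonperformers,
    group_psychometric,
    slice_sample_posterior,
    thresholds,
    toj_twi,
)
from .race import group_sign_permutation, race_test, rt_twi

__all__ = ["RunConfig", "StudyReport", "run_study"]

log = logging.getLogger("twindow")


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one analysis run (defaults are the analysis standards)."""

    seed: int = 0
    n_iter: int = 1000
    alpha: float = 0.05
    percentiles: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    n_samples: int = 2000
    burn_in: int = 100
    thin: int = 10
    priors: PriorSpec = field(default_factory=PriorSpec)
    soa_range: tuple[float, float] = (-400.0, 400.0)
    #: apply conservative twin-killing to the bisensory samples as well as
    #: visual-only.  Without it, participants with many catch guesses keep
    #: guess contamination in the tested samples while the progressive
    #: correction slows their null resamples, and the race test fires at
    #: every SOA.
    kill_twin_extend_to_av: bool = True


@dataclass
class StudyReport:
    """Serializable result of :func:`run_study`."""

    per_participant: list
    group: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "per_participant": self.per_participant,
            "group": self.group,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _round(x, nd=6):
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else round(x, nd)


def run_study(dataset: StudyDataset, config: RunConfig = RunConfig()) -> StudyReport:
    """Run the complete two-task analysis on a study.

    Kill-the-twin (conservative mode) is applied to each participant's
    visual-only distribution unless the dataset metadata flags it as
    already applied upstream.
    """
    root = np.random.SeedSequence(config.seed)
    twins_done = bool(dataset.metadata.get("kill_the_twin_already_applied", False))
    per_participant = []
    classifications: list[ParticipantClassification] = []
    retained_samples = []
    d_by_soa: dict[int, list[float]] = {s: [] for s in SOA_GRID}
    borderline_band = 0.01  # p within alpha +/- band flagged as seed-sensitive

    for p_idx, participant in enumerate(dataset):
        pid = participant.id
        log.info("participant %s: race-model analysis", pid)
        p_seed = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(p_idx,)
        )
        work = participant
        if not twins_done and participant.catch.finite.size:
            rt_map = dict(participant.rt)
            rt_map["visual_only"] = kill_the_twin(
                participant.visual, participant.catch, KillTwinMode.CONSERVATIVE
            )
            if config.kill_twin_extend_to_av:
                for soa in SOA_GRID:
                    rt_map[soa] = kill_the_twin(
                        rt_map[soa], participant.catch, KillTwinMode.CONSERVATIVE
                    )
            work = type(participant)(pid, rt_map, participant.toj)

        race_results = []
        for s_idx, soa in enumerate(SOA_GRID):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(p_idx, s_idx))
            )
            res = race_test(
                work,
                soa,
                n_iter=config.n_iter,
                alpha=config.alpha,
                rng=rng,
                percentiles=config.percentiles,
            )
            race_results.append(res)
            if np.isfinite(res.d):
                d_by_soa[soa].append(res.d)
        window_rt = rt_twi(race_results)

        log.info("participant %s: psychometric fit", pid)
        toj_seed = int(
            np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(p_idx, 1000)
            ).generate_state(1)[0] % (2**31 - 1)
        )
        samples = slice_sample_posterior(
            work.toj,
            priors=config.priors,
            n_samples=config.n_samples,
            burn_in=config.burn_in,
            thin=config.thin,
            rng=toj_seed,
        )
        window_toj = toj_twi(samples)
        keep, reason = exclude_nonperformers(window_toj, config.soa_range)
        medians = samples.medians()

        classification = detect_dissociation(
            pid, race_results, window_rt, window_toj, work.toj
        )
        if keep:
            retained_samples.append(samples)
            classifications.append(classification)

        per_participant.append(
            {
                "id": pid,
                "guess_rate": _round(work.guess_rate()),
                "race": [
                    {
                        "soa": r.soa,
                        "d": _round(r.d, 4),
                        "p": _round(r.p, 6),
                        "significant": bool(r.significant),
                        "untestable": bool(r.untestable),
                        "borderline": bool(
                            not r.untestable
                            and abs(r.p - config.alpha) < borderline_band
                        ),
                    }
                    for r in race_results
                ],
                "rt_twi": None
                if window_rt is None
                else {
                    "lower": window_rt.lower,
                    "upper": window_rt.upper,
                    "members": list(window_rt.members),
                },
                "posterior_medians": {
                    "mu": _round(medians.mu, 3),
                    "sigma": _round(medians.sigma, 3),
                    "lambda_a": _round(medians.lambda_a, 5),
                    "lambda_v": _round(medians.lambda_v, 5),
                },
                "posterior_lag1_autocorr": [
                    _round(a, 4) for a in samples.lag1_autocorr
                ],
                "toj_twi": {
                    "threshold_a": _round(window_toj.threshold_a, 3),
                    "threshold_v": _round(window_toj.threshold_v, 3),
                    "width": _round(window_toj.width, 3),
                },
                "retained": bool(keep),
                "exclusion_reason": reason,
                "dissociation_soas": list(classification.dissociation_soas),
                "malleable": bool(keep and classification.malleable),
                "mean_toj_accuracy_at_dissociation": _round(
                    classification.mean_toj_accuracy_at_dissociation, 4
                ),
            }
        )

    group: dict = {"illustrative": True}
    sign_perm = {}
    for soa in SOA_GRID:
        vals = d_by_soa[soa]
        if len(vals) == len(dataset) and len(vals) > 0:
            sign_perm[str(soa)] = _round(group_sign_permutation(vals), 6)
        else:
            sign_perm[str(soa)] = None
    group["sign_permutation_p"] = sign_perm
    group["rt_twi"] = _group_rt_window(sign_perm)
    if retained_samples:
        params, (thr_a, thr_v) = group_psychometric(retained_samples)
        group["psychometric"] = {
            "mu": _round(params.mu, 3),
            "sigma": _round(params.sigma, 3),
            "lambda_a": _round(params.lambda_a, 5),
            "lambda_v": _round(params.lambda_v, 5),
            "threshold_a": _round(thr_a, 3),
            "threshold_v": _round(thr_v, 3),
        }
    else:
        group["psychometric"] = None
    group["comparison"] = _jsonable(compare_groups(classifications)) if classifications else None
    group["n_retained"] = len(classifications)

    provenance = {
        "package": "twindow",
        "version": __version__,
        "seed": config.seed,
        "n_iter": config.n_iter,
        "alpha": config.alpha,
        "percentiles": list(config.percentiles),
        "n_samples": config.n_samples,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "kill_the_twin_applied_here": not twins_done,
        "dataset_metadata": _jsonable(dataset.metadata),
        "n_participants": len(dataset),
    }
    return StudyReport(per_participant, group, provenance)


def _group_rt_window(sign_perm: dict) -> dict | None:
    """Contiguity rule applied to the group sign-permutation p values."""
    sig = [int(s) for s, p in sign_perm.items() if p is not None and p < 0.05]
    if not sig:
        return None

    class _R:
        def __init__(self, soa):
            self.soa = soa
            self.significant = soa in sig
            self.untestable = False

    window = rt_twi([_R(s) for s in SOA_GRID])
    if window is None:
        return None
    return {"lower": window.lower, "upper": window.upper, "members": list(window.members)}


def _jsonable(obj):
    """Best-effort conversion of report fragments to JSON-native types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
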