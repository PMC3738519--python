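"""In-memory containers and file I/O for audiovisual RT / TOJ studies.

A study couples, per participant, a reaction-time (RT) experiment — catch
trials, auditory-only, visual-only, and bisensory trials at 23 stimulus
onset asynchronies (SOAs) — with a temporal-order-judgment (TOJ) table of
"visual first" counts per SOA.  The sign convention is fixed throughout the
package: negative SOA means the auditory stimulus led, positive means the
visual stimulus led.  Misses (no response) are coded as ``math.inf``.

Two on-disk representations are supported: the published MAT container of
the original study (read-only) and a native, diff-friendly CSV dialect
(read/write, lossless round trip).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io

__all__ = [
    "SOA_GRID",
    "CONDITION_ORDER",
    "INFINITE",
    "ConditionRTs",
    "TOJTable",
    "ParticipantData",
    "StudyDataset",
    "ValidationError",
    "ShapeError",
    "ParseError",
    "read_dataset_s1",
    "read_native",
    "write_native",
]

#: Bisensory SOA grid in ms, ascending.  Negative = auditory leading.
SOA_GRID: tuple[int, ...] = (
    -400, -300, -250, -200, -150, -120, -100, -80, -60, -40, -20,
    0, 20, 40, 60, 80, 100, 120, 150, 200, 250, 300, 400,
)

#: Condition labels in the MAT container's row order (26 conditions).
CONDITION_ORDER: tuple[object, ...] = ("catch", "auditory_only") + SOA_GRID + ("visual_only",)

#: Distinguished latency for misses / killed twins.
INFINITE: float = math.inf

CATCH = "catch"
AUDITORY = "auditory_only"
VISUAL = "visual_only"


class ValidationError(ValueError):
    """A dataset value violates a structural invariant."""


class ShapeError(ValidationError):
    """An array in a container file has the wrong shape."""


class ParseError(ValueError):
    """A container file is missing an expected field."""


@dataclass(frozen=True)
class ConditionRTs:
    """RT sample for one participant x condition.

    Parameters
    ----------
    condition_label : str
        One of ``"catch"``, ``"auditory_only"``, ``"visual_only"`` or
        ``"av"`` (bisensory).
    soa : int or None
        Signed SOA in ms for bisensory conditions, ``None`` otherwise.
    latencies : numpy.ndarray
        Response latencies in ms; each entry is finite positive or ``inf``.
    """

    condition_label: str
    soa: int | None
    latencies: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.latencies, dtype=float)
        object.__setattr__(self, "latencies", lat)
        if lat.ndim != 1:
            raise ValidationError("latencies must be one-dimensional")
        fin = lat[np.isfinite(lat)]
        if np.any(fin <= 0) or np.any(np.isnan(lat)):
            raise ValidationError(
                f"{self.condition_label}: finite latencies must be > 0"
            )
        if self.condition_label == "av":
            if self.soa is None or int(self.soa) not in SOA_GRID:
                raise ValidationError(f"SOA {self.soa} not on the tested grid")
        elif self.soa is not None:
            raise ValidationError(
                f"{self.condition_label} carries an SOA ({self.soa})"
            )

    @property
    def n_total(self) -> int:
        return int(self.latencies.size)

    @property
    def finite(self) -> np.ndarray:
        """Finite latencies, in input order."""
        return self.latencies[np.isfinite(self.latencies)]

    @property
    def n_infinite(self) -> int:
        return int(np.isinf(self.latencies).sum())


@dataclass(frozen=True)
class TOJTable:
    """Per-SOA counts of "visual first" responses.

    ``soas`` strictly increasing; ``0 <= counts <= totals``.  Unisensory
    conditions are never part of a TOJ table.
    """

    soas: np.ndarray
    counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        soas = np.asarray(self.soas, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        totals = np.asarray(self.totals, dtype=int)
        for name, arr in (("soas", soas), ("counts", counts), ("totals", totals)):
            if arr.ndim != 1 or arr.size != soas.size:
                raise ValidationError(f"TOJ column {name!r} has wrong shape")
        if np.any(np.diff(soas) <= 0):
            raise ValidationError("TOJ SOAs must be strictly increasing")
        bad = np.nonzero((counts < 0) | (counts > totals) | (totals < 0))[0]
        if bad.size:
            raise ValidationError(
                f"TOJ rows with counts outside [0, n]: {soas[bad].tolist()}"
            )
        off = [int(s) for s in soas if int(s) not in SOA_GRID]
        if off:
            raise ValidationError(f"TOJ SOAs off the tested grid: {off}")
        object.__setattr__(self, "soas", soas)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "totals", totals)

    @property
    def n_soas(self) -> int:
        return int(self.soas.size)

    def proportion_visual_first(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.totals > 0, self.counts / np.maximum(self.totals, 1), np.nan)


@dataclass
class ParticipantData:
    """All data for one participant: 26 RT conditions plus the TOJ table.

    ``rt`` maps ``"catch"`` / ``"auditory_only"`` / ``"visual_only"`` /
    ``int`` SOA to :class:`ConditionRTs`.
    """

    id: str
    rt: dict
    toj: TOJTable

    def __post_init__(self) -> None:
        missing = [k for k in CONDITION_ORDER if k not in self.rt]
        if missing:
            raise ValidationError(
                f"participant {self.id}: missing RT conditions {missing}"
            )

    @property
    def catch(self) -> ConditionRTs:
        return self.rt[CATCH]

    @property
    def auditory(self) -> ConditionRTs:
        return self.rt[AUDITORY]

    @property
    def visual(self) -> ConditionRTs:
        return self.rt[VISUAL]

    def av(self, soa: int) -> ConditionRTs:
        return self.rt[int(soa)]

    def guess_rate(self) -> float:
        """Fraction of catch trials that drew a (guess) response."""
        c = self.catch
        if c.n_total == 0:
            return 0.0
        return c.finite.size / c.n_total


@dataclass
class StudyDataset:
    """Ordered collection of participants plus provenance metadata."""

    participants: list[ParticipantData]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)


# ---------------------------------------------------------------------------
# MAT container (published study layout)
# ---------------------------------------------------------------------------

def _cell_to_latencies(cell_row: Iterable) -> np.ndarray:
    """Flatten one row of a MAT cell array into a latency vector.

    Empty cells (trials excluded upstream) are simply absent from the
    result; ``Inf`` entries are preserved as misses.
    """
    out: list[float] = []
    for entry in cell_row:
        arr = np.asarray(entry, dtype=float).ravel()
        out.extend(float(v) for v in arr)
    return np.asarray(out, dtype=float)


def _participant_from_arrays(pid: str, rt_cell: np.ndarray, toj_arr: np.ndarray) -> ParticipantData:
    rt_cell = np.atleast_2d(np.asarray(rt_cell, dtype=object))
    if rt_cell.shape[0] != 26:
        raise ShapeError(
            f"participant {pid}: RT cell array has {rt_cell.shape[0]} rows, expected 26"
        )
    toj_arr = np.atleast_2d(np.asarray(toj_arr, dtype=float))
    if toj_arr.shape != (23, 3):
        raise ShapeError(
            f"participant {pid}: TOJ array has shape {toj_arr.shape}, expected (23, 3)"
        )
    rt: dict = {}
    for idx, label in enumerate(CONDITION_ORDER):
        lat = _cell_to_latencies(rt_cell[idx])
        if lat.size > 60:
            raise ValidationError(
                f"participant {pid}: condition {label} has {lat.size} trials (> 60)"
            )
        if isinstance(label, str):
            rt[label] = ConditionRTs(label, None, lat)
        else:
            rt[int(label)] = ConditionRTs("av", int(label), lat)
    order = np.argsort(toj_arr[:, 0])
    toj = TOJTable(toj_arr[order, 0], toj_arr[order, 1], toj_arr[order, 2])
    if np.any(toj.totals > 60):
        raise ValidationError(f"participant {pid}: TOJ totals exceed 60")
    return ParticipantData(pid, rt, toj)


def read_dataset_s1(path: str | os.PathLike) -> StudyDataset:
    """Read the published MAT container (one struct, one substruct per subject).

    Each participant substructure holds a 26x60 RT cell array (row order:
    catch, auditory-only, SOAs -400 ... +400 ascending, visual-only) and a
    23x3 numeric TOJ array (SOA, visual-first count, total).  The RT data in
    the published file have already undergone the kill-the-twin procedure,
    which is recorded in the returned metadata.
    """
    try:
        mat = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ParseError(f"cannot read MAT container {path}: {exc}") from exc
    top = {k: v for k, v in mat.items() if not k.startswith("__")}
    if not top:
        raise ParseError("MAT container holds no data variables")
    # The single top-level variable is the study struct.
    root = next(iter(top.values()))
    if not hasattr(root, "_fieldnames"):
        raise ParseError("top-level MAT variable is not a structure")
    participants = []
    for name in root._fieldnames:
        sub = getattr(root, name)
        if not hasattr(sub, "_fieldnames"):
            raise ParseError(f"participant field {name!r} is not a structure")
        rt_cell = toj_arr = None
        for fname in sub._fieldnames:
            val = getattr(sub, fname)
            arr = np.atleast_2d(np.asarray(val))
            if arr.dtype == object or arr.shape[0] == 26:
                rt_cell = val
            elif arr.shape in ((23, 3), (3, 23)):
                toj_arr = arr if arr.shape == (23, 3) else arr.T
        if rt_cell is None:
            raise ParseError(f"participant {name!r}: no 26-row RT cell array found")
        if toj_arr is None:
            raise ParseError(f"participant {name!r}: no 23x3 TOJ array found")
        participants.append(_participant_from_arrays(name, rt_cell, toj_arr))
    return StudyDataset(
        participants,
        metadata={
            "source": str(path),
            "kill_the_twin_already_applied": True,
            "toj_false_alarms_already_excluded": True,
        },
    )


# ---------------------------------------------------------------------------
# Native CSV dialect
# ---------------------------------------------------------------------------
# rt.csv:  participant,condition,soa,latency   (one row per trial; latency
#          "inf" for misses; soa empty for non-bisensory conditions)
# toj.csv: participant,soa,visual_first,total
# metadata.json: free-form provenance (seed, ground truth, flags)

def _fmt_latency(v: float) -> str:
    return "inf" if math.isinf(v) else repr(float(v))


def write_native(dataset: StudyDataset, directory: str | os.PathLike) -> dict:
    """Write a study as the native CSV dialect; returns the paths written."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rt_rows = []
    toj_rows = []
    for p in dataset:
        for key in CONDITION_ORDER:
            cond = p.rt[key]
            soa = "" if cond.soa is None else int(cond.soa)
            for lat in cond.latencies:
                rt_rows.append((p.id, cond.condition_label, soa, _fmt_latency(lat)))
        for s, c, n in zip(p.toj.soas, p.toj.counts, p.toj.totals):
            toj_rows.append((p.id, int(s), int(c), int(n)))
    rt_path = os.path.join(directory, "rt.csv")
    toj_path = os.path.join(directory, "toj.csv")
    meta_path = os.path.join(directory, "metadata.json")
    pd.DataFrame(rt_rows, columns=["participant", "condition", "soa", "latency"]).to_csv(
        rt_path, index=False
    )
    pd.DataFrame(toj_rows, columns=["participant", "soa", "visual_first", "total"]).to_csv(
        toj_path, index=False
    )
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(dataset.metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return {"rt": rt_path, "toj": toj_path, "metadata": meta_path}


def read_native(
    rt_path: str | os.PathLike,
    toj_path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> StudyDataset:
    """Read a study written by :func:`write_native` (lossless round trip)."""
    rt = pd.read_csv(
        rt_path,
        dtype={"participant": str, "condition": str},
        float_precision="round_trip",
    )
    toj = pd.read_csv(toj_path, dtype={"participant": str})
    errors: list[str] = []
    lat = pd.to_numeric(rt["latency"].replace("inf", np.inf), errors="coerce")
    bad = rt.index[lat.isna() | (np.isfinite(lat) & (lat <= 0))]
    if len(bad):
        errors.append(f"rt rows with non-positive/unparseable latency: {list(bad[:10])}")
    bad = toj.index[(toj["visual_first"] < 0) | (toj["visual_first"] > toj["total"])]
    if len(bad):
        errors.append(f"toj rows with counts outside [0, n]: {list(bad[:10])}")
    bad = toj.index[~toj["soa"].isin(SOA_GRID)]
    if len(bad):
        errors.append(f"toj rows with off-grid SOA: {list(bad[:10])}")
    av = rt[rt["condition"] == "av"]
    bad = av.index[~pd.to_numeric(av["soa"], errors="coerce").isin(SOA_GRID)]
    if len(bad):
        errors.append(f"rt rows with off-grid SOA: {list(bad[:10])}")
    if errors:
        raise ValidationError("; ".join(errors))
    rt = rt.assign(latency=lat)

    participants = []
    order = rt["participant"].drop_duplicates().tolist()
    for extra in toj["participant"].drop_duplicates():
        if extra not in order:
            order.append(extra)
    for pid in order:
        sub = rt[rt["participant"] == pid]
        conds: dict = {}
        for key in CONDITION_ORDER:
            if isinstance(key, str):
                sel = sub[sub["condition"] == key]
                conds[key] = ConditionRTs(key, None, sel["latency"].to_numpy())
            else:
                sel = sub[(sub["condition"] == "av") & (pd.to_numeric(sub["soa"], errors="coerce") == key)]
                conds[key] = ConditionRTs("av", key, sel["latency"].to_numpy())
        tsub = toj[toj["participant"] == pid].sort_values("soa")
        table = TOJTable(
            tsub["soa"].to_numpy(), tsub["visual_first"].to_numpy(), tsub["total"].to_numpy()
        )
        participants.append(ParticipantData(pid, conds, table))
    metadata: dict = {}
    if metadata_path is not None and os.path.exists(os.fspath(metadata_path)):
        with open(metadata_path, "r", encoding="utf-8") as fh:
            metadata = json.load(fh)
    return StudyDataset(participants, metadata)
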