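"""Personalized targeting assets: target filtering, retention-time prediction,
inclusion-list scheduling, burden profiling, and the RTS FASTA / inclusion CSV
writers.

Scheduling enumerates every Met-oxidation variant and charge state of each
retained target and opens a +/-15 min window (default) around its predicted
retention time, clamped to the LC gradient.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .chem import Peptidoform

__all__ = [
    "KYTE_DOOLITTLE",
    "TargetPeptide",
    "InclusionEntry",
    "ScheduledInclusionList",
    "select_targets",
    "predict_rt",
    "LinearHydropathyRT",
    "schedule",
    "burden_profile",
    "write_rts_fasta",
    "write_inclusion_csv",
    "read_inclusion_csv",
]

#: Kyte-Doolittle hydropathy indices, used by the built-in RT surrogate.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class TargetPeptide:
    sequence: str
    class_label: str = "other"  # neoantigen | TAA | other
    annotations: dict[str, float] = field(default_factory=dict)
    rt_pred: float | None = None  # minutes


@dataclass(frozen=True)
class InclusionEntry:
    """One scheduled precursor: a peptidoform/charge with an RT window."""

    sequence: str
    mods: tuple[tuple[int, float], ...]
    mz: float
    z: int
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_stop:
            raise ValueError("inclusion window must have t_start < t_stop")

    @property
    def compound_id(self) -> str:
        return Peptidoform(self.sequence, self.mods, self.z).compound_id


@dataclass
class ScheduledInclusionList:
    entries: list[InclusionEntry]
    gradient_min: float = 125.0

    def active_at(self, t: float) -> list[InclusionEntry]:
        """Entries whose (closed) RT window contains minute t."""
        return [e for e in self.entries if e.t_start <= t <= e.t_stop]


def select_targets(
    candidates: pd.DataFrame,
    length_range: tuple[int, int] = (8, 11),
    min_presence: int = 0,
    rank_filters: Mapping[str, Callable[[float], bool]] | None = None,
    class_column: str = "class",
) -> list[TargetPeptide]:
    """Filter a candidate table down to the targeting list.

    Retains sequences inside ``length_range``, observed in at least
    ``min_presence`` replicates (column ``n_replicates``; required when
    min_presence > 0), and passing every rank predicate (column name ->
    predicate on the value, e.g. target-allele %-rank < 2 and off-target
    %-ranks >= 10). Output is deduplicated and ordered by sequence.
    """
    if "sequence" not in candidates.columns:
        raise KeyError("candidate table lacks a 'sequence' column")
    rank_filters = dict(rank_filters or {})
    for col in rank_filters:
        if col not in candidates.columns:
            raise KeyError(f"rank filter references missing column {col!r}")
    if min_presence > 0 and "n_replicates" not in candidates.columns:
        raise KeyError("min_presence > 0 requires an 'n_replicates' column")

    lo, hi = length_range
    seen: dict[str, TargetPeptide] = {}
    for _, row in candidates.iterrows():
        seq = str(row["sequence"]).upper()
        if not lo <= len(seq) <= hi:
            continue
        if min_presence > 0 and int(row["n_replicates"]) < min_presence:
            continue
        if not all(pred(row[col]) for col, pred in rank_filters.items()):
            continue
        if seq in seen:
            continue
        annotations = {
            c: float(row[c])
            for c in candidates.columns
            if c not in ("sequence", class_column, "n_replicates", "rt_min")
            and pd.api.types.is_number(row[c])
        }
        seen[seq] = TargetPeptide(
            sequence=seq,
            class_label=str(row[class_column]) if class_column in candidates else "other",
            annotations=annotations,
            rt_pred=float(row["rt_min"]) if "rt_min" in candidates and pd.notna(row.get("rt_min")) else None,
        )
    return [seen[s] for s in sorted(seen)]


class LinearHydropathyRT:
    """Built-in RT surrogate: least-squares ``rt = a*hydropathy_sum + b*length + c``.

    A stand-in for an external deep RT predictor; external predictions can
    always be supplied directly through the ``rt_min`` input column.
    """

    min_calibration = 10

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None

    @staticmethod
    def _features(sequences: Sequence[str]) -> np.ndarray:
        return np.array(
            [
                [sum(KYTE_DOOLITTLE[aa] for aa in s), float(len(s)), 1.0]
                for s in sequences
            ]
        )

    def fit(self, calibration: Sequence[tuple[str, float]]) -> "LinearHydropathyRT":
        if len(calibration) < self.min_calibration:
            raise ValueError(
                f"need >= {self.min_calibration} calibration pairs, "
                f"got {len(calibration)}"
            )
        seqs = [s for s, _ in calibration]
        rts = np.array([rt for _, rt in calibration])
        self.coef_, *_ = np.linalg.lstsq(self._features(seqs), rts, rcond=None)
        return self

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("surrogate is not fitted")
        return self._features(sequences) @ self.coef_


def predict_rt(
    targets: Sequence[TargetPeptide],
    calibration: Sequence[tuple[str, float]] | None = None,
    predictor: LinearHydropathyRT | None = None,
    gradient_min: float | None = None,
) -> list[TargetPeptide]:
    """Fill ``rt_pred`` on every target; targets that already carry one pass through.

    Uses a supplied fitted predictor, or fits the built-in hydropathy surrogate
    on ``calibration`` (>= 10 (peptide, rt) pairs). Predictions are clamped to
    [0, gradient_min] when a gradient is given.
    """
    missing = [t for t in targets if t.rt_pred is None]
    if missing:
        if predictor is None:
            if calibration is None:
                raise ValueError("targets lack rt_pred and no calibration given")
            predictor = LinearHydropathyRT().fit(calibration)
        preds = predictor.predict([t.sequence for t in missing])
        for t, rt in zip(missing, preds):
            t.rt_pred = float(rt)
    if gradient_min is not None:
        for t in targets:
            t.rt_pred = float(np.clip(t.rt_pred, 0.0, gradient_min))
    return list(targets)


def schedule(
    targets: Sequence[TargetPeptide],
    varmods: dict[str, float] | None = None,
    max_mods: int = 3,
    charges: Sequence[int] = (1, 2, 3),
    halfwidth_min: float = 15.0,
    gradient_min: float = 125.0,
) -> ScheduledInclusionList:
    """Enumerate precursors per target and schedule RT windows around rt_pred.

    All modification variants inherit the unmodified peptide's predicted RT
    (the surrogate cannot distinguish oxidation). Windows are closed intervals
    clamped to [0, gradient_min].
    """
    entries: list[InclusionEntry] = []
    for t in sorted(targets, key=lambda t: t.sequence):
        if t.rt_pred is None:
            raise ValueError(f"target {t.sequence} has no rt_pred; run predict_rt")
        lo = max(0.0, t.rt_pred - halfwidth_min)
        hi = min(gradient_min, t.rt_pred + halfwidth_min)
        for prec in chem.enumerate_precursors(t.sequence, varmods, max_mods, charges):
            entries.append(
                InclusionEntry(
                    sequence=prec.peptidoform.sequence,
                    mods=prec.peptidoform.mods,
                    mz=prec.mz,
                    z=prec.peptidoform.charge,
                    t_start=lo,
                    t_stop=hi,
                )
            )
    return ScheduledInclusionList(entries, gradient_min)


def burden_profile(
    sil: ScheduledInclusionList, times: Sequence[float]
) -> pd.DataFrame:
    """Number of scheduled precursors whose window contains each time point."""
    times = np.asarray(times, dtype=float)
    if len(sil.entries):
        starts = np.array([e.t_start for e in sil.entries])
        stops = np.array([e.t_stop for e in sil.entries])
        counts = (
            (times[:, None] >= starts[None, :]) & (times[:, None] <= stops[None, :])
        ).sum(axis=1)
    else:
        counts = np.zeros(times.size, dtype=int)
    return pd.DataFrame({"t_min": times, "n_scheduled": counts})


def write_rts_fasta(targets: Sequence[TargetPeptide], path: str | Path) -> None:
    """One FASTA record per target peptide sequence (the real-time search space)."""
    if not targets:
        raise ValueError("cannot write an empty RTS FASTA")
    seen: dict[str, TargetPeptide] = {}
    for t in targets:
        if t.sequence in seen:
            warnings.warn(f"duplicate target sequence {t.sequence} collapsed")
            continue
        seen[t.sequence] = t
    chem.write_peptide_fasta(
        (
            (f"pep_{i:04d}", t.sequence, t.class_label)
            for i, t in enumerate(seen.values(), start=1)
        ),
        path,
    )


_CSV_HEADER = ["Compound", "m/z", "z", "t start (min)", "t stop (min)"]


def write_inclusion_csv(sil: ScheduledInclusionList, path: str | Path) -> None:
    """Vendor-style inclusion CSV; m/z at 5 decimals (lossless round-trip there)."""
    if not sil.entries:
        warnings.warn(f"writing header-only inclusion CSV to {path}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for e in sil.entries:
            writer.writerow(
                [e.compound_id, f"{e.mz:.5f}", e.z, f"{e.t_start:g}", f"{e.t_stop:g}"]
            )


def read_inclusion_csv(
    path: str | Path, gradient_min: float = 125.0
) -> ScheduledInclusionList:
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_HEADER:
        raise ValueError(f"unexpected inclusion CSV header in {path}")
    entries = []
    for _, row in df.iterrows():
        compound = str(row["Compound"])
        seq_part, _, _ = compound.partition("/")
        seq = seq_part.split("[")[0]
        mods: list[tuple[int, float]] = []
        rest = seq_part[len(seq):]
        while rest.startswith("["):
            body, _, rest = rest[1:].partition("]")
            pos, _, delta = body.partition(":")
            mods.append((int(pos), float(delta)))
        entries.append(
            InclusionEntry(
                sequence=seq,
                mods=tuple(mods),
                mz=float(row["m/z"]),
                z=int(row["z"]),
                t_start=float(row["t start (min)"]),
                t_stop=float(row["t stop (min)"]),
            )
        )
    return ScheduledInclusionList(entries, gradient_min)
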