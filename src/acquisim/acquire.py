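"""The cycle-budgeted acquisition engine: DDA, inclusion-list DDA (ilDDA), and
real-time-search-gated targeted DDA ("rtsdda").

Acquisition runs on a fixed 3-s cycle grid. Each cycle spends its budget in
priority order: the MS1 survey scan, the targeted branch (inclusion-list
matches; in rtsdda a scouting sMS2 whose real-time search result gates a
high-sensitivity hMS2, in ilDDA an hMS2 directly), then TopN discovery dMS2
scans with dynamic exclusion and a minimum-intensity gate. Targeted scans are
deliberately exempt from dynamic exclusion and the intensity gate. Per-cycle
per-precursor sampling caps are 3 for rtsdda (sMS2 + hMS2 + dMS2), 2 for
ilDDA (hMS2 + dMS2) and 1 for DDA.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem, scoring, simulate
from ._seeds import derive_seed
from .scoring import PSMScore, PeakList, RTSFilterConfig
from .simulate import MS1Feature, SampleMixture, ScanParams, SignalModel
from .targets import InclusionEntry, ScheduledInclusionList

__all__ = [
    "METHODS",
    "MethodConfig",
    "ScanRecord",
    "RTSEvent",
    "ScanLog",
    "default_scan_params",
    "run_acquisition",
    "rts_evaluate",
    "ExclusionState",
    "cycle_budget_report",
    "write_scanlog",
    "read_scanlog",
]

METHODS = ("dda", "ildda", "rtsdda")
_DEFAULT_CAPS = {"dda": 1, "ildda": 2, "rtsdda": 3}


def default_scan_params() -> dict[str, ScanParams]:
    """Default per-scan-type parameters.

    hMS2 runs 5x longer than sMS2 with a 5x injection time and a raised AGC
    target, which is what buys its sensitivity. Durations and targets are
    calibration constants of the simulator, all configurable.
    """
    return {
        "MS1": ScanParams("MS1", duration_ms=110.0, max_inject_ms=50.0, agc_target=1e6),
        "sMS2": ScanParams("sMS2", duration_ms=30.0, max_inject_ms=20.0,
                           agc_target=1e4, isolation_width=1.2),
        "hMS2": ScanParams("hMS2", duration_ms=150.0, max_inject_ms=100.0,
                           agc_target=5e5, isolation_width=1.2,
                           stepped_ce="27/30/33"),
        "dMS2": ScanParams("dMS2", duration_ms=40.0, max_inject_ms=25.0,
                           agc_target=3e4, isolation_width=3.2),
    }


@dataclass
class MethodConfig:
    method: str
    cycle_ms: float = 3000.0
    scan_params: dict[str, ScanParams] = field(default_factory=default_scan_params)
    dda_isolation_width: float = 3.2  # Th; 1.2 for the narrow-window variant
    min_precursor_intensity: float = 40.0  # flux units; discovery branch only
    dynamic_exclusion_s: float = 20.0
    dynamic_exclusion_tol_ppm: float = 10.0
    inclusion_match_tol_ppm: float = 10.0
    top_n: int = 10
    rts: RTSFilterConfig = field(default_factory=RTSFilterConfig)
    max_scans_per_precursor: int | None = None  # per cycle; None = method default

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.cycle_ms <= self.scan_params["MS1"].duration_ms:
            raise ValueError("cycle_ms must exceed the MS1 scan duration")
        if self.max_scans_per_precursor is None:
            self.max_scans_per_precursor = _DEFAULT_CAPS[self.method]
        if self.max_scans_per_precursor < 1:
            raise ValueError("per-precursor scan cap must be >= 1")
        hms2 = self.scan_params["hMS2"]
        sms2 = self.scan_params["sMS2"]
        if hms2.duration_ms > 5.0 * sms2.duration_ms:
            raise ValueError("hMS2 duration must be <= 5x the sMS2 duration")


@dataclass
class ScanRecord:
    scan_id: int
    cycle_index: int
    scan_type: str  # MS1 | sMS2 | hMS2 | dMS2
    start_ms: float
    duration_ms: float
    precursor_mz: float | None = None
    precursor_z: int | None = None
    isolation_lo: float | None = None
    isolation_hi: float | None = None
    peaks: PeakList | None = None
    features: list[MS1Feature] | None = None  # MS1 scans only
    provenance: str = ""  # triggering inclusion compound_id, or "topN"


@dataclass
class RTSEvent:
    event_id: int
    sms2_scan_id: int
    entry_compound_id: str
    entry_sequence: str
    best_candidate: str | None  # compound id of the best-scoring RTS candidate
    score: PSMScore | None
    hit: bool
    hms2_scan_id: int | None = None
    note: str = ""


@dataclass
class ScanLog:
    method: str
    config: MethodConfig
    gradient_min: float
    seed: int
    scans: list[ScanRecord] = field(default_factory=list)
    events: list[RTSEvent] = field(default_factory=list)

    def ms1_features_by_cycle(self) -> dict[int, list[MS1Feature]]:
        return {
            s.cycle_index: s.features or []
            for s in self.scans
            if s.scan_type == "MS1"
        }

    def ms2_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.scan_type != "MS1"]

    def scan_by_id(self) -> dict[int, ScanRecord]:
        return {s.scan_id: s for s in self.scans}


class ExclusionState:
    """Dynamic exclusion: m/z values banned from discovery TopN for a while.

    Only discovery (dMS2) scans write to or read from this state. Matching and
    the expiry are both closed-interval: a precursor fragmented at t with
    duration d is ineligible for t' in [t, t + d].
    """

    def __init__(self, duration_s: float, tol_ppm: float) -> None:
        self.duration_s = duration_s
        self.tol_ppm = tol_ppm
        self._entries: list[tuple[float, float]] = []  # (mz, expiry_s)

    def exclude(self, mz: float, t_s: float) -> None:
        self._entries.append((mz, t_s + self.duration_s))

    def prune(self, t_s: float) -> None:
        self._entries = [(mz, exp) for mz, exp in self._entries if exp >= t_s]

    def is_excluded(self, mz: float, t_s: float) -> bool:
        for emz, expiry in self._entries:
            if t_s <= expiry and abs(mz - emz) / emz * 1e6 <= self.tol_ppm:
                return True
        return False


@dataclass(frozen=True)
class _RTSCandidate:
    peptidoform: chem.Peptidoform
    mz: float


def _build_rts_db(sil: ScheduledInclusionList) -> list[_RTSCandidate]:
    seen: set[str] = set()
    db: list[_RTSCandidate] = []
    for e in sil.entries:
        pf = chem.Peptidoform(e.sequence, e.mods, e.z)
        if pf.compound_id in seen:
            continue
        seen.add(pf.compound_id)
        db.append(_RTSCandidate(pf, e.mz))
    db.sort(key=lambda c: (c.mz, c.peptidoform.compound_id))
    return db


def rts_evaluate(
    sms2: ScanRecord,
    rts_db: Sequence[_RTSCandidate],
    cfg: RTSFilterConfig,
    event_id: int = 0,
    entry: InclusionEntry | None = None,
) -> RTSEvent:
    """Score an sMS2 scan against the real-time search space and apply the filter.

    Candidates are all target peptidoforms whose precursor m/z lies inside the
    scan's isolation window. The best cross-correlation defines the match; dCn
    is computed over the sorted candidate scores and the ppm deviation against
    the best candidate's theoretical m/z.
    """
    if sms2.scan_type != "sMS2" or sms2.precursor_mz is None:
        raise ValueError("rts_evaluate needs an sMS2 record with a precursor")
    base = RTSEvent(
        event_id=event_id,
        sms2_scan_id=sms2.scan_id,
        entry_compound_id=entry.compound_id if entry else "",
        entry_sequence=entry.sequence if entry else "",
        best_candidate=None,
        score=None,
        hit=False,
    )
    candidates = [
        c for c in rts_db if sms2.isolation_lo <= c.mz <= sms2.isolation_hi
    ]
    if not candidates or sms2.peaks is None or len(sms2.peaks) == 0:
        return base
    pre = scoring.xcorr_preprocess(scoring.bin_spectrum(sms2.peaks))
    xcorrs = [scoring.xcorr(c.peptidoform, pre) for c in candidates]
    best_i = max(range(len(candidates)), key=lambda i: (xcorrs[i], -candidates[i].mz))
    best = candidates[best_i]
    score = PSMScore(
        xcorr=xcorrs[best_i],
        dcn=scoring.delta_cn(xcorrs),
        delta_ppm=scoring.delta_ppm(sms2.precursor_mz, best.mz),
        charge=sms2.precursor_z,
    )
    base.best_candidate = best.peptidoform.compound_id
    base.score = score
    base.hit = scoring.rtsf_pass(score, cfg)
    return base


def _match_inclusion(
    features: Sequence[MS1Feature],
    active: Sequence[InclusionEntry],
    tol_ppm: float,
) -> list[tuple[MS1Feature, InclusionEntry]]:
    """Pair MS1 features with active inclusion entries (same z, |ppm| <= tol).

    A feature matching several entries keeps the closest one. Output ordered
    by intensity descending, ties by m/z ascending.
    """
    matched: list[tuple[MS1Feature, InclusionEntry]] = []
    for f in features:
        best: tuple[float, InclusionEntry] | None = None
        for e in active:
            if e.z != f.z:
                continue
            dppm = abs(f.mz - e.mz) / e.mz * 1e6
            if dppm <= tol_ppm and (best is None or dppm < best[0]):
                best = (dppm, e)
        if best is not None:
            matched.append((f, best[1]))
    matched.sort(key=lambda fe: (-fe[0].intensity, fe[0].mz))
    return matched


def run_acquisition(
    m: SampleMixture,
    sil: ScheduledInclusionList | None,
    cfg: MethodConfig,
    model: SignalModel,
    seed: int,
) -> ScanLog:
    """Simulate a full LC-MS run and return the complete scan log.

    With an empty (or None) inclusion list the targeted branch is idle, so
    ilDDA and rtsdda runs collapse to plain DDA with the same seed.
    """
    if sil is None:
        sil = ScheduledInclusionList([], model.gradient_min)
    rts_db = _build_rts_db(sil) if cfg.method == "rtsdda" else []
    log = ScanLog(cfg.method, cfg, model.gradient_min, seed)
    exclusion = ExclusionState(cfg.dynamic_exclusion_s, cfg.dynamic_exclusion_tol_ppm)
    params = cfg.scan_params
    cap = cfg.max_scans_per_precursor
    n_cycles = int(model.gradient_min * 60000.0 / cfg.cycle_ms)
    scan_id = 0
    targeted = cfg.method in ("ildda", "rtsdda")

    for cycle in range(n_cycles):
        cycle_start = cycle * cfg.cycle_ms
        t_min = cycle_start / 60000.0
        exclusion.prune(cycle_start / 1000.0)
        features = simulate.ms1_observe(m, t_min, model, seed)
        clock = params["MS1"].duration_ms
        log.scans.append(
            ScanRecord(scan_id, cycle, "MS1", cycle_start, params["MS1"].duration_ms,
                       features=features)
        )
        scan_id += 1
        counts: dict[tuple[float, int], int] = {}

        def acquire_ms2(f: MS1Feature, sp: ScanParams, iso_width: float,
                        provenance: str) -> ScanRecord:
            nonlocal scan_id, clock
            peaks = simulate.simulate_ms2(
                f.mz, iso_width, m, t_min, sp, model,
                derive_seed(seed, "scan", cycle, scan_id),
                features=features, precursor_charge=f.z,
            )
            rec = ScanRecord(
                scan_id, cycle, sp.scan_type, cycle_start + clock, sp.duration_ms,
                precursor_mz=f.mz, precursor_z=f.z,
                isolation_lo=f.mz - iso_width / 2.0,
                isolation_hi=f.mz + iso_width / 2.0,
                peaks=peaks, provenance=provenance,
            )
            log.scans.append(rec)
            scan_id += 1
            clock += sp.duration_ms
            key = (round(f.mz, 4), f.z)
            counts[key] = counts.get(key, 0) + 1
            return rec

        if targeted and sil.entries:
            active = sil.active_at(t_min)
            for f, entry in _match_inclusion(features, active, cfg.inclusion_match_tol_ppm):
                key = (round(f.mz, 4), f.z)
                if counts.get(key, 0) >= cap:
                    continue
                if cfg.method == "ildda":
                    hp = params["hMS2"]
                    if clock + hp.duration_ms > cfg.cycle_ms:
                        break
                    acquire_ms2(f, hp, hp.isolation_width, entry.compound_id)
                else:  # rtsdda: sMS2 -> real-time search filter -> hMS2
                    sp = params["sMS2"]
                    if clock + sp.duration_ms > cfg.cycle_ms:
                        break
                    sms2 = acquire_ms2(f, sp, sp.isolation_width, entry.compound_id)
                    event = rts_evaluate(sms2, rts_db, cfg.rts, len(log.events), entry)
                    if event.hit:
                        hp = params["hMS2"]
                        if (clock + hp.duration_ms <= cfg.cycle_ms
                                and counts.get(key, 0) < cap):
                            hrec = acquire_ms2(f, hp, hp.isolation_width,
                                               entry.compound_id)
                            event.hms2_scan_id = hrec.scan_id
                        else:
                            event.note = "hms2_skipped_no_budget"
                    log.events.append(event)

        # discovery branch: TopN by intensity with exclusion and intensity gate
        dp = params["dMS2"]
        n_discovery = 0
        t_s = (cycle_start + clock) / 1000.0
        for f in sorted(features, key=lambda f: (-f.intensity, f.mz)):
            if n_discovery >= cfg.top_n:
                break
            if clock + dp.duration_ms > cfg.cycle_ms:
                break
            if f.intensity < cfg.min_precursor_intensity:
                continue
            key = (round(f.mz, 4), f.z)
            if counts.get(key, 0) >= cap:
                continue
            t_s = (cycle_start + clock) / 1000.0
            if exclusion.is_excluded(f.mz, t_s):
                continue
            acquire_ms2(f, dp, cfg.dda_isolation_width, "topN")
            exclusion.exclude(f.mz, t_s)
            n_discovery += 1

    return log


def cycle_budget_report(log: ScanLog) -> pd.DataFrame:
    """Per-cycle time accounting: MS1, targeted, discovery and idle milliseconds."""
    cycle_ms = log.config.cycle_ms
    n_cycles = int(log.gradient_min * 60000.0 / cycle_ms)
    rows = []
    per_cycle: dict[int, dict[str, float]] = {
        c: {"ms1_ms": 0.0, "targeted_ms": 0.0, "discovery_ms": 0.0}
        for c in range(n_cycles)
    }
    for s in log.scans:
        slot = per_cycle[s.cycle_index]
        if s.scan_type == "MS1":
            slot["ms1_ms"] += s.duration_ms
        elif s.provenance == "topN":
            slot["discovery_ms"] += s.duration_ms
        else:
            slot["targeted_ms"] += s.duration_ms
    for c in range(n_cycles):
        slot = per_cycle[c]
        used = slot["ms1_ms"] + slot["targeted_ms"] + slot["discovery_ms"]
        rows.append(
            {"cycle": c, **slot, "idle_ms": cycle_ms - used}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scan-log persistence: JSON header + TSV scan/feature/event tables + MGF peaks.

def write_scanlog(log: ScanLog, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "method": log.method,
        "gradient_min": log.gradient_min,
        "seed": log.seed,
        "config": dataclasses.asdict(log.config),
    }
    (directory / "header.json").write_text(json.dumps(header, indent=2))

    scan_rows = []
    feat_rows = []
    spectra = []
    for s in log.scans:
        scan_rows.append(
            {
                "scan_id": s.scan_id, "cycle_index": s.cycle_index,
                "scan_type": s.scan_type, "start_ms": s.start_ms,
                "duration_ms": s.duration_ms,
                "precursor_mz": s.precursor_mz if s.precursor_mz is not None else "",
                "precursor_z": s.precursor_z if s.precursor_z is not None else "",
                "isolation_lo": s.isolation_lo if s.isolation_lo is not None else "",
                "isolation_hi": s.isolation_hi if s.isolation_hi is not None else "",
                "provenance": s.provenance,
            }
        )
        if s.features is not None:
            for f in s.features:
                feat_rows.append(
                    {"scan_id": s.scan_id, "mz": f.mz, "z": f.z,
                     "intensity": f.intensity, "sequence": f.sequence}
                )
        if s.peaks is not None and len(s.peaks):
            spectra.append((f"scan={s.scan_id}", s.peaks))
    pd.DataFrame(scan_rows).to_csv(directory / "scans.tsv", sep="\t", index=False)
    pd.DataFrame(feat_rows, columns=["scan_id", "mz", "z", "intensity", "sequence"]).to_csv(
        directory / "ms1_features.tsv", sep="\t", index=False
    )
    scoring.write_mgf(spectra, directory / "spectra.mgf")

    event_rows = [
        {
            "event_id": e.event_id, "sms2_scan_id": e.sms2_scan_id,
            "entry_compound_id": e.entry_compound_id,
            "entry_sequence": e.entry_sequence,
            "best_candidate": e.best_candidate or "",
            "xcorr": e.score.xcorr if e.score else "",
            "dcn": e.score.dcn if e.score else "",
            "delta_ppm": e.score.delta_ppm if e.score else "",
            "hit": e.hit,
            "hms2_scan_id": e.hms2_scan_id if e.hms2_scan_id is not None else "",
            "note": e.note,
        }
        for e in log.events
    ]
    pd.DataFrame(
        event_rows,
        columns=["event_id", "sms2_scan_id", "entry_compound_id", "entry_sequence",
                 "best_candidate", "xcorr", "dcn", "delta_ppm", "hit",
                 "hms2_scan_id", "note"],
    ).to_csv(directory / "rts_events.tsv", sep="\t", index=False)


def _config_from_dict(d: dict) -> MethodConfig:
    scan_params = {k: ScanParams(**v) for k, v in d["scan_params"].items()}
    rts_d = dict(d["rts"])
    rts_d["charges"] = tuple(rts_d["charges"])
    return MethodConfig(
        method=d["method"], cycle_ms=d["cycle_ms"], scan_params=scan_params,
        dda_isolation_width=d["dda_isolation_width"],
        min_precursor_intensity=d["min_precursor_intensity"],
        dynamic_exclusion_s=d["dynamic_exclusion_s"],
        dynamic_exclusion_tol_ppm=d["dynamic_exclusion_tol_ppm"],
        inclusion_match_tol_ppm=d["inclusion_match_tol_ppm"],
        top_n=d["top_n"], rts=RTSFilterConfig(**rts_d),
        max_scans_per_precursor=d["max_scans_per_precursor"],
    )


def read_scanlog(directory: str | Path) -> ScanLog:
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    cfg = _config_from_dict(header["config"])
    log = ScanLog(header["method"], cfg, header["gradient_min"], header["seed"])

    feats = pd.read_csv(directory / "ms1_features.tsv", sep="\t", float_precision="round_trip")
    feats_by_scan: dict[int, list[MS1Feature]] = {}
    for r in feats.itertuples():
        feats_by_scan.setdefault(int(r.scan_id), []).append(
            MS1Feature(float(r.mz), int(r.z), float(r.intensity), str(r.sequence))
        )
    peaks_by_scan = {
        int(title.split("=")[1]): pl
        for title, pl in scoring.read_mgf(directory / "spectra.mgf")
    }
    scans = pd.read_csv(directory / "scans.tsv", sep="\t", float_precision="round_trip")
    for r in scans.itertuples():
        sid = int(r.scan_id)
        rec = ScanRecord(
            scan_id=sid, cycle_index=int(r.cycle_index), scan_type=str(r.scan_type),
            start_ms=float(r.start_ms), duration_ms=float(r.duration_ms),
            precursor_mz=None if pd.isna(r.precursor_mz) else float(r.precursor_mz),
            precursor_z=None if pd.isna(r.precursor_z) else int(r.precursor_z),
            isolation_lo=None if pd.isna(r.isolation_lo) else float(r.isolation_lo),
            isolation_hi=None if pd.isna(r.isolation_hi) else float(r.isolation_hi),
            peaks=peaks_by_scan.get(sid),
            features=feats_by_scan.get(sid) if str(r.scan_type) == "MS1" else None,
            provenance="" if pd.isna(r.provenance) else str(r.provenance),
        )
        if rec.peaks is not None and rec.precursor_z is not None:
            rec.peaks.precursor_charge = rec.precursor_z
        log.scans.append(rec)

    events = pd.read_csv(directory / "rts_events.tsv", sep="\t")
    for r in events.itertuples():
        score = None
        if not pd.isna(r.xcorr):
            score = PSMScore(
                xcorr=float(r.xcorr), dcn=float(r.dcn), delta_ppm=float(r.delta_ppm),
                charge=None,
            )
        log.events.append(
            RTSEvent(
                event_id=int(r.event_id), sms2_scan_id=int(r.sms2_scan_id),
                entry_compound_id=str(r.entry_compound_id),
                entry_sequence=str(r.entry_sequence),
                best_candidate=None if pd.isna(r.best_candidate) else str(r.best_candidate),
                score=score, hit=bool(r.hit),
                hms2_scan_id=None if pd.isna(r.hms2_scan_id) else int(r.hms2_scan_id),
                note="" if pd.isna(r.note) else str(r.note),
            )
        )
    return log
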