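"""Simplified offline search engine over scan logs.

Non-enzymatic search of every MS2 scan against a peptide database with
reversed-sequence decoys. In chimeric mode, candidates are additionally drawn
around every MS1 feature co-isolated in the scan's window, so one wide-window
spectrum can yield identifications whose precursor mass deviates from the
isolated mass (co-isolated PSMs). Hyperscore ranks PSMs for target-decoy FDR;
cross-correlation and spectral angle are reported as auxiliary scores.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chem, scoring
from .acquire import ScanLog, ScanRecord
from .chem import Peptidoform
from .scoring import PSMScore, PeakList

__all__ = [
    "SearchConfig",
    "DBEntry",
    "PSM",
    "TID",
    "generate_decoys",
    "build_search_db",
    "search_scan",
    "search_scanlog",
    "fdr_filter",
    "peptide_fdr",
    "classify_tids",
    "mass_diff_analysis",
    "psm_table",
]


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 10.0  # around the isolated (or co-isolated) mass
    fragment_tol_ppm: float = 20.0
    varmods: tuple[tuple[str, float], ...] = (("M", chem.MET_OXIDATION),)
    max_mods: int = 3
    charges: tuple[int, ...] = (1, 2, 3)
    fdr_level: float = 0.01
    chimeric: bool = True
    #: |ppm| beyond which a candidate precursor counts as co-isolated
    isolated_tol_ppm: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")


@dataclass(frozen=True)
class DBEntry:
    peptidoform: Peptidoform
    mz: float
    is_decoy: bool


@dataclass
class PSM:
    scan_id: int
    scan_type: str
    peptidoform: Peptidoform
    score: PSMScore
    is_decoy: bool
    isolation_status: str  # isolated | co_isolated
    group_mz: float  # precursor mass hypothesis the candidate was matched to
    q_value: float = math.nan

    @property
    def sequence(self) -> str:
        return self.peptidoform.sequence


@dataclass(frozen=True)
class TID:
    """A target identification: an RTS event whose peptide is PSMed offline."""

    rts_event_id: int
    sequence: str
    supporting_scan_types: frozenset[str]  # subset of {sMS2, hMS2}


def generate_decoys(sequences: Iterable[str]) -> list[str]:
    """Full-sequence reversal; decoys colliding with any target are dropped."""
    targets = set(sequences)
    decoys = []
    seen: set[str] = set()
    for seq in sorted(targets):
        rev = seq[::-1]
        if rev in targets or rev in seen:
            continue
        seen.add(rev)
        decoys.append(rev)
    return decoys


class _Index:
    """Per-charge sorted m/z index over database entries."""

    def __init__(self, entries: Sequence[DBEntry]):
        self.by_charge: dict[int, tuple[list[float], list[DBEntry]]] = {}
        groups: dict[int, list[DBEntry]] = {}
        for e in entries:
            groups.setdefault(e.peptidoform.charge, []).append(e)
        for z, group in groups.items():
            group.sort(key=lambda e: (e.mz, e.peptidoform.compound_id))
            self.by_charge[z] = ([e.mz for e in group], group)

    def query(self, mz: float, z: int, tol_ppm: float) -> list[DBEntry]:
        if z not in self.by_charge:
            return []
        mzs, group = self.by_charge[z]
        tol = mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(mzs, mz - tol)
        hi = bisect.bisect_right(mzs, mz + tol)
        return group[lo:hi]


def build_search_db(
    sequences: Iterable[str],
    cfg: SearchConfig,
    with_decoys: bool = True,
) -> list[DBEntry]:
    """Enumerate all peptidoform/charge candidates (targets, then decoys)."""
    varmods = dict(cfg.varmods)
    seqs = sorted(set(sequences))
    entries: list[DBEntry] = []
    for seq, is_decoy in itertools.chain(
        ((s, False) for s in seqs),
        ((d, True) for d in (generate_decoys(seqs) if with_decoys else [])),
    ):
        for prec in chem.enumerate_precursors(seq, varmods, cfg.max_mods, cfg.charges):
            entries.append(DBEntry(prec.peptidoform, prec.mz, is_decoy))
    return entries


def _score_candidate(
    entry: DBEntry,
    pl: PeakList,
    preprocessed: scoring.BinnedSpectrum,
    group_mz: float,
    cfg: SearchConfig,
) -> PSMScore:
    pf = entry.peptidoform
    frags = chem.fragment_mzs(pf, scoring.fragment_charge_range(pf.charge))
    res = scoring.match_fragments(pl, frags, cfg.fragment_tol_ppm)
    obs = np.zeros(len(frags))
    for i, j in enumerate(res.peak_index):
        if j >= 0:
            obs[i] = math.sqrt(float(pl.intensity[j]))
    norm = np.linalg.norm(obs) * math.sqrt(len(frags))
    if norm > 0:
        cos = float(np.clip(obs.sum() / norm, -1.0, 1.0))
        angle = 1.0 - (2.0 / math.pi) * math.acos(cos)
    else:
        angle = 0.0
    return PSMScore(
        xcorr=scoring.xcorr(pf, preprocessed),
        delta_ppm=scoring.delta_ppm(group_mz, entry.mz),
        hyperscore=scoring.hyperscore(
            res.n_matched_b, res.n_matched_y, res.sum_I_b, res.sum_I_y
        ),
        spectral_angle=angle,
        n_matched_b=res.n_matched_b,
        n_matched_y=res.n_matched_y,
        sum_I_b=res.sum_I_b,
        sum_I_y=res.sum_I_y,
        charge=pf.charge,
    )


def search_scan(
    scan: ScanRecord,
    index: _Index,
    features: Sequence,  # MS1 features of the scan's cycle
    cfg: SearchConfig,
) -> list[PSM]:
    """Candidate PSMs for one MS2 scan: best target and best decoy per group.

    Group 0 is the isolated precursor mass; with chimeric search enabled, every
    MS1 feature inside the isolation window whose m/z deviates from the
    isolated mass by more than the isolated-match tolerance opens a co-isolated
    group.
    """
    if scan.scan_type == "MS1" or scan.precursor_mz is None:
        raise ValueError("search_scan needs an MS2 record")
    if scan.peaks is None or len(scan.peaks) == 0:
        return []
    groups: list[tuple[float, int, str]] = [
        (scan.precursor_mz, scan.precursor_z, "isolated")
    ]
    if cfg.chimeric:
        seen = {(round(scan.precursor_mz, 4), scan.precursor_z)}
        for f in features:
            if not scan.isolation_lo <= f.mz <= scan.isolation_hi:
                continue
            dppm = abs(f.mz - scan.precursor_mz) / scan.precursor_mz * 1e6
            if dppm <= cfg.isolated_tol_ppm:
                continue
            key = (round(f.mz, 4), f.z)
            if key in seen:
                continue
            seen.add(key)
            groups.append((f.mz, f.z, "co_isolated"))

    preprocessed: scoring.BinnedSpectrum | None = None
    psms: list[PSM] = []
    for gmz, gz, status in groups:
        candidates = index.query(gmz, gz, cfg.precursor_tol_ppm)
        if not candidates:
            continue
        if preprocessed is None:
            preprocessed = scoring.xcorr_preprocess(scoring.bin_spectrum(scan.peaks))
        best: dict[bool, PSM] = {}
        for entry in candidates:
            s = _score_candidate(entry, scan.peaks, preprocessed, gmz, cfg)
            psm = PSM(
                scan_id=scan.scan_id, scan_type=scan.scan_type,
                peptidoform=entry.peptidoform, score=s, is_decoy=entry.is_decoy,
                isolation_status=status, group_mz=gmz,
            )
            cur = best.get(entry.is_decoy)
            if cur is None or (
                (s.hyperscore, s.xcorr, psm.peptidoform.compound_id)
                > (cur.score.hyperscore, cur.score.xcorr, cur.peptidoform.compound_id)
            ):
                best[entry.is_decoy] = psm
        psms.extend(best.values())
    return psms


def search_scanlog(
    log: ScanLog, db: Sequence[DBEntry], cfg: SearchConfig
) -> list[PSM]:
    """Search every MS2 scan of a log against the database."""
    index = _Index(db)
    feats = log.ms1_features_by_cycle()
    psms: list[PSM] = []
    for scan in log.ms2_scans():
        psms.extend(search_scan(scan, index, feats.get(scan.cycle_index, []), cfg))
    return psms


def fdr_filter(psms: Sequence[PSM], level: float = 0.01) -> list[PSM]:
    """Target-decoy FDR with the conservative (decoys + 1)/targets estimator.

    PSMs are sorted by hyperscore descending; q-values are the running FDR
    estimate made monotone from the bottom. Returns accepted target PSMs
    (q <= level); q-values are written onto every input PSM.
    """
    if not psms:
        return []
    order = sorted(
        psms,
        key=lambda p: (-p.score.hyperscore, p.is_decoy, p.peptidoform.compound_id),
    )
    n_decoys = 0
    n_targets = 0
    fdrs = []
    for p in order:
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append((n_decoys + 1) / max(n_targets, 1))
    q = np.minimum.accumulate(np.asarray(fdrs)[::-1])[::-1]
    for p, qv in zip(order, q):
        p.q_value = float(min(qv, 1.0))
    return [p for p in order if not p.is_decoy and p.q_value <= level]


def peptide_fdr(psms: Sequence[PSM], level: float = 0.01) -> list[PSM]:
    """Peptide-level filtering: best PSM per stripped sequence, same estimator."""
    best: dict[tuple[str, bool], PSM] = {}
    for p in psms:
        key = (p.sequence, p.is_decoy)
        cur = best.get(key)
        if cur is None or p.score.hyperscore > cur.score.hyperscore:
            best[key] = p
    return fdr_filter(list(best.values()), level)


def classify_tids(
    log: ScanLog, accepted: Sequence[PSM], target_sequences: Iterable[str]
) -> list[TID]:
    """One TID per RTS event whose peptide is PSMed on its sMS2 and/or hMS2 scan."""
    targets = set(target_sequences)
    by_scan: dict[int, set[str]] = {}
    for p in accepted:
        if not p.is_decoy:
            by_scan.setdefault(p.scan_id, set()).add(p.sequence)
    tids: list[TID] = []
    for e in log.events:
        seq = e.entry_sequence
        if seq not in targets:
            continue
        support = set()
        if seq in by_scan.get(e.sms2_scan_id, ()):
            support.add("sMS2")
        if e.hms2_scan_id is not None and seq in by_scan.get(e.hms2_scan_id, ()):
            support.add("hMS2")
        if support:
            tids.append(TID(e.event_id, seq, frozenset(support)))
    return tids


def mass_diff_analysis(accepted: Sequence[PSM]) -> tuple[pd.DataFrame, float]:
    """Neutral mass differences of co-identified PSM pairs within one scan.

    For every scan with >= 2 accepted same-charge PSMs, reports the absolute
    neutral mass difference, its nearest integer multiple of 1 Da, and the
    residual. Returns the residual table (same-charge pairs) and the fraction
    of all within-scan pairs that share a charge. Because residue-mass
    fractional parts span < 0.1 Da, residuals concentrate near 0.
    """
    by_scan: dict[int, list[PSM]] = {}
    for p in accepted:
        if not p.is_decoy:
            by_scan.setdefault(p.scan_id, []).append(p)
    rows = []
    n_pairs = 0
    n_same = 0
    for scan_id in sorted(by_scan):
        group = by_scan[scan_id]
        if len(group) < 2:
            continue
        for a, b in itertools.combinations(group, 2):
            n_pairs += 1
            if a.peptidoform.charge != b.peptidoform.charge:
                continue
            n_same += 1
            delta = abs(
                chem.monoisotopic_mass(a.peptidoform)
                - chem.monoisotopic_mass(b.peptidoform)
            )
            nearest = round(delta)
            rows.append(
                {
                    "scan_id": scan_id,
                    "sequence_a": a.sequence,
                    "sequence_b": b.sequence,
                    "delta_da": delta,
                    "nearest_int_da": nearest,
                    "residual_da": abs(delta - nearest),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["scan_id", "sequence_a", "sequence_b",
                 "delta_da", "nearest_int_da", "residual_da"],
    )
    frac = n_same / n_pairs if n_pairs else 0.0
    return df, frac


def tid_table(tids: Sequence[TID]) -> pd.DataFrame:
    """Flat TID table for TSV export."""
    return pd.DataFrame(
        [
            {
                "rts_event_id": t.rts_event_id,
                "sequence": t.sequence,
                "supported_by_sms2": "sMS2" in t.supporting_scan_types,
                "supported_by_hms2": "hMS2" in t.supporting_scan_types,
            }
            for t in tids
        ],
        columns=["rts_event_id", "sequence",
                 "supported_by_sms2", "supported_by_hms2"],
    )


def psm_table(psms: Sequence[PSM]) -> pd.DataFrame:
    """Flat PSM table for TSV export."""
    return pd.DataFrame(
        [
            {
                "scan_id": p.scan_id,
                "scan_type": p.scan_type,
                "sequence": p.sequence,
                "mods": p.peptidoform.mod_signature,
                "z": p.peptidoform.charge,
                "hyperscore": p.score.hyperscore,
                "xcorr": p.score.xcorr,
                "spectral_angle": p.score.spectral_angle,
                "delta_ppm": p.score.delta_ppm,
                "n_matched_b": p.score.n_matched_b,
                "n_matched_y": p.score.n_matched_y,
                "is_decoy": p.is_decoy,
                "isolation_status": p.isolation_status,
                "q_value": p.q_value,
            }
            for p in psms
        ],
        columns=["scan_id", "scan_type", "sequence", "mods", "z", "hyperscore",
                 "xcorr", "spectral_angle", "delta_ppm", "n_matched_b",
                 "n_matched_y", "is_decoy", "isolation_status", "q_value"],
    )
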