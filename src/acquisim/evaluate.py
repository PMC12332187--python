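"""Benchmark metrics and the end-to-end dilution-series benchmark.

Target sensitivity (unique target sequences and target PSM counts), global
depth (unique stripped sequences), overlap coefficients, the sensitivity/depth
trade-off ratio, the real-time-search funnel (events -> hits -> TIDs),
replicate reproducibility cross-tabulations, and MS1-based quantification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import acquire, identify, simulate, targets as targets_mod
from ._seeds import child_rng, derive_seed
from .acquire import MethodConfig, ScanLog, run_acquisition
from .identify import PSM, TID, SearchConfig, build_search_db, classify_tids
from .simulate import SampleMixture, SignalModel
from .targets import ScheduledInclusionList, TargetPeptide

__all__ = [
    "RunSummary",
    "ComparisonReport",
    "BenchmarkConfig",
    "overlap_coefficient",
    "jaccard_index",
    "tradeoff_ratio",
    "rts_funnel",
    "reproducibility_matrix",
    "quantify",
    "peptide_quant",
    "replicate_correlation",
    "summarize_run",
    "benchmark_dilution",
]


def overlap_coefficient(A: Iterable, B: Iterable) -> float:
    """Szymkiewicz-Simpson overlap, |A n B| / min(|A|, |B|)."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap coefficient is undefined for an empty set")
    return len(A & B) / min(len(A), len(B))


def jaccard_index(A: Iterable, B: Iterable) -> float:
    A, B = set(A), set(B)
    if not A | B:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(A & B) / len(A | B)


def tradeoff_ratio(
    depth_method: float, depth_dda: float,
    targets_method: float, targets_dda: float,
) -> float:
    """Percent target gain per percent of global depth lost, both versus DDA.

    Returns 0 when target counts are unchanged and ``inf`` when there is no
    depth loss to pay for a gain.
    """
    if depth_dda <= 0 or targets_dda <= 0:
        raise ValueError("DDA depth and target counts must be positive")
    gain_pct = (targets_method - targets_dda) / targets_dda * 100.0
    loss_pct = (depth_dda - depth_method) / depth_dda * 100.0
    if gain_pct == 0:
        return 0.0
    if loss_pct <= 0:
        return math.inf
    return gain_pct / loss_pct


@dataclass
class FunnelCounts:
    n_events: int
    n_hits: int
    n_tids: int
    hit_rate: float
    tid_rate: float
    flagged: bool = False  # a zero denominator was encountered


def rts_funnel(log: ScanLog, tids: Sequence[TID]) -> FunnelCounts:
    """Counts and rates along events -> hits -> TIDs; TIDs <= hits <= events."""
    n_events = len(log.events)
    n_hits = sum(1 for e in log.events if e.hit)
    n_tids = len(tids)
    if n_tids > n_hits:
        raise ValueError(f"funnel violation: {n_tids} TIDs > {n_hits} hits")
    flagged = n_events == 0 or n_hits == 0
    return FunnelCounts(
        n_events=n_events, n_hits=n_hits, n_tids=n_tids,
        hit_rate=n_hits / n_events if n_events else 0.0,
        tid_rate=n_tids / n_hits if n_hits else 0.0,
        flagged=flagged,
    )


def reproducibility_matrix(
    sets_a: Sequence[set[str]],
    sets_b: Sequence[set[str]],
    universe: Iterable[str],
    n_reps: int = 3,
) -> np.ndarray:
    """Cross-tabulation: entry (i, j) counts targets found in exactly i replicates
    of method A and j replicates of method B; the matrix partitions the universe.
    """
    if len(sets_a) != n_reps or len(sets_b) != n_reps:
        raise ValueError(f"expected {n_reps} replicate sets per method")
    M = np.zeros((n_reps + 1, n_reps + 1), dtype=int)
    for t in set(universe):
        i = sum(t in s for s in sets_a)
        j = sum(t in s for s in sets_b)
        M[i, j] += 1
    return M


def quantify(accepted: Sequence[PSM], log: ScanLog, tol_ppm: float = 10.0) -> pd.DataFrame:
    """MS1-based quantification of accepted PSMs.

    Precursor intensity is the maximum MS1 feature intensity over that
    precursor's PSMs (feature matched in the PSM's cycle by charge and ppm);
    PSMs with no matching feature contribute 0 and are flagged.
    """
    feats = log.ms1_features_by_cycle()
    scan_cycle = {s.scan_id: s.cycle_index for s in log.scans}
    rows: dict[tuple[str, str, int], dict] = {}
    for p in accepted:
        if p.is_decoy:
            continue
        cycle = scan_cycle[p.scan_id]
        best = 0.0
        found = False
        for f in feats.get(cycle, []):
            if f.z != p.peptidoform.charge:
                continue
            if abs(f.mz - p.group_mz) / p.group_mz * 1e6 <= tol_ppm:
                best = max(best, f.intensity)
                found = True
        key = (p.sequence, p.peptidoform.mod_signature, p.peptidoform.charge)
        row = rows.setdefault(
            key,
            {"sequence": key[0], "mods": key[1], "z": key[2],
             "intensity": 0.0, "n_psms": 0, "unmatched_flag": False},
        )
        row["intensity"] = max(row["intensity"], best)
        row["n_psms"] += 1
        row["unmatched_flag"] = row["unmatched_flag"] or not found
    return pd.DataFrame(
        list(rows.values()),
        columns=["sequence", "mods", "z", "intensity", "n_psms", "unmatched_flag"],
    )


def peptide_quant(precursor_table: pd.DataFrame) -> pd.DataFrame:
    """Peptide intensity = sum of that peptide's precursor intensities."""
    if precursor_table.empty:
        return pd.DataFrame(columns=["sequence", "intensity"])
    return (
        precursor_table.groupby("sequence", as_index=False)["intensity"].sum()
    )


def replicate_correlation(
    quant_tables: Sequence[pd.DataFrame],
    target_sequences: Iterable[str],
    min_shared: int = 3,
) -> pd.DataFrame:
    """R^2 of log10 precursor intensities between replicate pairs.

    Reported separately for target and non-target precursors; pairs with fewer
    than ``min_shared`` shared quantified precursors are flagged undefined.
    """
    if len(quant_tables) < 2:
        raise ValueError("need at least two replicates")
    targets = set(target_sequences)
    rows = []
    for (i, qa), (j, qb) in itertools.combinations(enumerate(quant_tables), 2):
        for label in ("target", "non_target"):
            a = qa[(qa["intensity"] > 0)]
            b = qb[(qb["intensity"] > 0)]
            mask_a = a["sequence"].isin(targets) if label == "target" else ~a["sequence"].isin(targets)
            mask_b = b["sequence"].isin(targets) if label == "target" else ~b["sequence"].isin(targets)
            a_i = a[mask_a].set_index(["sequence", "mods", "z"])["intensity"]
            b_i = b[mask_b].set_index(["sequence", "mods", "z"])["intensity"]
            shared = a_i.index.intersection(b_i.index)
            if len(shared) < min_shared:
                rows.append({"rep_a": i, "rep_b": j, "population": label,
                             "n_shared": len(shared), "r2": math.nan, "flagged": True})
                continue
            x = np.log10(a_i.loc[shared].to_numpy(dtype=float))
            y = np.log10(b_i.loc[shared].to_numpy(dtype=float))
            r = np.corrcoef(x, y)[0, 1]
            rows.append({"rep_a": i, "rep_b": j, "population": label,
                         "n_shared": len(shared), "r2": float(r * r),
                         "flagged": False})
    return pd.DataFrame(rows)


@dataclass
class RunSummary:
    method: str
    replicate: int
    ratio: float
    depth: int  # unique stripped sequences among accepted PSMs
    target_sequences: set[str]
    target_psm_counts: dict[str, int]
    funnel: FunnelCounts
    quant: pd.DataFrame

    @property
    def n_targets(self) -> int:
        return len(self.target_sequences)

    @property
    def n_target_psms(self) -> int:
        return sum(self.target_psm_counts.values())


def summarize_run(
    method: str,
    replicate: int,
    ratio: float,
    log: ScanLog,
    accepted_psms: Sequence[PSM],
    target_sequences: Iterable[str],
    tids: Sequence[TID],
) -> RunSummary:
    targets = set(target_sequences)
    depth_seqs = {p.sequence for p in accepted_psms}
    found_targets = depth_seqs & targets
    counts: dict[str, int] = {}
    for p in accepted_psms:
        if p.sequence in targets:
            counts[p.sequence] = counts.get(p.sequence, 0) + 1
    return RunSummary(
        method=method, replicate=replicate, ratio=ratio,
        depth=len(depth_seqs), target_sequences=found_targets,
        target_psm_counts=counts, funnel=rts_funnel(log, tids),
        quant=quantify(accepted_psms, log),
    )


@dataclass
class BenchmarkConfig:
    """Study conditions for the dilution-series benchmark.

    Defaults are scaled-down conditions suitable for a workstation: a short
    gradient with proportionally narrowed RT scheduling windows; the method
    parameters themselves (cycle time, thresholds, isolation widths, caps)
    keep their full-scale defaults.
    """

    n_background: int = 250
    n_spike: int = 40
    ratios: tuple[float, ...] = (1 / 16, 1 / 1024, 0.0)
    methods: tuple[str, ...] = ("dda", "ildda", "rtsdda")
    n_replicates: int = 3
    gradient_min: float = 8.0
    rt_halfwidth_min: float = 3.0
    rt_error_sd_min: float = 1.0  # error of the RT predictor stand-in
    interferents_per_target: int = 1
    interferent_tol_ppm: float = 10.0
    charges: tuple[int, ...] = (1, 2, 3)
    signal_model: SignalModel | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    fdr_level: float = 0.01

    def resolved_signal_model(self) -> SignalModel:
        if self.signal_model is not None:
            return self.signal_model
        return SignalModel(gradient_min=self.gradient_min)


@dataclass
class ComparisonReport:
    config: BenchmarkConfig
    runs: list[RunSummary]
    inclusion_list: ScheduledInclusionList
    target_sequences: set[str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "method": r.method, "replicate": r.replicate, "ratio": r.ratio,
                    "depth": r.depth, "n_targets": r.n_targets,
                    "n_target_psms": r.n_target_psms,
                    "rts_events": r.funnel.n_events, "rts_hits": r.funnel.n_hits,
                    "tids": r.funnel.n_tids,
                }
                for r in self.runs
            ]
        )

    def median_depth(self, method: str, ratio: float) -> float:
        vals = [r.depth for r in self.runs if r.method == method and r.ratio == ratio]
        return float(np.median(vals)) if vals else math.nan

    def median_targets(self, method: str, ratio: float) -> float:
        vals = [r.n_targets for r in self.runs if r.method == method and r.ratio == ratio]
        return float(np.median(vals)) if vals else math.nan

    def replicate_target_sets(self, method: str, ratio: float) -> list[set[str]]:
        return [
            r.target_sequences
            for r in sorted(
                (r for r in self.runs if r.method == method and r.ratio == ratio),
                key=lambda r: r.replicate,
            )
        ]


def _method_config(method: str, cfg: BenchmarkConfig) -> MethodConfig:
    return MethodConfig(method=method, rts=acquire.RTSFilterConfig(charges=cfg.charges))


def benchmark_dilution(cfg: BenchmarkConfig, seed: int) -> ComparisonReport:
    """Run the full pipeline: peptidomes -> dilution series (+ interferents) ->
    scheduling -> acquisition per method x replicate -> search -> summaries.

    Replicate seeds are paired across methods (same sample realization and
    scan-noise seeds), so method comparisons are matched.
    """
    model = cfg.resolved_signal_model()
    background = simulate.generate_peptidome(
        cfg.n_background, derive_seed(seed, "background"),
        gradient_min=cfg.gradient_min, source="background",
    )
    spike = simulate.generate_peptidome(
        cfg.n_spike, derive_seed(seed, "spike"),
        gradient_min=cfg.gradient_min, source="spike", target_fraction=1.0,
    )
    for p in spike:
        p.is_target = True

    rng = child_rng(seed, "rt_prediction")
    target_list = [
        TargetPeptide(
            p.sequence, class_label="TAA",
            rt_pred=float(np.clip(
                p.rt_apex + rng.normal(0.0, cfg.rt_error_sd_min),
                0.0, cfg.gradient_min,
            )),
        )
        for p in spike
    ]
    sil = targets_mod.schedule(
        target_list, charges=cfg.charges,
        halfwidth_min=cfg.rt_halfwidth_min, gradient_min=cfg.gradient_min,
    )
    target_sequences = {t.sequence for t in target_list}

    mixtures = simulate.make_dilution_series(
        background, spike, cfg.ratios, derive_seed(seed, "series")
    )
    mixtures = [
        simulate.spike_interferents(
            mx, sil, cfg.interferents_per_target, cfg.interferent_tol_ppm,
            derive_seed(seed, "interferents"),
        )
        for mx in mixtures
    ]

    runs: list[RunSummary] = []
    for ratio_idx, mixture in enumerate(mixtures):
        db = build_search_db(
            sorted(mixture.sequences | target_sequences), cfg.search
        )
        for method in cfg.methods:
            mcfg = _method_config(method, cfg)
            for rep in range(cfg.n_replicates):
                run_seed = derive_seed(seed, "run", ratio_idx, rep)  # paired
                log = run_acquisition(mixture, sil, mcfg, model, run_seed)
                psms = identify.search_scanlog(log, db, cfg.search)
                accepted = identify.fdr_filter(psms, cfg.fdr_level)
                tids = classify_tids(log, accepted, target_sequences)
                runs.append(
                    summarize_run(
                        method, rep, mixture.ratio, log, accepted,
                        target_sequences, tids,
                    )
                )
    return ComparisonReport(cfg, runs, sil, target_sequences)
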