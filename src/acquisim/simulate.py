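"""Synthetic ground truth: peptidomes, dilution series, MS1 features and noisy
MS2 spectra under scan-parameter-dependent signal quality.

The generator stands in for the cell-line immunopeptidomes used on the real
instrument: random 8-14-mer sequences with a length mode of 9, log-normal
abundances, Gaussian elution peaks, and length-dependent charge priors.
Ion statistics follow ``min(AGC target, flux * injection time)`` with Poisson
counting noise, which is the mechanism giving high-sensitivity scans their
signal advantage over scouting and discovery scans.

Every stochastic step derives its generator from a master seed plus a stable
entity token, so end-to-end runs are bit-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from ._seeds import child_rng, derive_seed
from .chem import Peptidoform
from .scoring import PeakList, fragment_charge_range
from .targets import ScheduledInclusionList

__all__ = [
    "DEFAULT_LENGTH_PROBS",
    "DEFAULT_DILUTION_RATIOS",
    "GroundTruthPeptide",
    "SampleMixture",
    "SignalModel",
    "ScanParams",
    "MS1Feature",
    "generate_peptidome",
    "make_dilution_series",
    "ms1_observe",
    "simulate_ms2",
    "spike_interferents",
    "write_ground_truth",
    "read_ground_truth",
]

#: Length distribution over 8..14, peaked at 9 (mean ~9.6, as immunopeptidomes show).
DEFAULT_LENGTH_PROBS: dict[int, float] = {
    8: 0.16, 9: 0.46, 10: 0.16, 11: 0.10, 12: 0.06, 13: 0.04, 14: 0.02,
}

#: Spike-to-background dilution factors; 0 is the spike-free negative control.
DEFAULT_DILUTION_RATIOS: tuple[float, ...] = (1 / 16, 1 / 64, 1 / 256, 1 / 1024, 0.0)


@dataclass
class GroundTruthPeptide:
    sequence: str
    abundance: float
    rt_apex: float  # minutes
    rt_sigma: float = 0.25  # minutes
    charge_probs: tuple[float, float, float] = (0.2, 0.7, 0.1)  # z = 1, 2, 3
    source: str = "background"
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if abs(sum(self.charge_probs) - 1.0) > 1e-9:
            raise ValueError("charge_probs must sum to 1")


@dataclass
class SampleMixture:
    peptides: list[GroundTruthPeptide]
    ratio: float  # spike : background dilution factor
    seed: int

    @property
    def sequences(self) -> set[str]:
        return {p.sequence for p in self.peptides}


@dataclass
class SignalModel:
    """Calibration constants linking ground-truth abundance to detector signal.

    MS1 intensities are expressed directly in ion flux units (ions/ms entering
    the trap), so an MS2 scan over a window collects
    ``min(agc_target, sum(window flux) * max_inject_ms)`` ions.
    """

    gradient_min: float = 125.0
    ms1_noise_floor: float = 0.05  # ions/ms; weaker MS1 features are invisible
    ionization_flux: float = 2000.0  # ions/ms per abundance unit at elution apex
    ms2_chemical_noise_peaks: int = 15
    fragment_profile_concentration: float = 1.0  # Dirichlet concentration

    def __post_init__(self) -> None:
        if min(
            self.gradient_min,
            self.ms1_noise_floor,
            self.ionization_flux,
            self.fragment_profile_concentration,
        ) <= 0 or self.ms2_chemical_noise_peaks < 0:
            raise ValueError("signal-model parameters must be positive")


@dataclass(frozen=True)
class ScanParams:
    """Per-scan-type instrument parameters."""

    scan_type: str  # MS1 | dMS2 | sMS2 | hMS2
    duration_ms: float
    max_inject_ms: float = 25.0
    agc_target: float = 3.0e4
    isolation_width: float = 1.2  # Th
    stepped_ce: str | None = None  # metadata only

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("scan duration must be positive")


@dataclass(frozen=True)
class MS1Feature:
    mz: float
    z: int
    intensity: float  # ions/ms flux units
    sequence: str  # ground-truth provenance; acquisition logic never reads it


def _charge_probs_for_length(length: int) -> tuple[float, float, float]:
    # short HLA-I peptides are mostly 2+, longer ones shift toward 2+/3+
    if length <= 9:
        return (0.2, 0.7, 0.1)
    return (0.1, 0.65, 0.25)


def generate_peptidome(
    n: int,
    seed: int,
    length_probs: dict[int, float] | None = None,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.5,
    rt_sigma: float = 0.25,
    target_fraction: float = 0.0,
    gradient_min: float = 125.0,
    source: str = "background",
) -> list[GroundTruthPeptide]:
    """Draw ``n`` unique random peptides with abundances and elution apexes.

    Lengths follow ``length_probs`` (default peaked at 9 over 8-14), abundances
    are log-normal, apexes uniform over [5, gradient-5] minutes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = dict(length_probs or DEFAULT_LENGTH_PROBS)
    lengths = np.array(sorted(probs))
    pvals = np.array([probs[k] for k in lengths], dtype=float)
    pvals = pvals / pvals.sum()
    rng = np.random.default_rng(seed)
    # keep apexes away from the gradient edges (5 min margin on long gradients)
    rt_margin = min(5.0, 0.1 * gradient_min)
    alphabet = np.array(list(chem.STANDARD_RESIDUES))
    seen: set[str] = set()
    out: list[GroundTruthPeptide] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("could not generate enough unique sequences")
        L = int(rng.choice(lengths, p=pvals))
        seq = "".join(rng.choice(alphabet, size=L))
        if seq in seen:
            continue
        seen.add(seq)
        out.append(
            GroundTruthPeptide(
                sequence=seq,
                abundance=float(rng.lognormal(abundance_mu, abundance_sigma)),
                rt_apex=float(rng.uniform(rt_margin, gradient_min - rt_margin)),
                rt_sigma=rt_sigma,
                charge_probs=_charge_probs_for_length(L),
                source=source,
                is_target=bool(rng.random() < target_fraction),
            )
        )
    return out


def make_dilution_series(
    background: Sequence[GroundTruthPeptide],
    spike: Sequence[GroundTruthPeptide],
    ratios: Sequence[float] = DEFAULT_DILUTION_RATIOS,
    seed: int = 0,
) -> list[SampleMixture]:
    """Mixtures with spike abundances scaled by each ratio over a constant background.

    Ratio 0 is the spike-free negative control. Spike sequences colliding with
    the background are dropped with a warning so ground truth stays unambiguous.
    """
    bg_seqs = {p.sequence for p in background}
    clean_spike = []
    for p in spike:
        if p.sequence in bg_seqs:
            warnings.warn(f"spike sequence {p.sequence} collides with background; dropped")
            continue
        clean_spike.append(p)
    mixtures = []
    for i, ratio in enumerate(ratios):
        if ratio < 0:
            raise ValueError("dilution ratio must be non-negative")
        peptides = [replace(p) for p in background]
        if ratio > 0:
            peptides.extend(
                replace(p, abundance=p.abundance * ratio) for p in clean_spike
            )
        mixtures.append(
            SampleMixture(peptides, ratio, derive_seed(seed, "mixture", i, repr(ratio)))
        )
    return mixtures


def _sampled_charge(p: GroundTruthPeptide, seed: int) -> int:
    rng = child_rng(seed, "charge", p.sequence)
    return int(rng.choice((1, 2, 3), p=p.charge_probs))


def ms1_observe(
    m: SampleMixture, t: float, model: SignalModel, seed: int
) -> list[MS1Feature]:
    """MS1 features at minute t: Gaussian elution scaled to ion flux.

    Each peptide appears at one charge state, sampled once per (seed, peptide)
    so it is stable across the whole run. Features below the noise floor are
    omitted. Output is sorted by m/z.
    """
    if not 0 <= t <= model.gradient_min:
        raise ValueError(f"t={t} outside the gradient")
    feats: list[MS1Feature] = []
    for p in m.peptides:
        dt = t - p.rt_apex
        flux = (
            p.abundance
            * math.exp(-(dt * dt) / (2.0 * p.rt_sigma * p.rt_sigma))
            * model.ionization_flux
        )
        if flux < model.ms1_noise_floor:
            continue
        z = _sampled_charge(p, seed)
        mz = chem.precursor_mz(chem.monoisotopic_mass(p.sequence), z)
        feats.append(MS1Feature(mz, z, flux, p.sequence))
    feats.sort(key=lambda f: (f.mz, f.z))
    return feats


def _fragment_profile(m: SampleMixture, sequence: str, n_frags: int, model: SignalModel) -> np.ndarray:
    """Relative fragment intensities, drawn once per peptide and reused.

    Drawn from a symmetric Dirichlet whose concentration controls spectrum
    peakiness; reuse makes repeated scans of a precursor correlated, as on a
    real instrument.
    """
    rng = child_rng(m.seed, "profile", sequence, n_frags)
    return rng.dirichlet(np.full(n_frags, model.fragment_profile_concentration))


def simulate_ms2(
    window_center: float,
    isolation_width: float,
    m: SampleMixture,
    t: float,
    sp: ScanParams,
    model: SignalModel,
    seed: int,
    features: Sequence[MS1Feature] | None = None,
    precursor_charge: int = 2,
) -> PeakList:
    """A noisy MS2 spectrum of everything co-isolated in the window.

    All precursors whose m/z lies in ``[center - w/2, center + w/2]`` contribute
    b/y fragments (chimeric spectra arise naturally). The scan collects
    ``min(agc_target, window flux * max_inject_ms)`` ions on average; fragment
    counts are multinomial over the contributing per-peptide fragment profiles
    with Poisson shot noise, plus uniform chemical-noise peaks.
    """
    if isolation_width <= 0:
        raise ValueError("isolation width must be positive")
    if features is None:
        features = ms1_observe(m, t, model, seed)
    half = isolation_width / 2.0
    in_window = [f for f in features if window_center - half <= f.mz <= window_center + half]
    rng = child_rng(seed, "ms2", round(window_center, 4), round(t, 5), sp.scan_type)

    frag_mz: list[float] = []
    weights: list[float] = []
    total_flux = sum(f.intensity for f in in_window)
    for f in in_window:
        pf = Peptidoform(f.sequence, (), f.z)
        frags = chem.fragment_mzs(pf, fragment_charge_range(f.z))
        profile = _fragment_profile(m, f.sequence, len(frags), model)
        share = f.intensity / total_flux
        for frag, w in zip(frags, profile):
            frag_mz.append(frag.mz)
            weights.append(share * w)

    mzs: list[float] = []
    intensities: list[float] = []
    if weights:
        capacity = min(sp.agc_target, total_flux * sp.max_inject_ms)
        n_ions = int(rng.poisson(capacity))
        w = np.asarray(weights)
        counts = rng.multinomial(n_ions, w / w.sum())
        for mz, c in zip(frag_mz, counts):
            if c > 0:
                mzs.append(mz)
                intensities.append(float(c))
    for _ in range(model.ms2_chemical_noise_peaks):
        mzs.append(float(rng.uniform(100.0, 1700.0)))
        intensities.append(float(1 + rng.poisson(1.0)))

    # aggregate exact m/z collisions, then sort strictly increasing
    agg: dict[float, float] = {}
    for mz, inten in zip(mzs, intensities):
        agg[mz] = agg.get(mz, 0.0) + inten
    order = sorted(agg)
    return PeakList(
        np.array(order),
        np.array([agg[mz] for mz in order]),
        precursor_mz=window_center,
        precursor_charge=precursor_charge,
    )


def _isobaric_variant(sequence: str, rng: np.random.Generator) -> str:
    """A mass-preserving rearrangement: shuffle, with optional I/L swaps."""
    letters = list(sequence)
    rng.shuffle(letters)
    if rng.random() < 0.5:
        letters = ["L" if a == "I" else "I" if a == "L" else a for a in letters]
    return "".join(letters)


def spike_interferents(
    m: SampleMixture,
    sil: ScheduledInclusionList,
    per_target: int,
    tol_ppm: float = 10.0,
    seed: int = 0,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.5,
) -> SampleMixture:
    """Add isobaric non-target peptides that shadow inclusion entries.

    For each unmodified inclusion entry, ``per_target`` peptides are built by
    bounded rejection sampling over mass-preserving rearrangements of the
    entry's sequence (permutations and I/L swaps), eluting uniformly inside the
    entry's RT window at the entry's charge. These trigger the targeted branch
    but are not targets — the isobaric interference the real-time filter must
    reject.
    """
    if per_target < 0:
        raise ValueError("per_target must be >= 0")
    if per_target == 0:
        return m
    forbidden = {e.sequence for e in sil.entries} | m.sequences
    added: list[GroundTruthPeptide] = []
    target_mz = {}
    for e in sil.entries:
        if e.mods:
            continue  # a rearranged bare sequence cannot be isobaric with a mod form
        rng = child_rng(seed, "interferent", e.compound_id)
        made = 0
        for _ in range(50 * per_target):
            if made >= per_target:
                break
            cand = _isobaric_variant(e.sequence, rng)
            if cand == e.sequence or cand in forbidden:
                continue
            mz = chem.precursor_mz(chem.monoisotopic_mass(cand), e.z)
            if abs(mz - e.mz) / e.mz * 1e6 > tol_ppm:
                continue
            forbidden.add(cand)
            made += 1
            lo = max(0.0, e.t_start)
            hi = min(sil.gradient_min, e.t_stop)
            added.append(
                GroundTruthPeptide(
                    sequence=cand,
                    abundance=float(rng.lognormal(abundance_mu, abundance_sigma)),
                    rt_apex=float(rng.uniform(lo, hi)),
                    charge_probs=tuple(1.0 if z == e.z else 0.0 for z in (1, 2, 3)),
                    source="interferent",
                    is_target=False,
                )
            )
        if made < per_target:
            warnings.warn(
                f"only {made}/{per_target} interferents for {e.compound_id}"
            )
    return SampleMixture(list(m.peptides) + added, m.ratio, m.seed)


_GT_COLUMNS = [
    "sequence", "abundance", "rt_apex", "rt_sigma",
    "p_z1", "p_z2", "p_z3", "source", "is_target",
]


def write_ground_truth(m: SampleMixture, path: str | Path) -> None:
    rows = [
        {
            "sequence": p.sequence,
            "abundance": p.abundance,
            "rt_apex": p.rt_apex,
            "rt_sigma": p.rt_sigma,
            "p_z1": p.charge_probs[0],
            "p_z2": p.charge_probs[1],
            "p_z3": p.charge_probs[2],
            "source": p.source,
            "is_target": p.is_target,
        }
        for p in m.peptides
    ]
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path, ratio: float = 1.0, seed: int = 0) -> SampleMixture:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    peptides = [
        GroundTruthPeptide(
            sequence=str(r.sequence),
            abundance=float(r.abundance),
            rt_apex=float(r.rt_apex),
            rt_sigma=float(r.rt_sigma),
            charge_probs=(float(r.p_z1), float(r.p_z2), float(r.p_z3)),
            source=str(r.source),
            is_target=bool(r.is_target),
        )
        for r in df.itertuples()
    ]
    return SampleMixture(peptides, ratio, seed)
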