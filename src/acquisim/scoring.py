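"""Spectrum scoring for the real-time filter and the offline engine.

Implements the SEQUEST-style fast cross-correlation (unit binning, regional
normalization, mean-background subtraction), dCn, precursor ppm deviation,
a factorial hyperscore over matched b/y fragments, and the normalized
spectral contrast angle. The binning and theoretical-peak conventions follow
the open SEQUEST/Comet lineage; the vendor real-time implementation is
proprietary, so these are declared calibration conventions, not a claim
about instrument internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pyt_mgf

from . import chem
from .chem import FragmentIon, Peptidoform

__all__ = [
    "XCORR_BIN_WIDTH",
    "DEFAULT_MAX_MZ",
    "PeakList",
    "BinnedSpectrum",
    "PSMScore",
    "RTSFilterConfig",
    "MatchResult",
    "bin_spectrum",
    "xcorr_preprocess",
    "theoretical_binned",
    "xcorr",
    "delta_cn",
    "delta_ppm",
    "match_fragments",
    "hyperscore",
    "spectral_angle",
    "rtsf_pass",
    "fragment_charge_range",
    "read_mgf",
    "write_mgf",
]

XCORR_BIN_WIDTH = 1.0005079  # Da per bin (average peptide-mass spacing)
DEFAULT_MAX_MZ = 2000.0
_THEO_PEAK = 50.0
_THEO_FLANK = 25.0
_XCORR_DIVISOR = 1.0e4
_BACKGROUND_HALFWIDTH = 75  # bins each side; window of 151 includes tau = 0
_REGIONS = 10
_FACTORIAL_CAP = 64


@dataclass
class PeakList:
    """A centroided spectrum: sorted m/z values with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = 0.0
    precursor_charge: int = 2

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class BinnedSpectrum:
    bin_width: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned spectrum contains non-finite values")


@dataclass
class PSMScore:
    """All scores attached to one candidate peptide-spectrum match."""

    xcorr: float = 0.0
    dcn: float = 0.0
    delta_ppm: float = 0.0
    hyperscore: float = 0.0
    spectral_angle: float = 0.0
    n_matched_b: int = 0
    n_matched_y: int = 0
    sum_I_b: float = 0.0
    sum_I_y: float = 0.0
    charge: int | None = None  # precursor charge, used by the RTS filter


@dataclass(frozen=True)
class RTSFilterConfig:
    """Real-time search pass thresholds (Xcorr 0.4, dCn 0, |ppm| 5, z 1-3).

    ``max_search_ms`` is carried as instrument metadata only; the simulator
    charges no cycle time for the real-time search itself.
    """

    xcorr_min: float = 0.4
    dcn_min: float = 0.0
    ppm_max: float = 5.0
    charges: tuple[int, ...] = (1, 2, 3)
    max_search_ms: float = 40.0

    def __post_init__(self) -> None:
        if min(self.xcorr_min, self.dcn_min, self.ppm_max) < 0:
            raise ValueError("RTS thresholds must be non-negative")


def _n_bins(max_mz: float, bin_width: float) -> int:
    return int(round(max_mz / bin_width)) + 1


def bin_spectrum(
    pl: PeakList,
    bin_width: float = XCORR_BIN_WIDTH,
    max_mz: float = DEFAULT_MAX_MZ,
) -> BinnedSpectrum:
    """Square-root intensities, then drop peaks into ``round(mz/width)`` bins.

    Colliding peaks keep the maximum (sqrt-transformed) intensity; peaks above
    ``max_mz`` are discarded.
    """
    if len(pl) == 0:
        raise ValueError("cannot bin an empty peak list")
    values = np.zeros(_n_bins(max_mz, bin_width))
    idx = np.rint(pl.mz / bin_width).astype(int)
    keep = (idx >= 0) & (idx < values.size)
    np.maximum.at(values, idx[keep], np.sqrt(pl.intensity[keep]))
    return BinnedSpectrum(bin_width, values)


def xcorr_preprocess(bs: BinnedSpectrum) -> BinnedSpectrum:
    """Regional normalization then mean-background subtraction.

    The spectrum is split into 10 equal-width segments, each scaled so its
    maximum is 50 (all-zero segments untouched); then
    ``y'[i] = y[i] - (1/151) * sum_{tau=-75..+75} y[i+tau]`` with zero padding,
    which makes a single dot product equal the full offset cross-correlation.
    """
    y = bs.values.copy()
    n = y.size
    seg = -(-n // _REGIONS)  # ceil division
    for s in range(0, n, seg):
        m = y[s : s + seg].max(initial=0.0)
        if m > 0:
            y[s : s + seg] *= _THEO_PEAK / m
    window = 2 * _BACKGROUND_HALFWIDTH + 1
    background = np.convolve(y, np.full(window, 1.0 / window), mode="same")
    return BinnedSpectrum(bs.bin_width, y - background)


def fragment_charge_range(precursor_charge: int) -> int:
    """Highest fragment charge considered: z-1, floored at 1, capped at 2."""
    return max(1, min(2, precursor_charge - 1))


def theoretical_binned(
    p: Peptidoform,
    bin_width: float = XCORR_BIN_WIDTH,
    max_mz: float = DEFAULT_MAX_MZ,
    max_frag_charge: int | None = None,
) -> BinnedSpectrum:
    """Theoretical spectrum: 50 at each b/y fragment bin, 25 at the flanks.

    Collisions are combined by maximum, so a flank never overwrites a peak.
    """
    if max_frag_charge is None:
        max_frag_charge = fragment_charge_range(p.charge)
    values = np.zeros(_n_bins(max_mz, bin_width))
    for frag in chem.fragment_mzs(p, max_frag_charge):
        i = int(round(frag.mz / bin_width))
        if not 0 <= i < values.size:
            continue
        values[i] = max(values[i], _THEO_PEAK)
        for j in (i - 1, i + 1):
            if 0 <= j < values.size:
                values[j] = max(values[j], _THEO_FLANK)
    return BinnedSpectrum(bin_width, values)


def xcorr(
    p: Peptidoform,
    observed_preprocessed: BinnedSpectrum,
    max_frag_charge: int | None = None,
) -> float:
    """Fast cross-correlation: dot(theoretical, preprocessed observed) / 1e4."""
    theo = theoretical_binned(
        p,
        observed_preprocessed.bin_width,
        (observed_preprocessed.values.size - 1) * observed_preprocessed.bin_width,
        max_frag_charge,
    )
    n = min(theo.values.size, observed_preprocessed.values.size)
    return float(theo.values[:n] @ observed_preprocessed.values[:n]) / _XCORR_DIVISOR


def delta_cn(xcorrs: Sequence[float]) -> float:
    """(X1 - X2)/X1 over the two best scores; 1.0 for a lone candidate."""
    if len(xcorrs) == 0:
        raise ValueError("delta_cn needs at least one candidate score")
    ordered = sorted(xcorrs, reverse=True)
    x1 = ordered[0]
    if x1 <= 0:
        return 0.0
    if len(ordered) == 1:
        return 1.0
    return (x1 - ordered[1]) / x1


def delta_ppm(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative precursor mass deviation in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


@dataclass
class MatchResult:
    n_matched_b: int = 0
    n_matched_y: int = 0
    sum_I_b: float = 0.0
    sum_I_y: float = 0.0
    #: parallel to the fragment list: index of the matched peak or -1
    peak_index: list[int] = field(default_factory=list)


def match_fragments(
    pl: PeakList, frags: Sequence[FragmentIon], tol_ppm: float = 20.0
) -> MatchResult:
    """Match each theoretical fragment to the nearest observed peak within tol.

    The tolerance interval is closed; exact distance ties prefer the lower-m/z
    peak. One observed peak may serve several theoretical fragments whose
    windows overlap it.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    res = MatchResult()
    mzs = pl.mz
    for frag in frags:
        j = -1
        if mzs.size:
            k = int(np.searchsorted(mzs, frag.mz))
            best = None
            for cand in (k - 1, k):
                if 0 <= cand < mzs.size:
                    d = abs(mzs[cand] - frag.mz)
                    if best is None or d < best[0]:
                        best = (d, cand)
            if best is not None and best[0] <= frag.mz * tol_ppm * 1e-6:
                j = best[1]
        res.peak_index.append(j)
        if j >= 0:
            if frag.series == "b":
                res.n_matched_b += 1
                res.sum_I_b += float(pl.intensity[j])
            else:
                res.n_matched_y += 1
                res.sum_I_y += float(pl.intensity[j])
    return res


def hyperscore(n_b: int, n_y: int, sum_I_b: float, sum_I_y: float) -> float:
    """``ln(n_b! * n_y! * max(sum_I_b, 1) * max(sum_I_y, 1))``.

    Factorial arguments are capped at 64; zero matched fragments score 0.
    """
    if n_b < 0 or n_y < 0:
        raise ValueError("matched-fragment counts must be non-negative")
    if n_b + n_y == 0:
        return 0.0
    nb = min(n_b, _FACTORIAL_CAP)
    ny = min(n_y, _FACTORIAL_CAP)
    return (
        math.lgamma(nb + 1)
        + math.lgamma(ny + 1)
        + math.log(max(sum_I_b, 1.0))
        + math.log(max(sum_I_y, 1.0))
    )


def spectral_angle(
    pl: PeakList,
    p: Peptidoform,
    tol_ppm: float = 20.0,
    max_frag_charge: int | None = None,
) -> float:
    """Normalized spectral contrast angle, ``1 - (2/pi) * arccos(cos theta)``.

    Cosine similarity of square-rooted intensity vectors over the theoretical
    b/y fragment positions; no intensity prediction is available, so the
    theoretical vector is uniform. Unmatched theoretical positions contribute
    an observed 0; observed peaks off the theoretical positions are ignored.
    Zero-norm observed vectors score 0.
    """
    if max_frag_charge is None:
        max_frag_charge = fragment_charge_range(p.charge)
    frags = chem.fragment_mzs(p, max_frag_charge)
    res = match_fragments(pl, frags, tol_ppm)
    obs = np.zeros(len(frags))
    for i, j in enumerate(res.peak_index):
        if j >= 0:
            obs[i] = math.sqrt(float(pl.intensity[j]))
    theo = np.ones(len(frags))
    norm = np.linalg.norm(obs) * np.linalg.norm(theo)
    if norm == 0:
        return 0.0
    cos = float(np.clip(obs @ theo / norm, -1.0, 1.0))
    return 1.0 - (2.0 / math.pi) * math.acos(cos)


def rtsf_pass(s: PSMScore, cfg: RTSFilterConfig) -> bool:
    """The real-time search filter predicate on a fully populated score."""
    if s.charge is not None and s.charge not in cfg.charges:
        return False
    return (
        s.xcorr >= cfg.xcorr_min
        and s.dcn >= cfg.dcn_min
        and abs(s.delta_ppm) <= cfg.ppm_max
    )


# ---------------------------------------------------------------------------
# MGF interface.

def write_mgf(
    spectra: Iterable[tuple[str, PeakList]], path: str | Path
) -> None:
    """Write (title, PeakList) pairs to MGF; TITLE carries scan provenance."""
    entries = []
    for title, pl in spectra:
        entries.append(
            {
                "m/z array": pl.mz,
                "intensity array": pl.intensity,
                "params": {
                    "title": title,
                    "pepmass": pl.precursor_mz,
                    "charge": pl.precursor_charge,
                },
            }
        )
    _pyt_mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[tuple[str, PeakList]]:
    out: list[tuple[str, PeakList]] = []
    with _pyt_mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = params.get("charge", [2])
            z = int(charge[0]) if hasattr(charge, "__len__") else int(charge)
            pepmass = params.get("pepmass", (0.0,))
            pl = PeakList(
                np.asarray(spec["m/z array"], dtype=float),
                np.asarray(spec["intensity array"], dtype=float),
                precursor_mz=float(pepmass[0]),
                precursor_charge=z,
            )
            out.append((params.get("title", ""), pl))
    return out
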