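"""Peptide chemistry: residue masses, peptidoforms, precursor m/z and b/y fragments.

All masses are monoisotopic and in daltons; m/z values are in thomsons (Th).
Modifications are represented as ``(position, delta)`` pairs with 1-based
positions, so new variable modifications need no type changes. Only b/y
fragment series are produced (no neutral losses, no a/c/x/z ions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from pyteomics import fasta as _pyt_fasta
from pyteomics import mass as _pyt_mass

__all__ = [
    "RESIDUE_MASS",
    "PROTON",
    "WATER",
    "MET_OXIDATION",
    "STANDARD_RESIDUES",
    "AlphabetError",
    "ModificationError",
    "Peptidoform",
    "Precursor",
    "FragmentIon",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_mzs",
    "enumerate_precursors",
    "residue_fractional_span",
    "read_peptide_fasta",
    "write_peptide_fasta",
    "read_target_table",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: _pyt_mass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

PROTON = 1.007276  # Da
WATER = 18.010565  # Da
MET_OXIDATION = 15.994915  # Da, variable Met oxidation delta

#: Which residues may carry a given modification delta. Deltas not listed here
#: are accepted on any residue.
_MOD_ELIGIBILITY: dict[float, str] = {MET_OXIDATION: "M"}


class AlphabetError(ValueError):
    """A sequence contains a letter outside the 20-residue alphabet."""


class ModificationError(ValueError):
    """A modification sits on a position/residue that cannot carry it."""


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise AlphabetError("empty peptide sequence")
    bad = set(sequence) - set(STANDARD_RESIDUES)
    if bad:
        raise AlphabetError(
            f"invalid residue letter(s) {sorted(bad)} in {sequence!r}"
        )


@dataclass(frozen=True, order=True)
class Peptidoform:
    """A peptide sequence with variable modifications and a charge state."""

    sequence: str
    mods: tuple[tuple[int, float], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        mods = tuple(sorted(self.mods))
        object.__setattr__(self, "mods", mods)
        for pos, delta in mods:
            if not 1 <= pos <= len(self.sequence):
                raise ModificationError(
                    f"mod position {pos} outside 1..{len(self.sequence)}"
                )
            allowed = _MOD_ELIGIBILITY.get(delta)
            if allowed is not None and self.sequence[pos - 1] not in allowed:
                raise ModificationError(
                    f"delta {delta:+.6f} not allowed on "
                    f"{self.sequence[pos - 1]}{pos} of {self.sequence!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mod_signature(self) -> str:
        """Compact text form of the modification set, e.g. ``[3:+15.994915]``."""
        if not self.mods:
            return ""
        return "".join(f"[{p}:{d:+.6f}]" for p, d in self.mods)

    @property
    def compound_id(self) -> str:
        return f"{self.sequence}{self.mod_signature}/{self.charge}"


@dataclass(frozen=True)
class Precursor:
    """A peptidoform together with its neutral mass and m/z."""

    peptidoform: Peptidoform
    neutral_mass: float
    mz: float


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    ordinal: int
    charge: int
    mz: float


def monoisotopic_mass(p: Peptidoform | str) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    if isinstance(p, str):
        p = Peptidoform(p, charge=1)
    return (
        sum(RESIDUE_MASS[aa] for aa in p.sequence)
        + WATER
        + sum(delta for _, delta in p.mods)
    )


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """Protonated m/z, ``(M + z * proton) / z``."""
    if charge <= 0:
        raise ValueError(f"charge must be positive, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def fragment_mzs(p: Peptidoform, max_frag_charge: int = 1) -> list[FragmentIon]:
    """All b/y fragment ions with ordinals 1..L-1 and charges 1..max_frag_charge.

    Prefix (b) neutral masses are running residue+mod sums; suffix (y) masses
    additionally carry the C-terminal water. Fragment charge never exceeds the
    precursor charge.
    """
    L = len(p.sequence)
    if L < 2:
        raise ValueError(f"cannot fragment peptide of length {L}")
    max_z = max(1, min(max_frag_charge, p.charge))
    mods_at = dict(p.mods)
    prefix = [0.0]
    for i, aa in enumerate(p.sequence, start=1):
        prefix.append(prefix[-1] + RESIDUE_MASS[aa] + mods_at.get(i, 0.0))
    total = prefix[-1]
    out: list[FragmentIon] = []
    for i in range(1, L):
        b_neutral = prefix[i]
        y_neutral = total - prefix[L - i] + WATER
        for z in range(1, max_z + 1):
            out.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            out.append(FragmentIon("y", i, z, (y_neutral + z * PROTON) / z))
    return out


def _mod_site_subsets(
    sequence: str, varmods: dict[str, float], max_mods: int
) -> list[tuple[tuple[int, float], ...]]:
    sites = [
        (i, varmods[aa])
        for i, aa in enumerate(sequence, start=1)
        if aa in varmods
    ]
    subsets: list[tuple[tuple[int, float], ...]] = []
    for k in range(0, min(max_mods, len(sites)) + 1):
        subsets.extend(itertools.combinations(sites, k))
    # unmodified first, then by (size, position tuple)
    subsets.sort(key=lambda s: (len(s), tuple(p for p, _ in s)))
    return subsets


def enumerate_precursors(
    sequence: str,
    varmods: dict[str, float] | None = None,
    max_mods: int = 3,
    charges: Sequence[int] = (1, 2, 3),
) -> list[Precursor]:
    """Cartesian product of modification-site subsets (size <= max_mods) and charges.

    ``varmods`` maps residue letter -> delta; the default is Met oxidation
    only. Order is deterministic: unmodified form first, then by modification
    position tuple, charge ascending within each form.
    """
    _check_sequence(sequence)
    if varmods is None:
        varmods = {"M": MET_OXIDATION}
    out: list[Precursor] = []
    for mods in _mod_site_subsets(sequence, varmods, max_mods):
        for z in sorted(charges):
            p = Peptidoform(sequence, mods, z)
            m = monoisotopic_mass(p)
            out.append(Precursor(p, m, precursor_mz(m, z)))
    return out


def residue_fractional_span() -> float:
    """Span (max - min) of the fractional parts of the 20 residue masses, Da.

    The narrowness of this span (< 0.1 Da) is what concentrates co-isolated
    same-charge peptide mass differences near integer multiples of 1 Da.
    """
    fracs = [m % 1.0 for m in RESIDUE_MASS.values()]
    return max(fracs) - min(fracs)


# ---------------------------------------------------------------------------
# File interfaces: peptide FASTA (one record per peptide) and target TSV.

def write_peptide_fasta(
    records: Iterable[tuple[str, str, str | None]], path: str | Path
) -> None:
    """Write (identifier, sequence, class_label) records as a peptide FASTA.

    Headers look like ``>pep_0001 class=neoantigen``; a None label omits the
    class attribute.
    """
    entries = []
    for ident, seq, label in records:
        _check_sequence(seq)
        desc = ident if label is None else f"{ident} class={label}"
        entries.append((desc, seq))
    with open(path, "w") as fh:
        _pyt_fasta.write(entries, fh)


def read_peptide_fasta(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read a peptide FASTA written by :func:`write_peptide_fasta`."""
    out: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        for entry in _pyt_fasta.read(fh):
            parts = entry.description.split()
            ident = parts[0]
            label = None
            for token in parts[1:]:
                if token.startswith("class="):
                    label = token[len("class="):]
            seq = entry.sequence.upper()
            _check_sequence(seq)
            out.append((ident, seq, label))
    return out


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a target peptide table (TSV with at least a ``sequence`` column)."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValueError(f"target table {path} lacks a 'sequence' column")
    return df
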