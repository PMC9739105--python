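"""Disulfide-aware peptide mass arithmetic and MALDI-ISD fragment reasoning.

This module implements the mass-spectrometric toolbox used to characterize
small disulfide-rich venom peptides of the crotamine family:

* residue and peptide masses (monoisotopic and average), with oxidation
  accounting — each disulfide bond removes two hydrogen atoms from the
  reduced-form mass;
* in-source-decay (ISD) c/z fragment ladders and annotation of observed
  peak lists against a candidate sequence;
* inference of single-residue substitutions from a measured mass shift
  (e.g. the ~24 Da shift that distinguishes a His from a Leu isoform);
* pairwise global-alignment sequence identity.

Masses are computed from hard-coded residue elemental formulas and IUPAC
2021 standard atomic weights (average) / CODATA monoisotopic nuclide
masses, so the arithmetic is self-contained and auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "AMINO_ACIDS",
    "MassTable",
    "MASS_TABLE",
    "Peptide",
    "FragmentIon",
    "Annotation",
    "residue_mass",
    "peptide_mass",
    "mass_difference",
    "isd_ladder",
    "annotate_peaks",
    "infer_substitution",
    "pairwise_identity",
]

Mode = Literal["mono", "average"]

#: Monoisotopic nuclide masses (Da), CODATA/AME values.
_ELEM_MONO = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048,
              "O": 15.9949146196, "S": 31.97207100}
#: IUPAC 2021 standard atomic weights (Da).
_ELEM_AVG = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Residue (amino acid minus water) elemental formulas.
_RESIDUE_FORMULAS = {
    "G": "C2H3NO",   "A": "C3H5NO",   "S": "C3H5NO2",  "P": "C5H7NO",
    "V": "C5H9NO",   "T": "C4H7NO2",  "C": "C3H5NOS",  "L": "C6H11NO",
    "I": "C6H11NO",  "N": "C4H6N2O2", "D": "C4H5NO3",  "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3",  "M": "C5H9NOS",  "H": "C6H7N3O",
    "F": "C9H9NO",   "R": "C6H12N4O", "Y": "C9H9NO2",  "W": "C11H10N2O",
}

AMINO_ACIDS: str = "".join(sorted(_RESIDUE_FORMULAS))

PROTON_MASS = 1.00727646688  # Da; mass of H minus electron mass


def _formula_mass(formula: str, elements: dict[str, float]) -> float:
    return sum(elements[el] * int(n or 1)
               for el, n in re.findall(r"([A-Z])(\d*)", formula))


@dataclass(frozen=True)
class MassTable:
    """Per-residue monoisotopic and average masses plus small-molecule constants.

    All masses in daltons. ``residue[letter]`` maps one-letter codes to
    (mono, average) pairs; constants cover water, ammonia, hydrogen and
    the proton (for singly-protonated m/z).
    """

    residue_mono: dict[str, float] = field(default_factory=dict)
    residue_average: dict[str, float] = field(default_factory=dict)
    water_mono: float = _formula_mass("H2O", _ELEM_MONO)
    water_average: float = _formula_mass("H2O", _ELEM_AVG)
    ammonia_mono: float = _formula_mass("NH3", _ELEM_MONO)
    ammonia_average: float = _formula_mass("NH3", _ELEM_AVG)
    hydrogen_mono: float = _ELEM_MONO["H"]
    hydrogen_average: float = _ELEM_AVG["H"]
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        if not self.residue_mono:
            for aa, f in _RESIDUE_FORMULAS.items():
                self.residue_mono[aa] = _formula_mass(f, _ELEM_MONO)
                self.residue_average[aa] = _formula_mass(f, _ELEM_AVG)

    def residues(self, mode: Mode) -> dict[str, float]:
        _check_mode(mode)
        return self.residue_mono if mode == "mono" else self.residue_average

    def water(self, mode: Mode) -> float:
        _check_mode(mode)
        return self.water_mono if mode == "mono" else self.water_average

    def ammonia(self, mode: Mode) -> float:
        _check_mode(mode)
        return self.ammonia_mono if mode == "mono" else self.ammonia_average

    def hydrogen(self, mode: Mode) -> float:
        _check_mode(mode)
        return self.hydrogen_mono if mode == "mono" else self.hydrogen_average


MASS_TABLE = MassTable()


def _check_mode(mode: str) -> None:
    if mode not in ("mono", "average"):
        raise ValueError(f"mode must be 'mono' or 'average', got {mode!r}")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"unknown amino-acid code(s) {sorted(bad)}; expected one of {AMINO_ACIDS}"
        )


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with a declared number of disulfide bonds.

    ``n_disulfides`` only affects mass (−2 H per bond); the pairing of the
    cysteines is irrelevant to the arithmetic and is not modeled.
    """

    sequence: str
    n_disulfides: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        n_cys = self.sequence.count("C")
        if 2 * self.n_disulfides > n_cys:
            raise ValueError(
                f"{self.n_disulfides} disulfides require "
                f"{2 * self.n_disulfides} cysteines, sequence has {n_cys}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A c- or z-series backbone fragment (singly protonated m/z included)."""

    series: Literal["c", "z"]
    index: int
    neutral_mass: float
    mz_1plus: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


def residue_mass(letter: str, mode: Mode = "mono",
                 table: MassTable = MASS_TABLE) -> float:
    """Mass of a single amino-acid residue (amino acid minus water), in Da."""
    _check_mode(mode)
    try:
        return table.residues(mode)[letter]
    except KeyError:
        raise ValueError(
            f"unknown amino-acid code {letter!r}; expected one of {AMINO_ACIDS}"
        ) from None


def peptide_mass(peptide: Peptide, mode: Mode = "mono",
                 table: MassTable = MASS_TABLE) -> float:
    """Neutral peptide mass in Da: sum of residues + water − 2 H per disulfide."""
    _check_mode(mode)
    res = table.residues(mode)
    total = sum(res[a] for a in peptide.sequence) + table.water(mode)
    return total - peptide.n_disulfides * 2 * table.hydrogen(mode)


def mass_difference(pep_a: Peptide, pep_b: Peptide, mode: Mode = "mono",
                    table: MassTable = MASS_TABLE) -> float:
    """Signed mass difference mass(A) − mass(B), in Da."""
    return peptide_mass(pep_a, mode, table) - peptide_mass(pep_b, mode, table)


def isd_ladder(peptide: Peptide, table: MassTable = MASS_TABLE) -> list[FragmentIon]:
    """Full c/z fragment ladder of a peptide, monoisotopic masses.

    ISD with a DAN matrix cleaves N–Cα bonds by hydrogen-radical transfer,
    yielding c-ions (N-terminal) and z-type ions (C-terminal). Neutral
    masses follow the z+1 (z-dot + H) convention common in ISD spectra:

    * ``c_i``  = Σ residues(1..i) + NH3
    * ``z_j``  = Σ residues(n−j+1..n) + H2O − NH3 + 2 H

    so that ``c_i + z_{n−i} = M(reduced peptide) + 2 H`` for every cleavage
    site. Disulfides are ignored here: fragments of an oxidized peptide are
    reported at reduced-chain masses, which is how ISD ladders of
    disulfide-containing peptides are read after reduction in source.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("cannot fragment a single-residue peptide")
    res = table.residues("mono")
    masses = np.array([res[a] for a in peptide.sequence])
    prefix = np.cumsum(masses)
    ions: list[FragmentIon] = []
    for i in range(1, n):
        c_neutral = prefix[i - 1] + table.ammonia_mono
        ions.append(FragmentIon("c", i, c_neutral, c_neutral + table.proton))
    total = prefix[-1]
    for j in range(1, n):
        z_neutral = (total - prefix[n - j - 1] + table.water_mono
                     - table.ammonia_mono + 2 * table.hydrogen_mono)
        ions.append(FragmentIon("z", j, z_neutral, z_neutral + table.proton))
    return ions


@dataclass
class Annotation:
    """Result of matching an observed peak list against a candidate's ladder.

    ``coverage`` is the fraction of the n−1 inter-residue bonds supported by
    at least one matched c or z ion; ``terminal_span`` is the longest
    contiguous run of supported bonds starting from either terminus,
    expressed as a residue count (the length of the terminal fragment the
    spectrum reads through).
    """

    matches: pd.DataFrame  # columns: mz, ion, series, index, delta_mda? see below
    coverage: float
    terminal_span: int
    n_bonds: int
    supported_bonds: np.ndarray  # bool, length n_bonds, bond i = between res i,i+1


def annotate_peaks(peaks: pd.DataFrame | Sequence[float], candidate: Peptide,
                   tolerance: float = 0.1,
                   table: MassTable = MASS_TABLE) -> Annotation:
    """Greedily match observed m/z peaks to the candidate's c/z ladder.

    Peaks are singly-protonated m/z values (``mz`` column of a DataFrame or
    a plain sequence). Matching is greedy nearest-mass: candidate pairs
    within ``tolerance`` Da are accepted in order of |Δm| (ties: lower
    fragment index, c before z), each peak matching at most one ion and
    each ion at most one peak.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if isinstance(peaks, pd.DataFrame):
        mz = np.asarray(peaks["mz"], dtype=float)
    else:
        mz = np.asarray(peaks, dtype=float)
    ladder = isd_ladder(candidate, table)
    n = len(candidate)

    pairs = []
    for k, m in enumerate(mz):
        for ion in ladder:
            delta = m - ion.mz_1plus
            if abs(delta) <= tolerance:
                pairs.append((abs(delta), ion.index, 0 if ion.series == "c" else 1,
                              k, ion, delta))
    pairs.sort(key=lambda p: p[:3])

    used_peaks: set[int] = set()
    used_ions: set[str] = set()
    rows = []
    supported = np.zeros(n - 1, dtype=bool)
    for _, _, _, k, ion, delta in pairs:
        if k in used_peaks or ion.label in used_ions:
            continue
        used_peaks.add(k)
        used_ions.add(ion.label)
        rows.append({"mz": mz[k], "ion": ion.label, "series": ion.series,
                     "index": ion.index, "mz_calc": ion.mz_1plus, "delta": delta})
        # bond b (1-based) lies between residues b and b+1; c_i supports bond i,
        # z_j supports bond n-j
        bond = ion.index if ion.series == "c" else n - ion.index
        supported[bond - 1] = True

    matches = pd.DataFrame(rows, columns=["mz", "ion", "series", "index",
                                          "mz_calc", "delta"])
    coverage = float(supported.mean()) if n > 1 else 0.0
    terminal_span = max(_run_length(supported), _run_length(supported[::-1]))
    return Annotation(matches=matches, coverage=coverage,
                      terminal_span=terminal_span, n_bonds=n - 1,
                      supported_bonds=supported)


def _run_length(mask: np.ndarray) -> int:
    run = 0
    for m in mask:
        if not m:
            break
        run += 1
    return run


def infer_substitution(delta: float, tolerance: float = 0.1,
                       mode: Mode = "mono",
                       table: MassTable = MASS_TABLE) -> list[tuple[str, str]]:
    """All ordered residue pairs (A, B) with mass(A) − mass(B) ≈ |delta|.

    Brute force over all 380 ordered pairs of distinct standard residues;
    results sorted by |mismatch| (then alphabetically for stable ties).
    A measured shift of ~24 Da, for instance, returns (His, Leu) among the
    closest candidates.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    _check_mode(mode)
    res = table.residues(mode)
    target = abs(delta)
    hits = []
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            if a == b:
                continue
            mismatch = abs((res[a] - res[b]) - target)
            if mismatch <= tolerance:
                hits.append((mismatch, a, b))
    hits.sort()
    return [(a, b) for _, a, b in hits]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment (match 1, mismatch 0, gap −1).

    Identity = identical columns / alignment length × 100, computed on the
    highest-scoring global alignment.
    """
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return 100.0 * identities / aln.length
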