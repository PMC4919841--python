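"""In-silico tryptic digestion, peptide mass arithmetic and peptide indexing.

Trypsin/P cleaves C-terminal to K and R with no proline exception.  Up to
``max_missed`` internal cleavage sites are retained, carbamidomethylation
of cysteine is applied as a fixed modification and oxidation of methionine
is enumerated as a variable modification.  Peptide neutral monoisotopic
masses are computed from a residue table written to six decimals, and a
:class:`PeptideIndex` supports ppm-window precursor queries plus
peptide-to-protein lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .catalog_store import CANONICAL_RESIDUES, ProteinDatabase, ProteinRecord

# Monoisotopic residue masses (Da, 6 decimals), computed from atomic masses.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.007276

CARBAMIDOMETHYL = 57.021464  # fixed on C
OXIDATION = 15.994915  # variable on M


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) peptide form.

    ``mods`` is a tuple of ``(position, delta_mass)`` with 1-based residue
    positions; fixed and variable modifications both appear here so that
    ``mono_mass`` is always residue masses + water + mod deltas.
    """

    sequence: str
    missed_cleavages: int = 0
    mods: tuple[tuple[int, float], ...] = ()
    mono_mass: float = field(default=0.0, compare=False)

    @property
    def key(self) -> tuple[str, tuple[tuple[int, float], ...]]:
        return (self.sequence, self.mods)

    @property
    def mods_str(self) -> str:
        return ";".join(f"{p}:{d:+.6f}" for p, d in self.mods)


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings (defaults follow standard bottom-up practice)."""

    enzyme: str = "trypsin_p"
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 45
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    var_mods: tuple[tuple[str, float], ...] = (("M", OXIDATION),)
    max_var_mods: int = 3

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin_p":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")


def peptide_mass(peptide: Peptide | str, mods: Sequence[tuple[int, float]] = ()) -> float:
    """Neutral monoisotopic mass: sum of residue masses + water + mod deltas."""
    if isinstance(peptide, Peptide):
        sequence, mods = peptide.sequence, peptide.mods
    else:
        sequence = peptide
    total = WATER
    for aa in sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise KeyError(f"unknown residue {aa!r} in {sequence!r}") from None
    for _, delta in mods:
        total += delta
    return total


def precursor_mz(mono_mass: float, charge: int) -> float:
    """m/z of a protonated precursor: ``(M + z*proton) / z``."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mono_mass + charge * PROTON) / charge


def neutral_mass(mz: float, charge: int) -> float:
    """Inverse of :func:`precursor_mz`."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully-cleaved trypsin/P fragments of ``sequence``, in order.

    Cleavage occurs C-terminal to every K/R except a protein-terminal one
    (which would yield an empty fragment).
    """
    boundaries = [0]
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < n - 1:
            boundaries.append(i + 1)
    boundaries.append(n)
    return [sequence[boundaries[i] : boundaries[i + 1]] for i in range(len(boundaries) - 1)]


def _expand_mods(sequence: str, params: DigestParams) -> list[tuple[tuple[int, float], ...]]:
    """All modification-state tuples for one peptide sequence.

    Fixed modifications are applied to every matching residue; variable
    modifications are enumerated over subsets of matching positions up to
    ``max_var_mods`` per peptide.  Positions are 1-based; each returned
    tuple is sorted by position.
    """
    fixed: list[tuple[int, float]] = []
    for residue, delta in params.fixed_mods:
        fixed.extend((i + 1, delta) for i, aa in enumerate(sequence) if aa == residue)
    var_positions: list[tuple[int, float]] = []
    for residue, delta in params.var_mods:
        var_positions.extend((i + 1, delta) for i, aa in enumerate(sequence) if aa == residue)
    forms: list[tuple[tuple[int, float], ...]] = []
    max_k = min(params.max_var_mods, len(var_positions))
    for k in range(max_k + 1):
        for combo in itertools.combinations(var_positions, k):
            forms.append(tuple(sorted(fixed + list(combo))))
    return forms


def digest(protein: ProteinRecord | str, params: DigestParams | None = None) -> list[Peptide]:
    """Digest one protein into modified peptide forms.

    Peptides containing non-canonical residues (B/J/O/U/X/Z...) are
    skipped so that mass arithmetic stays well-defined; the protein itself
    is never rejected.
    """
    params = params or DigestParams()
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    fragments = cleavage_fragments(sequence)
    # prefix masses over fragments for O(1) window mass; invalid fragments poison windows
    peptides: list[Peptide] = []
    nfrag = len(fragments)
    frag_ok = [set(f) <= CANONICAL_RESIDUES for f in fragments]
    for start in range(nfrag):
        for missed in range(params.max_missed + 1):
            end = start + missed
            if end >= nfrag:
                break
            window = fragments[start : end + 1]
            if not all(frag_ok[start : end + 1]):
                continue
            pep_seq = "".join(window)
            if not (params.min_len <= len(pep_seq) <= params.max_len):
                continue
            for mods in _expand_mods(pep_seq, params):
                peptides.append(
                    Peptide(
                        sequence=pep_seq,
                        missed_cleavages=missed,
                        mods=mods,
                        mono_mass=peptide_mass(pep_seq, mods),
                    )
                )
    return peptides


class PeptideIndex:
    """Digest-derived search index over a protein database.

    Maps every digestible peptide sequence to all proteins containing it
    and keeps a mass-sorted table of modified peptide forms for
    ppm-window precursor queries.
    """

    def __init__(self, db: ProteinDatabase, params: DigestParams | None = None):
        self.params = params or DigestParams()
        self.pep_to_prot: dict[str, set[str]] = {}
        forms: dict[tuple[str, tuple[tuple[int, float], ...]], Peptide] = {}
        for record in db:
            seen_seqs: set[str] = set()
            for pep in digest(record, self.params):
                if pep.sequence not in seen_seqs:
                    seen_seqs.add(pep.sequence)
                    self.pep_to_prot.setdefault(pep.sequence, set()).add(record.accession)
                forms.setdefault(pep.key, pep)
        self.forms: list[Peptide] = sorted(
            forms.values(), key=lambda p: (p.mono_mass, p.sequence, p.mods)
        )
        self._masses = np.array([p.mono_mass for p in self.forms])

    def __len__(self) -> int:
        return len(self.forms)

    @property
    def peptide_sequences(self) -> set[str]:
        return set(self.pep_to_prot)

    def proteins_of(self, sequence: str) -> set[str]:
        return self.pep_to_prot.get(sequence, set())

    def lookup_mass(self, mass: float, tol_ppm: float) -> list[Peptide]:
        """All peptide forms with neutral mass within ``±tol_ppm`` of ``mass``."""
        delta = mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self._masses, mass - delta, side="left"))
        hi = int(np.searchsorted(self._masses, mass + delta, side="right"))
        return self.forms[lo:hi]


def build_index(db: ProteinDatabase, params: DigestParams | None = None) -> PeptideIndex:
    """Build a :class:`PeptideIndex` for ``db`` (must be non-empty)."""
    if len(db) == 0:
        raise ValueError("cannot index an empty database")
    return PeptideIndex(db, params)
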