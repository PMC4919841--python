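"""Peptide-spectrum matching: candidate retrieval, hyperscore, expect values.

The scorer is a documented, self-consistent member of the X!Tandem
hyperscore family: the dot product of matched (preprocessed) peak
intensities is multiplied by factorials of the matched singly-charged b-
and y-ion counts, with the factorial terms capped to avoid overflow
dominance.  Expect values come from a least-squares line fit to the
log-survival histogram of candidate scores; because desk-scale databases
give individual spectra only a handful of in-tolerance candidates, the
null fit is pooled across the run unless a spectrum has enough candidates
of its own (see ``search_run``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog_store import DECOY_PREFIX, ProteinDatabase
from .digestion import (
    PROTON,
    DigestParams,
    Peptide,
    PeptideIndex,
    RESIDUE_MASSES,
    WATER,
    build_index,
    neutral_mass,
)
from .spectra_io import Run, Spectrum, preprocess

FACTORIAL_CAP = 10  # n_b!/n_y! capped at 10!
MAX_PEPTIDE_LEN_FOR_FRAGMENTS = 100

EXPECT_MIN = 1e-20
EXPECT_MAX = 1e3


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances and charge handling.

    ``parent_tol_ppm``/``frag_tol_ppm`` default to 10/20 ppm as
    appropriate for a high-resolution instrument.  ``charges_tried`` is
    used when the precursor charge is unknown.  ``min_candidates_own_fit``
    is the candidate count above which a spectrum's expect value is fit
    from its own score distribution rather than the pooled run-level one.
    """

    parent_tol_ppm: float = 10.0
    frag_tol_ppm: float = 20.0
    charges_tried: tuple[int, ...] = (2, 3)
    max_rank: int = 1
    min_candidates_own_fit: int = 100
    null_decoys_per_spectrum: int = 8

    def __post_init__(self) -> None:
        if self.parent_tol_ppm <= 0 or self.frag_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match (best hit for its spectrum)."""

    scan_id: str
    peptide: Peptide
    protein_accessions: tuple[str, ...]
    hyperscore: float
    expect: float
    is_decoy: bool
    charge: int
    n_b: int = 0
    n_y: int = 0
    rt: float = 0.0
    precursor_mz: float = 0.0
    precursor_intensity: float | None = None
    expect_flag: str = ""


def candidates(
    index: PeptideIndex, precursor_mz: float, charge: int, params: SearchParams
) -> list[Peptide]:
    """All indexed peptide forms within the parent tolerance.

    The neutral mass is ``precursor_mz * z - z * proton`` and the window
    is ``±parent_tol_ppm`` around it.
    """
    mass = neutral_mass(precursor_mz, charge)
    return index.lookup_mass(mass, params.parent_tol_ppm)


def fragment_mzs(peptide: Peptide) -> tuple[np.ndarray, np.ndarray]:
    """Singly-charged b- and y-ion m/z ladders for a modified peptide."""
    seq = peptide.sequence
    n = len(seq)
    if n > MAX_PEPTIDE_LEN_FOR_FRAGMENTS:
        raise ValueError(f"peptide too long for fragment table ({n} residues)")
    residue = np.array([RESIDUE_MASSES[aa] for aa in seq])
    for pos, delta in peptide.mods:
        residue[pos - 1] += delta
    prefix = np.cumsum(residue)
    b = prefix[:-1] + PROTON
    total = prefix[-1]
    y = (total - prefix[:-1])[::-1] + WATER + PROTON
    return b, y


def _capped_factorial(n: int) -> float:
    return float(math.factorial(min(n, FACTORIAL_CAP)))


def hyperscore(
    spectrum: Spectrum, peptide: Peptide, frag_tol_ppm: float
) -> tuple[float, int, int]:
    """Score one candidate against a preprocessed spectrum.

    A fragment matches when a peak lies within ``±frag_tol_ppm``; every
    peak is allowed to match at most one fragment (nearest wins).  The
    score is the sum of matched peak intensities times ``n_b! * n_y!``
    (factorials capped).
    """
    b, y = fragment_mzs(peptide)
    frags = np.concatenate([b, y])
    n_b_frags = b.size
    mz, intensity = spectrum.mz, spectrum.intensity
    if mz.size == 0:
        return 0.0, 0, 0
    idx = np.searchsorted(mz, frags)
    # claimed[peak] = (|ppm error|, fragment index)
    claimed: dict[int, tuple[float, int]] = {}
    for fi in range(frags.size):
        f = frags[fi]
        tol = f * frag_tol_ppm * 1e-6
        best_peak = -1
        best_err = tol
        for pi in (idx[fi] - 1, idx[fi]):
            if 0 <= pi < mz.size:
                err = abs(mz[pi] - f)
                if err <= best_err:
                    best_err = err
                    best_peak = pi
        if best_peak < 0:
            continue
        prev = claimed.get(best_peak)
        if prev is None or best_err < prev[0]:
            claimed[best_peak] = (best_err, fi)
    if not claimed:
        return 0.0, 0, 0
    dot = 0.0
    n_b = n_y = 0
    for peak, (_, fi) in claimed.items():
        dot += float(intensity[peak])
        if fi < n_b_frags:
            n_b += 1
        else:
            n_y += 1
    score = dot * _capped_factorial(n_b) * _capped_factorial(n_y)
    return score, n_b, n_y


def _log_compress(score: float | np.ndarray) -> np.ndarray:
    """X!Tandem-style log compression used for histogramming scores."""
    return 4.0 * np.log10(1.0 + np.asarray(score, dtype=float))


#: Histogram bin width on the log-compressed score scale.  Half-unit bins
#: resolve the short null tail that sparse spectra produce.
SCORE_BIN_WIDTH = 0.5


def _score_bin(score: float | np.ndarray) -> np.ndarray:
    return np.floor(_log_compress(score) / SCORE_BIN_WIDTH).astype(int)


def fit_score_null(all_scores: Sequence[float]) -> tuple[float, float] | None:
    """Fit ``log10(survival count) = a + b * bin`` over the null region.

    Scores are log-compressed and binned at ``SCORE_BIN_WIDTH``.  The fit covers
    the contiguous non-empty bins above the histogram mode; bins beyond
    the first empty bin are treated as signal and excluded from both the
    fit and the survival counts.  Returns ``(a, b)`` or ``None`` when the
    fit is degenerate (< 3 usable tail bins or non-negative slope).
    """
    scores = np.asarray(all_scores, dtype=float)
    if scores.size < 3:
        return None
    bins = _score_bin(scores)
    counts = np.bincount(bins)
    mode = int(np.argmax(counts))
    tail: list[int] = []
    for b in range(mode + 1, counts.size):
        if counts[b] == 0:
            break
        tail.append(b)
    if len(tail) < 3:
        return None
    null_max_bin = tail[-1]
    null_bins = bins[bins <= null_max_bin]
    survival = np.array([(null_bins >= b).sum() for b in tail], dtype=float)
    slope, intercept = np.polyfit(np.array(tail, dtype=float), np.log10(survival), 1)
    if slope >= 0:
        return None
    return float(intercept), float(slope)


def expect_from_fit(fit: tuple[float, float] | None, best_score: float) -> tuple[float, str]:
    """Evaluate an expect value from a survival-count fit at a binned score."""
    if fit is None:
        return 1.0, "degenerate_fit"
    intercept, slope = fit
    b = float(_score_bin(best_score))
    expect = 10.0 ** (intercept + slope * b)
    return float(min(max(expect, EXPECT_MIN), EXPECT_MAX)), ""


def expect_value(best_score: float, all_scores: Sequence[float]) -> tuple[float, str]:
    """Expect value of ``best_score`` given the candidate score sample.

    Falls back to ``expect = 1`` with a flag when the survival fit is
    degenerate (too few candidates or too few non-empty tail bins).
    """
    return expect_from_fit(fit_score_null(all_scores), best_score)


def expect_from_pooled_null(
    fit: tuple[float, float] | None,
    n_null_scores: int,
    best_score: float,
    n_candidates: int,
) -> tuple[float, str]:
    """Expect from a run-pooled null: ``P(chance >= s) * n_candidates``.

    The pooled fit is over survival *counts* of the null sample; dividing
    by the null sample size turns it into a chance probability per
    candidate, and multiplying by the spectrum's own candidate count
    restores the 'expected number of equal-or-better chance matches for
    this spectrum' semantics.
    """
    if fit is None or n_null_scores <= 0:
        return 1.0, "degenerate_fit"
    intercept, slope = fit
    b = float(_score_bin(best_score))
    log_p = intercept + slope * b - np.log10(n_null_scores)
    expect = (10.0**log_p) * max(1, n_candidates)
    return float(min(max(expect, EXPECT_MIN), EXPECT_MAX)), ""


def search_run(
    run: Run,
    db: ProteinDatabase,
    dparams: DigestParams | None = None,
    sparams: SearchParams | None = None,
    index: PeptideIndex | None = None,
) -> list[PSM]:
    """Search every spectrum of a run, reporting the best hit per spectrum.

    Spectra are preprocessed on the fly.  Unknown precursor charges are
    expanded over ``charges_tried`` and the global best kept.  Ties on
    hyperscore break to the lower expect value, then the lexicographically
    smaller (sequence, mods).  Spectra whose best candidate matches no
    fragment (hyperscore 0) yield no PSM.

    Expect values: a null curve is fit per spectrum when it has at least
    ``min_candidates_own_fit`` scored candidates; otherwise the null is
    pooled over the run's decoy-candidate scores (a clean chance-match
    sample in a target-decoy search) and evaluated per spectrum as
    ``P(chance >= s) * n_candidates``.  A target-only search with too
    few candidates per spectrum has no usable null and falls back to
    ``expect = 1`` (the loose first-pass threshold is designed for this).
    """
    dparams = dparams or DigestParams()
    sparams = sparams or SearchParams()
    if index is None:
        index = build_index(db, dparams)

    decoy_cache: dict[str, bool] = {}

    def _is_decoy_pep(pep: Peptide) -> bool:
        flag = decoy_cache.get(pep.sequence)
        if flag is None:
            accs = index.proteins_of(pep.sequence)
            flag = bool(accs) and all(a.startswith(DECOY_PREFIX) for a in accs)
            decoy_cache[pep.sequence] = flag
        return flag

    def _sample_null_decoys(spec: Spectrum, z: int, k: int) -> list[Peptide]:
        """Deterministic decoy-form sample in a broad window around the
        precursor mass; feeds only the null score distribution."""
        mass = neutral_mass(spec.precursor_mz, z)
        lo = int(np.searchsorted(index._masses, mass * 0.75, side="left"))
        hi = int(np.searchsorted(index._masses, mass * 1.25, side="right"))
        if hi <= lo:
            return []
        picks = np.unique(np.linspace(lo, hi - 1, 4 * k).astype(int))
        out = []
        for i in picks:
            pep = index.forms[i]
            if _is_decoy_pep(pep):
                out.append(pep)
                if len(out) >= k:
                    break
        return out

    best_hits: list[tuple[Spectrum, int, Peptide, float, int, int, list[float]]] = []
    decoy_scores: list[float] = []
    for spectrum in run.spectra:
        spec = preprocess(spectrum)
        if not spec.searchable:
            continue
        charges = (spec.charge,) if spec.charge is not None else sparams.charges_tried
        spec_scores: list[float] = []
        best: tuple[float, str, tuple, Peptide, int, int, int] | None = None
        for z in charges:
            for pep in candidates(index, spec.precursor_mz, z, sparams):
                score, n_b, n_y = hyperscore(spec, pep, sparams.frag_tol_ppm)
                spec_scores.append(score)
                if _is_decoy_pep(pep):
                    decoy_scores.append(score)
                key = (-score, pep.sequence, pep.mods)
                if best is None or key < (-best[0], best[1], best[2]):
                    best = (score, pep.sequence, pep.mods, pep, z, n_b, n_y)
        if sparams.null_decoys_per_spectrum > 0:
            z0 = charges[0]
            for pep in _sample_null_decoys(spec, z0, sparams.null_decoys_per_spectrum):
                score, _, _ = hyperscore(spec, pep, sparams.frag_tol_ppm)
                decoy_scores.append(score)
        if best is not None and best[0] > 0:
            _, _, _, pep, z, n_b, n_y = best
            best_hits.append((spectrum, z, pep, best[0], n_b, n_y, spec_scores))

    pooled_fit = fit_score_null(decoy_scores)
    psms: list[PSM] = []
    for spectrum, z, pep, score, n_b, n_y, spec_scores in best_hits:
        if len(spec_scores) >= sparams.min_candidates_own_fit:
            own_fit = fit_score_null(spec_scores)
            if own_fit is not None:
                expect, flag = expect_from_fit(own_fit, score)
            else:
                expect, flag = expect_from_pooled_null(
                    pooled_fit, len(decoy_scores), score, len(spec_scores)
                )
        else:
            expect, flag = expect_from_pooled_null(
                pooled_fit, len(decoy_scores), score, len(spec_scores)
            )
        accessions = tuple(sorted(index.proteins_of(pep.sequence)))
        is_decoy = all(a.startswith(DECOY_PREFIX) for a in accessions)
        psms.append(
            PSM(
                scan_id=spectrum.scan_id,
                peptide=pep,
                protein_accessions=accessions,
                hyperscore=score,
                expect=expect,
                is_decoy=is_decoy,
                charge=z,
                n_b=n_b,
                n_y=n_y,
                rt=spectrum.rt,
                precursor_mz=spectrum.precursor_mz,
                precursor_intensity=spectrum.precursor_intensity,
                expect_flag=flag,
            )
        )
    return psms


def psms_to_rows(psms: Iterable[PSM]) -> list[dict]:
    """Flatten PSMs for a TSV table."""
    rows = []
    for p in psms:
        rows.append(
            {
                "scan_id": p.scan_id,
                "peptide": p.peptide.sequence,
                "mods": p.peptide.mods_str,
                "charge": p.charge,
                "hyperscore": p.hyperscore,
                "expect": p.expect,
                "accessions": ";".join(p.protein_accessions),
                "is_decoy": p.is_decoy,
            }
        )
    return rows
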