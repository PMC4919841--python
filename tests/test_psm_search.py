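"""Candidate retrieval, hyperscore, expect values and run-level search."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from metaproiq.catalog_store import ProteinDatabase, ProteinRecord, add_decoys
from metaproiq.digestion import DigestParams, Peptide, build_index, peptide_mass, precursor_mz
from metaproiq.psm_search import (
    SearchParams,
    candidates,
    expect_value,
    fragment_mzs,
    hyperscore,
    search_run,
)
from metaproiq.spectra_io import Run, Spectrum
from metaproiq.synthetic_fixtures import CommunitySpec, make_catalog, make_study
from .conftest import random_protein

PLAIN = DigestParams(fixed_mods=(), var_mods=(), min_len=5, max_len=40)


def spectrum_from_peaks(mz, intensity, precursor=500.0, charge=2, scan="t1"):
    s = Spectrum(scan, precursor, charge, 1.0, np.asarray(mz, float), np.asarray(intensity, float))
    s.preprocessed = True  # already on the normalised scale
    return s


class TestCandidates:
    def test_exact_mass_hit_and_tolerance_boundary(self):
        db = ProteinDatabase([ProteinRecord("A", "GGGKELVISKGGGR")])
        idx = build_index(db, PLAIN)
        pep = next(p for p in idx.forms if p.sequence == "ELVISK")
        params = SearchParams()
        mz = precursor_mz(pep.mono_mass, 2)
        assert pep in candidates(idx, mz, 2, params)
        mz_off = precursor_mz(pep.mono_mass * (1 + 20e-6), 2)
        assert pep not in candidates(idx, mz_off, 2, params)

    def test_equivalent_to_brute_force_scan(self, rng):
        db = ProteinDatabase(
            [ProteinRecord(f"p{i}", random_protein(rng, 80)) for i in range(30)]
        )
        idx = build_index(db, PLAIN)
        params = SearchParams()
        masses = np.array([p.mono_mass for p in idx.forms])
        for _ in range(100):
            q = float(rng.uniform(600.0, 3000.0))
            got = {p.key for p in candidates(idx, precursor_mz(q, 2), 2, params)}
            tol = q * 10e-6
            brute = {
                p.key for p, m in zip(idx.forms, masses) if abs(m - q) <= tol
            }
            assert got == brute


class TestHyperscore:
    def test_no_matching_peaks_scores_zero(self):
        pep = Peptide("PEPTIDEK", mono_mass=peptide_mass("PEPTIDEK"))
        s = spectrum_from_peaks([1500.0, 1600.0], [1.0, 0.5])
        score, n_b, n_y = hyperscore(s, pep, 20.0)
        assert (score, n_b, n_y) == (0.0, 0, 0)

    def test_hand_computed_oracle(self):
        """Three peaks (1.0, 0.5, 0.25) on two b-ions and one y-ion of
        PEPTIDEK give (1.0+0.5+0.25) * 2! * 1! = 3.5."""
        pep = Peptide("PEPTIDEK", mono_mass=peptide_mass("PEPTIDEK"))
        b, y = fragment_mzs(pep)
        s = spectrum_from_peaks(
            np.sort([b[1], b[3], y[2]]),
            [v for _, v in sorted(zip([b[1], b[3], y[2]], [1.0, 0.5, 0.25]))],
        )
        score, n_b, n_y = hyperscore(s, pep, 20.0)
        assert n_b == 2 and n_y == 1
        assert score == pytest.approx(1.75 * math.factorial(2) * math.factorial(1), abs=1e-12)

    def test_adding_matched_fragment_never_decreases_score(self, rng):
        pep = Peptide("ELVISLIVESK", mono_mass=peptide_mass("ELVISLIVESK"))
        b, y = fragment_mzs(pep)
        frags = np.concatenate([b, y])
        order = rng.permutation(frags.size)
        mzs, ints = [], []
        last = -1.0
        for fi in order:
            mzs.append(frags[fi])
            ints.append(float(rng.uniform(0.1, 1.0)))
            idx = np.argsort(mzs)
            s = spectrum_from_peaks(np.array(mzs)[idx], np.array(ints)[idx])
            score, _, _ = hyperscore(s, pep, 20.0)
            assert score >= last - 1e-12
            last = score

    def test_matches_brute_force_scorer(self, rng):
        """Independent O(frags x peaks) re-implementation agrees to 1e-9."""

        def brute(spec, pep, tol_ppm):
            b, y = fragment_mzs(pep)
            frags = list(enumerate(np.concatenate([b, y])))
            best_for_peak = {}
            for fi, f in frags:
                tol = f * tol_ppm * 1e-6
                errs = np.abs(spec.mz - f)
                pi = int(np.argmin(errs))
                if errs[pi] <= tol:
                    prev = best_for_peak.get(pi)
                    if prev is None or errs[pi] < prev[0]:
                        best_for_peak[pi] = (errs[pi], fi)
            if not best_for_peak:
                return 0.0
            dot = sum(float(spec.intensity[pi]) for pi in best_for_peak)
            n_b = sum(1 for _, fi in best_for_peak.values() if fi < len(b))
            n_y = len(best_for_peak) - n_b
            return dot * math.factorial(min(n_b, 10)) * math.factorial(min(n_y, 10))

        for trial in range(100):
            seq = random_protein(rng, int(rng.integers(6, 15)))
            pep = Peptide(seq, mono_mass=peptide_mass(seq))
            b, y = fragment_mzs(pep)
            frags = np.concatenate([b, y])
            n = int(rng.integers(3, 25))
            mz = np.sort(
                np.concatenate(
                    [
                        rng.choice(frags, size=min(n // 2 + 1, frags.size), replace=False)
                        * (1 + rng.normal(0, 5e-6, size=min(n // 2 + 1, frags.size))),
                        rng.uniform(150, 1500, size=n),
                    ]
                )
            )
            s = spectrum_from_peaks(mz, rng.uniform(0.05, 1.0, size=mz.size))
            score, _, _ = hyperscore(s, pep, 20.0)
            assert score == pytest.approx(brute(s, pep, 20.0), abs=1e-9)

    def test_too_long_peptide_rejected(self):
        seq = "A" * 150
        with pytest.raises(ValueError):
            fragment_mzs(Peptide(seq, mono_mass=0.0))


class TestExpectValue:
    def test_outlier_best_score_gets_small_expect(self, rng):
        null = np.abs(rng.normal(0, 1.0, size=200)) ** 3  # skewed chance scores
        e_hi, _ = expect_value(1e6, null)
        assert e_hi < 0.05

    def test_median_score_gets_large_expect(self, rng):
        null = np.abs(rng.normal(0, 1.0, size=200)) ** 3
        e_med, _ = expect_value(float(np.median(null)), null)
        assert e_med >= 0.5

    def test_single_candidate_falls_back_to_one(self):
        e, flag = expect_value(100.0, [100.0])
        assert e == 1.0 and flag == "degenerate_fit"


class TestSearchRun:
    def test_recovers_planted_peptides(self, tiny_study):
        _, catalog, study = tiny_study
        run = study.runs[0]
        truth = dict(zip(study.truth_peptides.scan_id, study.truth_peptides.peptide))
        psms = search_run(run, catalog.db)
        by_scan = {p.scan_id: p for p in psms}
        n_correct = sum(
            1 for scan, pep in truth.items()
            if scan in by_scan and by_scan[scan].peptide.sequence == pep
        )
        assert n_correct >= 0.99 * len(truth)

    def test_empty_run_yields_no_psms(self, small_db):
        assert search_run(Run("empty", []), small_db) == []

    def test_deterministic(self, tiny_study):
        _, catalog, study = tiny_study
        run = study.runs[0]
        a = search_run(run, catalog.db)
        b = search_run(run, catalog.db)
        assert [(p.scan_id, p.peptide.key, p.hyperscore, p.expect) for p in a] == [
            (p.scan_id, p.peptide.key, p.hyperscore, p.expect) for p in b
        ]

    def test_target_decoy_symmetry_on_pure_noise(self):
        """Noise spectra hit targets and decoys in roughly equal numbers."""
        import warnings

        spec = CommunitySpec(
            seed=42,
            n_catalog=1500,
            n_true=1,
            peptides_per_protein=1,
            n_noise_spectra=2500,
            noise_precursor="uniform",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            catalog = make_catalog(spec)
            study = make_study(spec, catalog)
            run = study.runs[0]
            noise_scans = set(
                study.truth_peptides.query("status == 'noise'").scan_id
            )
            td = add_decoys(catalog.db)
            psms = [p for p in search_run(run, td) if p.scan_id in noise_scans]
        n_decoy = sum(1 for p in psms if p.is_decoy)
        assert len(psms) >= 30
        assert sps.binomtest(n_decoy, len(psms), 0.5).pvalue > 0.001
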