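"""Protein grouping, razor assignment, MBR and MaxLFQ."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from metaproiq.protein_inference_quant import (
    PeptideFeature,
    QuantParams,
    assign_razor,
    group_proteins,
    match_between_runs,
    maxlfq,
    peptide_sample_matrix,
)
from metaproiq.synthetic_fixtures import make_feature_study


def invert(prot_peps):
    pep_prot = {}
    for acc, peps in prot_peps.items():
        for p in peps:
            pep_prot.setdefault(p, set()).add(acc)
    return pep_prot


def brute_components(prot_peps):
    """Independent pairwise-subset transitive closure."""
    accs = sorted(prot_peps)
    comp = {a: {a} for a in accs}
    for a, b in itertools.combinations(accs, 2):
        if prot_peps[a] <= prot_peps[b] or prot_peps[b] <= prot_peps[a]:
            merged = comp[a] | comp[b]
            for m in merged:
                comp[m] = merged
    return {frozenset(c) for c in comp.values()}


class TestGrouping:
    def test_subset_merges_with_leading(self):
        groups = group_proteins(invert({"P1": {"a", "b", "c"}, "P2": {"a", "b"}}))
        assert len(groups) == 1
        assert groups[0].leading == "P1"
        assert groups[0].members == ("P1", "P2")

    def test_incomparable_sets_stay_apart(self):
        groups = group_proteins(invert({"P1": {"a", "b"}, "P2": {"b", "c"}}))
        assert len(groups) == 2

    def test_matches_brute_force_closure(self, rng):
        peptide_pool = [f"pep{i}" for i in range(25)]
        for _ in range(20):
            prot_peps = {
                f"P{j:02d}": set(
                    rng.choice(peptide_pool, size=int(rng.integers(1, 6)), replace=False)
                )
                for j in range(50)
            }
            groups = group_proteins(invert(prot_peps))
            got = {frozenset(g.members) for g in groups}
            assert got == brute_components(prot_peps)

    def test_order_invariant_and_idempotent(self, rng):
        prot_peps = {
            f"P{j}": set(rng.choice([f"q{i}" for i in range(10)], size=3, replace=False))
            for j in range(12)
        }
        pep_prot = invert(prot_peps)
        g1 = group_proteins(pep_prot)
        shuffled = dict(sorted(pep_prot.items(), key=lambda kv: hash(kv[0]) % 7))
        g2 = group_proteins(shuffled)
        assert {frozenset(g.members) for g in g1} == {frozenset(g.members) for g in g2}


class TestRazor:
    def test_majority_rule(self):
        groups = group_proteins(
            invert({"G1": {"a", "b", "c", "d", "e", "s"}, "G2": {"x", "y", "s"}})
        )
        razor = assign_razor(groups)
        assert razor["s"] == "G1"

    def test_tie_breaks_lexicographically(self):
        groups = group_proteins(invert({"A1": {"a", "s"}, "B1": {"b", "s"}}))
        razor = assign_razor(groups)
        assert razor["s"] == "A1"

    def test_no_peptide_quantified_twice(self, rng):
        peptide_pool = [f"pep{i}" for i in range(15)]
        for _ in range(20):
            prot_peps = {
                f"P{j}": set(rng.choice(peptide_pool, size=int(rng.integers(2, 6)), replace=False))
                for j in range(10)
            }
            groups = group_proteins(invert(prot_peps))
            assign_razor(groups)
            counts = {}
            for g in groups:
                for p in g.quant_peptides:
                    counts[p] = counts.get(p, 0) + 1
            all_peps = {p for s in prot_peps.values() for p in s}
            assert set(counts) == all_peps
            assert all(c == 1 for c in counts.values())


def mk_feature(pep, sample, intensity, rt=50.0, mz=600.0, id_type="msms"):
    return PeptideFeature(pep, sample, intensity, rt, mz, id_type=id_type)


class TestMBR:
    def base_runs(self):
        shared = [
            (f"SHAREDPEP{i}K", 40.0 + 10 * i, 500.0 + 40 * i) for i in range(6)
        ]
        donor = [mk_feature(p, "R1", 100.0, rt, mz) for p, rt, mz in shared]
        acceptor = [mk_feature(p, "R2", 100.0, rt + 2.0, mz) for p, rt, mz in shared]
        donor.append(mk_feature("LONELYPEPK", "R1", 500.0, rt=50.0, mz=777.0))
        return {"R1": donor, "R2": acceptor}

    def test_transfer_within_window(self):
        feats = self.base_runs()
        cands = {"R1": [], "R2": [(777.0, 54.0, 321.0)]}  # aligned RT 52, |54-52|<=5
        out = match_between_runs(feats, cands, QuantParams())
        matched = [f for f in out["R2"] if f.id_type == "matched"]
        assert len(matched) == 1
        assert matched[0].peptide == "LONELYPEPK"
        assert matched[0].intensity == 321.0

    def test_no_transfer_outside_window(self):
        feats = self.base_runs()
        cands = {"R1": [], "R2": [(777.0, 58.0, 321.0)]}  # |58-52| > 5
        out = match_between_runs(feats, cands, QuantParams())
        assert not [f for f in out["R2"] if f.id_type == "matched"]

    def test_no_transfer_on_mz_mismatch(self):
        feats = self.base_runs()
        cands = {"R1": [], "R2": [(777.8, 52.0, 321.0)]}  # ~1000 ppm off
        out = match_between_runs(feats, cands, QuantParams())
        assert not [f for f in out["R2"] if f.id_type == "matched"]

    def test_never_transfers_already_identified_peptide(self):
        feats = self.base_runs()
        cands = {"R1": [], "R2": [(500.0, 42.0, 999.0)]}
        out = match_between_runs(feats, cands, QuantParams())
        assert not [f for f in out["R2"] if f.id_type == "matched"]

    def test_too_few_shared_peptides_blocks_transfer(self):
        feats = {
            "R1": [mk_feature("AAK", "R1", 1.0, 10.0, 400.0),
                   mk_feature("LONEK", "R1", 1.0, 50.0, 700.0)],
            "R2": [mk_feature("AAK", "R2", 1.0, 10.0, 400.0)],
        }
        cands = {"R1": [], "R2": [(700.0, 50.0, 5.0)]}
        with pytest.warns(UserWarning):
            out = match_between_runs(feats, cands, QuantParams())
        assert not [f for f in out["R2"] if f.id_type == "matched"]

    def test_planted_dropout_recovery(self):
        """Three-run study with 20 % dropouts: >= 90 % recovered, none false."""
        fs = make_feature_study(31, n_proteins=12, n_samples=3, cv=0.05, dropout_rate=0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = match_between_runs(fs.features_by_run, fs.candidates_by_run, QuantParams())
        planted = {(f.peptide, s) for s, fl in fs.features_by_run.items() for f in fl}
        matched = {(f.peptide, s) for s, fl in out.items() for f in fl if f.id_type == "matched"}
        assert len(matched) >= 0.9 * fs.n_dropouts
        assert not matched & planted  # never into a run with an MS/MS id


class TestMaxLfq:
    def one_group(self, pep_prot):
        groups = group_proteins(pep_prot)
        assign_razor(groups)
        return groups

    def test_single_peptide_identity(self):
        groups = self.one_group({"AAAK": {"P1"}})
        feats = [mk_feature("AAAK", s, v) for s, v in [("S1", 100.0), ("S2", 200.0), ("S3", 400.0)]]
        lfq = maxlfq(groups, feats)
        assert lfq.loc["P1"].tolist() == pytest.approx([100.0, 200.0, 400.0])

    def test_consistent_two_peptides_closed_form(self):
        groups = self.one_group({"AAAK": {"P1"}, "CCCK": {"P1"}})
        feats = []
        for s, scale in [("S1", 1.0), ("S2", 2.0), ("S3", 4.0)]:
            feats.append(mk_feature("AAAK", s, 100.0 * scale))
            feats.append(mk_feature("CCCK", s, 300.0 * scale))
        lfq = maxlfq(groups, feats)
        row = lfq.loc["P1"].to_numpy()
        assert row[1] / row[0] == pytest.approx(2.0, abs=1e-9)
        assert row[2] / row[0] == pytest.approx(4.0, abs=1e-9)
        assert row.sum() == pytest.approx(sum(f.intensity for f in feats), abs=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        """Noise-free 30 %-missing-but-connected data: least-squares
        log-abundances equal a brute-force normal-equations solve."""
        samples = [f"S{i}" for i in range(6)]
        for trial in range(10):
            true_log = rng.normal(6, 1, size=6)
            pep_prot = {f"PEP{j}K": {"PX"} for j in range(8)}
            groups = self.one_group(pep_prot)
            feats = []
            present = np.ones((8, 6), bool)
            miss = rng.random((8, 6)) < 0.3
            for i in range(6):  # keep every sample observed at least twice
                miss[rng.choice(8, 2, replace=False), i] = False
            present &= ~miss
            factors = rng.normal(0, 0.5, size=8)
            for j in range(8):
                for i in range(6):
                    if present[j, i]:
                        feats.append(
                            mk_feature(f"PEP{j}K", samples[i], float(2 ** (true_log[i] + factors[j])))
                        )
            lfq = maxlfq(groups, feats)
            row = np.log2(lfq.loc["PX"].to_numpy(float))
            got = row - np.nanmean(row)
            # oracle: solve the pairwise-median system via normal equations
            mat = peptide_sample_matrix(feats).to_numpy(float)
            n = 6
            L = np.zeros((n, n))
            b = np.zeros(n)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    both = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
                    if both.any():
                        r = np.median(np.log2(mat[both, i]) - np.log2(mat[both, j]))
                        L[i, i] += 1
                        L[i, j] -= 1
                        b[i] += r
            sol = np.linalg.lstsq(L + np.ones((n, n)) / n, b, rcond=None)[0]
            expected = sol - sol.mean()
            assert got == pytest.approx(expected, abs=1e-6)

    def test_disconnected_component_quantified_separately(self):
        groups = self.one_group({"AAAK": {"P1"}, "CCCK": {"P1"}})
        feats = [
            mk_feature("AAAK", "S1", 100.0),
            mk_feature("AAAK", "S2", 200.0),
            mk_feature("CCCK", "S3", 500.0),  # S3 shares no peptide with S1/S2
        ]
        lfq = maxlfq(groups, feats)
        # S3 forms its own component: quantified from raw intensity alone
        assert lfq.loc["P1", "S3"] == pytest.approx(500.0)
        assert lfq.loc["P1", "S1"] / lfq.loc["P1", "S2"] == pytest.approx(0.5)

    def test_group_without_features_is_all_missing(self):
        groups = self.one_group({"AAAK": {"P1"}, "GGGK": {"ZZ9"}})
        feats = [mk_feature("AAAK", "S1", 100.0)]
        lfq = maxlfq(groups, feats)
        assert lfq.loc["ZZ9"].isna().all()
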