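"""Protein grouping, razor peptides, match-between-runs and MaxLFQ.

Proteins identified by the same set or a subset of peptides collapse into
one protein group; peptides shared between groups are assigned as razor
peptides to the group with the most evidence and are used for that
group's quantification only.  Protein intensities follow the MaxLFQ
recipe: per sample pair, the median of log2 peptide-intensity ratios over
peptides observed in both samples; per connected component of the ratio
graph, a least-squares reconstruction of per-sample log-abundances,
rescaled so the summed LFQ intensity equals the summed raw intensity.
Identifications are transferred between runs by aligned retention time
and accurate precursor mass (match-between-runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .psm_search import PSM
from .spectra_io import Run


@dataclass(frozen=True)
class QuantParams:
    """Quantification windows and thresholds.

    ``rt_align_window`` (minutes) bounds the retention-time alignment
    between runs and ``match_window`` bounds the transfer of an aligned
    identification; ``min_ratio_count`` is the minimum number of shared
    peptides needed before a sample pair contributes a ratio.
    """

    rt_align_window: float = 20.0
    match_window: float = 5.0
    min_ratio_count: int = 1
    mbr_mz_tol_ppm: float = 10.0
    min_shared_for_alignment: int = 5

    def __post_init__(self) -> None:
        if self.match_window > self.rt_align_window:
            raise ValueError("match_window must not exceed rt_align_window")


@dataclass(frozen=True)
class PeptideFeature:
    """A quantifiable peptide occurrence in one run."""

    peptide: str
    sample_id: str
    intensity: float
    rt: float
    mz: float
    charge: int = 2
    id_type: str = "msms"  # "msms" | "matched"


@dataclass
class ProteinGroup:
    """Subset-merged proteins reported as one unit."""

    group_id: str
    members: tuple[str, ...]
    leading: str
    peptides: set[str] = field(default_factory=set)
    unique_peptides: set[str] = field(default_factory=set)
    razor_peptides: set[str] = field(default_factory=set)
    lfq: dict[str, float] = field(default_factory=dict)

    @property
    def quant_peptides(self) -> set[str]:
        return self.unique_peptides | self.razor_peptides


def group_proteins(
    peptide_protein_map: Mapping[str, set[str]],
    psm_counts: Mapping[str, int] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
) -> list[ProteinGroup]:
    """Merge proteins whose peptide sets are equal or subsets.

    Two proteins A and B fall in the same group when peptides(B) is a
    subset of peptides(A) (transitively closed).  The leading protein
    ranks by (#peptide sequences, #PSMs, sequence coverage) descending
    with a lexicographic accession tie-break; the group id is the leading
    accession.
    """
    psm_counts = psm_counts or {}
    protein_lengths = protein_lengths or {}
    prot_peps: dict[str, set[str]] = {}
    for pep, prots in peptide_protein_map.items():
        for acc in prots:
            prot_peps.setdefault(acc, set()).add(pep)
    accs = sorted(prot_peps)
    parent = {a: a for a in accs}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, a in enumerate(accs):
        pa = prot_peps[a]
        for b in accs[i + 1 :]:
            pb = prot_peps[b]
            if pa <= pb or pb <= pa:
                union(a, b)

    clusters: dict[str, list[str]] = {}
    for a in accs:
        clusters.setdefault(find(a), []).append(a)

    def rank_key(acc: str) -> tuple:
        n_pep = len(prot_peps[acc])
        n_psm = sum(psm_counts.get(p, 0) for p in prot_peps[acc])
        length = protein_lengths.get(acc, 0)
        coverage = (
            sum(len(p) for p in prot_peps[acc]) / length if length else 0.0
        )  # approximate coverage: summed peptide length over protein length
        return (-n_pep, -n_psm, -coverage, acc)

    groups: list[ProteinGroup] = []
    for members in clusters.values():
        ordered = tuple(sorted(members, key=rank_key))
        peptides = set()
        for acc in ordered:
            peptides |= prot_peps[acc]
        groups.append(
            ProteinGroup(
                group_id=ordered[0],
                members=ordered,
                leading=ordered[0],
                peptides=peptides,
            )
        )
    groups.sort(key=lambda g: g.group_id)

    # classify peptides: unique to one group vs shared across groups
    pep_groups: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        for pep in g.peptides:
            pep_groups.setdefault(pep, []).append(g)
    for g in groups:
        g.unique_peptides = {p for p in g.peptides if len(pep_groups[p]) == 1}
    return groups


def assign_razor(
    groups: Sequence[ProteinGroup], psm_counts: Mapping[str, int] | None = None
) -> dict[str, str]:
    """Assign each cross-group shared peptide to exactly one group.

    The winner is the group with the most peptide evidence, breaking ties
    by total PSM count then lexicographic leading accession.  Returns the
    peptide -> group_id razor map and updates ``razor_peptides`` in place.
    """
    psm_counts = psm_counts or {}
    pep_groups: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        g.razor_peptides = set()
        for pep in g.peptides:
            pep_groups.setdefault(pep, []).append(g)
    razor: dict[str, str] = {}
    for pep, gs in sorted(pep_groups.items()):
        if len(gs) == 1:
            continue
        winner = min(
            gs,
            key=lambda g: (
                -len(g.peptides),
                -sum(psm_counts.get(p, 0) for p in g.peptides),
                g.leading,
            ),
        )
        winner.razor_peptides.add(pep)
        razor[pep] = winner.group_id
    return razor


def extract_feature(run: Run, psm: PSM) -> PeptideFeature | None:
    """Turn a passing PSM into a quantifiable precursor feature.

    The intensity is the precursor intensity reported in the MGF PEPMASS
    line when present; otherwise the matched-fragment intensity sum
    (hyperscore with the factorial terms divided out) serves as a proxy.
    """
    intensity = psm.precursor_intensity
    if intensity is None or intensity <= 0:
        import math

        from .psm_search import FACTORIAL_CAP

        denom = math.factorial(min(psm.n_b, FACTORIAL_CAP)) * math.factorial(
            min(psm.n_y, FACTORIAL_CAP)
        )
        intensity = psm.hyperscore / denom if denom else 0.0
    if intensity <= 0:
        warnings.warn(f"no intensity for scan {psm.scan_id}; feature dropped", stacklevel=2)
        return None
    return PeptideFeature(
        peptide=psm.peptide.sequence,
        sample_id=run.sample_id,
        intensity=float(intensity),
        rt=psm.rt,
        mz=psm.precursor_mz,
        charge=psm.charge,
        id_type="msms",
    )


def _fit_alignment(
    donor_rts: np.ndarray, acceptor_rts: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Piecewise-linear RT map donor -> acceptor from shared peptides."""
    keep = np.abs(acceptor_rts - donor_rts) <= window
    x, y = donor_rts[keep], acceptor_rts[keep]
    if x.size < 2:
        return None
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # collapse duplicate donor RTs to their mean acceptor RT
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
    return ux, uy


def match_between_runs(
    features_by_run: Mapping[str, list[PeptideFeature]],
    candidates_by_run: Mapping[str, list[tuple[float, float, float]]],
    params: QuantParams | None = None,
) -> dict[str, list[PeptideFeature]]:
    """Transfer identifications between runs by aligned RT and accurate mass.

    For every (donor, acceptor) run pair a piecewise-linear RT alignment
    is fit on peptides MS/MS-identified in both runs; donor peptides
    absent from the acceptor gain an ``id_type="matched"`` feature when an
    unidentified acceptor precursor of the same m/z (within the MBR ppm
    tolerance) lies within the match window of the aligned RT.  A peptide
    is never transferred into a run where it was MS/MS-identified, and
    each acceptor candidate precursor is consumed at most once.
    """
    params = params or QuantParams()
    out: dict[str, list[PeptideFeature]] = {
        rid: list(feats) for rid, feats in features_by_run.items()
    }
    run_ids = sorted(features_by_run)
    msms_peptides = {
        rid: {f.peptide: f for f in features_by_run[rid] if f.id_type == "msms"}
        for rid in run_ids
    }
    available: dict[str, list[list[float] | None]] = {
        rid: [list(c) for c in candidates_by_run.get(rid, [])] for rid in run_ids
    }
    transferred: dict[str, set[str]] = {rid: set() for rid in run_ids}

    for acceptor in run_ids:
        for donor in run_ids:
            if donor == acceptor:
                continue
            shared = sorted(set(msms_peptides[donor]) & set(msms_peptides[acceptor]))
            if len(shared) < params.min_shared_for_alignment:
                warnings.warn(
                    f"MBR {donor}->{acceptor}: only {len(shared)} shared peptides, no transfer",
                    stacklevel=2,
                )
                continue
            dx = np.array([msms_peptides[donor][p].rt for p in shared])
            ay = np.array([msms_peptides[acceptor][p].rt for p in shared])
            fit = _fit_alignment(dx, ay, params.rt_align_window)
            if fit is None:
                continue
            ux, uy = fit
            pool = available[acceptor]
            for pep in sorted(msms_peptides[donor]):
                if pep in msms_peptides[acceptor] or pep in transferred[acceptor]:
                    continue
                f = msms_peptides[donor][pep]
                pred_rt = float(np.interp(f.rt, ux, uy))
                best_i, best_drt = -1, params.match_window
                for i, cand in enumerate(pool):
                    if cand is None:
                        continue
                    cmz, crt, _ = cand
                    if abs(cmz - f.mz) > f.mz * params.mbr_mz_tol_ppm * 1e-6:
                        continue
                    drt = abs(crt - pred_rt)
                    if drt <= best_drt:
                        best_drt = drt
                        best_i = i
                if best_i < 0:
                    continue
                cmz, crt, cint = pool[best_i]
                pool[best_i] = None
                transferred[acceptor].add(pep)
                out[acceptor].append(
                    PeptideFeature(
                        peptide=pep,
                        sample_id=acceptor,
                        intensity=float(cint),
                        rt=float(crt),
                        mz=float(cmz),
                        charge=f.charge,
                        id_type="matched",
                    )
                )
    return out


def peptide_sample_matrix(features: Iterable[PeptideFeature]) -> pd.DataFrame:
    """Summed feature intensity per (peptide, sample); absent = NaN."""
    totals: dict[tuple[str, str], float] = {}
    for f in features:
        if f.intensity <= 0:
            continue
        key = (f.peptide, f.sample_id)
        totals[key] = totals.get(key, 0.0) + f.intensity
    if not totals:
        return pd.DataFrame()
    peptides = sorted({k[0] for k in totals})
    samples = sorted({k[1] for k in totals})
    mat = pd.DataFrame(np.nan, index=peptides, columns=samples)
    for (pep, sid), v in totals.items():
        mat.at[pep, sid] = v
    return mat


def _solve_component(
    samples: list[int], ratios: dict[tuple[int, int], float]
) -> dict[int, float]:
    """Least-squares log2 abundances from pairwise median ratios."""
    if len(samples) == 1:
        return {samples[0]: 0.0}
    pos = {s: i for i, s in enumerate(samples)}
    rows = []
    rhs = []
    for (i, j), r in sorted(ratios.items()):
        if i in pos and j in pos:
            row = np.zeros(len(samples))
            row[pos[i]] = 1.0
            row[pos[j]] = -1.0
            rows.append(row)
            rhs.append(r)
    # anchor: mean log-abundance zero
    rows.append(np.ones(len(samples)) / len(samples))
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return {s: float(sol[pos[s]]) for s in samples}


def maxlfq(
    groups: Sequence[ProteinGroup],
    features: Iterable[PeptideFeature],
    params: QuantParams | None = None,
) -> pd.DataFrame:
    """MaxLFQ-style protein-group intensities (groups x samples).

    Per group, pairwise sample ratios are medians of log2 peptide ratios
    over peptides quantified in both samples (at least
    ``min_ratio_count`` such peptides required); per connected component
    of the ratio graph, log-abundances solve the pairwise system in the
    least-squares sense and are rescaled so the summed LFQ equals the
    summed raw intensity.  Samples outside any connected component stay
    missing (NaN).  The result is also stored on each group's ``lfq``.
    """
    params = params or QuantParams()
    mat = peptide_sample_matrix(features)
    samples = list(mat.columns) if not mat.empty else []
    lfq = pd.DataFrame(np.nan, index=[g.group_id for g in groups], columns=samples)
    for g in groups:
        peps = sorted(g.quant_peptides & set(mat.index)) if samples else []
        if not peps:
            g.lfq = {}
            continue
        sub = mat.loc[peps].to_numpy(dtype=float)
        present = ~np.isnan(sub)
        n = len(samples)
        ratios: dict[tuple[int, int], float] = {}
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                both = present[:, i] & present[:, j]
                if both.sum() >= params.min_ratio_count and both.any():
                    ratios[(i, j)] = float(
                        np.median(np.log2(sub[both, i]) - np.log2(sub[both, j]))
                    )
                    adj[i].add(j)
                    adj[j].add(i)
        has_data = {i for i in range(n) if present[:, i].any()}
        # connected components over samples with data
        seen: set[int] = set()
        for start in sorted(has_data):
            if start in seen:
                continue
            comp = []
            stack = [start]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(v for v in adj[u] if v not in seen)
            comp = sorted(set(comp) & has_data)
            if not comp:
                continue
            sol = _solve_component(comp, ratios)
            raw_total = np.nansum(sub[:, comp])
            rel = np.array([2.0 ** sol[s] for s in comp])
            scale = raw_total / rel.sum() if rel.sum() > 0 else 0.0
            for s, r in zip(comp, rel):
                lfq.at[g.group_id, samples[s]] = r * scale
        g.lfq = {
            s: float(lfq.at[g.group_id, s])
            for s in samples
            if not np.isnan(lfq.at[g.group_id, s])
        }
    return lfq
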