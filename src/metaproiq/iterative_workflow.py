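"""The iterative two-step search strategy with target-decoy FDR control.

Step 1 searches each sample against the full (target-only) gene catalog
with a loose expect threshold and extracts every matched protein as the
sample-specific reduced database.  Step 2 appends reversed decoys to the
reduced database and re-searches, filtering peptide-spectrum matches at a
q-value cutoff (default 0.01) and a maximum expect value (default 0.05).
The per-sample identified-protein lists are pooled into a combined
non-redundant database against which every run is searched once more for
quantification (step 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog_store import (
    ProteinDatabase,
    ProteinRecord,
    add_decoys,
    build_combined_nr,
    build_reduced_db,
    write_fasta,
)
from .digestion import DigestParams, PeptideIndex, build_index
from .psm_search import PSM, SearchParams, psms_to_rows, search_run
from .protein_inference_quant import (
    PeptideFeature,
    ProteinGroup,
    QuantParams,
    assign_razor,
    extract_feature,
    group_proteins,
    match_between_runs,
    maxlfq,
)
from .spectra_io import Run


@dataclass(frozen=True)
class FdrParams:
    """FDR-control thresholds for the two-step strategy.

    ``step1_max_expect`` is deliberately loose: step 1 is a
    recall-oriented database reduction; FDR control happens in step 2.
    """

    fdr_cutoff: float = 0.01
    max_expect: float = 0.05
    step1_max_expect: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must be in (0, 1)")


@dataclass
class IdentifiedList:
    """Post-FDR identifications of one sample."""

    sample_id: str
    psms: list[PSM] = field(default_factory=list)  # passing PSMs
    peptides: dict[str, PSM] = field(default_factory=dict)  # sequence -> best passing PSM
    proteins: ProteinDatabase = field(default_factory=lambda: ProteinDatabase(stage="sample_list"))
    qvalues: dict[str, float] = field(default_factory=dict)  # scan_id -> q


def step1_reduce(
    run: Run,
    catalog: ProteinDatabase,
    dparams: DigestParams | None = None,
    sparams: SearchParams | None = None,
    fparams: FdrParams | None = None,
    index: PeptideIndex | None = None,
) -> ProteinDatabase:
    """First-pass reduction of the catalog to a sample-specific database.

    All proteins mapped by any PSM with ``expect <= step1_max_expect``
    are extracted; no FDR filtering happens here.
    """
    if catalog.has_decoys:
        raise ValueError("step 1 searches the target-only catalog")
    fparams = fparams or FdrParams()
    psms = search_run(run, catalog, dparams, sparams, index=index)
    matched: set[str] = set()
    for p in psms:
        if p.expect <= fparams.step1_max_expect:
            matched.update(p.protein_accessions)
    return build_reduced_db(catalog, matched) if matched else ProteinDatabase(stage="sample_reduced")


def compute_qvalues(psms: Sequence[PSM]) -> list[tuple[PSM, float]]:
    """Target-decoy q-values over one sample's best-per-spectrum PSMs.

    PSMs are sorted by descending hyperscore; the running FDR at rank i
    is ``#decoys / max(1, #targets)`` and the q-value is the minimum FDR
    at that rank or any worse-scoring rank (monotone non-decreasing down
    the sorted list).
    """
    ordered = sorted(psms, key=lambda p: (-p.hyperscore, p.expect, p.peptide.sequence, p.peptide.mods))
    fdrs = []
    n_t = n_d = 0
    for p in ordered:
        if p.is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / max(1, n_t))
    out: list[tuple[PSM, float]] = []
    running_min = float("inf")
    for p, f in zip(reversed(ordered), reversed(fdrs)):
        running_min = min(running_min, f)
        out.append((p, running_min))
    out.reverse()
    return out


def filter_psms(psms: Sequence[PSM], fparams: FdrParams) -> tuple[list[PSM], dict[str, float]]:
    """Apply the q-value + expect + target filter; return passing PSMs and q map."""
    with_q = compute_qvalues(psms)
    qmap = {p.scan_id: q for p, q in with_q}
    passing = [
        p
        for p, q in with_q
        if q <= fparams.fdr_cutoff and p.expect <= fparams.max_expect and not p.is_decoy
    ]
    return passing, qmap


def step2_identify(
    run: Run,
    reduced: ProteinDatabase,
    dparams: DigestParams | None = None,
    sparams: SearchParams | None = None,
    fparams: FdrParams | None = None,
) -> IdentifiedList:
    """Target-decoy search of the reduced database with strict filtering."""
    fparams = fparams or FdrParams()
    out = IdentifiedList(sample_id=run.sample_id)
    if len(reduced) == 0:
        warnings.warn(f"sample {run.sample_id}: empty reduced database", stacklevel=2)
        return out
    with_decoys = add_decoys(reduced)
    psms = search_run(run, with_decoys, dparams, sparams)
    passing, qmap = filter_psms(psms, fparams)
    out.qvalues = qmap
    out.psms = passing
    for p in passing:
        prev = out.peptides.get(p.peptide.sequence)
        if prev is None or p.hyperscore > prev.hyperscore:
            out.peptides[p.peptide.sequence] = p
    accessions: set[str] = set()
    for p in passing:
        accessions.update(a for a in p.protein_accessions if a in reduced)
    out.proteins = ProteinDatabase(stage="sample_list")
    for record in reduced:
        if record.accession in accessions:
            out.proteins.add(record)
    return out


@dataclass
class WorkflowResult:
    """Everything the iterative workflow produces for one study."""

    combined_nr: ProteinDatabase
    identified: dict[str, IdentifiedList]
    step3_psms: dict[str, list[PSM]]
    features: dict[str, list[PeptideFeature]]
    groups: list[ProteinGroup]
    lfq: pd.DataFrame
    peptide_table: pd.DataFrame
    protein_table: pd.DataFrame
    identification_rate: dict[str, float]
    reduced_sizes: dict[str, int]


def run_workflow(
    runs: Sequence[Run],
    catalog: ProteinDatabase,
    dparams: DigestParams | None = None,
    sparams: SearchParams | None = None,
    fparams: FdrParams | None = None,
    qparams: QuantParams | None = None,
    outdir: str | Path | None = None,
) -> WorkflowResult:
    """Execute the full pipeline over a set of runs.

    Steps 1-2 run per sample against the catalog; the per-sample
    identified-protein lists are pooled into the combined non-redundant
    database; step 3 searches every run against that database (plus
    decoys), extracts precursor features, transfers identifications
    between runs, groups proteins and computes MaxLFQ-style intensities.
    """
    if not runs:
        raise ValueError("at least one run required")
    dparams = dparams or DigestParams()
    sparams = sparams or SearchParams()
    fparams = fparams or FdrParams()
    qparams = qparams or QuantParams()

    catalog_index = build_index(catalog, dparams)
    identified: dict[str, IdentifiedList] = {}
    reduced_sizes: dict[str, int] = {}
    for run in runs:
        try:
            reduced = step1_reduce(run, catalog, dparams, sparams, fparams, index=catalog_index)
            reduced_sizes[run.sample_id] = len(reduced)
            identified[run.sample_id] = step2_identify(run, reduced, dparams, sparams, fparams)
        except Exception as exc:
            raise RuntimeError(f"sample {run.sample_id}: {exc}") from exc

    combined = build_combined_nr([identified[r.sample_id].proteins for r in runs])

    step3_psms: dict[str, list[PSM]] = {}
    features: dict[str, list[PeptideFeature]] = {}
    candidate_pools: dict[str, list[tuple[float, float, float]]] = {}
    id_rate: dict[str, float] = {}
    if len(combined):
        quant_db = add_decoys(combined)
        quant_index = build_index(quant_db, dparams)
        for run in runs:
            psms = search_run(run, quant_db, dparams, sparams, index=quant_index)
            passing, _ = filter_psms(psms, fparams)
            step3_psms[run.sample_id] = passing
            id_rate[run.sample_id] = len(passing) / max(1, len(run.spectra))
            feats = []
            for p in passing:
                f = extract_feature(run, p)
                if f is not None:
                    feats.append(f)
            features[run.sample_id] = feats
            passing_scans = {p.scan_id for p in passing}
            candidate_pools[run.sample_id] = [
                (s.precursor_mz, s.rt, s.precursor_intensity if s.precursor_intensity else 0.0)
                for s in run.spectra
                if s.scan_id not in passing_scans
            ]
    else:
        for run in runs:
            step3_psms[run.sample_id] = []
            features[run.sample_id] = []
            id_rate[run.sample_id] = 0.0

    if len(runs) > 1 and len(combined):
        features = match_between_runs(features, candidate_pools, qparams)

    # protein grouping over identified peptides (targets only)
    pep_prot: dict[str, set[str]] = {}
    psm_counts: dict[str, int] = {}
    for sample_id, psms in sorted(step3_psms.items()):
        for p in psms:
            targets = {a for a in p.protein_accessions if a in combined}
            if not targets:
                continue
            pep_prot.setdefault(p.peptide.sequence, set()).update(targets)
            psm_counts[p.peptide.sequence] = psm_counts.get(p.peptide.sequence, 0) + 1
    lengths = {r.accession: len(r.sequence) for r in combined}
    groups = group_proteins(pep_prot, psm_counts=psm_counts, protein_lengths=lengths)
    assign_razor(groups, psm_counts=psm_counts)
    all_features = [f for sid in sorted(features) for f in features[sid]]
    lfq = maxlfq(groups, all_features, qparams)

    peptide_table = _peptide_table(features, sorted(f.sample_id for f in all_features))
    protein_table = _protein_table(groups, lfq)

    result = WorkflowResult(
        combined_nr=combined,
        identified=identified,
        step3_psms=step3_psms,
        features=features,
        groups=groups,
        lfq=lfq,
        peptide_table=peptide_table,
        protein_table=protein_table,
        identification_rate=id_rate,
        reduced_sizes=reduced_sizes,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _peptide_table(features: dict[str, list[PeptideFeature]], _samples) -> pd.DataFrame:
    samples = sorted(features)
    rows: dict[str, dict[str, object]] = {}
    for sid in samples:
        for f in features[sid]:
            row = rows.setdefault(f.peptide, {"sequence": f.peptide})
            key = f"intensity_{sid}"
            row[key] = row.get(key, 0.0) + f.intensity
            id_key = f"id_type_{sid}"
            # an MS/MS identification outranks a transferred one
            if row.get(id_key) != "msms":
                row[id_key] = f.id_type
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["sequence"]))
    if df.empty:
        return pd.DataFrame(columns=["sequence"])
    cols = ["sequence"] + [f"intensity_{s}" for s in samples] + [f"id_type_{s}" for s in samples]
    return df.reindex(columns=cols)


def _protein_table(groups: list[ProteinGroup], lfq: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for g in sorted(groups, key=lambda g: g.group_id):
        row = {
            "group_id": g.group_id,
            "members": ";".join(g.members),
            "leading": g.leading,
            "n_peptides": len(g.peptides),
        }
        if g.group_id in lfq.index:
            for s in lfq.columns:
                row[f"lfq_{s}"] = lfq.at[g.group_id, s]
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: WorkflowResult, outdir: str | Path) -> None:
    """Write the standard output files (TSV tables + FASTA databases)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.combined_nr, outdir / "combined_nr.fasta")
    for sample_id in sorted(result.identified):
        idl = result.identified[sample_id]
        pd.DataFrame(psms_to_rows(idl.psms)).to_csv(
            outdir / f"{sample_id}_psms.tsv", sep="\t", index=False
        )
        write_fasta(idl.proteins, outdir / f"{sample_id}_proteins.fasta")
    result.peptide_table.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    result.protein_table.to_csv(outdir / "proteinGroups.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        {
            "sample_id": sorted(result.identification_rate),
            "n_spectra_identified": [
                len(result.step3_psms[s]) for s in sorted(result.identification_rate)
            ],
            "identification_rate": [
                result.identification_rate[s] for s in sorted(result.identification_rate)
            ],
            "reduced_db_size": [
                result.reduced_sizes.get(s, 0) for s in sorted(result.identification_rate)
            ],
        }
    )
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
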