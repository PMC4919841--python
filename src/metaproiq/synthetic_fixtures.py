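"""Ground-truth synthetic metaproteomic studies.

The generator emulates the statistical structure of a two-group
(high-fat vs low-fat diet style) gut-microbiome experiment at desk
scale: a random protein catalog partitioned over a small taxonomy, a
true community expressed per sample, peptide-level precursor intensities
with log-normal biological variation and optional group-wise phylum or
protein multipliers, b/y-ladder MS/MS spectra with ppm jitter inside the
instrument tolerances, score-plausible noise spectra, and
match-between-runs-recoverable dropouts (the precursor survives, the
fragment evidence does not).  Every draw flows from one mandatory seed;
per-sample streams are derived sub-streams, so studies regenerate
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_store import ProteinDatabase, ProteinRecord, write_fasta
from .digestion import (
    CARBAMIDOMETHYL,
    DigestParams,
    Peptide,
    digest,
    precursor_mz,
)
from .functional_taxonomic import Taxonomy, TaxonNode
from .protein_inference_quant import PeptideFeature
from .psm_search import fragment_mzs
from .spectra_io import Run, Spectrum, write_mgf

AA_FREQS = {
    "A": 0.08, "C": 0.01, "D": 0.05, "E": 0.06, "F": 0.04,
    "G": 0.08, "H": 0.02, "I": 0.05, "K": 0.06, "L": 0.10,
    "M": 0.02, "N": 0.04, "P": 0.04, "Q": 0.04, "R": 0.05,
    "S": 0.08, "T": 0.06, "V": 0.08, "W": 0.01, "Y": 0.03,
}

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Verrucomicrobia")
COG_LETTERS = "CEGHIJKLMNOPQSTUV"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community study.

    The defaults describe the reference desk-scale benchmark: a
    1000-protein catalog of which 100 proteins are truly expressed,
    eight observable peptides per true protein (800 peptide spectra) plus
    400 noise spectra per sample.  ``fragment_keep_prob`` and the weak-
    spectrum fraction put a realistic share of spectra in the marginal-
    scoring regime; jitters sit inside the 10/20 ppm search tolerances.
    """

    seed: int
    n_catalog: int = 1000
    n_true: int = 100
    n_samples: int = 1
    group_of: tuple[str, ...] = ("A",)
    peptides_per_protein: int = 8
    n_noise_spectra: int = 400
    dropout_rate: float = 0.0
    intensity_cv: float = 0.0
    phylum_multipliers: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    n_differential: int = 0
    differential_fold: float = 4.0
    protein_length: tuple[int, int] = (100, 600)
    charge: int = 2
    fragment_keep_prob: float = 0.7
    weak_fraction: float = 0.15
    weak_keep_prob: float = 0.35
    frag_jitter_ppm: float = 5.0
    precursor_jitter_ppm: float = 3.0
    rt_span: tuple[float, float] = (10.0, 230.0)
    noise_precursor: str = "catalog"  # "catalog" | "uniform"

    def __post_init__(self) -> None:
        for frac in (self.dropout_rate, self.weak_fraction, self.fragment_keep_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if len(self.group_of) != self.n_samples:
            raise ValueError("group_of must name one group per sample")

    @property
    def group_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.group_of:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def phylum_multiplier(self, group: str, phylum: str) -> float:
        for g, pairs in self.phylum_multipliers:
            if g == group:
                for p, m in pairs:
                    if p == phylum:
                        return m
        return 1.0


@dataclass
class SyntheticCatalog:
    db: ProteinDatabase
    taxonomy: Taxonomy
    accession_to_taxon: dict[str, str]
    accession_to_species: dict[str, str]
    accession_to_phylum: dict[str, str]
    cog_annotation: dict[str, tuple[str, str]]


@dataclass
class SyntheticStudy:
    runs: list[Run]
    truth_peptides: pd.DataFrame
    truth_proteins: pd.DataFrame
    group_of: dict[str, str]
    spec: CommunitySpec


def _default_taxonomy() -> tuple[Taxonomy, list[str]]:
    """A fixed 5-phylum / 20-species tree; returns (tree, species ids)."""
    nodes = [
        TaxonNode("root", "root", "root", None),
        TaxonNode("sk_bacteria", "Bacteria", "superkingdom", "root"),
    ]
    species_ids: list[str] = []
    for phylum in PHYLA:
        pid = f"p_{phylum}"
        nodes.append(TaxonNode(pid, phylum, "phylum", "sk_bacteria"))
        for gi in (1, 2):
            gid = f"g_{phylum}_{gi}"
            nodes.append(TaxonNode(gid, f"{phylum} genus {gi}", "genus", pid))
            for si in (1, 2):
                sid = f"s_{phylum}_{gi}_{si}"
                nodes.append(TaxonNode(sid, f"{phylum} sp. {gi}-{si}", "species", gid))
                species_ids.append(sid)
    return Taxonomy(nodes), species_ids


def make_catalog(spec: CommunitySpec) -> SyntheticCatalog:
    """Random protein catalog with taxonomic and COG labels.

    Proteins (length 100-600) are assigned uniformly to species leaves;
    ~85 % receive a COG id with one (occasionally two) category letters.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 101])
    taxonomy, species = _default_taxonomy()
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    db = ProteinDatabase(stage="catalog")
    seen: set[str] = set()
    acc_taxon: dict[str, str] = {}
    acc_species: dict[str, str] = {}
    acc_phylum: dict[str, str] = {}
    annotation: dict[str, tuple[str, str]] = {}
    i = 0
    while len(db) < spec.n_catalog:
        length = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        if seq in seen:
            continue
        seen.add(seq)
        acc = f"SYN_{i:05d}"
        i += 1
        db.add(ProteinRecord(acc, seq, origin="synthetic_catalog"))
        sid = species[int(rng.integers(len(species)))]
        acc_taxon[acc] = sid
        acc_species[acc] = taxonomy.name_of(sid)
        acc_phylum[acc] = sid.split("_")[1]
        if rng.random() < 0.85:
            n_cat = 2 if rng.random() < 0.1 else 1
            cats = "".join(rng.choice(list(COG_LETTERS), size=n_cat, replace=False))
            annotation[acc] = (f"COG{int(rng.integers(1, 5000)):04d}", cats)
    return SyntheticCatalog(db, taxonomy, acc_taxon, acc_species, acc_phylum, annotation)


def _select_peptides(
    record: ProteinRecord, k: int, rng: np.random.Generator, params: DigestParams
) -> list[Peptide]:
    """Up to ``k`` fully-tryptic, oxidation-free peptide forms of a protein."""
    forms = [
        p
        for p in digest(record, params)
        if p.missed_cleavages == 0
        and len(p.sequence) <= 25
        and all(d == CARBAMIDOMETHYL for _, d in p.mods)
    ]
    forms = sorted({p.key: p for p in forms}.values(), key=lambda p: p.sequence)
    if len(forms) <= k:
        return forms
    idx = rng.choice(len(forms), size=k, replace=False)
    return [forms[j] for j in sorted(idx)]


def make_study(spec: CommunitySpec, catalog: SyntheticCatalog) -> SyntheticStudy:
    """Plant a community, emit per-sample MS/MS runs plus truth tables."""
    master = np.random.default_rng([spec.seed, 202])
    params = DigestParams()
    accs = catalog.db.accessions
    order = master.permutation(len(accs))
    true_accs = [accs[i] for i in order[: spec.n_true]]

    # differential proteins preferentially come from phyla without a
    # group multiplier so the two planted effects do not confound
    shifted_phyla = {p for _, pairs in spec.phylum_multipliers for p, _ in pairs}
    neutral = [a for a in true_accs if catalog.accession_to_phylum[a] not in shifted_phyla]
    non_neutral = [a for a in true_accs if a not in set(neutral)]
    diff_pool = neutral + non_neutral
    differential = {
        acc: (1 if j % 2 == 0 else -1) for j, acc in enumerate(diff_pool[: spec.n_differential])
    }

    base_abundance = {a: 10.0 ** master.normal(7.0, 0.5) for a in true_accs}
    peptide_plan: dict[str, list[tuple[Peptide, float, float]]] = {}
    for acc in true_accs:
        peps = _select_peptides(catalog.db.get(acc), spec.peptides_per_protein, master, params)
        plan = []
        for pep in peps:
            factor = 10.0 ** master.normal(0.0, 0.3)
            base_rt = master.uniform(*spec.rt_span)
            plan.append((pep, factor, base_rt))
        peptide_plan[acc] = plan

    # precursor pool for catalog-anchored noise spectra
    noise_masses = None
    if spec.n_noise_spectra and spec.noise_precursor == "catalog":
        pool_accs = [accs[i] for i in order[spec.n_true : spec.n_true + 200]]
        masses = []
        for acc in pool_accs:
            for pep in _select_peptides(catalog.db.get(acc), 4, master, params):
                masses.append(pep.mono_mass)
        noise_masses = np.array(sorted(masses))

    runs: list[Run] = []
    truth_pep_rows: list[dict] = []
    truth_prot_rows: list[dict] = []
    group_of: dict[str, str] = {}
    sigma_ln = spec.intensity_cv  # lognormal sigma ~ CV for small CV

    for si in range(spec.n_samples):
        group = spec.group_of[si]
        sample_id = f"S{si + 1:02d}"
        group_of[sample_id] = group
        rng = np.random.default_rng([spec.seed, 303, si])
        rt_slope = 1.0 + rng.normal(0.0, 0.01)
        rt_offset = rng.normal(0.0, 1.0)
        spectra: list[Spectrum] = []
        scan = 0
        for acc in true_accs:
            phylum = catalog.accession_to_phylum[acc]
            mult = spec.phylum_multiplier(group, phylum)
            sign = differential.get(acc, 0)
            if sign and group == spec.group_labels[0]:
                mult *= spec.differential_fold if sign > 0 else 1.0 / spec.differential_fold
            abundance = base_abundance[acc] * mult
            truth_prot_rows.append(
                {
                    "sample_id": sample_id,
                    "accession": acc,
                    "abundance": abundance,
                    "phylum": phylum,
                    "species": catalog.accession_to_species[acc],
                    "differential": sign,
                }
            )
            for pep, factor, base_rt in peptide_plan[acc]:
                intensity = abundance * factor
                if sigma_ln > 0:
                    intensity *= float(np.exp(rng.normal(0.0, sigma_ln)))
                rt = rt_slope * base_rt + rt_offset + rng.normal(0.0, 0.05)
                mz = precursor_mz(pep.mono_mass, spec.charge)
                mz_obs = mz * (1.0 + rng.normal(0.0, spec.precursor_jitter_ppm * 1e-6))
                weak = rng.random() < spec.weak_fraction
                keep_p = spec.weak_keep_prob if weak else spec.fragment_keep_prob
                b, y = fragment_mzs(pep)
                frags = np.concatenate([b, y])
                keep = rng.random(frags.size) < keep_p
                if keep.sum() < 3:
                    keep[rng.choice(frags.size, size=3, replace=False)] = True
                fmz = frags[keep] * (
                    1.0 + rng.normal(0.0, spec.frag_jitter_ppm * 1e-6, size=int(keep.sum()))
                )
                fint = rng.uniform(0.2, 1.0, size=fmz.size) * 1.0e4
                status = "weak" if weak else "clean"
                if rng.random() < spec.dropout_rate:
                    status = "dropout"
                    fmz = np.sort(rng.uniform(200.0, 1500.0, size=fmz.size))
                scan_id = f"{sample_id}_{scan:05d}"
                scan += 1
                spectra.append(
                    Spectrum(
                        scan_id=scan_id,
                        precursor_mz=float(mz_obs),
                        charge=spec.charge,
                        rt=float(max(rt, 0.0)),
                        mz=fmz,
                        intensity=fint,
                        precursor_intensity=float(intensity),
                    )
                )
                truth_pep_rows.append(
                    {
                        "sample_id": sample_id,
                        "scan_id": scan_id,
                        "peptide": pep.sequence,
                        "mods": pep.mods_str,
                        "protein": acc,
                        "charge": spec.charge,
                        "mz": mz,
                        "rt": rt,
                        "intensity": intensity,
                        "status": status,
                    }
                )
        n_real = len(spectra)
        for _ in range(spec.n_noise_spectra):
            template = spectra[int(rng.integers(n_real))] if n_real else None
            n_peaks = template.n_peaks if template is not None else int(rng.integers(8, 25))
            fint = (
                rng.permutation(template.intensity)
                if template is not None
                else rng.uniform(0.2, 1.0, size=n_peaks) * 1.0e4
            )
            fmz = np.sort(rng.uniform(200.0, 1500.0, size=n_peaks))
            if noise_masses is not None and noise_masses.size:
                mass = float(noise_masses[int(rng.integers(noise_masses.size))])
            else:
                mass = float(rng.uniform(700.0, 2500.0))
            mz_obs = precursor_mz(mass, spec.charge) * (
                1.0 + rng.normal(0.0, spec.precursor_jitter_ppm * 1e-6)
            )
            scan_id = f"{sample_id}_{scan:05d}"
            scan += 1
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    precursor_mz=float(mz_obs),
                    charge=spec.charge,
                    rt=float(rng.uniform(*spec.rt_span)),
                    mz=fmz,
                    intensity=np.asarray(fint, dtype=float),
                    precursor_intensity=float(rng.uniform(0.5, 2.0) * 1.0e5),
                )
            )
            truth_pep_rows.append(
                {
                    "sample_id": sample_id,
                    "scan_id": scan_id,
                    "peptide": "",
                    "mods": "",
                    "protein": "",
                    "charge": spec.charge,
                    "mz": mz_obs,
                    "rt": 0.0,
                    "intensity": 0.0,
                    "status": "noise",
                }
            )
        runs.append(Run(sample_id=sample_id, spectra=spectra))

    return SyntheticStudy(
        runs=runs,
        truth_peptides=pd.DataFrame(truth_pep_rows),
        truth_proteins=pd.DataFrame(truth_prot_rows),
        group_of=group_of,
        spec=spec,
    )


def write_study(
    study: SyntheticStudy, catalog: SyntheticCatalog, outdir: str | Path
) -> dict[str, Path]:
    """Write the study in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_fasta(catalog.db, outdir / "catalog.fasta")
    paths["catalog"] = outdir / "catalog.fasta"
    catalog.taxonomy.to_table(outdir / "taxonomy.tsv")
    paths["taxonomy"] = outdir / "taxonomy.tsv"
    pd.DataFrame(
        [
            {"accession": a, "cog_id": cid, "cog_category": cats}
            for a, (cid, cats) in sorted(catalog.cog_annotation.items())
        ]
    ).to_csv(outdir / "cog_annotation.tsv", sep="\t", index=False)
    paths["cog_annotation"] = outdir / "cog_annotation.tsv"
    pd.DataFrame(
        [{"accession": a, "taxon_id": t} for a, t in sorted(catalog.accession_to_taxon.items())]
    ).to_csv(outdir / "taxon_map.tsv", sep="\t", index=False)
    paths["taxon_map"] = outdir / "taxon_map.tsv"
    manifest = []
    for run in study.runs:
        mgf_path = outdir / f"{run.sample_id}.mgf"
        write_mgf(run, mgf_path)
        manifest.append(
            {
                "sample_id": run.sample_id,
                "path": mgf_path.name,
                "group": study.group_of[run.sample_id],
            }
        )
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.tsv"
    study.truth_peptides.to_csv(outdir / "truth_peptides.tsv", sep="\t", index=False)
    study.truth_proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t", index=False)
    return paths


@dataclass
class FeatureStudy:
    """Feature-level synthetic study for quantification benchmarks."""

    features_by_run: dict[str, list[PeptideFeature]]
    candidates_by_run: dict[str, list[tuple[float, float, float]]]
    pep_prot_map: dict[str, set[str]]
    truth: pd.DataFrame  # protein x sample planted abundance
    n_dropouts: int


def make_feature_study(
    seed: int,
    n_proteins: int = 10,
    n_samples: int = 6,
    peptides_per_protein: int = 5,
    cv: float = 0.0,
    dropout_rate: float = 0.0,
    abundance_log10_sd: float = 0.5,
) -> FeatureStudy:
    """Planted precursor features with optional MBR-recoverable dropouts.

    Each dropout removes the MS/MS feature but leaves an unidentified
    precursor candidate at the (run-shifted) retention time and the same
    m/z, which match-between-runs should recover from any sibling run.
    Proteins have disjoint peptide sets so the truth mapping is exact.
    """
    rng = np.random.default_rng([seed, 404])
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    rt_shift = {s: rng.normal(0.0, 2.0) for s in samples}
    aa = np.array(list("ACDEFGHLMNPQSTVWY"))  # no K/R/I: fully tryptic after suffix K
    features: dict[str, list[PeptideFeature]] = {s: [] for s in samples}
    candidates: dict[str, list[tuple[float, float, float]]] = {s: [] for s in samples}
    pep_prot: dict[str, set[str]] = {}
    truth_rows = []
    n_drop = 0
    for pi in range(n_proteins):
        acc = f"QPROT_{pi:03d}"
        base = {s: 10.0 ** rng.normal(6.0, abundance_log10_sd) for s in samples}
        truth_rows.append({"accession": acc, **base})
        for pj in range(peptides_per_protein):
            pep = "".join(rng.choice(aa, size=int(rng.integers(8, 14)))) + "K"
            pep_prot.setdefault(pep, set()).add(acc)
            factor = 10.0 ** rng.normal(0.0, 0.3)
            mz = float(rng.uniform(400.0, 1200.0))
            base_rt = float(rng.uniform(10.0, 230.0))
            for s in samples:
                intensity = base[s] * factor
                if cv > 0:
                    intensity *= float(np.exp(rng.normal(0.0, cv)))
                rt = base_rt + rt_shift[s] + float(rng.normal(0.0, 0.05))
                if rng.random() < dropout_rate:
                    n_drop += 1
                    candidates[s].append((mz, rt, intensity))
                else:
                    features[s].append(
                        PeptideFeature(
                            peptide=pep,
                            sample_id=s,
                            intensity=float(intensity),
                            rt=rt,
                            mz=mz,
                            id_type="msms",
                        )
                    )
    truth = pd.DataFrame(truth_rows).set_index("accession")[samples]
    return FeatureStudy(features, candidates, pep_prot, truth, n_drop)
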