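"""Functional (COG) and taxonomic (unique-peptide LCA) profiling.

COG annotations arrive as a precomputed best-hit table (accession ->
COG id + single-letter categories); protein-group LFQ intensities are
rolled up per category, falling back from the leading protein to the next
ranked member when the leader has no annotation.  Taxonomy uses a local
lowest-common-ancestor assignment over an I/L-collapsed peptide index
built from taxon-labelled proteins: a peptide is "unique to" the LCA of
all taxa whose proteins contain it, and taxon abundance at a rank is the
summed intensity of peptides whose LCA falls at or below that rank's
node, normalised by the per-sample total peptide intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_store import ProteinDatabase
from .digestion import DigestParams, digest
from .protein_inference_quant import PeptideFeature, ProteinGroup

#: Official single-letter COG functional categories.
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
UNANNOTATED = "?"

RANKS = ("root", "superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: str
    parent: str | None  # None only for the root


class Taxonomy:
    """A rooted taxonomy tree keyed by taxon id."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        self.root: str | None = None
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
            if node.parent is None:
                if self.root is not None:
                    raise ValueError("multiple roots")
                self.root = node.taxon_id
        if self.root is None:
            raise ValueError("taxonomy has no root")
        for node in self.nodes.values():  # acyclicity via lineage walk
            self.lineage(node.taxon_id)

    @classmethod
    def from_table(cls, path: str | Path) -> "Taxonomy":
        """Read a (taxon_id, name, rank, parent) TSV; empty parent = root."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        nodes = [
            TaxonNode(r.taxon_id, r.name, r.rank, r.parent or None)
            for r in df.itertuples(index=False)
        ]
        return cls(nodes)

    def to_table(self, path: str | Path) -> None:
        rows = [
            {"taxon_id": n.taxon_id, "name": n.name, "rank": n.rank, "parent": n.parent or ""}
            for n in self.nodes.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def lineage(self, taxon_id: str) -> list[str]:
        """Root-to-node path of taxon ids."""
        path = []
        tid: str | None = taxon_id
        seen = set()
        while tid is not None:
            if tid in seen:
                raise ValueError(f"cycle at taxon {tid!r}")
            seen.add(tid)
            path.append(tid)
            tid = self.nodes[tid].parent
        return path[::-1]

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty taxon set."""
        ids = sorted(set(taxon_ids))
        if not ids:
            raise ValueError("empty taxon set")
        common = self.lineage(ids[0])
        for tid in ids[1:]:
            lin = self.lineage(tid)
            k = 0
            while k < min(len(common), len(lin)) and common[k] == lin[k]:
                k += 1
            common = common[:k]
        return common[-1]

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        for tid in self.lineage(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def name_of(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name


def collapse_il(sequence: str) -> str:
    """Collapse isoleucine onto leucine (isobaric, indistinguishable by MS)."""
    return sequence.replace("I", "L")


def read_cog_annotation(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read an (accession, cog_id, cog_category) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ann: dict[str, tuple[str, str]] = {}
    for r in df.itertuples(index=False):
        cats = r.cog_category.strip()
        if cats and not set(cats) <= COG_CATEGORIES:
            raise ValueError(f"invalid COG categories {cats!r} for {r.accession}")
        ann[r.accession] = (r.cog_id, cats)
    return ann


def build_tax_index(
    db: ProteinDatabase,
    accession_to_taxon: Mapping[str, str],
    params: DigestParams | None = None,
) -> dict[str, set[str]]:
    """I/L-collapsed peptide -> taxon-id-set index from labelled proteins."""
    params = params or DigestParams()
    index: dict[str, set[str]] = {}
    for record in db:
        taxon = accession_to_taxon.get(record.accession)
        if taxon is None:
            continue
        for pep in digest(record, params):
            index.setdefault(collapse_il(pep.sequence), set()).add(taxon)
    return index


def _tryptic_parts(sequence: str) -> list[str]:
    parts = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < len(sequence) - 1:
            parts.append(sequence[start : i + 1])
            start = i + 1
    parts.append(sequence[start:])
    return [p for p in parts if p]


def lca_assign(
    peptide: str,
    index: Mapping[str, set[str]],
    taxonomy: Taxonomy,
    advanced_missed_cleavage: bool = True,
) -> str | None:
    """LCA taxon of one peptide, or None when unassignable.

    With advanced missed-cleavage handling, a peptide carrying internal
    K/R sites is additionally resolved through its fully-tryptic
    sub-peptides: the taxon sets of all sub-peptides found in the index
    are intersected with the direct hit (when any), mirroring how a
    missed-cleavage variant still pins the same organisms.
    """
    key = collapse_il(peptide)
    taxa = set(index.get(key, set()))
    if advanced_missed_cleavage:
        parts = _tryptic_parts(key)
        if len(parts) > 1:
            part_sets = [index[p] for p in parts if p in index]
            for s in part_sets:
                taxa = (taxa & s) if taxa else set(s)
    if not taxa:
        return None
    return taxonomy.lca(taxa)


def cog_rollup(
    groups: Sequence[ProteinGroup],
    lfq: pd.DataFrame,
    annotation: Mapping[str, tuple[str, str]],
    multi_category: bool = False,
) -> pd.DataFrame:
    """Sum protein-group LFQ intensity per COG category (category x sample).

    Each group is annotated through its leading protein; when the leader
    has no COG match the remaining members are checked in rank order.
    Unannotated groups accumulate under ``?``.  By default only the
    primary (first-listed) category receives the group's intensity, which
    keeps the roll-up conservative (category sums equal total group LFQ);
    ``multi_category=True`` credits the full intensity to every listed
    category instead.
    """
    samples = list(lfq.columns)
    totals: dict[str, np.ndarray] = {}
    for g in groups:
        if g.group_id not in lfq.index:
            continue
        cats = ""
        for acc in g.members:
            entry = annotation.get(acc)
            if entry is not None and entry[1]:
                cats = entry[1]
                break
        row = np.nan_to_num(lfq.loc[g.group_id].to_numpy(dtype=float))
        targets = list(cats) if (multi_category and cats) else [cats[0] if cats else UNANNOTATED]
        for cat in targets:
            totals[cat] = totals.get(cat, np.zeros(len(samples))) + row
    out = pd.DataFrame(totals).T
    if out.empty:
        return pd.DataFrame(columns=samples)
    out.columns = samples
    return out.sort_index()


def taxon_abundance(
    features: Iterable[PeptideFeature],
    assignments: Mapping[str, str | None],
    taxonomy: Taxonomy,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Relative taxon abundance at a rank (taxon-name x sample).

    A peptide counts toward taxon T when its LCA is T or a descendant of
    T.  Intensities are summed per sample and divided by the total
    identified peptide intensity of that sample (unassigned peptides stay
    in the denominator), so columns sum to at most 1.
    """
    totals: dict[str, float] = {}
    taxon_sums: dict[tuple[str, str], float] = {}
    for f in features:
        totals[f.sample_id] = totals.get(f.sample_id, 0.0) + f.intensity
        tid = assignments.get(collapse_il(f.peptide))
        if tid is None:
            continue
        anc = taxonomy.ancestor_at_rank(tid, rank)
        if anc is None:
            continue
        key = (taxonomy.name_of(anc), f.sample_id)
        taxon_sums[key] = taxon_sums.get(key, 0.0) + f.intensity
    samples = sorted(totals)
    taxa = sorted({k[0] for k in taxon_sums})
    out = pd.DataFrame(0.0, index=taxa, columns=samples)
    for (name, sid), v in taxon_sums.items():
        out.at[name, sid] = v / totals[sid]
    return out


def fb_ratio(phylum_matrix: pd.DataFrame) -> pd.Series:
    """Per-sample Firmicutes / Bacteroidetes intensity ratio.

    A zero Bacteroidetes intensity yields NaN (undefined, flagged) rather
    than infinity.  The ratio is invariant to the per-sample total
    normalisation of :func:`taxon_abundance`.
    """
    for phylum in ("Firmicutes", "Bacteroidetes"):
        if phylum not in phylum_matrix.index:
            raise KeyError(f"phylum {phylum!r} absent from matrix")
    f = phylum_matrix.loc["Firmicutes"]
    b = phylum_matrix.loc["Bacteroidetes"]
    return f.where(b > 0) / b.where(b > 0)
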