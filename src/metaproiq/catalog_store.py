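"""Protein sequence databases for metaproteomic searching.

A gut-microbial gene catalog is distributed as a protein FASTA with one
entry per predicted gene.  This module holds the in-memory database
container plus the database transformations the iterative workflow needs:
reversed-decoy generation, per-sample reduction after the first search
pass, and pooling of all samples' identified proteins into a combined
non-redundant database for the final quantification search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Accession prefix marking reversed-decoy entries.  Fixed so that the
#: target/decoy partition at FDR time is unambiguous.
DECOY_PREFIX = "DECOY_"

#: The twenty canonical amino acids.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One catalog (or decoy) protein sequence with provenance.

    Parameters
    ----------
    accession : str
        Unique identifier (first whitespace-delimited FASTA header token).
    sequence : str
        Upper-case amino-acid sequence, stop codons stripped.
    source : str
        ``"target"`` or ``"decoy"``.
    origin : str
        Free-text tag for the database the record came from.
    """

    accession: str
    sequence: str
    source: str = "target"
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        if self.source not in ("target", "decoy"):
            raise ValueError(f"invalid source {self.source!r}")

    @property
    def is_decoy(self) -> bool:
        return self.source == "decoy"


class ProteinDatabase:
    """Ordered collection of :class:`ProteinRecord` with unique accessions.

    ``stage`` tracks the database's role in the workflow:
    ``catalog`` (full gene catalog), ``sample_reduced`` (post step-1),
    ``sample_list`` (post-FDR identified list), ``combined_nr``
    (cross-sample non-redundant union) or ``with_decoys``.
    """

    def __init__(self, records: Iterable[ProteinRecord] = (), stage: str = "catalog"):
        self.stage = stage
        self._records: list[ProteinRecord] = []
        self._by_accession: dict[str, ProteinRecord] = {}
        for record in records:
            self.add(record)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._by_accession:
            raise ValueError(f"duplicate accession {record.accession!r}")
        self._records.append(record)
        self._by_accession[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self._records]

    @property
    def has_decoys(self) -> bool:
        return any(r.is_decoy for r in self._records)

    def targets(self) -> "ProteinDatabase":
        """Target-only view (new database, original stage)."""
        return ProteinDatabase((r for r in self._records if not r.is_decoy), stage=self.stage)


def read_fasta(path: str | Path, stage: str = "catalog", origin: str = "") -> ProteinDatabase:
    """Read a protein FASTA into a :class:`ProteinDatabase`.

    The accession is the first whitespace-delimited header token.
    Sequences are upper-cased and a terminal ``*`` (stop) is stripped.
    Duplicate accessions and empty files are hard errors.
    """
    path = Path(path)
    db = ProteinDatabase(stage=stage)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        accession = rec.id
        source = "decoy" if accession.startswith(DECOY_PREFIX) else "target"
        db.add(ProteinRecord(accession, seq, source=source, origin=origin or path.name))
    if len(db) == 0:
        raise ValueError(f"no FASTA entries in {path}")
    return db


def write_fasta(db: ProteinDatabase | Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``wrap`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for record in db:
            fh.write(f">{record.accession}\n")
            for i in range(0, len(record.sequence), wrap):
                fh.write(record.sequence[i : i + wrap] + "\n")


def add_decoys(db: ProteinDatabase) -> ProteinDatabase:
    """Append a reversed-sequence decoy for every target record.

    The decoy partner carries the ``DECOY_`` accession prefix and the exact
    character reversal of the target sequence (same length and residue
    composition, which keeps the decoy mass distribution matched to the
    target one).  Raises if the input already contains decoys.
    """
    if db.has_decoys:
        raise ValueError("database already contains decoy records")
    out = ProteinDatabase(stage="with_decoys")
    for record in db:
        out.add(record)
    for record in db:
        out.add(
            ProteinRecord(
                DECOY_PREFIX + record.accession,
                record.sequence[::-1],
                source="decoy",
                origin=record.origin,
            )
        )
    return out


def build_reduced_db(catalog: ProteinDatabase, matched_accessions: set[str]) -> ProteinDatabase:
    """Extract the sample-specific database after the first search pass.

    All proteins hit by any first-pass peptide-spectrum match are pulled
    from the catalog, preserving catalog order.  Unknown accessions are a
    hard error; an empty matched set yields an empty database with a
    warning (such a sample produces no identifications downstream).
    """
    unknown = sorted(a for a in matched_accessions if a not in catalog)
    if unknown:
        raise KeyError(f"accessions not in catalog: {', '.join(unknown)}")
    if not matched_accessions:
        warnings.warn("empty matched set: reduced database is empty", stacklevel=2)
    out = ProteinDatabase(stage="sample_reduced")
    for record in catalog:
        if record.accession in matched_accessions:
            out.add(record)
    return out


def build_combined_nr(per_sample_lists: Iterable[ProteinDatabase]) -> ProteinDatabase:
    """Pool per-sample identified-protein lists into one non-redundant DB.

    Records are united across lists and de-duplicated by exact sequence
    identity (the first-seen accession is kept).  Inputs must be
    target-only post-FDR lists.
    """
    out = ProteinDatabase(stage="combined_nr")
    seen: set[str] = set()
    for db in per_sample_lists:
        for record in db:
            if record.is_decoy:
                raise ValueError(f"decoy record {record.accession!r} in identified list")
            if record.sequence in seen:
                continue
            seen.add(record.sequence)
            if record.accession in out:
                # same accession re-identified in another sample with a new
                # sequence cannot happen for a shared catalog; guard anyway
                continue
            out.add(replace(record))
    return out
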