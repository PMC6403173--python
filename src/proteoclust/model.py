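"""Domain types and file I/O for multi-organism proteome sets.

A *proteome set* bundles the deduced protein sequences of several organisms
with their genomic context (replicon, coordinates, strand) and free-text
annotation labels.  Sequences arrive as amino-acid FASTA; the genomic context
arrives as a sidecar tab-separated table keyed by sequence id.  Clusterings
are persisted as a flat "cluster text file" (TSV) with one row per sequence.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

#: the 20 standard residues plus the ambiguity code X
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

TAXON_CLASSES = ("alpha", "beta", "gamma", "delta_epsilon", "other")
REPLICON_TYPES = ("chromosome", "plasmid")
STRANDS = ("+", "-")

METADATA_COLUMNS = [
    "seq_id", "organism_id", "organism_name", "taxon_class",
    "replicon_id", "replicon_type", "start", "end", "strand", "annotation",
]

CLUSTER_FILE_COLUMNS = ["cluster_id", "seq_id", "organism_id", "length", "annotation"]


class ProteomeError(ValueError):
    """Raised for malformed or inconsistent proteome inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """One deduced protein with its genomic context.

    Coordinates are 1-based inclusive base-pair positions on the replicon,
    following the GenBank feature convention.  ``replicon_id`` is scoped per
    organism: two organisms may reuse the same replicon name.
    """

    seq_id: str
    organism_id: str
    replicon_id: str
    replicon_type: str
    start: int
    end: int
    strand: str
    annotation: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"record {self.seq_id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ProteomeError(
                f"record {self.seq_id!r}: invalid residues {sorted(bad)}"
            )
        if self.replicon_type not in REPLICON_TYPES:
            raise ProteomeError(
                f"record {self.seq_id!r}: replicon_type {self.replicon_type!r}"
            )
        if self.strand not in STRANDS:
            raise ProteomeError(f"record {self.seq_id!r}: strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ProteomeError(
                f"record {self.seq_id!r}: bad coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        """Protein length in amino acids."""
        return len(self.sequence)


@dataclass(frozen=True)
class Organism:
    organism_id: str
    name: str
    taxon_class: str = "other"
    genome_size_bp: int | None = None
    gc_content: float | None = None

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ProteomeError(
                f"organism {self.organism_id!r}: taxon_class {self.taxon_class!r}"
            )
        if self.genome_size_bp is not None and self.genome_size_bp <= 0:
            raise ProteomeError(f"organism {self.organism_id!r}: genome_size_bp <= 0")
        if self.gc_content is not None and not (0.0 <= self.gc_content <= 1.0):
            raise ProteomeError(f"organism {self.organism_id!r}: gc_content not in [0,1]")


@dataclass
class ProteomeSet:
    """All organisms and protein records of one study.

    ``records`` is keyed by seq_id (unique across the whole set); every
    record's organism must be present in ``organisms``.
    """

    organisms: dict[str, Organism] = field(default_factory=dict)
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {r.organism_id for r in self.records.values()} - set(self.organisms)
        if missing:
            raise ProteomeError(f"records reference unknown organisms: {sorted(missing)}")

    @property
    def n_organisms(self) -> int:
        return len(self.organisms)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def seq_ids(self) -> list[str]:
        return sorted(self.records)

    def lengths(self) -> dict[str, int]:
        return {sid: rec.length for sid, rec in self.records.items()}

    def records_of(self, organism_id: str) -> list[ProteinRecord]:
        return [r for r in self.records.values() if r.organism_id == organism_id]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an amino-acid FASTA file into ``[(seq_id, sequence), ...]``.

    The seq_id is the header token up to the first whitespace.  Sequences are
    uppercased; a terminal ``*`` stop character is stripped.  Duplicate ids
    and residues outside the 20-letter alphabet plus X are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ProteomeError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}"
                )
            break
    else:
        return []

    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO("\n".join(lines)), "fasta"):
        seq_id = rec.id
        if not seq_id:
            raise ProteomeError(f"{path}: record with empty header id")
        if seq_id in seen:
            raise ProteomeError(f"{path}: duplicate seq_id {seq_id!r}")
        seen.add(seq_id)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ProteomeError(f"{path}: record {seq_id!r} has empty sequence")
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise ProteomeError(f"{path}: record {seq_id!r}: invalid residues {sorted(bad)}")
        out.append((seq_id, seq))
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in entries:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path, sequences: Iterable[tuple[str, str]]) -> ProteomeSet:
    """Join a metadata TSV with sequences into a validated :class:`ProteomeSet`.

    The TSV must carry the header ``seq_id organism_id organism_name
    taxon_class replicon_id replicon_type start end strand annotation``.
    Every seq_id must appear in both inputs (reconciliation is strict in both
    directions).
    """
    seq_map = dict(sequences)
    if len(seq_map) == 0:
        raise ProteomeError("no sequences supplied")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ProteomeError(f"{path}: missing metadata columns {missing_cols}")

    meta_ids = set(df["seq_id"])
    only_meta = sorted(meta_ids - set(seq_map))
    only_fasta = sorted(set(seq_map) - meta_ids)
    if only_meta or only_fasta:
        raise ProteomeError(
            f"{path}: seq_id mismatch between FASTA and metadata; "
            f"metadata-only={only_meta[:5]} fasta-only={only_fasta[:5]}"
        )
    if len(meta_ids) != len(df):
        dupes = df["seq_id"][df["seq_id"].duplicated()].tolist()
        raise ProteomeError(f"{path}: duplicate seq_id rows {dupes[:5]}")

    organisms: dict[str, Organism] = {}
    records: dict[str, ProteinRecord] = {}
    for row in df.itertuples(index=False):
        if row.organism_id not in organisms:
            organisms[row.organism_id] = Organism(
                organism_id=row.organism_id,
                name=row.organism_name,
                taxon_class=row.taxon_class,
            )
        start, end = int(row.start), int(row.end)
        records[row.seq_id] = ProteinRecord(
            seq_id=row.seq_id,
            organism_id=row.organism_id,
            replicon_id=row.replicon_id,
            replicon_type=row.replicon_type,
            start=start,
            end=end,
            strand=row.strand,
            annotation=row.annotation,
            sequence=seq_map[row.seq_id],
        )
    return ProteomeSet(organisms=organisms, records=records)


def write_metadata(proteome: ProteomeSet, path: str | Path) -> None:
    rows = []
    for sid in proteome.seq_ids():
        r = proteome.records[sid]
        org = proteome.organisms[r.organism_id]
        rows.append(
            (sid, r.organism_id, org.name, org.taxon_class, r.replicon_id,
             r.replicon_type, r.start, r.end, r.strand, r.annotation)
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cluster_file(assignment: Mapping[str, int], proteome: ProteomeSet,
                       path: str | Path) -> None:
    """Write the cluster text file (TSV), rows sorted by (cluster_id, seq_id).

    ``assignment`` must cover exactly the proteome's seq_ids.
    """
    if set(assignment) != set(proteome.records):
        extra = sorted(set(assignment) - set(proteome.records))
        missing = sorted(set(proteome.records) - set(assignment))
        raise ProteomeError(
            f"clustering does not cover the proteome; extra={extra[:5]} missing={missing[:5]}"
        )
    rows = []
    for sid, cid in assignment.items():
        rec = proteome.records[sid]
        rows.append((cid, sid, rec.organism_id, rec.length, rec.annotation))
    rows.sort(key=lambda t: (t[0], t[1]))
    pd.DataFrame(rows, columns=CLUSTER_FILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cluster_file(path: str | Path) -> dict[str, int]:
    """Read a cluster text file back into a seq_id -> cluster_id mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": int, "seq_id": str},
                     keep_default_na=False)
    missing_cols = [c for c in CLUSTER_FILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ProteomeError(f"{path}: missing cluster-file columns {missing_cols}")
    if df["seq_id"].duplicated().any():
        dupes = df["seq_id"][df["seq_id"].duplicated()].tolist()
        raise ProteomeError(f"{path}: seq_id appears more than once: {dupes[:5]}")
    return dict(zip(df["seq_id"], df["cluster_id"]))
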