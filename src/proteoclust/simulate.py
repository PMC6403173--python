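"""Synthetic pan-proteome generator with ground truth.

Emulates the structure of a multi-genome bacterial protein corpus: shared
protein families carried by every organism at varying divergence from a
family ancestor, occasional paralogous copies, chromosome/plasmid placement,
and a catalogue of annotation corruptions observed in real deposited
genomes — frameshift fragmentation, truncation, missing annotation, wrong
start codon, merged genes, and wrong product labels.  Every emitted record
is tracked in a truth table so downstream clustering and anomaly detection
can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    Organism,
    ProteinRecord,
    ProteomeSet,
    TAXON_CLASSES,
    write_fasta,
    write_metadata,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CORRUPTION_MODES = ("fragment", "truncate", "drop_annotation", "wrong_start",
                    "merge", "relabel")

#: truth-table marker for a partner gene consumed by a merge event
MERGE_CONSUMED = "merge_consumed"


def _default_corruption_rates() -> dict[str, float]:
    # Annotation issues are rare in real deposits (tens of cases per
    # thousands of genomes); defaults keep them rare but observable.
    return {
        "fragment": 0.01,
        "truncate": 0.01,
        "drop_annotation": 0.01,
        "wrong_start": 0.005,
        "merge": 0.005,
        "relabel": 0.015,
    }


@dataclass
class SimulationConfig:
    """Knobs of the pan-proteome simulation.

    ``identity_range`` is the target identity of each organism's family
    member to the family ancestor (so two members of the same family are
    pairwise roughly the square of that, plus chance agreement).
    """

    n_organisms: int = 20
    n_families: int = 10
    family_length_range: tuple[int, int] = (200, 600)
    identity_range: tuple[float, float] = (0.75, 0.95)
    paralog_probability: float = 0.1
    plasmid_probability: float = 0.05
    corruption_rates: dict[str, float] = field(default_factory=_default_corruption_rates)
    label_vocabulary: dict[str, list[tuple[str, float]]] | None = None
    indel_rate: float = 0.005
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_organisms < 1 or self.n_families < 1:
            raise ValueError("need at least one organism and one family")
        lo, hi = self.family_length_range
        if lo < 1 or hi < lo:
            raise ValueError("family_length_range must be positive and ordered")
        ilo, ihi = self.identity_range
        if not (0.0 < ilo <= ihi <= 1.0):
            raise ValueError("identity_range must lie in (0, 1]")
        for p in (self.paralog_probability, self.plasmid_probability, self.indel_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for mode, p in self.corruption_rates.items():
            if mode not in CORRUPTION_MODES:
                raise ValueError(f"unknown corruption mode {mode!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"corruption rate for {mode!r} outside [0, 1]")
        if sum(self.corruption_rates.values()) > 1.0:
            raise ValueError("corruption rates sum above 1")
        if self.label_vocabulary is not None:
            for fam, vocab in self.label_vocabulary.items():
                if not vocab:
                    raise ValueError(f"empty label vocabulary for family {fam!r}")


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``records`` has one row per emitted protein record (seq_id set) plus one
    row per gene with no emitted product (seq_id empty; drop_annotation and
    merge-consumed partners).  ``copy_counts`` tallies emitted copies per
    (organism, family, replicon_type).
    """

    records: pd.DataFrame
    copy_counts: pd.DataFrame

    def family_of(self) -> dict[str, str]:
        """seq_id -> true family, for emitted records only."""
        emitted = self.records[self.records["seq_id"] != ""]
        return dict(zip(emitted["seq_id"], emitted["family_id"]))

    def corruption_of(self) -> dict[str, str]:
        emitted = self.records[self.records["seq_id"] != ""]
        return dict(zip(emitted["seq_id"], emitted["corruption"]))

    def write(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def generate_ancestral_family(length: int, seed: int) -> str:
    """Draw a family ancestor of exactly ``length`` residues, i.i.d. uniform
    over the 20 amino acids.  Deterministic given ``seed``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def evolve_sequence(ancestor: str, target_identity: float, indel_rate: float,
                    seed: int) -> str:
    """Diverge ``ancestor`` to a descendant at the target identity.

    Each site is substituted (to a uniformly chosen *different* residue) with
    probability ``1 - target_identity``; indel events occur per site at
    ``indel_rate``, with geometric lengths (mean 2) and equal insert/delete
    odds.  Deterministic given ``seed``.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    p_sub = 1.0 - target_identity
    i = 0
    n = len(ancestor)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            ln = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before this site
                out.extend(rng.choice(list(AMINO_ACIDS), size=ln))
                continue
            i += ln  # deletion of ln sites
            continue
        res = ancestor[i]
        if p_sub > 0 and rng.random() < p_sub:
            alt = AMINO_ACIDS.replace(res, "") if res in AMINO_ACIDS else AMINO_ACIDS
            res = alt[rng.integers(len(alt))]
        out.append(res)
        i += 1
    if not out:  # pathological all-deleted case
        out.append(ancestor[0])
    return "".join(out)


def _replace(rec: ProteinRecord, **kw) -> ProteinRecord:
    d = {f: getattr(rec, f) for f in
         ("seq_id", "organism_id", "replicon_id", "replicon_type",
          "start", "end", "strand", "annotation", "sequence")}
    d.update(kw)
    return ProteinRecord(**d)


def corrupt(record: ProteinRecord, mode: str, params: dict | None = None,
            seed: int = 0) -> list[ProteinRecord]:
    """Apply one annotation corruption to ``record``.

    Returns 0, 1, or 2 records:

    - ``fragment``: a frameshift splits the CDS; two records at an interior
      breakpoint, adjacent on the same strand with a 1-100 bp gap.
    - ``truncate`` / ``wrong_start``: one shorter record (3' or 5' loss;
      wrong_start is always a 5' loss with most of the protein retained).
    - ``drop_annotation``: the gene is absent from the proteome (empty list).
    - ``merge``: one record whose sequence is the concatenation with
      ``params["other"]`` (two genes annotated as a single CDS).
    - ``relabel``: same sequence with ``params["new_label"]`` annotation.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    L = record.length

    if mode == "fragment":
        bp = int(params.get("breakpoint", rng.integers(2, L) if L > 2 else 0))
        if not (1 < bp < L):
            raise ValueError(f"fragment breakpoint {bp} outside (1, {L})")
        gap = int(params.get("gap_bp", rng.integers(1, 101)))
        part1 = record.sequence[:bp]
        part2 = record.sequence[bp:]
        s1, e1 = record.start, record.start + 3 * len(part1) - 1
        s2 = e1 + gap + 1
        e2 = s2 + 3 * len(part2) - 1
        return [
            _replace(record, seq_id=record.seq_id + "_p1", sequence=part1,
                     start=s1, end=e1),
            _replace(record, seq_id=record.seq_id + "_p2", sequence=part2,
                     start=s2, end=e2),
        ]

    if mode in ("truncate", "wrong_start"):
        if mode == "wrong_start":
            keep = float(params.get("keep_frac", rng.uniform(0.75, 0.95)))
            five_prime = True
        else:
            keep = float(params.get("keep_frac", rng.uniform(0.4, 0.75)))
            five_prime = bool(rng.random() < 0.5)
        keep_len = max(1, int(round(keep * L)))
        if five_prime:  # 5' loss: keep the 3' tail
            seq = record.sequence[L - keep_len:]
            start = record.end - 3 * keep_len + 1
            return [_replace(record, sequence=seq, start=start)]
        seq = record.sequence[:keep_len]
        end = record.start + 3 * keep_len - 1
        return [_replace(record, sequence=seq, end=end)]

    if mode == "drop_annotation":
        return []

    if mode == "merge":
        other: ProteinRecord = params["other"]
        seq = record.sequence + other.sequence
        end = record.start + 3 * len(seq) - 1
        return [_replace(record, seq_id=record.seq_id + "_m", sequence=seq, end=end)]

    if mode == "relabel":
        return [_replace(record, annotation=str(params["new_label"]))]

    raise ValueError(f"unknown corruption mode {mode!r}")


def default_label_vocabulary(n_families: int) -> dict[str, list[tuple[str, float]]]:
    """A Table-7-style heterogeneous product vocabulary per family: one
    dominant term, synonyms, and a 'hypothetical protein' tail."""
    vocab = {}
    for f in range(n_families):
        name = f"fam{f:02d}"
        vocab[name] = [
            (f"{name.capitalize()} protein", 0.60),
            (f"{name} family protein", 0.20),
            (f"putative {name} protein", 0.10),
            ("hypothetical protein", 0.10),
        ]
    return vocab


def generate_pan_proteome(config: SimulationConfig) -> tuple[ProteomeSet, TruthTable]:
    """Simulate a pan-proteome per ``config``.

    Each organism carries one copy of every family (extra copies with
    ``paralog_probability``, losses only through corruption).  Genes are laid
    left-to-right in family order with 200-2,000 bp intergenic gaps, so
    consecutive families form a conserved synteny pair; paralogs append at
    the end of the replicon.  At most one corruption applies per gene.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    fams = [f"fam{f:02d}" for f in range(config.n_families)]
    vocab = config.label_vocabulary or default_label_vocabulary(config.n_families)
    for fam in fams:
        if fam not in vocab or not vocab[fam]:
            raise ValueError(f"empty label vocabulary for family {fam!r}")

    lo, hi = config.family_length_range
    ancestors = {}
    fam_strand = {}
    for fam in fams:
        length = int(rng.integers(lo, hi + 1))
        ancestors[fam] = generate_ancestral_family(length, int(rng.integers(2**31)))
        fam_strand[fam] = "+" if rng.random() < 0.9 else "-"

    modes = list(CORRUPTION_MODES)
    rates = np.array([config.corruption_rates.get(m, 0.0) for m in modes])
    cum = np.cumsum(rates)

    organisms: dict[str, Organism] = {}
    records: dict[str, ProteinRecord] = {}
    truth_rows: list[tuple[str, str, str, str]] = []  # seq_id, organism, family, corruption

    for o in range(config.n_organisms):
        org_id = f"org{o:02d}"
        taxon = TAXON_CLASSES[o % 4]

        # draw genes: (family, copy_index, sequence, label, mode)
        genes: list[dict] = []
        for fam in fams:
            n_copies = 1 + int(rng.random() < config.paralog_probability)
            for c in range(n_copies):
                ident = float(rng.uniform(*config.identity_range))
                seq = evolve_sequence(ancestors[fam], ident, config.indel_rate,
                                      int(rng.integers(2**31)))
                labels, weights = zip(*vocab[fam])
                w = np.asarray(weights, float)
                label = labels[int(rng.choice(len(labels), p=w / w.sum()))]
                u = rng.random()
                k = int(np.searchsorted(cum, u, side="right"))
                mode = modes[k] if k < len(modes) else None
                genes.append(dict(family=fam, copy=c, sequence=seq, label=label,
                                  mode=mode))

        # resolve merge partners: a merge consumes the next single-copy,
        # uncorrupted gene of a different family; otherwise degrade to none
        by_fam_first = {}
        for g in genes:
            if g["copy"] == 0 and g["family"] not in by_fam_first:
                by_fam_first[g["family"]] = g
        for g in genes:
            if g["mode"] == "merge":
                partner = None
                fi = fams.index(g["family"])
                for step in range(1, len(fams)):
                    cand = by_fam_first.get(fams[(fi + step) % len(fams)])
                    if cand is not None and cand["mode"] is None and cand is not g:
                        partner = cand
                        break
                if partner is None:
                    g["mode"] = None
                else:
                    partner["mode"] = MERGE_CONSUMED
                    g["partner"] = partner

        # lay out coordinates and emit: single-copy genes first in family
        # order (synteny), then paralogs
        genes.sort(key=lambda g: (g["copy"], fams.index(g["family"])))
        cursors = {"chr": 0, "p1": 0}
        for g in genes:
            fam, c = g["family"], g["copy"]
            seq_id = f"{org_id}_{fam}_c{c}"
            if g["mode"] == MERGE_CONSUMED:
                truth_rows.append(("", org_id, fam, MERGE_CONSUMED))
                continue
            on_plasmid = rng.random() < config.plasmid_probability
            repl = "p1" if on_plasmid else "chr"
            gap = int(rng.integers(200, 2001))
            start = cursors[repl] + gap + 1
            end = start + 3 * len(g["sequence"]) - 1
            base = ProteinRecord(
                seq_id=seq_id, organism_id=org_id, replicon_id=repl,
                replicon_type="plasmid" if on_plasmid else "chromosome",
                start=start, end=end, strand=fam_strand[fam],
                annotation=g["label"], sequence=g["sequence"],
            )
            mode = g["mode"]
            if mode is None:
                emitted = [base]
            elif mode == "merge":
                emitted = corrupt(base, "merge", {"other": _partner_record(g)},
                                  int(rng.integers(2**31)))
            elif mode == "relabel":
                other_fam = fams[(fams.index(fam) + 1) % len(fams)]
                wrong = vocab[other_fam][0][0]
                emitted = corrupt(base, "relabel", {"new_label": wrong},
                                  int(rng.integers(2**31)))
            else:
                emitted = corrupt(base, mode, None, int(rng.integers(2**31)))
            if not emitted:
                truth_rows.append(("", org_id, fam, mode))
            for rec in emitted:
                records[rec.seq_id] = rec
                truth_rows.append((rec.seq_id, org_id, fam, mode or ""))
            cursors[repl] = max(cursors[repl], max((r.end for r in emitted),
                                                   default=cursors[repl]))

        organisms[org_id] = Organism(
            organism_id=org_id, name=f"Synthetica organismus {o:02d}",
            taxon_class=taxon, genome_size_bp=max(cursors["chr"], 1) + 1000,
            gc_content=float(np.round(rng.uniform(0.3, 0.7), 3)),
        )

    truth = pd.DataFrame(truth_rows,
                         columns=["seq_id", "organism_id", "family_id", "corruption"])
    emitted = truth[truth["seq_id"] != ""]
    counts = (emitted.merge(
                  pd.DataFrame([(r.seq_id, r.replicon_type) for r in records.values()],
                               columns=["seq_id", "replicon_type"]),
                  on="seq_id")
              .groupby(["organism_id", "family_id", "replicon_type"])
              .size().reset_index(name="copy_count"))
    proteome = ProteomeSet(organisms=organisms, records=records)
    return proteome, TruthTable(records=truth, copy_counts=counts)


def _partner_record(g: dict) -> ProteinRecord:
    p = g["partner"]
    # only the sequence matters for the concatenation
    return ProteinRecord(
        seq_id="partner", organism_id="x", replicon_id="chr",
        replicon_type="chromosome", start=1, end=3 * len(p["sequence"]),
        strand="+", annotation=p["label"], sequence=p["sequence"],
    )


def write_simulation(proteome: ProteomeSet, truth: TruthTable, outdir: str | Path,
                     prefix: str = "sim") -> dict[str, Path]:
    """Write FASTA + metadata TSV + truth TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{prefix}.faa"
    meta = outdir / f"{prefix}.meta.tsv"
    tr = outdir / f"{prefix}.truth.tsv"
    write_fasta(((sid, proteome.records[sid].sequence) for sid in proteome.seq_ids()),
                fasta)
    write_metadata(proteome, meta)
    truth.write(tr)
    return {"fasta": fasta, "metadata": meta, "truth": tr}
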