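"""Automatic detectors for annotation anomalies visible from clusters.

Real genome deposits contain frameshift-fragmented genes, truncated or
wrongly-started products, genes with no annotated product, two genes merged
into one CDS, wrong product labels, and broken gene-order (synteny)
conservation.  Each detector here encodes one of those failure modes as a
rule over cluster composition, member lengths (expectations come from
cluster medians), genomic coordinates, and annotation strings.  Findings
are ranked by deviation magnitude so the strongest candidates surface first.
"""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import ScoringParams, local_align
from .model import ProteinRecord, ProteomeSet
from .stats import representation

KINDS = ("truncated", "fragment_pair", "merged_gene", "missing_member",
         "mislabeled", "synteny_break")


@dataclass(frozen=True)
class AnomalyFinding:
    kind: str
    seq_ids: tuple[str, ...]
    organism_id: str
    evidence: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown finding kind {self.kind!r}")


def _median_length(members: Iterable[str], proteome: ProteomeSet) -> float:
    return float(statistics.median(proteome.records[s].length for s in members))


def detect_truncated(cluster: Sequence[str], proteome: ProteomeSet,
                     low_frac: float = 0.9, high_frac: float = 1.1) -> list[AnomalyFinding]:
    """Members much shorter (or longer) than the cluster's median length.

    Requires at least three members so the median is meaningful.
    """
    if len(cluster) < 3:
        raise ValueError("cluster must have >= 3 members for a meaningful median")
    med = _median_length(cluster, proteome)
    out = []
    for sid in sorted(cluster):
        L = proteome.records[sid].length
        if L < low_frac * med or L > high_frac * med:
            out.append(AnomalyFinding(
                kind="truncated", seq_ids=(sid,),
                organism_id=proteome.records[sid].organism_id,
                evidence={"length": L, "median": med},
                note=f"{L} aa vs cluster median {med:.0f} aa"))
    out.sort(key=lambda f: -abs(f.evidence["length"] - f.evidence["median"]))
    return out


def detect_fragment_pairs(proteome: ProteomeSet, assignment: Mapping[str, int],
                          max_gap_bp: int = 300, sum_tol: float = 0.10,
                          min_cluster_size: int = 3) -> list[AnomalyFinding]:
    """Adjacent same-strand gene pairs whose combined length matches a
    reference cluster's median — the signature of a frameshift that split
    one gene into two annotated CDS parts.

    A reference cluster is any cluster of ``min_cluster_size`` or more
    members containing at least one of the two records.
    """
    medians: dict[int, float] = {}
    members: dict[int, list[str]] = {}
    for sid, cid in assignment.items():
        members.setdefault(cid, []).append(sid)
    for cid, mem in members.items():
        if len(mem) >= min_cluster_size:
            medians[cid] = _median_length(mem, proteome)

    # group records by (organism, replicon, strand) and sort by coordinate
    groups: dict[tuple[str, str, str], list[ProteinRecord]] = {}
    for rec in proteome.records.values():
        groups.setdefault((rec.organism_id, rec.replicon_id, rec.strand), []).append(rec)
    out = []
    for key, recs in sorted(groups.items()):
        recs.sort(key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            gap = b.start - a.end - 1
            if gap < 0 or gap > max_gap_bp:
                continue
            combined = a.length + b.length
            ref = None
            for sid in (a.seq_id, b.seq_id):
                cid = assignment.get(sid)
                if cid in medians:
                    med = medians[cid]
                    if abs(combined - med) <= sum_tol * med:
                        ref = (cid, med)
                        break
            if ref is None:
                continue
            out.append(AnomalyFinding(
                kind="fragment_pair", seq_ids=(a.seq_id, b.seq_id),
                organism_id=a.organism_id,
                evidence={"len_a": a.length, "len_b": b.length,
                          "combined": combined, "median": ref[1],
                          "gap_bp": gap, "reference_cluster": ref[0]},
                note=f"{a.length}+{b.length}={combined} aa vs median {ref[1]:.0f}"))
    out.sort(key=lambda f: abs(f.evidence["combined"] - f.evidence["median"]))
    return out


def _representative(members: Sequence[str], proteome: ProteomeSet) -> str:
    """Member with length closest to the cluster median (smallest id on ties)."""
    med = _median_length(members, proteome)
    return min(sorted(members), key=lambda s: abs(proteome.records[s].length - med))


def detect_merged(cluster_a: Sequence[str], cluster_b: Sequence[str],
                  proteome: ProteomeSet, assignment: Mapping[str, int],
                  tol: float = 0.10, coverage: float = 0.8,
                  scoring: ScoringParams = ScoringParams()) -> list[AnomalyFinding]:
    """Sequences elsewhere whose length matches median(A)+median(B) and that
    align to representatives of both clusters — two genes fused into one CDS.
    """
    if len(cluster_a) < 3 or len(cluster_b) < 3:
        raise ValueError("reference clusters must have >= 3 members")
    in_ab = set(cluster_a) | set(cluster_b)
    med_a = _median_length(cluster_a, proteome)
    med_b = _median_length(cluster_b, proteome)
    target = med_a + med_b
    rep_a = proteome.records[_representative(cluster_a, proteome)]
    rep_b = proteome.records[_representative(cluster_b, proteome)]
    out = []
    for sid in sorted(assignment):
        if sid in in_ab:
            continue
        rec = proteome.records[sid]
        if abs(rec.length - target) > tol * target:
            continue
        ra = local_align(rec.sequence, rep_a.sequence, scoring, sid, rep_a.seq_id)
        rb = local_align(rec.sequence, rep_b.sequence, scoring, sid, rep_b.seq_id)
        if ra.align_len >= coverage * med_a and rb.align_len >= coverage * med_b:
            out.append(AnomalyFinding(
                kind="merged_gene", seq_ids=(sid,), organism_id=rec.organism_id,
                evidence={"length": rec.length, "median_a": med_a,
                          "median_b": med_b, "target": target,
                          "cover_a": ra.align_len, "cover_b": rb.align_len},
                note=f"{rec.length} aa ~ {med_a:.0f}+{med_b:.0f}"))
    out.sort(key=lambda f: abs(f.evidence["length"] - f.evidence["target"]))
    return out


def detect_missing_members(cluster: Sequence[str], proteome: ProteomeSet,
                           min_representation: float = 0.9) -> list[AnomalyFinding]:
    """For a near-universal cluster, report each organism with no member.

    Only fires when the cluster's organism representation reaches
    ``min_representation`` — a family found in most genomes is expected in
    all of them, so absences point at annotation gaps.
    """
    n_present, frac = representation(cluster, proteome)
    if frac < min_representation:
        return []
    present = {proteome.records[s].organism_id for s in cluster}
    out = []
    for org in sorted(set(proteome.organisms) - present):
        out.append(AnomalyFinding(
            kind="missing_member", seq_ids=(), organism_id=org,
            evidence={"representation": frac, "n_present": n_present},
            note="organism absent from a near-universal cluster"))
    return out


def infer_label_map(patterns: Sequence[str], assignment: Mapping[str, int],
                    proteome: ProteomeSet) -> dict[str, int]:
    """Home cluster per pattern: the cluster holding the strict majority of
    the pattern's matches.  Patterns with no strict majority are skipped
    with a warning."""
    import re
    out: dict[str, int] = {}
    for p in patterns:
        rx = re.compile(p, re.IGNORECASE)
        counts: dict[int, int] = {}
        for sid, cid in assignment.items():
            if rx.search(proteome.records[sid].annotation):
                counts[cid] = counts.get(cid, 0) + 1
        if not counts:
            warnings.warn(f"pattern {p!r} matches nothing; skipped")
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            warnings.warn(f"pattern {p!r} has no majority cluster; skipped")
            continue
        out[p] = ranked[0][0]
    return out


def detect_mislabeled(assignment: Mapping[str, int], proteome: ProteomeSet,
                      label_map: Mapping[str, int]) -> list[AnomalyFinding]:
    """Records whose annotation matches a pattern but that live outside the
    pattern's home cluster — the wrong-product-name signature."""
    import re
    out = []
    for p, home in label_map.items():
        rx = re.compile(p, re.IGNORECASE)
        for sid in sorted(assignment):
            if assignment[sid] != home and rx.search(proteome.records[sid].annotation):
                out.append(AnomalyFinding(
                    kind="mislabeled", seq_ids=(sid,),
                    organism_id=proteome.records[sid].organism_id,
                    evidence={"pattern": p, "home_cluster": home,
                              "actual_cluster": assignment[sid]},
                    note=f"label matches {p!r} but clustered elsewhere"))
    return out


def check_synteny_pair(proteome: ProteomeSet, members_a: Sequence[str],
                       members_b: Sequence[str], max_gap_bp: int = 2000
                       ) -> dict[str, str]:
    """Per-organism synteny status of an A-upstream-of-B gene pair.

    ``conserved``: some A member sits immediately upstream of a B member
    (same replicon and strand, transcription-direction-aware, gap <=
    ``max_gap_bp``); ``broken``: both present but no such arrangement;
    ``absent``: either side missing from the organism.
    """
    by_org_a: dict[str, list[ProteinRecord]] = {}
    by_org_b: dict[str, list[ProteinRecord]] = {}
    for sid in members_a:
        r = proteome.records[sid]
        by_org_a.setdefault(r.organism_id, []).append(r)
    for sid in members_b:
        r = proteome.records[sid]
        by_org_b.setdefault(r.organism_id, []).append(r)
    out = {}
    for org in sorted(proteome.organisms):
        alist, blist = by_org_a.get(org), by_org_b.get(org)
        if not alist or not blist:
            out[org] = "absent"
            continue
        conserved = False
        for a in alist:
            for b in blist:
                if a.replicon_id != b.replicon_id or a.strand != b.strand:
                    continue
                if a.strand == "+":
                    gap = b.start - a.end - 1
                else:
                    gap = a.start - b.end - 1
                if 0 <= gap <= max_gap_bp:
                    conserved = True
        out[org] = "conserved" if conserved else "broken"
    return out


def write_findings_tsv(findings: Sequence[AnomalyFinding], path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\torganism_id\tseq_ids\tevidence\tnote\n")
        for f in findings:
            fh.write(f"{f.kind}\t{f.organism_id}\t{','.join(f.seq_ids)}\t"
                     f"{json.dumps(f.evidence, sort_keys=True)}\t{f.note}\n")
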