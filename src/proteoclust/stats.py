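"""Descriptive statistics over clusters: regex extraction, length tables,
annotation-term census, organism representation, and copy-number reports.

Conventions fixed here: standard deviations are *sample* (n-1) deviations,
reported to one decimal; census percentages are count/total*100 rounded
half-up to two decimals; annotation strings are normalized by trimming and
collapsing internal whitespace before grouping.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .model import ProteomeSet


@dataclass(frozen=True)
class ClusterLengthStats:
    """Min/mean/max/sd of member protein lengths (aa); sd is the sample
    (n-1) deviation and is undefined (None) for singletons."""

    n_sequences: int
    min: int
    mean: float
    max: int
    std_dev: float | None

    def row(self) -> tuple:
        """Table-style row with sd to one decimal ('-' for singletons)."""
        sd = "-" if self.std_dev is None else f"{self.std_dev:.1f}"
        return (self.n_sequences, self.min, round(self.mean, 1), self.max, sd)


@dataclass(frozen=True)
class LabelCensus:
    """Annotation-term counts with percentages of a (possibly external)
    total, as in a product-name census of one cluster."""

    entries: list[tuple[str, int, float]]  # label, count, percent
    total: int


def percent(count: int, total: int) -> float:
    """count/total as a percentage, two decimals, half-up rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    exact = Decimal(count) * 100 / Decimal(total)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip())


def _compile(patterns: Sequence[str]) -> list[re.Pattern]:
    out = []
    for p in patterns:
        try:
            out.append(re.compile(p, re.IGNORECASE))
        except re.error as exc:
            raise ValueError(f"invalid pattern {p!r}: {exc}") from exc
    return out


def extract_clusters_by_pattern(assignment: Mapping[str, int], proteome: ProteomeSet,
                                patterns: Sequence[str]) -> dict[int, dict[str, list[str]]]:
    """Clusters containing at least one annotation matching any pattern.

    Patterns are matched case-insensitively (search semantics).  For each hit
    cluster the members are split into matched / unmatched lists so a reviewer
    can weed out false positives.
    """
    compiled = _compile(patterns)
    hits: dict[int, dict[str, list[str]]] = {}
    for sid in sorted(assignment):
        ann = proteome.records[sid].annotation
        if any(rx.search(ann) for rx in compiled):
            hits.setdefault(assignment[sid], {"matched": [], "unmatched": []})
            hits[assignment[sid]]["matched"].append(sid)
    for cid, d in hits.items():
        members = [s for s in sorted(assignment) if assignment[s] == cid]
        d["unmatched"] = [s for s in members if s not in set(d["matched"])]
    return hits


def length_stats_from_lengths(lengths: Sequence[int]) -> ClusterLengthStats:
    if not lengths:
        raise ValueError("empty cluster")
    n = len(lengths)
    sd = statistics.stdev(lengths) if n > 1 else None
    return ClusterLengthStats(n_sequences=n, min=min(lengths),
                              mean=sum(lengths) / n, max=max(lengths), std_dev=sd)


def length_stats(cluster: Iterable[str], proteome: ProteomeSet) -> ClusterLengthStats:
    """Length statistics of one cluster's member sequences."""
    return length_stats_from_lengths([proteome.records[s].length for s in cluster])


def label_census(cluster: Iterable[str], proteome: ProteomeSet,
                 external_total: int | None = None,
                 extra_counts: Mapping[str, int] | None = None) -> LabelCensus:
    """Census of normalized annotation terms in a cluster.

    ``extra_counts`` adds out-of-cluster rows (e.g. mislabeled sequences found
    elsewhere); ``external_total`` overrides the percentage denominator, as
    when such rows are included in the total.
    """
    counts: dict[str, int] = {}
    for sid in cluster:
        lab = normalize_label(proteome.records[sid].annotation)
        counts[lab] = counts.get(lab, 0) + 1
    for lab, c in (extra_counts or {}).items():
        counts[normalize_label(lab)] = counts.get(normalize_label(lab), 0) + c
    total = external_total if external_total is not None else sum(counts.values())
    if total <= 0:
        raise ValueError("empty cluster")
    entries = [(lab, c, percent(c, total)) for lab, c in
               sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return LabelCensus(entries=entries, total=total)


def representation(cluster: Iterable[str], proteome: ProteomeSet) -> tuple[int, float]:
    """(#organisms present in the cluster, fraction of all organisms).

    The denominator is every organism in the proteome set, whether or not it
    has any clustered sequence.
    """
    orgs = {proteome.records[s].organism_id for s in cluster}
    return len(orgs), len(orgs) / proteome.n_organisms


def representation_profile(assignment: Mapping[str, int], proteome: ProteomeSet,
                           q: float, include_singletons: bool = False) -> float:
    """Fraction of clusters whose organism representation is >= q.

    By default computed over non-singleton clusters only.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    clusters: dict[int, list[str]] = {}
    for sid, cid in assignment.items():
        clusters.setdefault(cid, []).append(sid)
    eligible = [mem for mem in clusters.values()
                if include_singletons or len(mem) > 1]
    if not eligible:
        return 0.0
    hit = sum(1 for mem in eligible if representation(mem, proteome)[1] >= q)
    return hit / len(eligible)


@dataclass(frozen=True)
class MultiplicityReport:
    """Per-organism copy counts of one cluster, split by replicon type,
    with mean copies per organism carrying the gene on each replicon type."""

    per_organism: dict[str, dict[str, int]]  # org -> {chromosome: n, plasmid: n}
    mean_chromosome: float | None
    mean_plasmid: float | None


def multiplicity_report(assignment: Mapping[str, int], proteome: ProteomeSet,
                        cluster_id: int) -> MultiplicityReport:
    members = [s for s, c in assignment.items() if c == cluster_id]
    if not members:
        raise ValueError(f"no such cluster {cluster_id!r}")
    per: dict[str, dict[str, int]] = {}
    for sid in members:
        rec = proteome.records[sid]
        d = per.setdefault(rec.organism_id, {"chromosome": 0, "plasmid": 0})
        d[rec.replicon_type] += 1
    chrom = [d["chromosome"] for d in per.values() if d["chromosome"] > 0]
    plas = [d["plasmid"] for d in per.values() if d["plasmid"] > 0]
    return MultiplicityReport(
        per_organism=per,
        mean_chromosome=sum(chrom) / len(chrom) if chrom else None,
        mean_plasmid=sum(plas) / len(plas) if plas else None,
    )
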