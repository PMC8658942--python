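"""Per-sample domain bookkeeping and cluster-annotation cross-referencing.

Combines per-sample A/C/KS domain hits with an external biosynthetic-gene-
cluster predictor's region table into per-sample count rows (domain counts,
their total, cluster count, and the number of domain hits that fall inside
a predicted cluster — "shared"), plus fieldwise group totals, e.g. sampling
campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .hits import DomainHit

CLUSTER_COLUMNS = ["sample", "contig_id", "nt_start", "nt_end",
                   "product_class", "closest_known", "similarity_pct"]


@dataclass(frozen=True)
class ClusterAnnotation:
    """One predicted biosynthetic gene cluster region on a contig."""

    sample: str
    contig_id: str
    nt_start: int
    nt_end: int
    product_class: str = ""
    closest_known: Optional[str] = None
    similarity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sample or not self.contig_id:
            raise ValueError("sample and contig_id must be non-empty")
        if self.nt_start > self.nt_end:
            raise ValueError(
                f"cluster on {self.contig_id}: nt_start {self.nt_start} > "
                f"nt_end {self.nt_end}")


@dataclass(frozen=True)
class DomainCountRow:
    """One sample's domain/cluster tallies (A, C, KS, their total, predicted
    clusters, and hits shared with a cluster interval)."""

    sample: str
    a_count: int
    c_count: int
    ks_count: int
    blast_total: int
    cluster_count: int
    shared_count: int

    def __post_init__(self) -> None:
        if self.blast_total != self.a_count + self.c_count + self.ks_count:
            raise ValueError("blast_total must equal a+c+ks")


def load_cluster_annotations(path, sep: str | None = None) -> list[ClusterAnnotation]:
    """Load a cluster-region table (TSV or CSV with a documented header).

    Malformed rows are reported with their line number; missing required
    columns raise an error listing them.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("sample", "contig_id", "nt_start", "nt_end")
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    out: list[ClusterAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            sim = getattr(row, "similarity_pct", None)
            out.append(ClusterAnnotation(
                sample=str(row.sample), contig_id=str(row.contig_id),
                nt_start=int(row.nt_start), nt_end=int(row.nt_end),
                product_class=str(getattr(row, "product_class", "") or ""),
                closest_known=(None if pd.isna(getattr(row, "closest_known", None))
                               else str(row.closest_known)),
                similarity_pct=None if sim is None or pd.isna(sim) else float(sim),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {line}: {exc}") from exc
    return out


def dedupe_hits(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Collapse hits identical in (contig, class, nt span) to one record;
    the alignment route takes precedence over the motif route."""
    best: dict[tuple, DomainHit] = {}
    order: list[tuple] = []
    for hit in hits:
        key = (hit.contig_id, hit.domain_class, hit.nt_start, hit.nt_end)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif hit.method == "alignment" and best[key].method == "motif":
            best[key] = hit
    return [best[k] for k in order]


def _overlap(hit: DomainHit, cluster: ClusterAnnotation) -> int:
    return (min(hit.nt_end, cluster.nt_end)
            - max(hit.nt_start, cluster.nt_start) + 1)


def find_shared(hits_by_sample: Mapping[str, Sequence[DomainHit]],
                clusters: Sequence[ClusterAnnotation],
                min_overlap: int = 1) -> dict[str, int]:
    """Count hits overlapping a same-sample, same-contig cluster interval by
    at least ``min_overlap`` bases; each hit counts at most once."""
    by_key: dict[tuple[str, str], list[ClusterAnnotation]] = {}
    for cl in clusters:
        by_key.setdefault((cl.sample, cl.contig_id), []).append(cl)
    shared: dict[str, int] = {}
    for sample, hits in hits_by_sample.items():
        n = 0
        for hit in hits:
            candidates = by_key.get((sample, hit.contig_id), ())
            if any(_overlap(hit, cl) >= min_overlap for cl in candidates):
                n += 1
        shared[sample] = n
    return shared


def count_domains(hits_by_sample: Mapping[str, Sequence[DomainHit]],
                  clusters: Sequence[ClusterAnnotation] = (),
                  confirmed_only: bool = True,
                  min_overlap: int = 1) -> list[DomainCountRow]:
    """Per-sample A/C/KS tallies plus cluster and shared counts.

    Hits are deduplicated by locus before counting; rows come back in
    sample-name order so output is deterministic.
    """
    samples = sorted(set(hits_by_sample) | {cl.sample for cl in clusters})
    kept = {
        sample: [h for h in dedupe_hits(hits_by_sample.get(sample, ()))
                 if h.confirmed or not confirmed_only]
        for sample in samples
    }
    shared = find_shared(kept, clusters, min_overlap=min_overlap)
    cluster_counts = {s: sum(cl.sample == s for cl in clusters) for s in samples}
    rows = []
    for sample in samples:
        per_class = {"A": 0, "C": 0, "KS": 0}
        for hit in kept[sample]:
            if hit.domain_class in per_class:
                per_class[hit.domain_class] += 1
        rows.append(DomainCountRow(
            sample=sample,
            a_count=per_class["A"], c_count=per_class["C"],
            ks_count=per_class["KS"],
            blast_total=sum(per_class.values()),
            cluster_count=cluster_counts[sample],
            shared_count=shared[sample]))
    return rows


def group_totals(rows: Sequence[DomainCountRow],
                 grouping: Mapping[str, str]) -> dict[str, DomainCountRow]:
    """Fieldwise sums of count rows per group (e.g. sampling year)."""
    totals: dict[str, dict[str, int]] = {}
    for row in rows:
        if row.sample not in grouping:
            raise ValueError(f"sample {row.sample!r} has no group assignment")
        g = totals.setdefault(grouping[row.sample],
                              dict(a=0, c=0, ks=0, cluster=0, shared=0))
        g["a"] += row.a_count
        g["c"] += row.c_count
        g["ks"] += row.ks_count
        g["cluster"] += row.cluster_count
        g["shared"] += row.shared_count
    return {
        label: DomainCountRow(
            sample=label, a_count=g["a"], c_count=g["c"], ks_count=g["ks"],
            blast_total=g["a"] + g["c"] + g["ks"],
            cluster_count=g["cluster"], shared_count=g["shared"])
        for label, g in sorted(totals.items())
    }


def counts_to_frame(rows: Sequence[DomainCountRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": r.sample, "a_count": r.a_count, "c_count": r.c_count,
          "ks_count": r.ks_count, "blast_total": r.blast_total,
          "cluster_count": r.cluster_count, "shared_count": r.shared_count}
         for r in rows])


def write_counts_csv(rows: Sequence[DomainCountRow], path) -> None:
    counts_to_frame(rows).to_csv(path, index=False)
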