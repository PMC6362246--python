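"""Contaminant removal from a similarity-hit table.

A contig is dropped only when three conditions hold simultaneously for its
best hit (highest bitscore; ties broken by lowest e-value, then subject
id): the hit is to a non-target taxon, the query coverage is strictly above
70%, the percent identity is strictly above 80 — and, additionally, no hit
in the contig's list falls in an available host genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

logger = logging.getLogger(__name__)

SUBJECT_GROUPS = ("target_clade", "host_genome", "other")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    subject_group: str  # target_clade | host_genome | other
    percent_identity: float  # 0..100
    query_coverage: float  # 0..1
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.subject_group not in SUBJECT_GROUPS:
            raise ValueError(f"unknown subject group {self.subject_group!r}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError("query_coverage must be in [0, 1]")


def best_hit(hits: List[HitRecord]) -> HitRecord:
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def classify_contig(
    hits: List[HitRecord], cov_min: float = 0.70, ident_min: float = 80.0
) -> Tuple[str, str]:
    """('keep'|'drop', reason) for one contig's hit list.

    Both thresholds are strict ("above 70%" / "above 80%"); an empty list
    keeps the contig for lack of evidence.
    """
    if not hits:
        return "keep", "no_evidence"
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("hits must all share one query_id")
    if any(h.subject_group == "host_genome" for h in hits):
        return "keep", "host_genome_hit"
    top = best_hit(hits)
    if top.subject_group != "other":
        return "keep", "best_hit_target"
    if top.query_coverage <= cov_min:
        return "keep", "coverage_not_above_threshold"
    if top.percent_identity <= ident_min:
        return "keep", "identity_not_above_threshold"
    return "drop", f"contaminant_best_hit:{top.subject_id}"


def filter_set(
    tset: Dict[str, str],
    hit_table: Iterable[HitRecord],
    cov_min: float = 0.70,
    ident_min: float = 80.0,
) -> Tuple[Dict[str, str], List[dict]]:
    """Partition a transcript set into kept sequences and a drop report.

    Hit rows naming unknown contigs are ignored with a warning.
    """
    by_query: Dict[str, List[HitRecord]] = {}
    unknown = 0
    for h in hit_table:
        if h.query_id not in tset:
            unknown += 1
            continue
        by_query.setdefault(h.query_id, []).append(h)
    if unknown:
        logger.warning("ignored %d hit rows for unknown contigs", unknown)
    kept: Dict[str, str] = {}
    report: List[dict] = []
    for cid, seq in tset.items():
        action, reason = classify_contig(by_query.get(cid, []), cov_min, ident_min)
        if action == "keep":
            kept[cid] = seq
        else:
            report.append({"contig": cid, "action": "drop", "reason": reason})
    return kept, report
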