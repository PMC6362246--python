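"""Clustering-guided iterative contig merging ("HomoloCAP3"-style reduction).

De novo assemblies of pooled, polymorphic RNA-seq libraries carry heavy
redundancy: near-identical copies of the same transcript differing by SNVs,
end truncations and variable UTRs.  This module reduces such a pool by

1. an initial strict end-overlap merge pass (>20 nt overlaps at 99%
   identity, emulating a CAP3 first pass),
2. three rounds of greedy longest-first identity clustering with a
   declining identity schedule (0.95/0.90 -> 0.90/0.80 -> 0.80/0.80 for
   identity / coverage-of-shorter), each followed by within-cluster
   overlap-consensus merging with automatically selected parameters,
3. a final relaxed-coverage clustering pass (0.95 / 0.5, min alignment
   120 nt) that groups surviving contigs into genes ("isoform grouping").

Alignment semantics mirror the CD-HIT thresholds: identity is
matches / alignment columns of the best local alignment, coverage is the
aligned span on the shorter sequence divided by its length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .orf import revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class ClusterParams:
    """Greedy-clustering thresholds (CD-HIT style -c / -aS / -A)."""

    identity_c: float
    coverage_aS: float
    min_aln_len: int = 0  # 0 = unused

    def __post_init__(self):
        if not 0 < self.identity_c <= 1:
            raise ValueError("identity_c must be in (0, 1]")
        if not 0 <= self.coverage_aS <= 1:
            raise ValueError("coverage_aS must be in [0, 1]")


@dataclass(frozen=True)
class MergeParams:
    """End-overlap merge thresholds (CAP3 style)."""

    min_overlap: int
    overlap_identity: float
    max_clip: int = 0

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.overlap_identity <= 1:
            raise ValueError("overlap_identity must be in (0, 1]")


@dataclass
class ReductionSchedule:
    """Ordered clustering rounds plus the final isoform-grouping parameters.

    ``initial_pass`` is the strict pre-clustering end-overlap merge applied
    to the whole input before round 1; set to None to skip it.
    ``round_merge_identity`` optionally overrides the per-round merge
    identity (by default each round merges at its own ``identity_c``).
    """

    rounds: List[ClusterParams] = field(
        default_factory=lambda: [
            ClusterParams(0.95, 0.90),
            ClusterParams(0.90, 0.80),
            ClusterParams(0.80, 0.80),
        ]
    )
    isoform: ClusterParams = field(
        default_factory=lambda: ClusterParams(0.95, 0.5, 120)
    )
    initial_pass: Optional[MergeParams] = field(
        default_factory=lambda: MergeParams(min_overlap=21, overlap_identity=0.99)
    )

    def __post_init__(self):
        ids = [r.identity_c for r in self.rounds]
        if any(a < b for a, b in zip(ids, ids[1:])):
            raise ValueError("identity_c must be non-increasing across rounds")


# ---------------------------------------------------------------------------
# pairwise local alignment

def _make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


_ALIGNER = _make_aligner()


_SCREEN_K = 10


def _kmer_set(s: str, k: int = _SCREEN_K) -> frozenset:
    return frozenset(s[i : i + k] for i in range(len(s) - k + 1))


def _shares_kmer(kmers_a: frozenset, b: str, k: int = _SCREEN_K) -> bool:
    """Cheap word filter: any alignment of >= 21 nt at >= 80% identity
    between near-identical copies almost surely contains an exact 10-mer."""
    return any(b[i : i + k] in kmers_a for i in range(len(b) - k + 1))


def _best_local(a: str, b: str):
    """Best local alignment of a (target) vs b (query), or None if no positive score."""
    if not a or not b:
        raise ValueError("empty sequence")
    alns = _ALIGNER.align(a, b)
    if alns.score <= 0:
        return None
    return alns[0]


def pairwise_identity(a: str, b: str) -> Tuple[float, int, float]:
    """(identity, aligned columns, coverage of the shorter sequence).

    Identity is matches / alignment columns of the best local alignment;
    coverage_short is the aligned span on the shorter sequence over its
    length.  Sequences with no positive-scoring local alignment return
    (0.0, 0, 0.0).
    """
    aln = _best_local(a, b)
    if aln is None:
        return 0.0, 0, 0.0
    c = aln.counts()
    columns = c.gaps + c.identities + c.mismatches
    identity = c.identities / columns if columns else 0.0
    ta, qa = aln.aligned  # blocks on target (a) and query (b)
    span_a = int(ta[-1][1] - ta[0][0])
    span_b = int(qa[-1][1] - qa[0][0])
    short_is_a = len(a) <= len(b)
    span_short = span_a if short_is_a else span_b
    coverage_short = span_short / min(len(a), len(b))
    return identity, int(columns), coverage_short


# ---------------------------------------------------------------------------
# greedy clustering


@dataclass
class Cluster:
    representative: str
    members: List[str]


def greedy_cluster(seqs: Dict[str, str], p: ClusterParams) -> List[Cluster]:
    """Longest-first greedy clustering with first-fit representative assignment.

    A sequence joins the first representative (in creation order) for which
    identity >= identity_c, coverage of the shorter >= coverage_aS and
    alignment length >= min_aln_len, considering both orientations;
    otherwise it founds a new cluster.
    """
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: List[Cluster] = []
    rep_kmers: Dict[str, frozenset] = {}
    for sid in order:
        s = seqs[sid]
        placed = False
        for cl in clusters:
            rep = seqs[cl.representative]
            kmers = rep_kmers[cl.representative]
            for cand in (s, revcomp(s)):
                if not _shares_kmer(kmers, cand):
                    continue
                ident, ncols, cov = pairwise_identity(rep, cand)
                if (
                    ident >= p.identity_c
                    and cov >= p.coverage_aS
                    and ncols >= p.min_aln_len
                ):
                    cl.members.append(sid)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            clusters.append(Cluster(sid, [sid]))
            rep_kmers[sid] = _kmer_set(s)
    return clusters


# ---------------------------------------------------------------------------
# merge-parameter selection and overlap-consensus merging


def auto_merge_params(
    member_seqs: Sequence[str], round_identity: float
) -> MergeParams:
    """Select overlap/clip parameters from the cluster's length distribution.

    min_overlap = max(21, round(0.05 * 10th-percentile length)); the merge
    identity is the round's clustering identity; max_clip = round(0.02 *
    median length).  Deterministic in the member multiset.
    """
    if not member_seqs:
        raise ValueError("empty cluster")
    lengths = np.array([len(s) for s in member_seqs], dtype=float)
    p10 = float(np.percentile(lengths, 10))
    med = float(np.median(lengths))
    return MergeParams(
        min_overlap=max(21, round(0.05 * p10)),
        overlap_identity=round_identity,
        max_clip=int(round(0.02 * med)),
    )


@dataclass
class Contig:
    """A working contig with provenance of the input sequences it absorbed."""

    id: str
    seq: str
    members: Tuple[str, ...]


def _as_contigs(seqs: Dict[str, str]) -> List[Contig]:
    return [Contig(i, s, (i,)) for i, s in seqs.items()]


def _try_join(a: Contig, b: Contig, m: MergeParams) -> Optional[Contig]:
    """Attempt containment collapse or dovetail join of two contigs.

    Tries both orientations of ``b``.  Returns the joined contig or None.
    At a dovetail join the aligned (overlap) region is taken wholly from the
    longer contig, which resolves every mismatch and gap column in favour of
    the longer sequence.
    """
    best: Optional[Tuple[int, Contig]] = None  # (columns, joined)
    a_kmers = _kmer_set(a.seq)
    for b_seq in (b.seq, revcomp(b.seq)):
        if not _shares_kmer(a_kmers, b_seq):
            continue
        aln = _best_local(a.seq, b_seq)
        if aln is None:
            continue
        c = aln.counts()
        columns = c.gaps + c.identities + c.mismatches
        if columns < m.min_overlap:
            continue
        identity = c.identities / columns
        if identity < m.overlap_identity:
            continue
        ta, qa = aln.aligned
        a0, a1 = int(ta[0][0]), int(ta[-1][1])
        b0, b1 = int(qa[0][0]), int(qa[-1][1])
        la, lb = len(a.seq), len(b_seq)
        members = tuple(sorted(set(a.members) | set(b.members)))
        new_id = a.id if la >= lb else b.id
        joined: Optional[Contig] = None
        # containment of the shorter within the longer (ends within clip)
        if lb <= la and b0 <= m.max_clip and lb - b1 <= m.max_clip:
            joined = Contig(a.id, a.seq, members)
        elif la <= lb and a0 <= m.max_clip and la - a1 <= m.max_clip:
            joined = Contig(b.id, b_seq, members)
        # dovetail: suffix of a overlaps prefix of b
        elif la - a1 <= m.max_clip and b0 <= m.max_clip:
            mid = a.seq[a0:a1] if la >= lb else b_seq[b0:b1]
            joined = Contig(new_id, a.seq[:a0] + mid + b_seq[b1:], members)
        # dovetail: suffix of b overlaps prefix of a
        elif lb - b1 <= m.max_clip and a0 <= m.max_clip:
            mid = a.seq[a0:a1] if la >= lb else b_seq[b0:b1]
            joined = Contig(new_id, b_seq[:b0] + mid + a.seq[a1:], members)
        if joined is not None and (best is None or columns > best[0]):
            best = (int(columns), joined)
    return best[1] if best else None


def merge_cluster(members: Dict[str, str], m: MergeParams) -> List[Contig]:
    """Repeatedly join the best qualifying overlap until none remains.

    Qualifying joins are containments or end-dovetails with >= min_overlap
    alignment columns at >= overlap_identity, allowing <= max_clip of
    unaligned terminal sequence on the inner ends.  Output is sorted
    longest-first, then by id.
    """
    contigs = _as_contigs(members)
    # pair results are cached by object identity: Contig instances are never
    # mutated, so only pairs involving a freshly joined contig need alignment;
    # `refs` pins every instance so id() values cannot be recycled
    cache: Dict[Tuple[int, int], Optional[Contig]] = {}
    refs: List[Contig] = list(contigs)
    changed = True
    while changed and len(contigs) > 1:
        changed = False
        contigs.sort(key=lambda c: (-len(c.seq), c.id))
        best: Optional[Tuple[int, int, int, Contig]] = None
        for i in range(len(contigs)):
            for j in range(i + 1, len(contigs)):
                key = (id(contigs[i]), id(contigs[j]))
                if key not in cache:
                    cache[key] = _try_join(contigs[i], contigs[j], m)
                joined = cache[key]
                if joined is None:
                    continue
                key = len(joined.seq)
                if best is None or key > best[0]:
                    best = (key, i, j, joined)
        if best is not None:
            _, i, j, joined = best
            contigs = [c for k, c in enumerate(contigs) if k not in (i, j)]
            contigs.append(joined)
            refs.append(joined)
            changed = True
    contigs.sort(key=lambda c: (-len(c.seq), c.id))
    return contigs


# ---------------------------------------------------------------------------
# full schedule


def run_schedule(
    seqs: Dict[str, str], schedule: Optional[ReductionSchedule] = None
) -> Tuple[List[Contig], Dict[str, List[str]], List[dict]]:
    """Run the full reduction: initial pass, three rounds, isoform grouping.

    Returns (contigs, gene_groups, round_log) where gene_groups maps a gene
    id (the group representative's contig id) to its member contig ids, and
    round_log records per-round cluster and contig counts.
    """
    if schedule is None:
        schedule = ReductionSchedule()
    log: List[dict] = []
    if not seqs:
        return [], {}, log

    contigs = _as_contigs(seqs)

    if schedule.initial_pass is not None:
        pool = {c.id: c.seq for c in contigs}
        membership = {c.id: c.members for c in contigs}
        merged = merge_cluster(pool, schedule.initial_pass)
        contigs = [
            Contig(
                c.id,
                c.seq,
                tuple(sorted({m for mid in c.members for m in membership[mid]})),
            )
            for c in merged
        ]
        log.append({"round": "initial", "contigs": len(contigs)})

    for rnum, cp in enumerate(schedule.rounds, start=1):
        pool = {c.id: c.seq for c in contigs}
        membership = {c.id: c.members for c in contigs}
        clusters = greedy_cluster(pool, cp)
        new_contigs: List[Contig] = []
        n_merges = 0
        for cl in clusters:
            member_seqs = {mid: pool[mid] for mid in cl.members}
            mp = auto_merge_params(list(member_seqs.values()), cp.identity_c)
            merged = merge_cluster(member_seqs, mp)
            n_merges += len(cl.members) - len(merged)
            for c in merged:
                prov = tuple(
                    sorted({m for mid in c.members for m in membership[mid]})
                )
                new_contigs.append(Contig(c.id, c.seq, prov))
        contigs = sorted(new_contigs, key=lambda c: (-len(c.seq), c.id))
        log.append(
            {
                "round": rnum,
                "clusters": len(clusters),
                "merges": n_merges,
                "contigs": len(contigs),
            }
        )
        logger.info(
            "round %s: %d clusters, %d merges, %d contigs",
            rnum,
            len(clusters),
            n_merges,
            len(contigs),
        )

    pool = {c.id: c.seq for c in contigs}
    groups = greedy_cluster(pool, schedule.isoform)
    gene_groups = {g.representative: sorted(g.members) for g in groups}
    log.append({"round": "isoform", "genes": len(gene_groups)})
    return contigs, gene_groups, log
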