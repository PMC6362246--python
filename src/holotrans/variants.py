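"""Variant classification, quality filtering, and per-population summaries.

Variant calls are consumed from VCF; this module reproduces the summary
layer: DP/MQ quality filtering (records with DP < 20 or MQ < 40 removed,
boundary values kept), transition/transversion/indel classification,
per-kilobase density over a contig universe, and selection of highly
polymorphic contigs (density at least twice the mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    population: str = "all"
    depth: Optional[int] = None  # DP
    mapping_quality: Optional[float] = None  # MQ


@dataclass(frozen=True)
class VariantSummary:
    population: str
    n_transitions: int
    n_transversions: int
    n_indels: int
    snps_per_kb: float
    tstv: Optional[float]  # None when no transversions

    @classmethod
    def from_counts(
        cls,
        n_transitions: int,
        n_transversions: int,
        n_indels: int,
        total_length_nt: float,
        population: str = "all",
    ) -> "VariantSummary":
        """Summary statistics straight from class counts and a total length.

        Density counts indels alongside SNVs, matching summary tables that
        list all three classes under one per-kb figure.
        """
        total = n_transitions + n_transversions + n_indels
        if total_length_nt <= 0:
            raise ValueError("total length must be positive")
        tstv = n_transitions / n_transversions if n_transversions > 0 else None
        return cls(
            population=population,
            n_transitions=n_transitions,
            n_transversions=n_transversions,
            n_indels=n_indels,
            snps_per_kb=total / (total_length_nt / 1000.0),
            tstv=tstv,
        )


def classify_variant(ref: str, alt: str) -> str:
    """'indel' on length change; else 'transition' for A<->G / C<->T, else 'transversion'."""
    if not ref or not alt or set(ref + alt) - set("ACGT"):
        raise ValueError(f"invalid alleles {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if len(ref) != len(alt):
        return "indel"
    if len(ref) > 1:
        # MNP: classify by the first differing base pair
        for r, a in zip(ref, alt):
            if r != a:
                ref, alt = r, a
                break
    return "transition" if {ref, alt} in _TRANSITION_PAIRS else "transversion"


def filter_variants(
    records: Iterable[VariantRecord], min_dp: int = 20, min_mq: float = 40.0
) -> List[VariantRecord]:
    """Drop records with DP < min_dp or MQ < min_mq; boundary values are kept.

    Records missing DP or MQ are removed and tallied in a warning.
    """
    kept: List[VariantRecord] = []
    missing = 0
    for r in records:
        if r.depth is None or r.mapping_quality is None:
            missing += 1
            continue
        if r.depth < min_dp or r.mapping_quality < min_mq:
            continue
        kept.append(r)
    if missing:
        logger.warning("removed %d records with missing DP/MQ", missing)
    return kept


def summarize(
    records: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    population: str = "all",
) -> VariantSummary:
    """Class counts, Ts/Tv and per-kb density over the summed contig length."""
    total_len = float(sum(contig_lengths.values()))
    if total_len <= 0:
        raise ValueError("zero total contig length")
    ts = tv = ind = 0
    for r in records:
        if r.contig not in contig_lengths:
            raise ValueError(f"record on unknown contig {r.contig!r}")
        kind = classify_variant(r.ref_allele, r.alt_allele)
        if kind == "transition":
            ts += 1
        elif kind == "transversion":
            tv += 1
        else:
            ind += 1
    return VariantSummary.from_counts(ts, tv, ind, total_len, population)


def per_contig_density(
    records: Iterable[VariantRecord], contig_lengths: Mapping[str, int]
) -> Dict[str, float]:
    """Variants per kilobase for every contig in the universe (0 when none)."""
    counts = {c: 0 for c in contig_lengths}
    for r in records:
        if r.contig not in counts:
            raise ValueError(f"record on unknown contig {r.contig!r}")
        counts[r.contig] += 1
    return {c: counts[c] / (contig_lengths[c] / 1000.0) for c in counts}


def highly_polymorphic(densities: Mapping[str, float], multiple: float = 2.0) -> Set[str]:
    """Contigs whose density is >= multiple x the mean density of the universe.

    Zero-density contigs are never selected when the mean is positive.
    """
    if not densities:
        raise ValueError("need at least one contig")
    mean = sum(densities.values()) / len(densities)
    if mean == 0:
        return set()
    return {c for c, d in densities.items() if d >= multiple * mean}


def split_multiallelic(
    contig: str,
    position: int,
    ref: str,
    alts: Iterable[str],
    population: str = "all",
    depth: Optional[int] = None,
    mapping_quality: Optional[float] = None,
) -> List[VariantRecord]:
    """One VariantRecord per alternate allele of a multi-allelic site."""
    return [
        VariantRecord(contig, position, ref, alt, population, depth, mapping_quality)
        for alt in alts
    ]
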