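"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs for this kind of study are hundreds of millions of reads plus
external databases; the generators here emulate the *structure* of those
inputs at desk scale so every downstream module can be exercised against a
planted truth:

* redundant transcript pools: gene families with mutated, end-truncated,
  UTR-flanked copies and optional internal-deletion isoforms;
* spiked contaminants with similarity-hit tables pointing to a non-target
  taxon;
* 4-stage count matrices from a negative binomial with fixed dispersion
  (variance = mu + phi mu^2, phi = 0.1) and planted fold changes at one
  non-reference stage per affected gene;
* variant tables with configured per-kilobase density (Poisson), a
  configured transition/transversion ratio and indel fraction;
* gene -> GO annotations with one planted enriched term plus a minimal
  ontology covering every used term.

All generators are deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .contam import HitRecord
from .de import CountMatrix
from .variants import VariantRecord

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

ROLES = ("full_length", "truncated_copy", "utr_variant", "isoform", "contaminant")

#: contig_id -> (gene_id, role)
TruthMap = Dict[str, Tuple[str, str]]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's defaults.

    The count model is NB with variance mu + dispersion * mu^2; variants use
    a transition/transversion ratio of 1.5 with a 5% indel fraction at
    30 variants per kilobase.
    """

    seed: int = 0
    n_genes: int = 20
    gene_length: int = 1000
    copies_per_gene: int = 3
    isoform_rate: float = 0.0
    point_mutation_rate: float = 0.01
    truncation_fraction: float = 0.2
    utr_noise_len: int = 60
    stages: Tuple[str, ...] = ("blastula", "gastrula", "auricularia", "pentactula")
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    de_fraction: float = 0.1
    fold_change: float = 8.0
    snv_density: float = 30.0
    tstv_ratio: float = 1.5
    indel_fraction: float = 0.05

    def __post_init__(self):
        for name in (
            "isoform_rate",
            "point_mutation_rate",
            "truncation_fraction",
            "de_fraction",
            "indel_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.snv_density < 0:
            raise ValueError("snv_density must be >= 0")
        if self.tstv_ratio <= 0:
            raise ValueError("tstv_ratio must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length < 300:
            raise ValueError("gene_length must be >= 300")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_redundant_transcripts(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], TruthMap]:
    """A gene-family pool: one full-length reference per gene plus noisy copies.

    Each copy is point-mutated, truncated at each end by up to
    ``truncation_fraction`` of the gene length, and given random UTR-like
    flanks of up to ``utr_noise_len`` nt.  With probability ``isoform_rate``
    a gene additionally contributes an internal-deletion isoform.
    """
    rng = np.random.default_rng(config.seed)
    tset: Dict[str, str] = {}
    truth: TruthMap = {}
    for gi in range(config.n_genes):
        gene = f"gene{gi:04d}"
        ref = _random_dna(rng, config.gene_length)
        rid = f"{gene}_ref"
        tset[rid] = ref
        truth[rid] = (gene, "full_length")
        for ci in range(config.copies_per_gene):
            seq = _mutate(rng, ref, config.point_mutation_rate)
            max_trunc = int(config.truncation_fraction * len(ref))
            t5 = int(rng.integers(0, max_trunc + 1))
            t3 = int(rng.integers(0, max_trunc + 1))
            seq = seq[t5 : len(seq) - t3] if t3 else seq[t5:]
            f5 = int(rng.integers(0, config.utr_noise_len + 1))
            f3 = int(rng.integers(0, config.utr_noise_len + 1))
            seq = _random_dna(rng, f5) + seq + _random_dna(rng, f3)
            if t5 or t3:
                role = "truncated_copy"
            elif f5 or f3:
                role = "utr_variant"
            else:
                role = "full_length"
            cid = f"{gene}_copy{ci}"
            tset[cid] = seq
            truth[cid] = (gene, role)
        if config.isoform_rate > 0 and rng.random() < config.isoform_rate:
            span = int(len(ref) * rng.uniform(0.1, 0.3))
            start = int(rng.integers(100, len(ref) - span - 100))
            iid = f"{gene}_iso"
            tset[iid] = ref[:start] + ref[start + span :]
            truth[iid] = (gene, "isoform")
    return tset, truth


def spike_contaminants(
    tset: Dict[str, str], n: int, seed: int = 0, contig_length: int = 600
) -> Tuple[Dict[str, str], List[HitRecord]]:
    """Add n random-composition contaminant contigs plus a synthetic hit table.

    Each contaminant's best hit is to a non-target taxon with coverage > 0.7
    and identity > 80; every host contig gets a target-clade hit so the
    contamination filter retains it.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = dict(tset)
    hits: List[HitRecord] = []
    for qid in tset:
        hits.append(
            HitRecord(
                query_id=qid,
                subject_id=f"echinoderm_prot_{rng.integers(0, 10**6)}",
                subject_group="target_clade",
                percent_identity=float(rng.uniform(70, 99)),
                query_coverage=float(rng.uniform(0.5, 1.0)),
                bitscore=float(rng.uniform(100, 500)),
                evalue=float(10.0 ** -rng.uniform(10, 60)),
            )
        )
    for i in range(n):
        cid = f"contam{i:03d}"
        out[cid] = _random_dna(rng, contig_length)
        hits.append(
            HitRecord(
                query_id=cid,
                subject_id=f"proteobact_prot_{i:03d}",
                subject_group="other",
                percent_identity=float(rng.uniform(81, 99)),
                query_coverage=float(rng.uniform(0.71, 0.99)),
                bitscore=float(rng.uniform(200, 600)),
                evalue=float(10.0 ** -rng.uniform(20, 80)),
            )
        )
    return out, hits


def simulate_stage_counts(
    config: SimulationConfig,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """NB counts for n_genes x stages with planted fold changes.

    A ``de_fraction`` of genes has its mean at one uniformly chosen
    non-reference stage multiplied or divided (equal probability) by
    ``fold_change``.  Returns the count matrix and a truth table with
    columns gene, stage, direction ('up'/'down').
    """
    if len(config.stages) < 2:
        raise ValueError("need at least two stages")
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lengths = pd.Series(
        rng.integers(500, 2501, size=config.n_genes), index=genes, name="length"
    )
    mu = np.full((config.n_genes, len(config.stages)), config.baseline_mean)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    truth_rows = []
    for gi in de_idx:
        si = int(rng.integers(1, len(config.stages)))
        up = bool(rng.random() < 0.5)
        mu[gi, si] = (
            mu[gi, si] * config.fold_change if up else mu[gi, si] / config.fold_change
        )
        truth_rows.append(
            {
                "gene": genes[gi],
                "stage": config.stages[si],
                "direction": "up" if up else "down",
            }
        )
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=list(config.stages)),
        lengths=lengths,
    )
    truth = pd.DataFrame(truth_rows, columns=["gene", "stage", "direction"])
    return cm, truth


def simulate_variants(
    contigs: Dict[str, str],
    config: SimulationConfig,
    seed: Optional[int] = None,
    population: str = "all",
    dp_range: Tuple[int, int] = (5, 100),
    mq_range: Tuple[int, int] = (20, 60),
) -> List[VariantRecord]:
    """Plant variants on contigs at the configured density and class mix.

    Per-contig variant counts are Poisson(length/1000 * snv_density);
    each variant is an indel with probability ``indel_fraction``, otherwise
    a transition with probability tstv/(1+tstv).  Positions are unique per
    contig; DP and MQ are drawn uniformly from the given inclusive ranges.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: List[VariantRecord] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        lam = len(seq) / 1000.0 * config.snv_density
        m = int(rng.poisson(lam)) if lam > 0 else 0
        # anchored deletions span up to 3 following bases; keep clear of the end
        usable = max(0, len(seq) - 4)
        m = min(m, usable)
        if m == 0:
            continue
        positions = np.sort(rng.choice(usable, size=m, replace=False)) + 1
        for pos in positions:
            ref_base = seq[pos - 1]
            if ref_base == "N":
                continue
            dp = int(rng.integers(dp_range[0], dp_range[1] + 1))
            mq = float(rng.integers(mq_range[0], mq_range[1] + 1))
            if rng.random() < config.indel_fraction:
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # deletion
                    ref = seq[pos - 1 : pos + size]
                    alt = ref_base
                else:  # insertion
                    ref = ref_base
                    alt = ref_base + _random_dna(rng, size)
            else:
                ref = ref_base
                p_ts = config.tstv_ratio / (1.0 + config.tstv_ratio)
                if rng.random() < p_ts:
                    alt = _TRANSITION[ref_base]
                else:
                    alt = _TRANSVERSIONS[ref_base][rng.integers(0, 2)]
            records.append(
                VariantRecord(
                    contig=cid,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    population=population,
                    depth=dp,
                    mapping_quality=mq,
                )
            )
    return records


def generate_annotation(
    genes: Sequence[str],
    n_terms: int,
    terms_per_gene: int,
    planted_term: Optional[str] = None,
    planted_genes: Sequence[str] = (),
    seed: int = 0,
) -> Tuple[Dict[str, Set[str]], Dict[str, Tuple[str, str]]]:
    """Uniform background GO annotation with one planted enriched term.

    Returns (gene -> term set, term -> (name, namespace)).  The planted
    term is attached to every planted gene and to no other gene.  Raises
    on planted genes absent from ``genes``.
    """
    genes = list(genes)
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    background = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    ann: Dict[str, Set[str]] = {g: set() for g in genes}
    if terms_per_gene > 0 and n_terms > 0:
        for g in genes:
            k = min(terms_per_gene, n_terms)
            ann[g] = set(rng.choice(background, size=k, replace=False))
    if planted_term is not None:
        if planted_term in background:
            raise ValueError("planted_term must not collide with background terms")
        for g in planted_genes:
            ann[g].add(planted_term)
    ann = {g: t for g, t in ann.items() if t}
    used = sorted(set().union(*ann.values())) if ann else []
    terms = {
        t: (f"synthetic process {t}", "biological_process") for t in used
    }
    return ann, terms
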