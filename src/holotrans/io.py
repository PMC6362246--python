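"""Readers and writers for the pipeline's plain-text formats.

FASTA via Bio.SeqIO (uppercased on read, wrapped at 80 columns on write);
counts, annotations, gene lists and hit tables as TSV; variants as VCF 4.2
through pysam; ontology subsets as minimal OBO (read with obonet).  All
writers round-trip with the corresponding readers.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import obonet
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contam import HitRecord
from .de import CountMatrix
from .variants import VariantRecord, split_multiallelic

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> Dict[str, str]:
    """Ordered id -> sequence mapping; sequences are uppercased."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(tset: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in tset.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str, read_pair_span: int = 200) -> CountMatrix:
    """TSV with columns: gene, length, then one column per stage (in order)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "gene" or df.columns[1] != "length":
        raise ValueError("counts table must start with 'gene' and 'length' columns")
    df = df.set_index("gene")
    return CountMatrix(
        counts=df.drop(columns="length"),
        lengths=df["length"],
        read_pair_span=read_pair_span,
    )


def write_counts(cm: CountMatrix, path: str) -> None:
    df = cm.counts.copy()
    df.insert(0, "length", cm.lengths)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# similarity-hit tables (12-column tabular format + subject-group map)

_HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_hit_table(
    path: str,
    query_lengths: Mapping[str, int],
    subject_groups: Mapping[str, str],
) -> List[HitRecord]:
    """Parse a 12-column tabular hit file.

    Query coverage is alignment length / query length (query lengths are
    supplied separately, e.g. from the FASTA); subject groups come from a
    subject -> group map.  Lines starting with '#' are skipped.
    """
    records: List[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                aln_len = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            qid, sid = parts[0], parts[1]
            qlen = query_lengths.get(qid)
            cov = min(1.0, aln_len / qlen) if qlen else 0.0
            records.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    subject_group=subject_groups.get(sid, "other"),
                    percent_identity=pident,
                    query_coverage=cov,
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return records


def write_hit_table(
    hits: Iterable[HitRecord],
    path: str,
    query_lengths: Mapping[str, int],
    group_map_path: Optional[str] = None,
) -> None:
    """Emit hits in the 12-column format plus an optional subject-group map.

    Alignment length is reconstructed from coverage x query length; the
    unused columns are filled with zeros.
    """
    groups: Dict[str, str] = {}
    with open(path, "w") as fh:
        for h in hits:
            qlen = query_lengths.get(h.query_id, 0)
            aln_len = int(round(h.query_coverage * qlen))
            row = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(aln_len),
                "0",
                "0",
                "1",
                str(max(1, aln_len)),
                "1",
                str(max(1, aln_len)),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
            ]
            fh.write("\t".join(row) + "\n")
            groups[h.subject_id] = h.subject_group
    if group_map_path:
        with open(group_map_path, "w") as fh:
            for sid in sorted(groups):
                fh.write(f"{sid}\t{groups[sid]}\n")


def read_group_map(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, group = line.split("\t")
            out[sid] = group
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    records: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    path: str,
) -> None:
    """VCF 4.2 with INFO DP, MQ and POP; positions are 1-based in the file."""
    header = pysam.VariantHeader()
    for cid in sorted(contig_lengths):
        header.contigs.add(cid, length=contig_lengths[cid])
    header.info.add("DP", 1, "Integer", "Read depth")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("POP", 1, "String", "Population label")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.contig, r.position)):
            rec = vf.new_record(
                contig=r.contig,
                start=r.position - 1,
                alleles=(r.ref_allele, r.alt_allele),
            )
            if r.depth is not None:
                rec.info["DP"] = r.depth
            if r.mapping_quality is not None:
                rec.info["MQ"] = float(r.mapping_quality)
            rec.info["POP"] = r.population
            vf.write(rec)


def read_vcf(path: str, default_population: str = "all") -> List[VariantRecord]:
    """Read VCF; multi-allelic sites are split into one record per alt allele."""
    out: List[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            dp = rec.info.get("DP")
            mq = rec.info.get("MQ")
            pop = rec.info.get("POP", default_population)
            out.extend(
                split_multiallelic(
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    [a for a in (rec.alts or ()) if a],
                    population=pop,
                    depth=int(dp) if dp is not None else None,
                    mapping_quality=float(mq) if mq is not None else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# GO annotation + OBO subset


def read_annotation(path: str) -> Dict[str, Set[str]]:
    """Two-column gene<TAB>term table -> gene -> term set."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_annotation(ann: Mapping[str, Set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(ann):
            for t in sorted(ann[g]):
                fh.write(f"{g}\t{t}\n")


def write_obo(terms: Mapping[str, Tuple[str, str]], path: str) -> None:
    """Minimal OBO subset: one [Term] stanza per term with name and namespace."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(terms):
            name, namespace = terms[t]
            fh.write(f"\n[Term]\nid: {t}\nname: {name}\nnamespace: {namespace}\n")


def read_obo(path: str) -> Dict[str, Tuple[str, str]]:
    """term id -> (name, namespace), via obonet."""
    graph = obonet.read_obo(path)
    return {
        t: (data.get("name", ""), data.get("namespace", ""))
        for t, data in graph.nodes(data=True)
    }


# ---------------------------------------------------------------------------
# gene lists and truth tables


def read_gene_list(path: str) -> Set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_truth_map(truth: Mapping[str, Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tgene\trole\n")
        for cid in sorted(truth):
            gene, role = truth[cid]
            fh.write(f"{cid}\t{gene}\t{role}\n")


def read_truth_map(path: str) -> Dict[str, Tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {r.contig: (r.gene, r.role) for r in df.itertuples()}
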