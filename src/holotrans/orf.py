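"""Stop-to-stop CDS extraction from assembled contigs.

De novo transcriptome contigs are frequently 5'-truncated, so anchoring
coding regions at ATG loses real CDS fragments.  The rule implemented here
instead treats *stop codons* as the delimiters: every maximal inter-stop
segment in each of the six reading frames is a candidate CDS, including the
leading segment before the first stop (flagged ``partial5``) and the
trailing segment after the last stop (flagged ``partial3``).  Candidates
shorter than a minimum number of translatable codons (default 30 residues)
are discarded.

Coordinates are 0-based half-open on the forward strand of the contig; the
terminal stop codon, when present, is included in the coordinate span but
excluded from ``aa_length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # TAA, TAG, TGA
_FORWARD = dict(_STANDARD_TABLE.forward_table)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, strand: str = "+") -> str:
    """Translate with the standard code; codons containing N give 'X', stops '*'.

    N-containing codons never count as stops, matching the extraction rule.
    """
    seq = dna.upper()
    if strand == "-":
        seq = revcomp(seq)
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOP_CODONS:
            out.append("*")
        else:
            out.append(_FORWARD[codon])
    return "".join(out)


@dataclass(frozen=True)
class CdsRecord:
    """One stop-to-stop coding region located on a contig.

    ``start``/``end`` are 0-based half-open forward-strand coordinates.
    ``aa_length`` excludes the terminal stop; the stop's three nucleotides
    are included in the span when present (``partial3`` false).
    """

    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2 on the reading strand
    start: int
    end: int
    aa_length: int
    partial5: bool
    partial3: bool

    @property
    def complete(self) -> bool:
        return not (self.partial5 or self.partial3)


def _segments_in_frame(n_codons: int, stop_idx: List[int]):
    """Yield (first_codon, last_codon_exclusive, partial5, partial3) segments.

    Codons are indexed 0..n_codons-1 within one frame; stop_idx are the stop
    codon indices.  Segments exclude stop codons themselves.
    """
    prev = -1
    for s in stop_idx:
        yield prev + 1, s, prev == -1, False
        prev = s
    yield prev + 1, n_codons, prev == -1, True


def extract_cds(
    sequence: str, min_aa_len: int = 30, contig_id: str = ""
) -> List[CdsRecord]:
    """Segment all six frames at stop codons and keep segments of >= min_aa_len codons.

    Raises ValueError on characters outside {A,C,G,T,N}.  An empty sequence
    yields an empty list.
    """
    seq = sequence.upper()
    if not seq:
        return []
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")

    L = len(seq)
    records: List[CdsRecord] = []
    for strand in "+-":
        work = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            n_codons = (L - frame) // 3
            if n_codons <= 0:
                continue
            stops = [
                i
                for i in range(n_codons)
                if work[frame + 3 * i : frame + 3 * i + 3] in _STOP_CODONS
            ]
            for first, last, p5, p3 in _segments_in_frame(n_codons, stops):
                aa = last - first
                if aa < min_aa_len:
                    continue
                # span on the working strand; include the terminal stop when present
                ws = frame + 3 * first
                we = frame + 3 * last + (0 if p3 else 3)
                if strand == "+":
                    start, end = ws, we
                else:
                    start, end = L - we, L - ws
                records.append(
                    CdsRecord(contig_id, strand, frame, start, end, aa, p5, p3)
                )
    records.sort(key=lambda r: (-r.aa_length, r.strand, r.frame, r.start))
    return records


def select_primary_cds(records: List[CdsRecord]) -> Optional[CdsRecord]:
    """Longest CDS of one contig; ties prefer complete, then '+' strand, then lowest start."""
    if not records:
        return None
    return min(
        records,
        key=lambda r: (-r.aa_length, not r.complete, r.strand != "+", r.start),
    )


def cds_sequence(contig_seq: str, rec: CdsRecord) -> str:
    """Nucleotide sequence of a CDS on its reading strand."""
    region = contig_seq.upper()[rec.start : rec.end]
    return region if rec.strand == "+" else revcomp(region)
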