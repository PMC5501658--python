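"""Exhaustive missense enumeration over a coding annotation.

Given a genome sequence (rCRS or any toy stand-in) and a gene coordinate
table, every single-nucleotide substitution at every coding position is
translated under the vertebrate mitochondrial genetic code and emitted as a
:class:`~apogee.variants.VariantRecord` whenever the encoded amino acid
changes.  Overlapping genes (ATP8/ATP6, ND4L/ND4 in the real annotation) are
evaluated independently, so one genomic substitution may yield one record
per overlapping gene.  Stop gains/losses count as amino-acid changes by
default (``include_stop_changes``); codons are translated literally, with no
initiator-codon special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

from .exceptions import AnnotationError
from .variants import UNKNOWN, VariantRecord

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_CODON_TO_AA = dict(_MITO_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _MITO_TABLE.stop_codons})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """One codon -> one-letter amino acid ('*' for stop), mito code."""
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise AnnotationError(f"untranslatable codon {codon!r}") from None


@dataclass(frozen=True)
class GeneSpan:
    """One coding gene: 1-based inclusive genomic span, strand, reading frame."""

    gene: str
    start: int
    end: int
    strand: str
    codon_start: int = 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene}: strand must be '+' or '-'")
        if not (1 <= self.codon_start <= 3):
            raise AnnotationError(f"{self.gene}: codon_start must be 1..3")
        if self.end < self.start:
            raise AnnotationError(f"{self.gene}: end < start")


def read_gene_table(path) -> list[GeneSpan]:
    """Read the 5-column tab file: gene, start, end, strand, codon_start."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "start", "end", "strand", "codon_start"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: gene table missing columns {missing}")
    return [
        GeneSpan(row.gene, int(row.start), int(row.end), str(row.strand), int(row.codon_start))
        for row in df.itertuples()
    ]


def read_genome_fasta(path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AnnotationError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def _coding_positions(span: GeneSpan, genome_len: int):
    """Genomic positions (1-based) of the coding sequence, 5'->3' in gene order."""
    if span.end > genome_len:
        raise AnnotationError(f"{span.gene}: span end {span.end} beyond sequence length {genome_len}")
    if span.strand == "+":
        positions = list(range(span.start + span.codon_start - 1, span.end + 1))
    else:
        positions = list(range(span.end - span.codon_start + 1, span.start - 1, -1))
    if len(positions) % 3 != 0:
        raise AnnotationError(
            f"{span.gene}: coding length {len(positions)} not divisible by 3 "
            "after codon_start adjustment"
        )
    return positions


def enumerate_missense(genome: str, genes, include_stop_changes: bool = True) -> list[VariantRecord]:
    """All single-nucleotide substitutions that change the encoded amino acid.

    Returns records ordered deterministically by (gene, position, alt);
    synonymous substitutions are never emitted.  When
    ``include_stop_changes`` is False, substitutions creating or removing a
    stop codon are excluded as well.
    """
    genome = str(genome).upper()
    records: list[VariantRecord] = []
    for span in genes:
        positions = _coding_positions(span, len(genome))
        # coding-strand nucleotide at each coding position
        if span.strand == "+":
            cds = [genome[p - 1] for p in positions]
        else:
            cds = [_COMPLEMENT[genome[p - 1]] for p in positions]
        for codon_idx in range(0, len(cds), 3):
            codon = "".join(cds[codon_idx:codon_idx + 3])
            ref_aa = translate_codon(codon)
            aa_number = codon_idx // 3 + 1
            for within in range(3):
                pos = positions[codon_idx + within]
                genomic_ref = genome[pos - 1]
                for genomic_alt in _BASES:
                    if genomic_alt == genomic_ref:
                        continue
                    coding_alt = genomic_alt if span.strand == "+" else _COMPLEMENT[genomic_alt]
                    alt_codon = codon[:within] + coding_alt + codon[within + 1:]
                    alt_aa = translate_codon(alt_codon)
                    if alt_aa == ref_aa:
                        continue
                    if not include_stop_changes and "*" in (ref_aa, alt_aa):
                        continue
                    records.append(
                        VariantRecord(
                            gene=span.gene,
                            position=pos,
                            ref_allele=genomic_ref,
                            alt_allele=genomic_alt,
                            aa_change=f"{ref_aa}{aa_number}{alt_aa}",
                            label=UNKNOWN,
                        )
                    )
    records.sort(key=lambda r: (r.gene, r.position, r.alt_allele))
    return records
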