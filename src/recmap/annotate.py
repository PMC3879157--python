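"""Coding consequence annotation of single-base substitutions.

Maps a genomic substitution onto a single-transcript gene model, locates the
affected codon in the spliced CDS, translates reference and mutant codons
with the standard genetic code, classifies the consequence (synonymous,
missense, stop-gain, stop-lost) and composes HGVS-style ``c.`` / ``p.``
names.  Premature stop codons are written with the suffix ``X``
(e.g. ``p.Cys161X``) and their truncation length is reported as the number
of residues removed from the wild-type protein.

Only substitutions are handled; the gene model is one transcript with
ordered, non-overlapping CDS exons (the terminal stop codon included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .exceptions import ContractError, InputError, ReferenceMismatchError

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "X",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InMemoryReference:
    """Minimal reference-sequence store: ``{chrom: sequence}``.

    Provides the same 1-based inclusive ``fetch`` used for FASTA-backed
    references, so gene models can be resolved without touching disk.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seq = {k: str(v).upper() for k, v in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seq[chrom]
        if start < 1 or end > len(seq):
            raise InputError(
                f"requested {chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]


class FastaReference:
    """1-based inclusive fetch over an indexed FASTA file."""

    def __init__(self, path):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start - 1 : end])


@dataclass
class GeneModel:
    """Single-transcript gene model.

    ``exons`` are CDS exons as 1-based inclusive genomic intervals in
    transcription order: ascending genomic coordinates on the ``+`` strand,
    descending on the ``-`` strand.  The spliced CDS (start codon through
    terminal stop) is obtained by concatenating exon sequences in that
    order, reverse-complemented on the minus strand.
    """

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise InputError(f"exon interval {start}-{end} inverted")
        genomic_starts = sorted(s for s, _ in self.exons)
        expected = sorted(self.exons) if self.strand == "+" else sorted(self.exons, reverse=True)
        if list(self.exons) != expected:
            raise InputError("exons must be listed in transcription order")
        # non-overlap
        intervals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise InputError("exons overlap")
        del genomic_starts

    # -- geometry -------------------------------------------------------
    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based spliced-CDS offset of genomic ``pos``; None if non-coding."""
        offset = 0
        for start, end in self.exons:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start + 1)
                return offset + (end - pos + 1)
            offset += end - start + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= self.cds_length:
            raise InputError(f"cds_pos {cds_pos} outside CDS of length {self.cds_length}")
        offset = 0
        for start, end in self.exons:
            length = end - start + 1
            if cds_pos <= offset + length:
                within = cds_pos - offset
                if self.strand == "+":
                    return start + within - 1
                return end - within + 1
            offset += length
        raise AssertionError("unreachable")

    # -- sequence -------------------------------------------------------
    def spliced_cds(self, reference) -> str:
        parts = []
        for start, end in self.exons:
            seq = reference.fetch(self.chrom, start, end)
            if self.strand == "-":
                seq = _revcomp(seq)
            parts.append(seq)
        return "".join(parts)

    def protein_length(self, reference) -> int:
        """Residue count of the encoded protein (terminal stop excluded)."""
        cds = self.spliced_cds(reference)
        prot = str(Seq(cds).translate())
        return len(prot) - 1 if prot.endswith("*") else len(prot)

    def validate(self, reference) -> list[str]:
        """Structural warnings (not errors): length, start and stop codon."""
        warnings = []
        cds = self.spliced_cds(reference)
        if len(cds) % 3 != 0:
            warnings.append(f"CDS length {len(cds)} not divisible by 3")
        table = CodonTable.unambiguous_dna_by_id[1]
        if cds[:3] not in table.start_codons:
            warnings.append(f"CDS starts with {cds[:3]}, not a start codon")
        if cds[-3:] not in table.stop_codons:
            warnings.append(f"CDS ends with {cds[-3:]}, not a stop codon")
        return warnings

    # -- serialisation --------------------------------------------------
    def to_exon_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "chrom": self.chrom,
                "strand": self.strand,
                "rank": np.arange(1, len(self.exons) + 1),
                "start": [s for s, _ in self.exons],
                "end": [e for _, e in self.exons],
            }
        )

    @classmethod
    def from_exon_table(cls, table: pd.DataFrame, gene: str | None = None) -> "GeneModel":
        if gene is not None:
            table = table[table["gene"] == gene]
        if table.empty:
            raise InputError(f"gene {gene!r} absent from exon table")
        names = table["gene"].unique()
        if len(names) > 1:
            raise InputError(f"exon table mixes genes {list(names)}; pass gene=")
        table = table.sort_values("rank")
        return cls(
            gene=str(names[0]),
            chrom=str(table["chrom"].iloc[0]),
            strand=str(table["strand"].iloc[0]),
            exons=[(int(s), int(e)) for s, e in zip(table["start"], table["end"])],
        )


@dataclass
class CodingVariant:
    """A single-base coding substitution and its predicted consequence."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cds_pos: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str
    hgvs_c: str
    hgvs_p: str
    truncation: int


def genomic_to_cds(pos: int, gene_model: GeneModel) -> int | None:
    """1-based spliced CDS position of ``pos``; None signals non-coding."""
    return gene_model.genomic_to_cds(pos)


def cds_to_genomic(cds_pos: int, gene_model: GeneModel) -> int:
    return gene_model.cds_to_genomic(cds_pos)


def consequence(
    pos: int,
    ref: str,
    alt: str,
    gene_model: GeneModel,
    reference,
) -> CodingVariant | None:
    """Annotate the substitution ``ref>alt`` at genomic ``pos``.

    ``ref`` and ``alt`` are given on the reference strand (as in a VCF);
    for minus-strand genes they are complemented onto the coding strand.
    Returns ``None`` when ``pos`` is outside the CDS, raises
    :class:`ReferenceMismatchError` when ``ref`` disagrees with the
    reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise InputError("consequence() handles single-base substitutions only")
    observed = reference.fetch(gene_model.chrom, pos, pos)
    if observed != ref:
        raise ReferenceMismatchError(
            f"declared ref {ref} at {gene_model.chrom}:{pos} but reference has {observed}"
        )
    cds_pos = gene_model.genomic_to_cds(pos)
    if cds_pos is None:
        return None

    cds = gene_model.spliced_cds(reference)
    ref_cds, alt_cds = (ref, alt) if gene_model.strand == "+" else (
        _revcomp(ref),
        _revcomp(alt),
    )
    if cds[cds_pos - 1] != ref_cds:
        raise ReferenceMismatchError(
            f"spliced CDS has {cds[cds_pos - 1]} at c.{cds_pos}, expected {ref_cds}"
        )

    codon_index = (cds_pos - 1) // 3 + 1
    within = (cds_pos - 1) % 3  # 0-based position inside the codon
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = ref_codon[:within] + alt_cds + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "stop_gain"
    elif ref_aa == "*":
        kind = "stop_lost"
    else:
        kind = "missense"

    protein_length = gene_model.protein_length(reference)
    truncation = protein_length - codon_index if kind == "stop_gain" else 0

    return CodingVariant(
        gene=gene_model.gene,
        chrom=gene_model.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        cds_pos=cds_pos,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=kind,
        hgvs_c=f"c.{cds_pos}{ref_cds}>{alt_cds}",
        hgvs_p=f"p.{_AA3[ref_aa]}{codon_index}{_AA3[alt_aa]}",
        truncation=truncation,
    )


def truncation_length(variant: CodingVariant, protein_length: int) -> int:
    """Residues removed by a premature stop: protein length minus codon index."""
    if variant.consequence != "stop_gain":
        raise ContractError(
            f"truncation length defined for stop-gain variants only, got {variant.consequence}"
        )
    return protein_length - variant.codon_index


def domain_overlap(codon_index: int, domain_spans) -> list[dict]:
    """Protein domains whose 1-based inclusive span contains ``codon_index``.

    ``domain_spans`` is an iterable of ``(label, start, end)``.  Each hit is
    returned with the span length ``end - start + 1``.
    """
    hits = []
    for label, start, end in domain_spans:
        start, end = int(start), int(end)
        if start < 1 or end < start:
            raise InputError(f"malformed domain span {label!r}: {start}-{end}")
        if start <= codon_index <= end:
            hits.append({"label": label, "start": start, "end": end, "length": end - start + 1})
    return hits


def annotate_variants(variants: pd.DataFrame, gene_models, reference) -> pd.DataFrame:
    """Annotate a variant table against one or more gene models.

    ``variants`` needs columns ``chrom, pos, ref, alt``; each single-base
    substitution is tested against every gene model on its chromosome and
    one row per (variant, overlapping gene) is returned, mirroring a
    candidate-variant effect table (chrom, pos, ref, alt, gene, effect...).
    """
    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    rows = []
    for rec in variants.itertuples(index=False):
        if len(str(rec.ref)) != 1 or len(str(rec.alt)) != 1:
            continue  # substitutions only
        for gm in gene_models:
            if gm.chrom != str(rec.chrom):
                continue
            cv = consequence(int(rec.pos), str(rec.ref), str(rec.alt), gm, reference)
            if cv is None:
                continue
            rows.append(
                {
                    "chrom": cv.chrom,
                    "pos": cv.pos,
                    "ref": cv.ref,
                    "alt": cv.alt,
                    "gene": cv.gene,
                    "consequence": cv.consequence,
                    "hgvs_c": cv.hgvs_c,
                    "hgvs_p": cv.hgvs_p,
                    "codon_index": cv.codon_index,
                    "truncation": cv.truncation,
                }
            )
    columns = [
        "chrom", "pos", "ref", "alt", "gene", "consequence",
        "hgvs_c", "hgvs_p", "codon_index", "truncation",
    ]
    return pd.DataFrame(rows, columns=columns)
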