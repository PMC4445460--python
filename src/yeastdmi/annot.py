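"""Nonsense-mutation and tRNA-suppressor annotation.

A nonsense call is a substitution that converts a non-stop codon into one
of the three stop codons (TAA ochre, TAG amber, TGA opal) before the
terminal codon of an ORF.  ORF coordinates are 1-based from the A of the
start codon, so a variant in codon c (1-based) has its codon's first base
at nucleotide 3*(c-1)+1.

A tRNA becomes a nonsense suppressor when an anticodon mutation makes the
codon it reads — the reverse complement of the DNA-strand anticodon — equal
to a stop codon: e.g. a tyrosine tRNA anticodon GTA (reads TAC) mutated to
TTA reads TAA and suppresses ochre stops.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "STOP_CODONS",
    "NonsenseCall",
    "SuppressorCall",
    "call_nonsense",
    "call_nonsense_genomic",
    "genomic_to_orf_variant",
    "count_nonsense_by_class",
    "shared_nonsense_genes",
    "detect_trna_suppressor",
    "scan_trnas",
]

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
_DNA = set("ACGT")


class VariantInputError(ValueError):
    pass


@dataclass(frozen=True)
class NonsenseCall:
    """A premature stop gained inside an ORF."""

    gene_id: str
    codon_index: int      # 1-based codon number
    orf_nt_pos: int       # 1-based position of the codon's first base
    ref_codon: str
    alt_codon: str

    def __post_init__(self):
        if self.alt_codon not in STOP_CODONS:
            raise ValueError("alt codon is not a stop codon")
        if self.ref_codon in STOP_CODONS:
            raise ValueError("ref codon already a stop codon")
        if self.orf_nt_pos != 3 * (self.codon_index - 1) + 1:
            raise ValueError("orf_nt_pos inconsistent with codon_index")

    @property
    def stop_class(self) -> str:
        return self.alt_codon


@dataclass(frozen=True)
class SuppressorCall:
    trna_id: str
    anticodon_before: str
    anticodon_after: str

    @property
    def suppressed_stop(self) -> str:
        return str(Seq(self.anticodon_after).reverse_complement())


def _check_dna(s: str, what: str, length: int | None = None) -> str:
    s = s.upper()
    if not set(s) <= _DNA:
        raise VariantInputError(f"{what} contains non-ACGT characters: {s!r}")
    if length is not None and len(s) != length:
        raise VariantInputError(f"{what} must be length {length}, got {s!r}")
    return s


def call_nonsense(orf_sequence: str, variants, gene_id: str = "gene",
                  phased: bool = False) -> list:
    """Nonsense calls from single-nucleotide variants on an ORF.

    ``variants`` is an iterable of (orf_pos 1-based, ref_base, alt_base).
    By default each variant is applied independently to the reference ORF;
    ``phased=True`` applies all variants jointly first and then compares
    codons against the reference.  Variants in the terminal codon, or whose
    reference codon is already a stop, never yield a call.
    """
    seq = _check_dna(str(orf_sequence), "ORF sequence")
    if len(seq) % 3 != 0:
        raise VariantInputError("ORF length not divisible by 3")
    if not seq.startswith("ATG"):
        warnings.warn(f"{gene_id}: ORF does not start with ATG", stacklevel=2)
    if seq[-3:] not in STOP_CODONS:
        warnings.warn(f"{gene_id}: ORF does not end with a stop codon", stacklevel=2)
    n_codons = len(seq) // 3

    variants = list(variants)
    for pos, ref, alt in variants:
        if not 1 <= pos <= len(seq):
            raise VariantInputError(f"{gene_id}: variant position {pos} outside ORF")
        ref = _check_dna(ref, "ref base", 1)
        alt = _check_dna(alt, "alt base", 1)
        if seq[pos - 1] != ref:
            raise VariantInputError(
                f"{gene_id}: ref mismatch at ORF position {pos}: "
                f"sequence has {seq[pos - 1]}, variant says {ref}"
            )

    mutated = seq
    if phased:
        chars = list(seq)
        for pos, _ref, alt in variants:
            chars[pos - 1] = alt.upper()
        mutated = "".join(chars)
        codon_set = {(pos - 1) // 3 for pos, _r, _a in variants}
        calls = []
        for ci in sorted(codon_set):
            ref_codon = seq[3 * ci: 3 * ci + 3]
            alt_codon = mutated[3 * ci: 3 * ci + 3]
            if (alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS
                    and ci + 1 < n_codons):
                calls.append(
                    NonsenseCall(gene_id=gene_id, codon_index=ci + 1,
                                 orf_nt_pos=3 * ci + 1, ref_codon=ref_codon,
                                 alt_codon=alt_codon)
                )
        return calls

    calls = []
    for pos, _ref, alt in variants:
        ci = (pos - 1) // 3  # 0-based codon index
        ref_codon = seq[3 * ci: 3 * ci + 3]
        offset = (pos - 1) % 3
        alt_codon = ref_codon[:offset] + alt.upper() + ref_codon[offset + 1:]
        if alt_codon not in STOP_CODONS or ref_codon in STOP_CODONS:
            continue
        if ci + 1 >= n_codons:  # terminal codon: not a premature stop
            continue
        calls.append(
            NonsenseCall(gene_id=gene_id, codon_index=ci + 1,
                         orf_nt_pos=3 * ci + 1, ref_codon=ref_codon,
                         alt_codon=alt_codon)
        )
    return calls


def genomic_to_orf_variant(gene_start: int, gene_end: int, strand: str,
                           pos: int, ref: str, alt: str) -> tuple:
    """Map a genomic SNV onto ORF coordinates for a gene model.

    For minus-strand genes the ORF runs from ``gene_end`` back to
    ``gene_start`` and alleles are complemented.
    """
    if not gene_start <= pos <= gene_end:
        raise VariantInputError(f"position {pos} outside gene [{gene_start}, {gene_end}]")
    if strand == "+":
        return pos - gene_start + 1, ref.upper(), alt.upper()
    if strand == "-":
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return (gene_end - pos + 1, comp[ref.upper()], comp[alt.upper()])
    raise VariantInputError(f"unknown strand {strand!r}")


def call_nonsense_genomic(orf_sequence: str, gene_model, variants,
                          gene_id: str = "gene") -> list:
    """Nonsense calls for a gene given genomic-coordinate variants.

    ``gene_model`` is (chrom, start, end, strand); variants are
    (chrom, pos, ref, alt) and only those on the gene's chromosome inside
    its span are considered.
    """
    chrom, start, end, strand = gene_model
    orf_variants = [
        genomic_to_orf_variant(start, end, strand, pos, ref, alt)
        for vchrom, pos, ref, alt in variants
        if vchrom == chrom and start <= pos <= end
    ]
    return call_nonsense(orf_sequence, orf_variants, gene_id=gene_id)


def count_nonsense_by_class(calls_per_strain: dict) -> pd.DataFrame:
    """Strain x stop-class count matrix (columns TAA, TAG, TGA)."""
    rows = {}
    for strain, calls in calls_per_strain.items():
        row = {c: 0 for c in STOP_CODONS}
        for call in calls:
            row[call.stop_class] += 1
        rows[strain] = row
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    return df.reindex(columns=list(STOP_CODONS), fill_value=0)


def shared_nonsense_genes(calls_per_strain: dict) -> tuple:
    """(genes with calls in >= 2 strains, genes with calls in >= 1 strain)."""
    gene_strains: dict = {}
    for strain, calls in calls_per_strain.items():
        for call in calls:
            gene_strains.setdefault(call.gene_id, set()).add(strain)
    n_total = len(gene_strains)
    n_shared = sum(1 for strains in gene_strains.values() if len(strains) >= 2)
    return n_shared, n_total


def detect_trna_suppressor(anticodon_before: str, anticodon_after: str,
                           trna_id: str = "tRNA"):
    """Suppressor call iff the mutated anticodon now reads a stop codon.

    Anticodons are DNA 5'->3'; the codon read is the reverse complement.
    Returns None when the mutation does not create a stop-reading anticodon
    or when the tRNA already read a stop.
    """
    before = _check_dna(anticodon_before, "anticodon", 3)
    after = _check_dna(anticodon_after, "anticodon", 3)
    reads_before = str(Seq(before).reverse_complement())
    reads_after = str(Seq(after).reverse_complement())
    if reads_after not in STOP_CODONS or reads_before in STOP_CODONS:
        return None
    return SuppressorCall(trna_id=trna_id, anticodon_before=before,
                          anticodon_after=after)


def scan_trnas(trna_table, variants: dict | None = None) -> list:
    """Scan a tRNA gene set for suppressor-creating anticodon mutations.

    ``trna_table`` is an iterable of (trna_id, anticodon) pairs (DNA
    5'->3'); ``variants`` maps trna_id -> list of (anticodon_pos 1..3,
    ref_base, alt_base).  An empty result is a valid, logged outcome.
    """
    variants = variants or {}
    trna_table = list(trna_table)
    calls = []
    for trna_id, anticodon in trna_table:
        anticodon = _check_dna(anticodon, f"{trna_id} anticodon", 3)
        muts = variants.get(trna_id, [])
        if not muts:
            continue
        after = list(anticodon)
        for pos, ref, alt in muts:
            if not 1 <= pos <= 3:
                raise VariantInputError(f"{trna_id}: anticodon position {pos} invalid")
            if after[pos - 1] != ref.upper():
                raise VariantInputError(
                    f"{trna_id}: ref mismatch at anticodon position {pos}"
                )
            after[pos - 1] = _check_dna(alt, "alt base", 1)
        call = detect_trna_suppressor(anticodon, "".join(after), trna_id=trna_id)
        if call is not None:
            calls.append(call)
    if not calls:
        log.info("no tRNA suppressor of any anticodon class found "
                 "(%d tRNA genes scanned)", len(list(trna_table)))
    return calls
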