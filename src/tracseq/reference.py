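"""Mature tRNA reference construction and the m7G codon decoding map.

tRNA genes are supplied as FASTA with a pipe-delimited header dialect::

    >gene_id|isotype|anticodon[|introns=a-b[,c-d]]

Intron intervals are 1-based, closed, on the unspliced gene sequence.
A mature tRNA is the spliced gene sequence with ``CCA`` appended to the
3' end; all coordinates downstream (pileups, site calls) are 1-based
positions on this mature sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceError",
    "TRNAGene",
    "MatureTRNA",
    "M7GCodonSet",
    "revcomp",
    "build_mature_trna",
    "build_reference",
    "load_trna_genes",
    "load_mature_trnas",
    "decoded_codons",
    "build_m7g_codon_set",
    "write_reference_fasta",
    "write_reference_table",
]

DNA_ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3)) if c not in STOP_CODONS
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Wobble pairing at the codon third position: anticodon 5' base (position 34)
#: -> admissible codon third bases.  Watson-Crick partner always included.
WOBBLE_THIRD_BASE = {"G": "CT", "T": "AG", "A": "T", "C": "G"}


class ReferenceError(ValueError):
    """Raised for malformed tRNA gene models or inconsistent references."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_dna(seq: str, what: str) -> str:
    seq = _normalize(seq)
    if not seq or set(seq) - DNA_ALPHABET:
        raise ReferenceError(f"{what} contains non-ACGT characters: {seq!r}")
    return seq


@dataclass(frozen=True)
class TRNAGene:
    """An unspliced tRNA gene model (tRNAscan-SE style prediction)."""

    gene_id: str
    genomic_sequence: str
    anticodon: str
    isotype: str
    intron_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomic_sequence", _check_dna(self.genomic_sequence, f"gene {self.gene_id}"))
        object.__setattr__(self, "anticodon", _check_dna(self.anticodon, f"anticodon of {self.gene_id}"))
        if len(self.anticodon) != 3:
            raise ReferenceError(f"anticodon of {self.gene_id} is not a 3-mer: {self.anticodon!r}")
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intron_intervals))
        n = len(self.genomic_sequence)
        prev_end = 0
        for a, b in ivs:
            if a < 1 or b > n or a > b:
                raise ReferenceError(f"intron ({a},{b}) out of range for gene {self.gene_id} (length {n})")
            if a <= prev_end:
                raise ReferenceError(f"overlapping introns in gene {self.gene_id}")
            prev_end = b
        object.__setattr__(self, "intron_intervals", ivs)
        if self.anticodon not in self.spliced_sequence:
            raise ReferenceError(f"anticodon {self.anticodon} absent from spliced sequence of {self.gene_id}")

    @property
    def spliced_sequence(self) -> str:
        seq = self.genomic_sequence
        out = []
        pos = 0
        for a, b in self.intron_intervals:
            out.append(seq[pos : a - 1])
            pos = b
        out.append(seq[pos:])
        return "".join(out)


@dataclass(frozen=True)
class MatureTRNA:
    """A mature tRNA: spliced sequence with the 3' CCA tail appended."""

    trna_id: str
    sequence: str
    anticodon: str
    isotype: str
    source_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, f"mature tRNA {self.trna_id}"))
        if not self.sequence.endswith("CCA"):
            raise ReferenceError(f"mature tRNA {self.trna_id} does not end in CCA")
        if not self.source_gene_ids:
            object.__setattr__(self, "source_gene_ids", (self.trna_id,))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class M7GCodonSet:
    """Codons decoded by m7G-modified tRNAs.

    ``codons`` holds sense codons only; any decoded stop codon (possible
    only for suppressor-like anticodons or under wobble expansion) is
    excluded from ``codons`` and flagged in ``stop_codons``.
    """

    codons: frozenset[str]
    source_trnas: tuple[str, ...]
    stop_codons: frozenset[str] = frozenset()

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons

    def __len__(self) -> int:
        return len(self.codons)


def build_mature_trna(gene: TRNAGene) -> MatureTRNA:
    """Excise the predicted introns and append CCA to the 3' end."""
    return MatureTRNA(
        trna_id=gene.gene_id,
        sequence=gene.spliced_sequence + "CCA",
        anticodon=gene.anticodon,
        isotype=gene.isotype,
        source_gene_ids=(gene.gene_id,),
    )


def build_reference(genes: Iterable[TRNAGene], collapse_duplicates: bool = True) -> list[MatureTRNA]:
    """Build the mature reference, optionally collapsing identical mature
    sequences from distinct gene loci into one entry with a multi-locus id list."""
    matures = [build_mature_trna(g) for g in genes]
    if not collapse_duplicates:
        return matures
    by_seq: dict[str, MatureTRNA] = {}
    order: list[str] = []
    for m in matures:
        if m.sequence in by_seq:
            prev = by_seq[m.sequence]
            by_seq[m.sequence] = MatureTRNA(
                trna_id=prev.trna_id,
                sequence=prev.sequence,
                anticodon=prev.anticodon,
                isotype=prev.isotype,
                source_gene_ids=prev.source_gene_ids + (m.trna_id,),
            )
        else:
            by_seq[m.sequence] = m
            order.append(m.sequence)
    return [by_seq[s] for s in order]


def _parse_header(header: str) -> tuple[str, str, str, tuple[tuple[int, int], ...]]:
    parts = header.split("|")
    if len(parts) < 3:
        raise ReferenceError(f"malformed header (need id|isotype|anticodon[|introns=..]): {header!r}")
    gene_id, isotype, anticodon = parts[0], parts[1], parts[2]
    introns: tuple[tuple[int, int], ...] = ()
    for extra in parts[3:]:
        if extra.startswith("introns="):
            spans = extra[len("introns=") :]
            if spans:
                try:
                    introns = tuple(
                        (int(a), int(b)) for a, b in (span.split("-") for span in spans.split(","))
                    )
                except ValueError as exc:
                    raise ReferenceError(f"bad intron annotation in header {header!r}") from exc
        elif extra:
            raise ReferenceError(f"unrecognized header field {extra!r} in {header!r}")
    return gene_id, isotype, anticodon, introns


def load_trna_genes(path: str | Path) -> list[TRNAGene]:
    """Load tRNA gene models from FASTA with the pipe-delimited header dialect."""
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        try:
            gene_id, isotype, anticodon, introns = _parse_header(header)
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    genomic_sequence=str(rec.seq),
                    anticodon=anticodon,
                    isotype=isotype,
                    intron_intervals=introns,
                )
            )
        except ReferenceError as exc:
            raise ReferenceError(f"record {rec.id!r}: {exc}") from exc
    return genes


def load_mature_trnas(path: str | Path) -> list[MatureTRNA]:
    """Load a pre-built mature tRNA FASTA (CCA already present) as-is."""
    matures = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        trna_id, isotype, anticodon, _ = _parse_header(header)
        matures.append(
            MatureTRNA(trna_id=trna_id, sequence=str(rec.seq), anticodon=anticodon, isotype=isotype)
        )
    return matures


def decoded_codons(anticodon: str, wobble: bool = False) -> set[str]:
    """Codons read by a tRNA with the given anticodon.

    With ``wobble`` off the decoded codon is the strict reverse complement
    (e.g. anticodon CTT -> codon AAG).  With ``wobble`` on, the codon third
    position is additionally expanded per the anticodon-34 wobble table.
    """
    anticodon = _check_dna(anticodon, "anticodon")
    if len(anticodon) != 3:
        raise ReferenceError(f"anticodon is not a 3-mer: {anticodon!r}")
    base = revcomp(anticodon)
    if not wobble:
        return {base}
    return {base[:2] + third for third in WOBBLE_THIRD_BASE[anticodon[0]]}


def build_m7g_codon_set(
    calls: Sequence,
    reference: Sequence[MatureTRNA],
    wobble: bool = False,
) -> M7GCodonSet:
    """Union of decoded codons over tRNAs carrying at least one m7G site call.

    ``calls`` is any sequence of objects with ``trna_id`` and (optionally)
    ``passed`` attributes; non-passing calls are ignored.
    """
    by_id = {m.trna_id: m for m in reference}
    called: list[str] = []
    for call in calls:
        if getattr(call, "passed", True):
            tid = getattr(call, "trna_id", call if isinstance(call, str) else None)
            if tid not in by_id:
                raise ReferenceError(f"m7G call references unknown tRNA {tid!r}")
            if tid not in called:
                called.append(tid)
    codons: set[str] = set()
    for tid in called:
        codons |= decoded_codons(by_id[tid].anticodon, wobble=wobble)
    return M7GCodonSet(
        codons=frozenset(codons - STOP_CODONS),
        source_trnas=tuple(called),
        stop_codons=frozenset(codons & STOP_CODONS),
    )


def write_reference_fasta(matures: Sequence[MatureTRNA], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=f"{m.trna_id}|{m.isotype}|{m.anticodon}", description="")
        for m in matures
    ]
    SeqIO.write(records, str(path), "fasta")


def write_reference_table(matures: Sequence[MatureTRNA], path: str | Path) -> None:
    """TSV reference table: trna_id, isotype, anticodon, length, source loci."""
    with open(path, "w") as fh:
        fh.write("# trna_id\tisotype\tanticodon\tlength\tsource_gene_ids\n")
        for m in matures:
            fh.write(
                f"{m.trna_id}\t{m.isotype}\t{m.anticodon}\t{m.length}\t{','.join(m.source_gene_ids)}\n"
            )
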