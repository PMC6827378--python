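"""Paired protein/CDS records with residue-to-codon mapping.

A :class:`ProteinRecord` couples an amino-acid sequence with its coding
sequence so that any residue — in particular any proline — can be traced back
to the codon that encoded it. This mapping is what turns a peptide-level
substitution detection into a codon-resolved mistranslation event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

#: forward codon table of the standard genetic code, DNA alphabet
CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

_DNA = set("ACGT")


class ProteomeError(ValueError):
    """Raised for malformed or inconsistent protein/CDS input."""


def translate_cds(cds: str) -> str:
    """Translate a coding sequence under the standard genetic code.

    A single trailing stop codon is accepted and yields no residue; an
    internal stop codon, a length not divisible by 3 or a non-ACGT character
    raises :class:`ProteomeError`. ``U`` is accepted as a synonym of ``T``.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ProteomeError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - _DNA
    if bad:
        raise ProteomeError(f"non-ACGT character(s) in CDS: {sorted(bad)}")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ProteomeError(f"internal stop codon {codon} at codon index {i}")
        residues.append(CODON_TABLE[codon])
    return "".join(residues)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein and its coding sequence, validated to translate exactly."""

    id: str
    aa_seq: str
    cds_seq: str  # DNA alphabet, may carry a trailing stop codon

    def __post_init__(self) -> None:
        if not self.id:
            raise ProteomeError("empty record id")
        cds = self.cds_seq.upper().replace("U", "T")
        object.__setattr__(self, "cds_seq", cds)
        object.__setattr__(self, "aa_seq", self.aa_seq.upper())
        translated = translate_cds(cds)
        if translated != self.aa_seq:
            diff = next(
                (i for i, (a, b) in enumerate(zip(translated, self.aa_seq)) if a != b),
                min(len(translated), len(self.aa_seq)),
            )
            raise ProteomeError(
                f"record {self.id!r}: CDS translation differs from protein at "
                f"residue {diff + 1} (1-based)"
            )
        if len(cds) not in (3 * len(self.aa_seq), 3 * len(self.aa_seq) + 3):
            raise ProteomeError(f"record {self.id!r}: CDS/protein length mismatch")

    def __len__(self) -> int:
        return len(self.aa_seq)

    def codon_at(self, residue_index: int, alphabet: str = "rna") -> str:
        """Codon encoding residue ``residue_index`` (0-based).

        ``alphabet`` selects ``"rna"`` (default; proline codons read CCA/CCG/
        CCU/CCC) or ``"dna"`` reporting.
        """
        if not 0 <= residue_index < len(self.aa_seq):
            raise IndexError(
                f"residue index {residue_index} out of range for {self.id!r} "
                f"(length {len(self.aa_seq)})"
            )
        codon = self.cds_seq[3 * residue_index : 3 * residue_index + 3]
        if alphabet == "rna":
            return codon.replace("T", "U")
        if alphabet == "dna":
            return codon
        raise ValueError(f"unknown codon alphabet {alphabet!r}")


def codon_at(record: ProteinRecord, residue_index: int, alphabet: str = "rna") -> str:
    """Functional alias for :meth:`ProteinRecord.codon_at`."""
    return record.codon_at(residue_index, alphabet=alphabet)


@dataclass
class Proteome:
    """A collection of :class:`ProteinRecord` keyed by id."""

    records: Dict[str, ProteinRecord] = field(default_factory=dict)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self.records:
            raise ProteomeError(f"duplicate record id {record.id!r}")
        self.records[record.id] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records.values())

    def __getitem__(self, record_id: str) -> ProteinRecord:
        return self.records[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.records


def _read_fasta(path: str | Path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ProteomeError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def load_proteome(
    aa_fasta: str | Path,
    cds_fasta: str | Path,
    on_unpaired: str = "error",
    permissive: bool = False,
) -> Proteome:
    """Load a matched protein/CDS FASTA pair into a validated :class:`Proteome`.

    Records are matched by id (first whitespace-delimited header token).
    ``on_unpaired`` is ``"error"`` or ``"skip"`` for records present in only
    one file. With ``permissive=True`` records containing ambiguity characters
    (N in the CDS, X in the protein) are dropped with a warning instead of
    raising.
    """
    if on_unpaired not in ("error", "skip"):
        raise ValueError("on_unpaired must be 'error' or 'skip'")
    aa = _read_fasta(aa_fasta)
    cds = _read_fasta(cds_fasta)
    unpaired = set(aa) ^ set(cds)
    if unpaired:
        if on_unpaired == "error":
            raise ProteomeError(
                f"{len(unpaired)} record(s) lack a partner, e.g. {sorted(unpaired)[:3]}"
            )
        logger.warning("skipping %d unpaired record(s)", len(unpaired))
    proteome = Proteome()
    for rid in aa:
        if rid not in cds:
            continue
        if permissive and (set(aa[rid]) - set("ACDEFGHIKLMNPQRSTVWY") or
                           set(cds[rid].replace("U", "T")) - _DNA):
            logger.warning("dropping record %r: ambiguity characters", rid)
            continue
        proteome.add(ProteinRecord(rid, aa[rid], cds[rid]))
    if not len(proteome):
        raise ProteomeError("no valid records loaded")
    return proteome


def write_proteome(
    proteome: Proteome, aa_fasta: str | Path, cds_fasta: str | Path
) -> None:
    """Write a proteome back to a protein/CDS FASTA pair."""
    aa_records: Iterable[SeqRecord] = (
        SeqRecord(Seq(r.aa_seq), id=r.id, description="") for r in proteome
    )
    cds_records: Iterable[SeqRecord] = (
        SeqRecord(Seq(r.cds_seq), id=r.id, description="") for r in proteome
    )
    SeqIO.write(aa_records, str(aa_fasta), "fasta")
    SeqIO.write(cds_records, str(cds_fasta), "fasta")
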