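"""In-silico LysC digestion and the searchable peptide index.

LysC cleaves C-terminal to lysine, including K-P bonds (no proline rule,
unlike trypsin). Digestion products carry their protein coordinates so the
index can flag sequence uniqueness and map each proline within a peptide to
the codon that encoded it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .proteome import ProteinRecord, Proteome


@dataclass(frozen=True)
class PeptideLocus:
    """One digestion product located on one protein."""

    protein_id: str
    start: int  # 0-based inclusive residue index
    end: int  # exclusive
    seq: str
    n_missed: int

    def __len__(self) -> int:
        return len(self.seq)


def digest_lysc(
    aa_seq: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: Optional[int] = 50,
    protein_id: str = "",
) -> List[PeptideLocus]:
    """Digest a protein C-terminal to every lysine.

    Fragments between cut sites are merged into peptides with up to
    ``max_missed`` internal (missed) K sites, then filtered to
    ``[min_len, max_len]`` residues (``max_len=None`` disables the upper
    bound). Peptides are returned ordered by start position, then length.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    if max_missed < 0 or min_len < 1:
        raise ValueError("max_missed must be >= 0 and min_len >= 1")
    aa_seq = aa_seq.upper()
    # fragment boundaries: cut after every K
    starts = [0] + [i + 1 for i, aa in enumerate(aa_seq) if aa == "K" and i + 1 < len(aa_seq)]
    ends = starts[1:] + [len(aa_seq)]
    out: List[PeptideLocus] = []
    for i, start in enumerate(starts):
        for m in range(max_missed + 1):
            if i + m >= len(ends):
                break
            end = ends[i + m]
            seq = aa_seq[start:end]
            if len(seq) < min_len or (max_len is not None and len(seq) > max_len):
                continue
            n_missed = seq[:-1].count("K")
            out.append(PeptideLocus(protein_id, start, end, seq, n_missed))
    return out


@dataclass
class PeptideEntry:
    """Index entry for one peptide sequence."""

    seq: str
    loci: List[PeptideLocus]
    proline_positions: Tuple[int, ...]  # 0-based positions of P within the peptide

    @property
    def is_unique(self) -> bool:
        return len(self.loci) == 1

    @property
    def n_prolines(self) -> int:
        return len(self.proline_positions)


class PeptideIndex:
    """Map from peptide sequence to loci, uniqueness and proline codons."""

    def __init__(self, proteome: Proteome, codon_alphabet: str = "rna") -> None:
        self._proteome = proteome
        self._codon_alphabet = codon_alphabet
        self._entries: Dict[str, PeptideEntry] = {}

    def _add_locus(self, locus: PeptideLocus) -> None:
        entry = self._entries.get(locus.seq)
        if entry is None:
            prolines = tuple(i for i, aa in enumerate(locus.seq) if aa == "P")
            entry = PeptideEntry(locus.seq, [], prolines)
            self._entries[locus.seq] = entry
        entry.loci.append(locus)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, seq: str) -> bool:
        return seq in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def lookup(self, seq: str) -> Optional[PeptideEntry]:
        """Entry for ``seq``, or ``None`` if the sequence was never produced."""
        return self._entries.get(seq)

    def codons_at(self, seq: str, peptide_pos: int) -> List[str]:
        """Codons encoding peptide position ``peptide_pos``, one per locus."""
        entry = self._entries[seq]
        return [
            self._proteome[loc.protein_id].codon_at(
                loc.start + peptide_pos, alphabet=self._codon_alphabet
            )
            for loc in entry.loci
        ]

    def single_proline_codon(self, seq: str) -> Optional[str]:
        """The codon of a unique single-proline peptide, else ``None``."""
        entry = self._entries.get(seq)
        if entry is None or not entry.is_unique or entry.n_prolines != 1:
            return None
        return self.codons_at(seq, entry.proline_positions[0])[0]

    def to_frame(self) -> pd.DataFrame:
        """Export as a table (coordinates 1-based, as reported to users)."""
        rows = []
        for entry in sorted(self._entries.values(), key=lambda e: e.seq):
            for loc in entry.loci:
                rows.append(
                    {
                        "sequence": entry.seq,
                        "protein_id": loc.protein_id,
                        "start": loc.start + 1,
                        "end": loc.end,
                        "n_missed": loc.n_missed,
                        "is_unique": int(entry.is_unique),
                        "proline_positions": ";".join(
                            str(p + 1) for p in entry.proline_positions
                        ),
                        "codons": ";".join(
                            self._proteome[loc.protein_id].codon_at(
                                loc.start + p, alphabet=self._codon_alphabet
                            )
                            for p in entry.proline_positions
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_peptide_index(
    proteome: Proteome,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: Optional[int] = 50,
    codon_alphabet: str = "rna",
) -> PeptideIndex:
    """Digest every record and assemble the peptide index."""
    index = PeptideIndex(proteome, codon_alphabet=codon_alphabet)
    for record in proteome:
        for locus in digest_lysc(
            record.aa_seq,
            max_missed=max_missed,
            min_len=min_len,
            max_len=max_len,
            protein_id=record.id,
        ):
            index._add_locus(locus)
    return index
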