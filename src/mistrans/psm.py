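"""Peptide-spectrum matches: masses, decoys and target-decoy FDR.

The PSM model mirrors what a search engine exports after identification:
a base (proteome-space) peptide sequence, a modification list, a neutral
monoisotopic observed mass, a score (higher is better; adapters may negate
e-values on import) and a decoy flag. The serine-for-proline substitution is
carried as a variable modification whose delta is mass(Ser) - mass(Pro), the
same trick the search uses to detect substituted peptides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .proteome import ProteinRecord, Proteome

WATER_MONO = _pmass.calculate_mass(formula="H2O")

#: monoisotopic residue (not free amino acid) masses, Da
RESIDUE_MASS = dict(_pmass.std_aa_mass)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class ModKind(str, enum.Enum):
    """Modification vocabulary of the search."""

    CARBAMIDOMETHYL_C = "carbamidomethyl_C"  # fixed, on C
    OXIDATION_M = "oxidation_M"  # variable, on M
    ACETYL_NTERM = "acetyl_protein_Nterm"  # variable, protein N-terminus
    PRO_TO_SER = "pro_to_ser_sub"  # variable, on P: the substitution itself


MOD_DELTA = {
    ModKind.CARBAMIDOMETHYL_C: _pmass.calculate_mass(formula="H3C2NO"),
    ModKind.OXIDATION_M: _pmass.calculate_mass(formula="O"),
    ModKind.ACETYL_NTERM: _pmass.calculate_mass(formula="C2H2O"),
    ModKind.PRO_TO_SER: RESIDUE_MASS["S"] - RESIDUE_MASS["P"],
}

NTERM = None  # position sentinel for protein N-terminal modifications
MAX_SUBS_PER_PSM = 2


@dataclass(frozen=True)
class Modification:
    """One modification at a 0-based peptide position (None = N-terminus)."""

    kind: ModKind
    position: Optional[int] = NTERM

    def to_token(self) -> str:
        pos = "nterm" if self.position is NTERM else str(self.position + 1)
        return f"{self.kind.value}@{pos}"

    @classmethod
    def from_token(cls, token: str) -> "Modification":
        kind_s, _, pos_s = token.partition("@")
        kind = ModKind(kind_s)
        return cls(kind, NTERM if pos_s == "nterm" else int(pos_s) - 1)


def _validate_mods(seq: str, mods: Sequence[Modification]) -> None:
    site_aa = {
        ModKind.CARBAMIDOMETHYL_C: "C",
        ModKind.OXIDATION_M: "M",
        ModKind.PRO_TO_SER: "P",
    }
    n_subs = 0
    for mod in mods:
        if mod.kind is ModKind.ACETYL_NTERM:
            if mod.position not in (NTERM, 0):
                raise ValueError("N-terminal acetylation must sit at the N-terminus")
            continue
        if mod.position is NTERM or not 0 <= mod.position < len(seq):
            raise ValueError(f"modification {mod.to_token()} out of range")
        want = site_aa[mod.kind]
        if seq[mod.position] != want:
            raise ValueError(
                f"{mod.kind.value} at position {mod.position + 1} requires {want}, "
                f"found {seq[mod.position]}"
            )
        if mod.kind is ModKind.PRO_TO_SER:
            n_subs += 1
    if n_subs > MAX_SUBS_PER_PSM:
        raise ValueError(f"more than {MAX_SUBS_PER_PSM} Pro->Ser substitutions")


def peptide_monoisotopic_mass(seq: str, mods: Sequence[Modification] = ()) -> float:
    """Neutral monoisotopic peptide mass with modification deltas applied."""
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue(s): {sorted(bad)}")
    _validate_mods(seq, mods)
    return (
        sum(RESIDUE_MASS[aa] for aa in seq)
        + WATER_MONO
        + sum(MOD_DELTA[m.kind] for m in mods)
    )


def within_precursor_tolerance(
    observed: float, theoretical: float, tol_ppm: float = 50.0
) -> bool:
    """True when |observed - theoretical| is within ``tol_ppm`` of theoretical."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(observed - theoretical) / theoretical * 1e6 <= tol_ppm


def generate_decoy_proteome(proteome: Proteome) -> Proteome:
    """Full-protein reversal decoys, one per target, ids prefixed ``decoy_``.

    The CDS is reversed codon-wise (after stripping any trailing stop) so the
    decoy record still satisfies the translation invariant.
    """
    decoys = Proteome()
    for rec in proteome:
        cds = rec.cds_seq[: 3 * len(rec.aa_seq)]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        decoys.add(
            ProteinRecord(
                f"decoy_{rec.id}", rec.aa_seq[::-1], "".join(reversed(codons))
            )
        )
    return decoys


@dataclass
class PSMRecord:
    """One peptide-spectrum match as exported after the search."""

    spectrum_id: str
    base_seq: str
    mods: Tuple[Modification, ...] = ()
    observed_mass: float = 0.0
    score: float = 0.0
    is_decoy: bool = False
    replicate_id: str = "rep1"
    q_value: Optional[float] = None

    @property
    def sub_positions(self) -> Tuple[int, ...]:
        return tuple(
            m.position for m in self.mods if m.kind is ModKind.PRO_TO_SER
        )

    @property
    def has_extra_modification(self) -> bool:
        """Variable modifications other than the substitution itself."""
        return any(
            m.kind in (ModKind.OXIDATION_M, ModKind.ACETYL_NTERM) for m in self.mods
        )

    @property
    def substituted_seq(self) -> str:
        """The sequence with P->S applied at the substituted positions."""
        seq = list(self.base_seq)
        for pos in self.sub_positions:
            seq[pos] = "S"
        return "".join(seq)


def compute_qvalues(psms: Sequence[PSMRecord]) -> List[PSMRecord]:
    """Assign target-decoy q-values.

    At each score threshold s, FDR(s) = #decoys(score >= s) / max(1,
    #targets(score >= s)); the q-value is the running minimum of FDR over
    decreasing score. Tied target/decoy scores are counted decoys-first
    (conservative). Returns the PSMs sorted by decreasing score.
    """
    if not psms:
        raise ValueError("empty PSM list")
    scores = np.array([p.score for p in psms], dtype=float)
    is_decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    # sort by decreasing score; among ties decoys come first
    order = np.lexsort((~is_decoy, -scores))
    d_sorted = is_decoy[order]
    cum_decoys = np.cumsum(d_sorted)
    cum_targets = np.cumsum(~d_sorted)
    fdr = cum_decoys / np.maximum(1, cum_targets)
    qvals = np.minimum.accumulate(fdr[::-1])[::-1]
    return [replace(psms[i], q_value=float(q)) for i, q in zip(order, qvals)]


def filter_psms(psms: Sequence[PSMRecord], alpha: float = 0.01) -> List[PSMRecord]:
    """Target PSMs surviving the q-value cut (decoys are never returned)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    out = []
    for p in psms:
        if p.is_decoy:
            continue
        if p.q_value is None:
            raise ValueError("q-values not computed; run compute_qvalues first")
        if p.q_value <= alpha:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# PSM TSV interchange format

PSM_COLUMNS = [
    "spectrum_id",
    "replicate_id",
    "base_seq",
    "mods",
    "observed_mass",
    "score",
    "is_decoy",
]


def psms_to_frame(psms: Iterable[PSMRecord]) -> pd.DataFrame:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "replicate_id": p.replicate_id,
            "base_seq": p.base_seq,
            "mods": ";".join(m.to_token() for m in p.mods),
            "observed_mass": p.observed_mass,
            "score": p.score,
            "is_decoy": int(p.is_decoy),
        }
        for p in psms
    ]
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_tsv(psms: Iterable[PSMRecord], path: str | Path) -> None:
    psms_to_frame(psms).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def frame_to_psms(df: pd.DataFrame) -> List[PSMRecord]:
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PSM table missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        mods = tuple(
            Modification.from_token(tok)
            for tok in str(row.mods).split(";")
            if tok and tok != "nan"
        )
        out.append(
            PSMRecord(
                spectrum_id=str(row.spectrum_id),
                replicate_id=str(row.replicate_id),
                base_seq=str(row.base_seq),
                mods=mods,
                observed_mass=float(row.observed_mass),
                score=float(row.score),
                is_decoy=bool(int(row.is_decoy)),
            )
        )
    return out


def read_psm_tsv(path: str | Path) -> List[PSMRecord]:
    return frame_to_psms(pd.read_csv(path, sep="\t", keep_default_na=False))
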