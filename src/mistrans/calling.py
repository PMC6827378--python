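"""Substitution calling and mistranslation-frequency estimation.

The frequency statistic is detection-level: among unique, proline-containing
peptides detected in a replicate, the fraction whose serine-substituted
version was also detected. Stringent filters suppress false substitution
calls: a candidate fails if it carries additional variable modifications
(oxidation or N-terminal acetylation), if its wild-type peptide was never
detected in the same replicate, or — an extra safeguard added here, on by
default — if the substituted sequence collides with a wild-type peptide
elsewhere in the proteome. Codon-resolved estimates use only peptides with a
single proline so the substituted site (and hence the codon) is unambiguous.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .digest import PeptideIndex
from .psm import (
    PSMRecord,
    peptide_monoisotopic_mass,
    within_precursor_tolerance,
)

logger = logging.getLogger(__name__)

PROLINE_CODONS = ("CCA", "CCG", "CCU", "CCC")


class FilterFailure(str, enum.Enum):
    EXTRA_MODIFICATION = "extra_modification"
    NO_WILDTYPE_COUNTERPART = "no_wildtype_counterpart"
    AMBIGUOUS_MAPPING = "ambiguous_mapping"
    MULTI_PROLINE = "multi_proline"  # codon-level eligibility only


@dataclass
class SubstitutionCall:
    """One substituted-peptide detection with its filter outcome."""

    base_seq: str
    sub_positions: Tuple[int, ...]  # 0-based within peptide
    replicate_id: str
    protein_id: Optional[str] = None  # set for unique peptides
    protein_residue_indices: Tuple[int, ...] = ()  # 0-based
    codons: Tuple[str, ...] = ()  # one per substituted site (unique peptides)
    passed: bool = True
    fail_reason: Optional[FilterFailure] = None

    def fail(self, reason: FilterFailure) -> None:
        self.passed = False
        self.fail_reason = reason


@dataclass
class MistranslationEstimate:
    """numerator / denominator frequency for one scope and replicate."""

    scope: str  # "overall" or a proline codon
    numerator: int
    denominator: int
    replicate_id: str

    @property
    def frequency(self) -> Optional[float]:
        """Fraction, or None when no eligible peptide was detected."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def annotate_psms(
    psms: Sequence[PSMRecord],
    index: PeptideIndex,
    tol_ppm: Optional[float] = 50.0,
) -> Tuple[List[PSMRecord], List[SubstitutionCall]]:
    """Split filtered target PSMs into base detections and candidates.

    PSMs whose base sequence is absent from the index are dropped (logged),
    as are PSMs whose observed mass is outside ``tol_ppm`` of the theoretical
    modified mass (``tol_ppm=None`` skips the check). Candidates whose
    substituted sequence equals a wild-type peptide anywhere in the index are
    flagged ``ambiguous_mapping`` here; remaining filters are applied by
    :func:`apply_filters`.
    """
    base_detections: List[PSMRecord] = []
    candidates: List[SubstitutionCall] = []
    n_unmapped = n_mass = 0
    for psm in psms:
        entry = index.lookup(psm.base_seq)
        if entry is None:
            n_unmapped += 1
            continue
        if tol_ppm is not None:
            theoretical = peptide_monoisotopic_mass(psm.base_seq, psm.mods)
            if not within_precursor_tolerance(
                psm.observed_mass, theoretical, tol_ppm
            ):
                n_mass += 1
                continue
        subs = psm.sub_positions
        if not subs:
            base_detections.append(psm)
            continue
        call = SubstitutionCall(
            base_seq=psm.base_seq,
            sub_positions=subs,
            replicate_id=psm.replicate_id,
        )
        if psm.has_extra_modification:
            call.fail(FilterFailure.EXTRA_MODIFICATION)
        if call.passed and index.lookup(psm.substituted_seq) is not None:
            call.fail(FilterFailure.AMBIGUOUS_MAPPING)
        if entry.is_unique:
            locus = entry.loci[0]
            call.protein_id = locus.protein_id
            call.protein_residue_indices = tuple(locus.start + p for p in subs)
            call.codons = tuple(index.codons_at(psm.base_seq, p)[0] for p in subs)
        candidates.append(call)
    if n_unmapped:
        logger.warning("dropped %d PSM(s) not mappable to the index", n_unmapped)
    if n_mass:
        logger.warning("dropped %d PSM(s) outside precursor tolerance", n_mass)
    return base_detections, candidates


def apply_filters(
    candidates: Iterable[SubstitutionCall],
    base_detections: Sequence[PSMRecord],
) -> List[SubstitutionCall]:
    """Apply the wild-type-counterpart filter; keep failures for reporting.

    A base detection in the same replicate counts as the wild-type
    counterpart whatever its oxidation/acetylation state (the extra-
    modification filter applies to substituted peptides only).
    """
    detected: Dict[str, Set[str]] = {}
    for psm in base_detections:
        detected.setdefault(psm.replicate_id, set()).add(psm.base_seq)
    out = []
    for call in candidates:
        if call.passed and call.base_seq not in detected.get(
            call.replicate_id, set()
        ):
            call.fail(FilterFailure.NO_WILDTYPE_COUNTERPART)
        out.append(call)
    return out


def _detected_unique_by_replicate(
    base_detections: Sequence[PSMRecord], index: PeptideIndex
) -> Dict[str, Set[str]]:
    """Per replicate, the unique peptide sequences with a base detection."""
    out: Dict[str, Set[str]] = {}
    for psm in base_detections:
        entry = index.lookup(psm.base_seq)
        if entry is not None and entry.is_unique:
            out.setdefault(psm.replicate_id, set()).add(psm.base_seq)
    return out


def estimate_overall(
    calls: Sequence[SubstitutionCall],
    base_detections: Sequence[PSMRecord],
    index: PeptideIndex,
) -> Dict[str, MistranslationEstimate]:
    """Overall mistranslation frequency per replicate.

    Denominator: distinct unique peptides with at least one proline detected
    (as a base PSM, any modification state) in the replicate. Numerator:
    those with at least one passing substitution call.
    """
    detected = _detected_unique_by_replicate(base_detections, index)
    passing: Dict[str, Set[str]] = {}
    for call in calls:
        if call.passed:
            passing.setdefault(call.replicate_id, set()).add(call.base_seq)
    out = {}
    for rep, seqs in sorted(detected.items()):
        eligible = {s for s in seqs if index.lookup(s).n_prolines >= 1}
        num = len(eligible & passing.get(rep, set()))
        out[rep] = MistranslationEstimate("overall", num, len(eligible), rep)
    return out


def estimate_per_codon(
    calls: Sequence[SubstitutionCall],
    base_detections: Sequence[PSMRecord],
    index: PeptideIndex,
) -> Dict[str, Dict[str, MistranslationEstimate]]:
    """Per-proline-codon frequency per replicate.

    Only unique peptides with exactly one proline are eligible (multi-proline
    peptides are excluded to avoid site-localization ambiguity); each is
    assigned to the codon encoding that proline.
    """
    detected = _detected_unique_by_replicate(base_detections, index)
    passing: Dict[str, Set[str]] = {}
    for call in calls:
        if call.passed:
            passing.setdefault(call.replicate_id, set()).add(call.base_seq)
    out: Dict[str, Dict[str, MistranslationEstimate]] = {}
    for rep, seqs in sorted(detected.items()):
        by_codon: Dict[str, Set[str]] = {c: set() for c in PROLINE_CODONS}
        for s in seqs:
            codon = index.single_proline_codon(s)
            if codon is not None:
                by_codon[codon].add(s)
        out[rep] = {
            codon: MistranslationEstimate(
                codon,
                len(members & passing.get(rep, set())),
                len(members),
                rep,
            )
            for codon, members in by_codon.items()
        }
    return out


def welch_t_test(xs: Sequence[float], ys: Sequence[float]) -> Tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each sample needs at least 2 values")
    import numpy as np

    if np.var(xs, ddof=1) == 0 and np.var(ys, ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# tabular summaries


def estimates_to_frame(
    overall: Dict[str, MistranslationEstimate],
    per_codon: Dict[str, Dict[str, MistranslationEstimate]],
) -> pd.DataFrame:
    rows = []
    for rep in sorted(overall):
        for est in [overall[rep]] + [per_codon[rep][c] for c in PROLINE_CODONS]:
            rows.append(
                {
                    "replicate_id": rep,
                    "scope": est.scope,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "frequency": (
                        "" if est.frequency is None else f"{est.frequency:.6f}"
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["replicate_id", "scope", "numerator", "denominator", "frequency"]
    )


def calls_to_frame(calls: Sequence[SubstitutionCall]) -> pd.DataFrame:
    rows = [
        {
            "replicate_id": c.replicate_id,
            "base_seq": c.base_seq,
            "sub_positions": ";".join(str(p + 1) for p in c.sub_positions),
            "protein_id": c.protein_id or "",
            "protein_positions": ";".join(
                str(i + 1) for i in c.protein_residue_indices
            ),
            "codons": ";".join(c.codons),
            "passed": int(c.passed),
            "fail_reason": c.fail_reason.value if c.fail_reason else "",
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "replicate_id",
            "base_seq",
            "sub_positions",
            "protein_id",
            "protein_positions",
            "codons",
            "passed",
            "fail_reason",
        ],
    )


@dataclass
class QuantificationResult:
    """End-to-end output of the quantification pipeline."""

    overall: Dict[str, MistranslationEstimate]
    per_codon: Dict[str, Dict[str, MistranslationEstimate]]
    calls: List[SubstitutionCall]
    n_psms_in: int
    n_psms_passing_fdr: int

    @property
    def estimates(self) -> pd.DataFrame:
        return estimates_to_frame(self.overall, self.per_codon)

    def mean_overall_frequency(self) -> Optional[float]:
        vals = [e.frequency for e in self.overall.values() if e.frequency is not None]
        return sum(vals) / len(vals) if vals else None


def quantify(
    psms: Sequence[PSMRecord],
    index: PeptideIndex,
    fdr: float = 0.01,
    tol_ppm: Optional[float] = 50.0,
    ambiguity_filter: bool = True,
) -> QuantificationResult:
    """Run FDR filtering, annotation, filters and both estimators."""
    from .psm import compute_qvalues, filter_psms

    with_q = compute_qvalues(psms)
    survivors = filter_psms(with_q, alpha=fdr)
    base, candidates = annotate_psms(survivors, index, tol_ppm=tol_ppm)
    if not ambiguity_filter:
        for call in candidates:
            if call.fail_reason is FilterFailure.AMBIGUOUS_MAPPING:
                call.passed, call.fail_reason = True, None
    calls = apply_filters(candidates, base)
    return QuantificationResult(
        overall=estimate_overall(calls, base, index),
        per_codon=estimate_per_codon(calls, base, index),
        calls=calls,
        n_psms_in=len(psms),
        n_psms_passing_fdr=len(survivors),
    )
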