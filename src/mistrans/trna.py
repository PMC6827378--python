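"""tRNA cloverleaf annotation and structural classification of mutations.

Positions follow Sprinzl-style labels (insertions such as "20b", extended
variable-arm labels such as "e21"). A mutation in a loop or linker is
``single_stranded``; a mutation at a paired position either turns a
Watson-Crick pair into a G:U wobble (``creates_GU``), leaves a valid pair in
place (``other_stem``), or abolishes pairing altogether (``abolishes_pair``).
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

STEM_ELEMENTS = {
    "acceptor_stem",
    "D_stem",
    "anticodon_stem",
    "variable_arm_stem",
    "T_stem",
}
LOOP_ELEMENTS = {
    "D_loop",
    "anticodon_loop",
    "variable_arm_loop",
    "T_loop",
    "linker",
}
ELEMENTS = STEM_ELEMENTS | LOOP_ELEMENTS

WATSON_CRICK = ({"A", "U"}, {"G", "C"})
WOBBLE = {"G", "U"}


def is_valid_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble."""
    return {a, b} in WATSON_CRICK or {a, b} == WOBBLE


class Category(str, enum.Enum):
    SINGLE_STRANDED = "single_stranded"
    CREATES_GU = "creates_GU"
    ABOLISHES_PAIR = "abolishes_pair"
    OTHER_STEM = "other_stem"


@dataclass(frozen=True)
class Position:
    label: str
    base: str
    element: str
    partner: Optional[str]  # label of the paired position, or None


class CloverleafError(ValueError):
    """Raised for malformed annotations or variant labels."""


class CloverleafAnnotation:
    """Position-wise secondary structure of one tRNA."""

    def __init__(self, positions: Sequence[Position]) -> None:
        self.positions: Dict[str, Position] = {}
        for pos in positions:
            if pos.label in self.positions:
                raise CloverleafError(f"duplicate position label {pos.label!r}")
            if pos.element not in ELEMENTS:
                raise CloverleafError(
                    f"unknown element {pos.element!r} at {pos.label}"
                )
            if pos.base not in "ACGU":
                raise CloverleafError(f"invalid base {pos.base!r} at {pos.label}")
            self.positions[pos.label] = pos
        self._validate()

    def _validate(self) -> None:
        for pos in self.positions.values():
            if pos.partner is None:
                if pos.element in STEM_ELEMENTS:
                    raise CloverleafError(f"stem position {pos.label} unpaired")
                continue
            if pos.element not in STEM_ELEMENTS:
                raise CloverleafError(f"paired position {pos.label} not in a stem")
            mate = self.positions.get(pos.partner)
            if mate is None or mate.partner != pos.label:
                raise CloverleafError(
                    f"pairing not symmetric at {pos.label}:{pos.partner}"
                )
            if not is_valid_pair(pos.base, mate.base):
                raise CloverleafError(
                    f"wild-type pair {pos.label}:{pos.partner} "
                    f"({pos.base}:{mate.base}) is neither Watson-Crick nor G:U"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, label: str) -> Position:
        try:
            return self.positions[label]
        except KeyError:
            raise CloverleafError(f"no position {label!r} in annotation") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CloverleafAnnotation":
        required = {"label", "base", "element", "partner"}
        missing = required - set(df.columns)
        if missing:
            raise CloverleafError(f"annotation missing column(s): {sorted(missing)}")
        positions = [
            Position(
                label=str(row.label),
                base=str(row.base),
                element=str(row.element),
                partner=None if str(row.partner) in ("", "-", "nan") else str(row.partner),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(positions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CloverleafAnnotation":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


@dataclass(frozen=True)
class VariantClassification:
    label: str
    position: str
    ref_base: str
    alt_base: str
    element: str
    category: Category


_LABEL_RE = re.compile(r"^([ACGU])((?:e\d+|\d+)[a-z]?)([ACGU])$")


def parse_variant_label(label: str) -> Tuple[str, str, str]:
    """Split a label like ``C40U``, ``A20bG`` or ``Ge23A`` into
    (ref_base, position_token, alt_base)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise CloverleafError(f"malformed variant label {label!r}")
    ref, pos, alt = m.groups()
    if ref == alt:
        raise CloverleafError(f"label {label!r} does not change the base")
    return ref, pos, alt


def classify_variant(
    label: str, annotation: CloverleafAnnotation
) -> VariantClassification:
    """Classify one point mutation against a cloverleaf annotation."""
    ref, pos_label, alt = parse_variant_label(label)
    pos = annotation[pos_label]
    if pos.base != ref:
        raise CloverleafError(
            f"label {label!r}: annotation has {pos.base} at {pos_label}, not {ref}"
        )
    if pos.element in LOOP_ELEMENTS:
        category = Category.SINGLE_STRANDED
    else:
        mate = annotation[pos.partner]
        if {alt, mate.base} == WOBBLE:
            category = Category.CREATES_GU
        elif is_valid_pair(alt, mate.base):
            category = Category.OTHER_STEM
        else:
            category = Category.ABOLISHES_PAIR
    return VariantClassification(
        label=label,
        position=pos_label,
        ref_base=ref,
        alt_base=alt,
        element=pos.element,
        category=category,
    )


@dataclass
class ClassificationSummary:
    classifications: List[VariantClassification]

    @property
    def by_category(self) -> Dict[str, int]:
        counts = Counter(c.category.value for c in self.classifications)
        return {cat.value: counts.get(cat.value, 0) for cat in Category}

    @property
    def by_element(self) -> Dict[str, int]:
        return dict(Counter(c.element for c in self.classifications))

    @property
    def n_single_stranded(self) -> int:
        return self.by_category[Category.SINGLE_STRANDED.value]

    @property
    def n_stem(self) -> int:
        return len(self.classifications) - self.n_single_stranded

    def members(self, category: Category) -> List[str]:
        return [c.label for c in self.classifications if c.category is category]

    @property
    def pairing_altering(self) -> set:
        """Mutations that create a G:U or abolish a pair."""
        return set(self.members(Category.CREATES_GU)) | set(
            self.members(Category.ABOLISHES_PAIR)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": c.label,
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "alt_base": c.alt_base,
                    "element": c.element,
                    "category": c.category.value,
                }
                for c in self.classifications
            ]
        )


def summarize_classification(
    labels: Sequence[str], annotation: CloverleafAnnotation
) -> ClassificationSummary:
    """Classify a list of mutation labels; order does not affect counts."""
    return ClassificationSummary(
        [classify_variant(label, annotation) for label in labels]
    )


# ---------------------------------------------------------------------------
# packaged reference data: serine tRNA with a UGG (proline) anticodon


def _data_path(name: str):
    return resources.files("mistrans.data").joinpath(name)


def load_reference_cloverleaf() -> CloverleafAnnotation:
    """The packaged hand-encoded cloverleaf of tRNA-Ser with a UGG anticodon."""
    with resources.as_file(_data_path("trna_ser_ugg_cloverleaf.tsv")) as p:
        return CloverleafAnnotation.from_tsv(p)


def load_reference_variants() -> pd.DataFrame:
    """Packaged table of secondary mutations with doubling times (min) and
    heat-shock folds; the ``reference`` row is the wild-type serine tRNA."""
    with resources.as_file(_data_path("trna_ser_ugg_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def reference_variant_labels() -> List[str]:
    """The secondary-mutation labels (reference row excluded)."""
    df = load_reference_variants()
    return [m for m in df["mutation"] if m != "reference"]
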