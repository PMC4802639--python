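"""Classification of mutagenesis results and pigment phenotype groups.

A candidate mutation set in a background pigment is judged against a
*target* pigment (the ancestral pigment when mutating a present-day one,
and vice versa) on two axes:

* d(λ_max) — mutant λ_max minus target λ_max, in nm;
* d(A/B)   — mutant A/B ratio minus target A/B ratio.

Class I mutants reproduce both the target λ_max (|d(λ_max)| within a
3–5 nm tolerance that widens with the size of the total λ_max shift)
and the target HBN signature (|d(A/B)| ≤ 0.002); class II mutants
reproduce only λ_max; class III mutants reproduce neither.  A mutant
whose λ_max cannot be measured (structurally unstable pigment) is ND.

Phenotype groups: group 1 (UV, λ_max 354–371 nm), group 3 (violet,
395–440 nm), and group 2 for the intermediate 393-nm pigments, which on
the A/B axis occupy only a narrow strip near 0.49 and are therefore
assignable by identity rather than by interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

GAP = "-"

#: Default d(A/B) tolerance for a fully converted HBN signature.
DEFAULT_AB_TOL = 0.002

#: Default two-step |d(λ_max)| tolerance: 3 nm for small total shifts,
#: 5 nm once the total λ_max shift reaches the breakpoint.
DEFAULT_LAMBDA_TOL_LOW = 3.0
DEFAULT_LAMBDA_TOL_HIGH = 5.0
DEFAULT_SHIFT_BREAKPOINT = 40.0

#: Pigments assigned to phenotype group 2 by identity.
GROUP2_PIGMENTS = frozenset({"AncBird-393", "pigeon-393", "Pigeon-393"})

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_INDEL_RE = re.compile(r"^([A-Z])(\d+)\s+(deletion|insertion)$")


class MutationKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"


@dataclass(frozen=True)
class MutationSpec:
    """A single amino-acid change in bovine-rhodopsin numbering."""

    site: int
    from_aa: str
    to_aa: str
    kind: MutationKind = MutationKind.SUBSTITUTION

    def __post_init__(self) -> None:
        if not 31 <= self.site <= 312:
            raise ValueError(f"site {self.site} outside the modelled segment [31, 312]")
        if self.kind is MutationKind.DELETION and self.to_aa != GAP:
            raise ValueError("deletion must have to_aa = '-'")
        if self.kind is MutationKind.INSERTION and self.from_aa != GAP:
            raise ValueError("insertion must have from_aa = '-'")

    @classmethod
    def parse(cls, token: str) -> "MutationSpec":
        """Parse ``"F86S"``, ``"F86 deletion"`` or ``"F86 insertion"``."""
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if m:
            return cls(int(m.group(2)), m.group(1), m.group(3))
        m = _INDEL_RE.match(token)
        if m:
            aa, site, kind = m.group(1), int(m.group(2)), m.group(3)
            if kind == "deletion":
                return cls(site, aa, GAP, MutationKind.DELETION)
            return cls(site, GAP, aa, MutationKind.INSERTION)
        raise ValueError(f"cannot parse mutation token {token!r}")

    def reversed(self) -> "MutationSpec":
        """The opposite-direction change (F86S ↔ S86F; deletion ↔ insertion)."""
        kind = {
            MutationKind.SUBSTITUTION: MutationKind.SUBSTITUTION,
            MutationKind.DELETION: MutationKind.INSERTION,
            MutationKind.INSERTION: MutationKind.DELETION,
        }[self.kind]
        return MutationSpec(self.site, self.to_aa, self.from_aa, kind)

    def __str__(self) -> str:
        if self.kind is MutationKind.DELETION:
            return f"{self.from_aa}{self.site} deletion"
        if self.kind is MutationKind.INSERTION:
            return f"{self.to_aa}{self.site} insertion"
        return f"{self.from_aa}{self.site}{self.to_aa}"


def parse_mutation_set(text: str) -> tuple[MutationSpec, ...]:
    """Parse a slash-separated mutation string such as ``"F86S/T93I"``."""
    return tuple(MutationSpec.parse(t) for t in text.split("/") if t.strip())


class MutantClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    ND = "ND"


_CLASS_ORDER = {MutantClass.I: 0, MutantClass.II: 1, MutantClass.III: 2}


@dataclass
class ClassificationResult:
    d_lambda: Optional[float]
    d_ab: Optional[float]
    total_shift: Optional[float]
    lambda_threshold_used: Optional[float]
    mutant_class: MutantClass


@dataclass
class ClassifierConfig:
    """Tunable criteria thresholds (defaults as used throughout)."""

    ab_tol: float = DEFAULT_AB_TOL
    lambda_tol_low: float = DEFAULT_LAMBDA_TOL_LOW
    lambda_tol_high: float = DEFAULT_LAMBDA_TOL_HIGH
    shift_breakpoint: float = DEFAULT_SHIFT_BREAKPOINT


def shift_threshold(total_shift: float, config: ClassifierConfig | None = None) -> float:
    """|d(λ_max)| tolerance in nm given the magnitude of the total
    background→target λ_max shift: the tolerance steps from 3 nm to 5 nm
    at the configured breakpoint (40 nm by default)."""
    config = config or ClassifierConfig()
    if total_shift < 0:
        raise ValueError(f"total_shift must be >= 0, got {total_shift}")
    return config.lambda_tol_low if total_shift < config.shift_breakpoint else config.lambda_tol_high


def classify_mutant(
    mutant_lambda: Optional[float],
    mutant_ab: Optional[float],
    target_lambda: float,
    target_ab: Optional[float],
    background_lambda: float,
    config: ClassifierConfig | None = None,
    d_lambda: Optional[float] = None,
    d_ab: Optional[float] = None,
) -> ClassificationResult:
    """Classify one mutagenesis result as class I, II, III or ND.

    ``d_lambda``/``d_ab`` may be supplied directly (e.g. tabulated
    rounded differences); otherwise they are computed as mutant − target.
    ND (λ_max unmeasurable) propagates whenever the mutant λ_max is
    unknown and no d(λ_max) is supplied.
    """
    config = config or ClassifierConfig()
    total = abs(target_lambda - background_lambda)
    if d_lambda is None:
        if mutant_lambda is None:
            return ClassificationResult(None, None, total, None, MutantClass.ND)
        d_lambda = mutant_lambda - target_lambda
    if d_ab is None and mutant_ab is not None and target_ab is not None:
        d_ab = mutant_ab - target_ab
    thresh = shift_threshold(total, config)
    if abs(d_lambda) > thresh:
        cls = MutantClass.III
    elif d_ab is not None and abs(d_ab) <= config.ab_tol:
        cls = MutantClass.I
    else:
        cls = MutantClass.II
    return ClassificationResult(d_lambda, d_ab, total, thresh, cls)


def class_at_most(a: MutantClass, b: MutantClass) -> bool:
    """True when class ``a`` is at least as good as ``b`` in the ordering
    I ≺ II ≺ III (ND incomparable)."""
    if MutantClass.ND in (a, b):
        return a == b
    return _CLASS_ORDER[a] <= _CLASS_ORDER[b]


class PhenotypeGroupId(int, Enum):
    UV = 1
    INTERMEDIATE = 2
    VIOLET = 3


@dataclass
class PhenotypeGroup:
    group: Optional[PhenotypeGroupId]
    basis: str  # "lambda" or "ab_swiss"
    unclassified: bool = False


#: λ_max intervals (nm) for groups 1 and 3.
LAMBDA_RANGES = {PhenotypeGroupId.UV: (354.0, 371.0), PhenotypeGroupId.VIOLET: (395.0, 440.0)}
#: Raw-homology-model (SWISS) A/B intervals for groups 1 and 3.
AB_SWISS_RANGES = {
    PhenotypeGroupId.UV: (0.535, 0.577),
    PhenotypeGroupId.VIOLET: (0.355, 0.526),
}
#: Group-2 A/B strip (intermediate pigments cluster tightly near 0.49).
AB_GROUP2_STRIP = (0.489, 0.495)


def assign_phenotype_group(
    value: float,
    basis: str = "lambda",
    pigment_id: Optional[str] = None,
) -> PhenotypeGroup:
    """Assign a pigment to phenotype group 1 (UV), 2 (intermediate) or
    3 (violet) from its λ_max (``basis="lambda"``) or its raw-model A/B
    ratio (``basis="ab_swiss"``).

    Group 2 is claimed only by identity (the known 393-nm pigments) or,
    on the A/B axis, by the narrow strip near 0.49; A/B values inside
    that strip are otherwise still within the violet interval and are
    assigned to group 3.  Values outside every interval are returned
    with ``unclassified=True``, never silently defaulted.
    """
    if pigment_id is not None and pigment_id in GROUP2_PIGMENTS:
        return PhenotypeGroup(PhenotypeGroupId.INTERMEDIATE, basis)
    if basis == "lambda":
        ranges = LAMBDA_RANGES
    elif basis == "ab_swiss":
        ranges = AB_SWISS_RANGES
    else:
        raise ValueError(f"unknown basis {basis!r}")
    for group, (lo, hi) in ranges.items():
        if lo <= value <= hi:
            return PhenotypeGroup(group, basis)
    return PhenotypeGroup(None, basis, unclassified=True)
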