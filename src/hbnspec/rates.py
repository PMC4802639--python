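"""Nucleotide substitution rates over opsin coding sequences.

The pipeline follows the classical relative-rate construction: for a
violet opsin gene A, a UV opsin gene B and a more distantly related
third gene C, pairwise Jukes–Cantor distances

    d = −(3/4) ln[1 − (4/3) p]

are computed from the proportion p of differing nucleotides, the
post-divergence branch lengths of A and B are

    b_A = (d_AB + d_AC − d_BC) / 2,    b_B = (d_AB − d_AC + d_BC) / 2,

and per-year rates follow by dividing by the divergence time.  The
comparison can be restricted to the *critical codon sites* — the 17
positions known to shift SWS1 λ_max — by masking the alignment to those
codons; codon 86 is dropped automatically when a compared sequence lacks
it (the scabbardfish case), leaving 16 codons.

The standard error attached to a distance is the delta-method value
[9p(1−p) / {(3−4p)² n}]^{1/2}; when attached to a rate it is scaled by
the same 1/(divergence time) factor as the point estimate.  Propagation
through the three-taxon branch decomposition is not attempted; the SE is
always that of a single pairwise comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

#: Bovine-rhodopsin codon numbers of the critical spectral-tuning sites.
CRITICAL_SITES: Tuple[int, ...] = (
    46, 49, 52, 86, 90, 91, 93, 97, 109, 113, 114, 116, 118, 179, 207, 256, 277,
)

_VALID = frozenset("ACGT")
_MISSING = frozenset("-N")


class SaturationError(ValueError):
    """p >= 3/4: the Jukes–Cantor distance is undefined (saturated)."""


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment with a codon-number map.

    ``codon_map`` sends a bovine-rhodopsin codon number to the 1-based
    codon index within the alignment (identity by default).  All
    coordinates exposed by this class are 1-based.
    """

    sequences: Dict[str, str]
    critical_sites: Tuple[int, ...] = CRITICAL_SITES
    codon_map: Optional[Dict[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise ValueError(f"alignment length {self.length} is not a multiple of 3")
        bad = set("".join(self.sequences.values()).upper()) - _VALID - _MISSING
        if bad:
            raise ValueError(f"unexpected alignment characters: {sorted(bad)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        if self.codon_map is None:
            self.codon_map = {i: i for i in range(1, self.length // 3 + 1)}

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon_positions(self, codon_number: int) -> Tuple[int, int, int]:
        """1-based nucleotide positions of one (bovine-numbered) codon."""
        idx = self.codon_map.get(codon_number)
        if idx is None or not 1 <= idx <= self.n_codons:
            raise KeyError(f"codon {codon_number} not mapped into the alignment")
        start = 3 * (idx - 1) + 1
        return (start, start + 1, start + 2)

    def _codon_missing(self, seq_id: str, codon_number: int) -> bool:
        idx = self.codon_map.get(codon_number)
        if idx is None:
            return True
        seq = self.sequences[seq_id]
        codon = seq[3 * (idx - 1) : 3 * idx]
        return any(c in _MISSING for c in codon)

    def critical_mask(self, seq_ids: Iterable[str]) -> List[int]:
        """1-based nucleotide positions of the critical codons, dropping
        any codon absent (gapped/unmapped) in one of ``seq_ids`` — so a
        scabbardfish-style comparison uses 16 codons, not 17."""
        positions: List[int] = []
        for codon in self.critical_sites:
            if any(self._codon_missing(sid, codon) for sid in seq_ids):
                continue
            positions.extend(self.codon_positions(codon))
        return positions


def pairwise_p(
    alignment: CodonAlignment,
    id_a: str,
    id_b: str,
    site_mask: Optional[Sequence[int]] = None,
    critical_only: bool = False,
) -> Tuple[float, int]:
    """Proportion of differing nucleotides between two sequences.

    Positions where either sequence has a gap or ambiguous base are
    excluded pairwise.  ``site_mask`` is a sequence of 1-based nucleotide
    positions; ``critical_only`` uses the critical-codon mask instead.
    Returns ``(p, n_sites_compared)``.
    """
    for sid in (id_a, id_b):
        if sid not in alignment.sequences:
            raise KeyError(f"sequence {sid!r} not in alignment")
    if critical_only:
        if site_mask is not None:
            raise ValueError("give either site_mask or critical_only, not both")
        site_mask = alignment.critical_mask((id_a, id_b))
    a, b = alignment.sequences[id_a], alignment.sequences[id_b]
    positions = range(1, alignment.length + 1) if site_mask is None else site_mask
    n = diff = 0
    for pos in positions:
        ca, cb = a[pos - 1], b[pos - 1]
        if ca in _VALID and cb in _VALID:
            n += 1
            diff += ca != cb
    if n == 0:
        raise ValueError(f"no comparable sites between {id_a!r} and {id_b!r}")
    return diff / n, n


def jc_distance(p: float) -> float:
    """Jukes–Cantor distance d = −(3/4) ln[1 − (4/3)p], substitutions
    per site.  Undefined (saturated) for p >= 3/4."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"p = {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_se(p: float, n: int) -> float:
    """Delta-method standard error of the Jukes–Cantor distance,
    [9p(1−p) / {(3−4p)² n}]^{1/2}."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"p = {p} outside [0, 0.75)")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return math.sqrt(9.0 * p * (1.0 - p) / ((3.0 - 4.0 * p) ** 2 * n))


def relative_rate_branches(d_ab: float, d_ac: float, d_bc: float) -> Tuple[float, float, bool]:
    """Post-divergence branch lengths of A and B from the three pairwise
    distances to an outgroup C.

    Returns ``(b_a, b_b, negative_flag)``; b_a + b_b = d_ab identically.
    Negative branch estimates (statistically possible) are returned
    as-is with the flag set.
    """
    for name, d in (("d_ab", d_ab), ("d_ac", d_ac), ("d_bc", d_bc)):
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {d}")
    b_a = 0.5 * (d_ab + d_ac - d_bc)
    b_b = 0.5 * (d_ab - d_ac + d_bc)
    return b_a, b_b, (b_a < 0 or b_b < 0)


def substitution_rate(branch_length: float, divergence_time_my: float) -> float:
    """Rate in units of 10⁻⁹ substitutions per site per year."""
    if divergence_time_my <= 0:
        raise ValueError(f"divergence time must be > 0, got {divergence_time_my}")
    return branch_length / (divergence_time_my * 1e6) * 1e9


@dataclass
class RateEstimate:
    """Per-lineage substitution-rate estimate with its provenance."""

    seq_id: str
    p: float
    n_sites: int
    d: float
    branch_length: float
    rate: float  # 10^-9 substitutions / site / year
    se: float  # same units
    divergence_time_my: float
    negative_branch: bool = False


def lineage_rates(
    alignment: CodonAlignment,
    id_a: str,
    id_b: str,
    id_c: str,
    divergence_time_my: float,
    critical_only: bool = False,
) -> Tuple[RateEstimate, RateEstimate]:
    """Full relative-rate analysis for the triple (A, B, outgroup C).

    Computes the three pairwise Jukes–Cantor distances, splits d_AB into
    the per-lineage branches, and converts each to a rate using the A–B
    divergence time.  The SE reported for each lineage is the pairwise
    A–B distance SE scaled by the same 1/time factor (see module notes).
    """
    p_ab, n_ab = pairwise_p(alignment, id_a, id_b, critical_only=critical_only)
    p_ac, _ = pairwise_p(alignment, id_a, id_c, critical_only=critical_only)
    p_bc, _ = pairwise_p(alignment, id_b, id_c, critical_only=critical_only)
    d_ab, d_ac, d_bc = jc_distance(p_ab), jc_distance(p_ac), jc_distance(p_bc)
    b_a, b_b, neg = relative_rate_branches(d_ab, d_ac, d_bc)
    se = substitution_rate(jc_se(p_ab, n_ab), divergence_time_my)
    return (
        RateEstimate(id_a, p_ab, n_ab, d_ab, b_a, substitution_rate(b_a, divergence_time_my), se, divergence_time_my, neg),
        RateEstimate(id_b, p_ab, n_ab, d_ab, b_b, substitution_rate(b_b, divergence_time_my), se, divergence_time_my, neg),
    )
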