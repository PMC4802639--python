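"""Exact epistasis decomposition of full-factorial λ_max tables.

Given a background pigment and measured λ_max values for every
combination of k candidate mutations (2^k pigments in all), the λ_max of
each mutant is written as

    λ(S) = λ_background + Σ_{∅ ≠ T ⊆ S} θ(T),

where θ of a singleton is a main mutational effect and θ of a larger
subset is the epistatic interaction unique to that subset.  On a
complete factorial this system is triangular and the θ coefficients are
obtained exactly by inclusion–exclusion in order of subset size — no
least squares is involved, and integer λ_max inputs yield integer θ.

Forward mutations in an ancestral pigment and the corresponding reverse
mutations in its descendant define two *independent* models of this
form; their coefficients are not sign-symmetric (the central epistasis
observation).  :func:`complement_model` re-indexes a reverse factorial
around its full mutant so the implied forward-direction coefficients can
be read off, and :func:`complement_equivalence` pairs each reverse
subset with its functionally equivalent forward complement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .classifier import MutationSpec, parse_mutation_set

Subset = FrozenSet[MutationSpec]


class IncompleteDesignError(ValueError):
    """The measurement table is not a complete single-copy factorial."""


@dataclass
class MutantMeasurement:
    """λ_max of one (possibly multiply) mutated pigment.

    ``subset`` is the set of mutations carried; the empty set denotes the
    unmutated background.
    """

    background_id: str
    subset: Subset
    lambda_nm: float

    @classmethod
    def from_string(cls, background_id: str, mutations: str, lambda_nm: float) -> "MutantMeasurement":
        subset = frozenset(parse_mutation_set(mutations)) if mutations.strip() not in ("", "-") else frozenset()
        return cls(background_id, subset, lambda_nm)


def subset_key(subset: Iterable[MutationSpec]) -> Tuple[str, ...]:
    """Canonical key: mutation strings sorted by site then direction.

    Keeping the direction tag in the key means a forward model (F86S…)
    and its reverse counterpart (S86F…) can never be merged by accident.
    """
    return tuple(str(m) for m in sorted(subset, key=lambda m: (m.site, m.from_aa, m.to_aa)))


def format_subset(subset: Iterable[MutationSpec]) -> str:
    return "/".join(subset_key(subset)) or "(background)"


@dataclass
class EpistasisModel:
    """Background λ_max plus θ coefficients for every non-empty subset of
    the k mutations (2^k − 1 coefficients)."""

    background_id: str
    background_lambda: float
    mutations: Tuple[MutationSpec, ...]
    theta: Dict[Subset, float]

    @property
    def k(self) -> int:
        return len(self.mutations)

    def theta_by_name(self) -> Dict[str, float]:
        return {format_subset(s): v for s, v in sorted(self.theta.items(), key=lambda kv: (len(kv[0]), subset_key(kv[0])))}


def _check_complete(measurements: Sequence[MutantMeasurement]) -> Tuple[Tuple[MutationSpec, ...], Dict[Subset, float]]:
    table: Dict[Subset, float] = {}
    duplicates = []
    for m in measurements:
        if m.subset in table:
            duplicates.append(format_subset(m.subset))
        table[m.subset] = m.lambda_nm
    mutations = tuple(sorted(set().union(*table.keys()) if table else (), key=lambda m: (m.site, m.from_aa, m.to_aa)))
    k = len(mutations)
    expected = {frozenset(c) for r in range(k + 1) for c in itertools.combinations(mutations, r)}
    missing = sorted(format_subset(s) for s in expected - set(table))
    if duplicates or missing or len(table) != 2**k:
        extra = sorted(format_subset(s) for s in set(table) - expected)
        raise IncompleteDesignError(
            f"not a complete factorial over {k} mutations: "
            f"missing={missing}, duplicated={sorted(set(duplicates))}, unexpected={extra}"
        )
    return mutations, table


def decompose_effects(measurements: Sequence[MutantMeasurement]) -> EpistasisModel:
    """Exact inclusion–exclusion decomposition of a complete factorial.

    Proceeds by subset size: θ(S) = λ(S) − λ_background − Σ θ(T) over the
    proper non-empty subsets T of S.  Raises
    :class:`IncompleteDesignError` listing missing/duplicated subsets if
    the table is not a single-copy full factorial.
    """
    if not measurements:
        raise IncompleteDesignError("no measurements supplied")
    mutations, table = _check_complete(measurements)
    background_id = measurements[0].background_id
    background_lambda = table[frozenset()]
    theta: Dict[Subset, float] = {}
    for size in range(1, len(mutations) + 1):
        for combo in itertools.combinations(mutations, size):
            s = frozenset(combo)
            lower = sum(
                theta[frozenset(c)]
                for r in range(1, size)
                for c in itertools.combinations(combo, r)
            )
            theta[s] = table[s] - background_lambda - lower
    return EpistasisModel(background_id, background_lambda, mutations, theta)


def reconstruct_lambda(model: EpistasisModel, subset: Iterable[MutationSpec]) -> float:
    """λ_max implied by the model for any subset of its mutations."""
    s = frozenset(subset)
    unknown = s - set(model.mutations)
    if unknown:
        raise KeyError(f"mutations not in model: {sorted(str(m) for m in unknown)}")
    return model.background_lambda + sum(
        v for t, v in model.theta.items() if t <= s
    )


def complement_model(measurements: Sequence[MutantMeasurement]) -> EpistasisModel:
    """Decompose a factorial re-indexed around its *full* mutant.

    Each reverse subset S is re-labelled as the direction-flipped
    complement (full set minus S), with the full mutant serving as the
    new background.  Applied to a reverse factorial over a present-day
    pigment, this yields the forward-direction θ values that the reverse
    experiment implies — a derived convenience, not an independent fit.
    """
    mutations, table = _check_complete(measurements)
    full = frozenset(mutations)
    flipped = {m: m.reversed() for m in mutations}
    reindexed = [
        MutantMeasurement(
            background_id=f"{measurements[0].background_id}+full",
            subset=frozenset(flipped[m] for m in full - s),
            lambda_nm=lam,
        )
        for s, lam in table.items()
    ]
    return decompose_effects(reindexed)


def complement_equivalence(
    forward: EpistasisModel, reverse: EpistasisModel
) -> pd.DataFrame:
    """Pair each reverse-model subset with its forward complement.

    A reverse subset S applied to the descendant leaves exactly the
    mutations in the forward complement (full set minus the
    direction-flip of S) un-reverted, so the two pigments are
    functionally equivalent; the table reports both λ_max values and
    their difference.  Raises ``ValueError`` when the two models do not
    cover the same sites with opposite substitution directions.
    """
    fwd_by_site = {m.site: m for m in forward.mutations}
    rev_by_site = {m.site: m for m in reverse.mutations}
    if set(fwd_by_site) != set(rev_by_site) or any(
        rev_by_site[site] != fwd_by_site[site].reversed() for site in fwd_by_site
    ):
        raise ValueError(
            "forward and reverse models must cover the same sites with "
            "opposite substitution directions"
        )
    rows = []
    rev_full = frozenset(reverse.mutations)
    for size in range(len(rev_full) + 1):
        for combo in itertools.combinations(sorted(rev_full, key=lambda m: m.site), size):
            rev_subset = frozenset(combo)
            fwd_subset = frozenset(
                fwd_by_site[m.site] for m in rev_full - rev_subset
            )
            lam_rev = reconstruct_lambda(reverse, rev_subset)
            lam_fwd = reconstruct_lambda(forward, fwd_subset)
            rows.append(
                {
                    "reverse_subset": format_subset(rev_subset),
                    "forward_subset": format_subset(fwd_subset),
                    "lambda_reverse": lam_rev,
                    "lambda_forward": lam_fwd,
                    "difference": lam_rev - lam_fwd,
                }
            )
    return pd.DataFrame(rows)


def fit_replicated(measurements: Sequence[MutantMeasurement]) -> EpistasisModel:
    """Least-squares variant for replicated measurements (off the default
    path): replicates of each subset are averaged, after which the exact
    decomposition applies.  Requires every subset to appear at least once."""
    grouped: Dict[Subset, list[float]] = {}
    for m in measurements:
        grouped.setdefault(m.subset, []).append(m.lambda_nm)
    averaged = [
        MutantMeasurement(measurements[0].background_id, s, sum(v) / len(v))
        for s, v in grouped.items()
    ]
    return decompose_effects(averaged)
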