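"""Enumeration of condition rankings and the 82-profile interaction catalog.

A two-signal factorial experiment measures an output (log2 expression) in
four conditions: control (0), signal X alone, signal Y alone and the
combination X+Y.  Writing ``e_0, e_X, e_Y, e_XY`` for the four condition
means, the qualitative outcome of the experiment for one output is a
*ranking* — a weak ordering of the four values — encoded as the vector of
signs of the six ordered pairwise comparisons

    (e_X − e_0, e_Y − e_0, e_XY − e_0, e_Y − e_X, e_XY − e_X, e_XY − e_Y)

with each component in {−1, 0, +1}.  Exactly 75 such rankings exist for
four conditions.  On the log2 (Bliss independence) scale, a *positive
interaction* means the combined increment exceeds the sum of the single
increments, ``e_XY − e_X − e_Y + e_0 > 0``, and a negative interaction is
the reverse inequality.  A ranking may admit a positive realization, a
negative one, both, or neither; deciding which is a linear feasibility
problem over values bounded to the dynamic range of the assay
(log2 microarray intensities, taken as [2, 16]).

This module enumerates the rankings, decides sign feasibility by linear
programming with an explicit positive margin for strict inequalities, and
builds the catalog of 82 interaction profiles (41 positive + 41 negative:
29 rankings admit only one sign each, 12 "ambiguous" rankings admit both
and are split in two, and 5 purely additive rankings are excluded).
Every profile carries a *prototype*: a concrete quadruple of values that
realizes its ranking and sign with maximal slack (a Chebyshev-center style
solution), used downstream for nearest-neighbour classification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, NamedTuple

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "CONDITIONS",
    "COMPARISON_PAIRS",
    "DEFAULT_BOUNDS",
    "ComparisonVector",
    "InteractionProfile",
    "Catalog",
    "count_rankings",
    "enumerate_rankings",
    "encode_ranking",
    "check_feasibility",
    "classify_ranking",
    "compute_prototype",
    "build_catalog",
    "flip_vector",
    "swap_xy",
]

#: condition order used throughout: (control, X alone, Y alone, combination)
CONDITIONS = ("CTRL", "X", "Y", "XY")

#: ordered index pairs (i, j) into (e_0, e_X, e_Y, e_XY); component = sign(e_i − e_j)
COMPARISON_PAIRS = ((1, 0), (2, 0), (3, 0), (2, 1), (3, 1), (3, 2))

#: default value bounds, the approximate log2 range of Affymetrix intensities
DEFAULT_BOUNDS = (2.0, 16.0)

#: interaction contrast coefficients for (e_0, e_X, e_Y, e_XY)
_INTERACTION_COEF = np.array([1.0, -1.0, -1.0, 1.0])

#: strict inequalities are accepted only with at least this LP margin
MARGIN_TOL = 1e-9

Sign = Literal["positive", "negative"]
POSITIVE: Sign = "positive"
NEGATIVE: Sign = "negative"

FeasibilityLabel = Literal[
    "positive_only", "negative_only", "ambiguous", "additive_only"
]


class ComparisonVector(NamedTuple):
    """Six-component qualitative encoding of a ranking of the four conditions.

    Components are the signs of, in order:
    ``e_X−e_0, e_Y−e_0, e_XY−e_0, e_Y−e_X, e_XY−e_X, e_XY−e_Y``.
    """

    c1: int
    c2: int
    c3: int
    c4: int
    c5: int
    c6: int

    def ranks(self) -> tuple[int, ...] | None:
        """Rank of each condition (0 = lowest) if the vector is a weak
        ordering, else None.

        For a transitively consistent vector the rank of a condition equals
        the number of conditions strictly below it; re-encoding that rank
        assignment must reproduce the vector exactly.
        """
        sign = [[0] * 4 for _ in range(4)]
        for comp, (i, j) in zip(self, COMPARISON_PAIRS):
            sign[i][j] = comp
            sign[j][i] = -comp
        ranks = tuple(sum(s == 1 for s in row) for row in sign)
        if encode_rank_assignment(ranks) != self:
            return None
        return ranks

    def is_valid_ranking(self) -> bool:
        return self.ranks() is not None

    def levels(self) -> int:
        """Number of distinct value groups k in {1,..,4}."""
        ranks = self.ranks()
        if ranks is None:
            raise ValueError(f"{tuple(self)} is not a transitive ranking")
        return len(set(ranks))


def flip_vector(vec: ComparisonVector) -> ComparisonVector:
    """Sign reflection e ↦ −e (equivalently 18−e within [2,16]): negates
    every comparison."""
    return ComparisonVector(*(-c for c in vec))


def swap_xy(vec: ComparisonVector) -> ComparisonVector:
    """Exchange the roles of the two stimuli: swap c1↔c2, c5↔c6, negate c4."""
    c1, c2, c3, c4, c5, c6 = vec
    return ComparisonVector(c2, c1, c3, -c4, c6, c5)


def encode_rank_assignment(ranks: Iterable[int]) -> ComparisonVector:
    """Encode an integer rank assignment for (CTRL, X, Y, XY)."""
    r = tuple(ranks)
    return ComparisonVector(
        *(int(np.sign(r[i] - r[j])) for i, j in COMPARISON_PAIRS)
    )


def encode_ranking(
    values: Iterable[float], tol: float = 0.0
) -> ComparisonVector:
    """Encode four real values (e_0, e_X, e_Y, e_XY) as a comparison vector.

    Differences with absolute value ≤ ``tol`` are coded 0.  ``tol`` defaults
    to 0 for exact inputs; pass a small positive tolerance for means
    computed in floating point.
    """
    v = np.asarray(list(values), dtype=float)
    if v.shape != (4,) or not np.all(np.isfinite(v)):
        raise ValueError("encode_ranking expects four finite values")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    comps = []
    for i, j in COMPARISON_PAIRS:
        d = v[i] - v[j]
        comps.append(0 if abs(d) <= tol else (1 if d > 0 else -1))
    return ComparisonVector(*comps)


@lru_cache(maxsize=None)
def _rankings_count(n: int, k: int) -> int:
    # A^n_k = k * (A^{n-1}_k + A^{n-1}_{k-1}); ordered set partitions of n
    # conditions into k nonempty ranked groups (k! * Stirling2(n, k)).
    if n == 1:
        return 1 if k == 1 else 0
    if k < 1 or k > n:
        return 0
    return k * (_rankings_count(n - 1, k) + _rankings_count(n - 1, k - 1))


def count_rankings(n: int, k: int | str = "all") -> int:
    """Number of weak orderings of ``n`` conditions into exactly ``k``
    statistically distinct groups (or summed over k for ``k="all"``).

    Satisfies the recurrence A^n_k = k·(A^{n−1}_k + A^{n−1}_{k−1}) with
    A^1_1 = 1 (a new condition either joins one of the k groups or creates
    one, and in either case the group it lands in can be any of the k);
    for ``k="all"`` this is the ordered Bell (Fubini) number: 1, 3, 13, 75,
    541 for n = 1..5.  Four conditions give 75 rankings, of which 14 have
    exactly two distinct levels.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if k == "all":
        return sum(_rankings_count(n, kk) for kk in range(1, n + 1))
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n} or 'all', got {k!r}")
    return _rankings_count(n, int(k))


@lru_cache(maxsize=1)
def enumerate_rankings() -> tuple[ComparisonVector, ...]:
    """All 75 distinct rankings of the four conditions, in lexicographic
    order of their comparison vectors."""
    seen = {
        encode_rank_assignment(ranks)
        for ranks in itertools.product(range(4), repeat=4)
    }
    return tuple(sorted(seen))


def _ranking_constraints(vec: ComparisonVector):
    """Split a comparison vector into equality pairs and strict pairs."""
    if not vec.is_valid_ranking():
        raise ValueError(f"{tuple(vec)} is not a transitive ranking")
    eqs, stricts = [], []
    for comp, (i, j) in zip(vec, COMPARISON_PAIRS):
        if comp == 0:
            eqs.append((i, j))
        else:
            stricts.append((i, j) if comp == 1 else (j, i))
    return eqs, stricts


def check_feasibility(
    vec: ComparisonVector,
    sign: Sign,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> bool:
    """Can the ranking be realized together with a strict positive (or
    negative) interaction, with all four values inside ``bounds``?

    Decided exactly by a linear program that maximizes a common margin t
    over all strict inequalities; the system of strict constraints is
    simultaneously satisfiable iff the optimal margin is positive
    (> ``MARGIN_TOL``).
    """
    if sign not in (POSITIVE, NEGATIVE):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    eqs, stricts = _ranking_constraints(vec)
    lo, hi = bounds
    # variables: e_0, e_X, e_Y, e_XY, t ; maximize t
    n_var = 5
    a_ub, b_ub = [], []
    for i, j in stricts:  # e_i − e_j ≥ t  →  −e_i + e_j + t ≤ 0
        row = [0.0] * n_var
        row[i], row[j], row[4] = -1.0, 1.0, 1.0
        a_ub.append(row)
        b_ub.append(0.0)
    coef = _INTERACTION_COEF if sign == POSITIVE else -_INTERACTION_COEF
    a_ub.append([-coef[0], -coef[1], -coef[2], -coef[3], 1.0])
    b_ub.append(0.0)
    a_eq, b_eq = [], []
    for i, j in eqs:
        row = [0.0] * n_var
        row[i], row[j] = 1.0, -1.0
        a_eq.append(row)
        b_eq.append(0.0)
    res = linprog(
        c=[0.0, 0.0, 0.0, 0.0, -1.0],
        A_ub=np.array(a_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(a_eq) if a_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(lo, hi)] * 4 + [(0.0, hi - lo)],
        method="highs",
    )
    return bool(res.status == 0 and -res.fun > MARGIN_TOL)


def classify_ranking(
    vec: ComparisonVector, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> FeasibilityLabel:
    """Feasibility label of a ranking: which interaction signs it admits.

    Over the 75 rankings the labels split 29 positive_only / 29
    negative_only / 12 ambiguous / 5 additive_only.
    """
    pos = check_feasibility(vec, POSITIVE, bounds)
    neg = check_feasibility(vec, NEGATIVE, bounds)
    if pos and neg:
        return "ambiguous"
    if pos:
        return "positive_only"
    if neg:
        return "negative_only"
    return "additive_only"


def compute_prototype(
    vec: ComparisonVector,
    sign: Sign | None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> tuple[float, float, float, float]:
    """Deterministic representative values for a ranking (+ optional sign).

    Solves a Chebyshev-center style LP over the k distinct level values:
    maximize the minimum slack t of every strict constraint (level gaps,
    distance to the bounds, and the strict interaction inequality when a
    sign is given).  Conditions tied in the ranking receive *identical*
    values, so the prototype re-encodes to its ranking with tol=0.  For
    ``sign=None`` (additive rankings) the additivity equality
    e_XY − e_X − e_Y + e_0 = 0 is imposed instead; the all-equal ranking
    yields the center of the bounds, (9, 9, 9, 9) by default.

    A tiny secondary objective (−1e−7·Σ levels) makes the optimum unique
    in degenerate cases without materially changing the margin.
    """
    raw = ComparisonVector(*vec).ranks()
    if raw is None:
        raise ValueError(f"{tuple(vec)} is not a transitive ranking")
    dense = {r: lvl for lvl, r in enumerate(sorted(set(raw)))}
    ranks = tuple(dense[r] for r in raw)
    k = len(dense)
    lo, hi = bounds
    # variables: v_0 < v_1 < ... < v_{k-1}, t ; condition i has value v_{ranks[i]}
    n_var = k + 1
    a_ub, b_ub = [], []
    for level in range(k - 1):  # v_{level+1} − v_level ≥ t
        row = [0.0] * n_var
        row[level], row[level + 1], row[k] = 1.0, -1.0, 1.0
        a_ub.append(row)
        b_ub.append(0.0)
    row = [0.0] * n_var  # v_0 ≥ lo + t
    row[0], row[k] = -1.0, 1.0
    a_ub.append(row)
    b_ub.append(-lo)
    row = [0.0] * n_var  # v_{k-1} ≤ hi − t
    row[k - 1], row[k] = 1.0, 1.0
    a_ub.append(row)
    b_ub.append(hi)
    # interaction contrast expressed in level coordinates
    level_coef = [0.0] * k
    for cond, c in enumerate(_INTERACTION_COEF):
        level_coef[ranks[cond]] += c
    a_eq = b_eq = None
    if sign is None:
        a_eq = [level_coef + [0.0]]
        b_eq = [0.0]
    else:
        s = 1.0 if sign == POSITIVE else -1.0
        a_ub.append([-s * c for c in level_coef] + [1.0])
        b_ub.append(0.0)
    c_obj = [1e-7] * k + [-1.0]
    res = linprog(
        c=c_obj,
        A_ub=np.array(a_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(a_eq) if a_eq is not None else None,
        b_eq=np.array(b_eq) if b_eq is not None else None,
        bounds=[(lo, hi)] * k + [(0.0, hi - lo)],
        method="highs",
    )
    if res.status != 0 or res.x[k] <= MARGIN_TOL:
        raise RuntimeError(
            f"no strict realization for ranking {tuple(vec)} sign={sign}"
        )
    levels = [round(float(v), 9) for v in res.x[:k]]
    return tuple(levels[r] for r in ranks)


def _format_component(c: int) -> str:
    return f"+{c}" if c > 0 else str(c)


def profile_id(vec: ComparisonVector, sign: Sign) -> str:
    """Stable human-readable id, e.g. ``"0,0,+1,0,+1,+1|pos"``."""
    return ",".join(_format_component(c) for c in vec) + (
        "|pos" if sign == POSITIVE else "|neg"
    )


@dataclass(frozen=True)
class InteractionProfile:
    """One of the 82 realizable (ranking, interaction sign) combinations."""

    id: str
    ranking: ComparisonVector
    sign: Sign
    prototype: tuple[float, float, float, float]

    def interaction_contrast(self) -> float:
        """e_XY − e_X − e_Y + e_0 evaluated on the prototype."""
        return float(np.dot(_INTERACTION_COEF, self.prototype))


@dataclass(frozen=True)
class Catalog:
    """The full profile catalog plus the feasibility labelling of rankings."""

    profiles: tuple[InteractionProfile, ...]
    labels: dict[ComparisonVector, FeasibilityLabel]
    bounds: tuple[float, float]

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def by_id(self) -> dict[str, InteractionProfile]:
        return {p.id: p for p in self.profiles}

    def profiles_with_sign(self, sign: Sign) -> tuple[InteractionProfile, ...]:
        return tuple(p for p in self.profiles if p.sign == sign)

    def additive_rankings(self) -> tuple[ComparisonVector, ...]:
        return tuple(
            v for v, lab in sorted(self.labels.items())
            if lab == "additive_only"
        )

    def match(
        self, vec: Iterable[int], sign: Sign
    ) -> InteractionProfile | None:
        """Profile with exactly this ranking and sign, or None."""
        key = ComparisonVector(*vec)
        for p in self.profiles:
            if p.ranking == key and p.sign == sign:
                return p
        return None

    def label_counts(self) -> dict[FeasibilityLabel, int]:
        out: dict[FeasibilityLabel, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def build_catalog(bounds: tuple[float, float] = DEFAULT_BOUNDS) -> Catalog:
    """Enumerate rankings, label sign feasibility, and attach prototypes.

    Rankings feasible under both signs contribute two profiles (one per
    sign); additive-only rankings contribute none.  Profiles are ordered
    lexicographically by ranking, positive before negative.
    """
    labels: dict[ComparisonVector, FeasibilityLabel] = {}
    profiles: list[InteractionProfile] = []
    for vec in enumerate_rankings():
        lab = classify_ranking(vec, bounds)
        labels[vec] = lab
        signs: tuple[Sign, ...]
        if lab == "positive_only":
            signs = (POSITIVE,)
        elif lab == "negative_only":
            signs = (NEGATIVE,)
        elif lab == "ambiguous":
            signs = (POSITIVE, NEGATIVE)
        else:
            signs = ()
        for sign in signs:
            proto = compute_prototype(vec, sign, bounds)
            profiles.append(
                InteractionProfile(profile_id(vec, sign), vec, sign, proto)
            )
    return Catalog(tuple(profiles), labels, bounds)
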