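"""The ten biological interaction modes.

The 82 interaction profiles are grouped into 10 named classes ("modes")
that share a biological interpretation: five for positive interactions
(low stabilization, X restores Y, Y restores X, positive synergy,
emergent positive synergy) and five conjugate negative counterparts
(high stabilization, X inhibits Y, Y inhibits X, negative synergy,
emergent negative synergy).  Conjugate modes are exchanged by flipping
the interaction sign; the restore/inhibit pairs are additionally
*opposite* modes, exchanged by swapping the roles of the two stimuli.

Assignment is a deterministic decision tree on the single-signal effects
c1 = sign(e_X − e_0) and c2 = sign(e_Y − e_0) of a profile's ranking.
For a positive profile:

1. neither signal acts alone (c1 = c2 = 0)      → emergent positive synergy
2. neither signal decreases, at least one acts  → positive synergy
3. Y decreases, X does not (c2 = −1, c1 ≥ 0)    → X restores Y
4. X decreases, Y does not (c1 = −1, c2 ≥ 0)    → Y restores X
5. both decrease (c1 = c2 = −1)                 → low stabilization

Negative profiles use the sign-flipped mirror of the same tree.  This
reconstruction reproduces every verbal mode description and worked
example in the source material and satisfies the conjugation and
stimulus-swap symmetries; it is versioned here and should not be changed
silently (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import (
    NEGATIVE,
    POSITIVE,
    Catalog,
    ComparisonVector,
    InteractionProfile,
    Sign,
)

__all__ = [
    "InteractionMode",
    "MODES",
    "MODE_NAMES",
    "assign_mode",
    "partition_catalog",
    "mode_counts",
    "profiles_per_mode",
    "is_edge_case",
]


@dataclass(frozen=True)
class InteractionMode:
    """A named interaction class with its conjugate/opposite structure."""

    name: str
    sign: Sign
    conjugate: str
    opposite: str | None = None


MODES: dict[str, InteractionMode] = {
    m.name: m
    for m in (
        InteractionMode("low_stabilization", POSITIVE, "high_stabilization"),
        InteractionMode("x_restores_y", POSITIVE, "x_inhibits_y", "y_restores_x"),
        InteractionMode("y_restores_x", POSITIVE, "y_inhibits_x", "x_restores_y"),
        InteractionMode("positive_synergy", POSITIVE, "negative_synergy"),
        InteractionMode(
            "emergent_positive_synergy", POSITIVE, "emergent_negative_synergy"
        ),
        InteractionMode("high_stabilization", NEGATIVE, "low_stabilization"),
        InteractionMode("x_inhibits_y", NEGATIVE, "x_restores_y", "y_inhibits_x"),
        InteractionMode("y_inhibits_x", NEGATIVE, "y_restores_x", "x_inhibits_y"),
        InteractionMode("negative_synergy", NEGATIVE, "positive_synergy"),
        InteractionMode(
            "emergent_negative_synergy", NEGATIVE, "emergent_positive_synergy"
        ),
    )
}

#: canonical order: the five positive modes, then their conjugates
MODE_NAMES = tuple(MODES)


def assign_mode(profile: InteractionProfile) -> str:
    """Mode name for a catalog profile (total on all 82 profiles)."""
    return assign_mode_from(profile.ranking, profile.sign)


def assign_mode_from(ranking: ComparisonVector, sign: Sign) -> str:
    """Decision-tree mode assignment from a ranking and interaction sign."""
    c1, c2 = ranking.c1, ranking.c2
    if sign == POSITIVE:
        if c1 == 0 and c2 == 0:
            return "emergent_positive_synergy"
        if c1 >= 0 and c2 >= 0:
            return "positive_synergy"
        if c2 == -1 and c1 >= 0:
            return "x_restores_y"
        if c1 == -1 and c2 >= 0:
            return "y_restores_x"
        return "low_stabilization"
    if sign == NEGATIVE:
        if c1 == 0 and c2 == 0:
            return "emergent_negative_synergy"
        if c1 <= 0 and c2 <= 0:
            return "negative_synergy"
        if c2 == 1 and c1 <= 0:
            return "x_inhibits_y"
        if c1 == 1 and c2 <= 0:
            return "y_inhibits_x"
        return "high_stabilization"
    raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")


def is_edge_case(profile: InteractionProfile) -> bool:
    """Stabilization profiles whose combination crosses the control level.

    A low-stabilization profile (both signals decrease) whose combination
    nevertheless ends above control — or the conjugate situation for high
    stabilization — sits at the boundary of the stabilization concept and
    is flagged for the user's attention.
    """
    mode = assign_mode(profile)
    c3 = profile.ranking.c3
    return (mode == "low_stabilization" and c3 == 1) or (
        mode == "high_stabilization" and c3 == -1
    )


def partition_catalog(
    catalog: Catalog,
) -> dict[str, tuple[InteractionProfile, ...]]:
    """Partition the 82 profiles into the 10 modes (all nonempty)."""
    out: dict[str, list[InteractionProfile]] = {name: [] for name in MODE_NAMES}
    for p in catalog.profiles:
        out[assign_mode(p)].append(p)
    return {name: tuple(v) for name, v in out.items()}


def mode_counts(catalog: Catalog) -> dict[str, int]:
    """Number of catalog profiles per mode."""
    return {name: len(v) for name, v in partition_catalog(catalog).items()}


def profiles_per_mode(catalog: Catalog) -> dict[str, int]:
    """Alias for :func:`mode_counts`, the normalizer used when reporting
    the per-mode distribution of classified genes."""
    return mode_counts(catalog)
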