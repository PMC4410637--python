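"""Synthetic factorial expression data with known interaction ground truth.

The generator emulates the structure of replicated two-signal microarray
experiments: four conditions (CTRL, X, Y, XY), a handful of biological
replicates (3 by default, matching typical donor counts), log2 values in
the Affymetrix range [2, 16], and i.i.d. Gaussian replicate noise on the
log2 scale (σ = 0.2 by default, a realistic replicate-to-replicate spread
for normalised arrays).

Three gene populations are planted:

* *profile genes* — condition means equal to a catalog profile's
  prototype, so each carries a known interaction profile, mode and
  strength;
* *additive genes* — random single-signal increments with
  Δe_XY = Δe_X + Δe_Y exactly (regulated but non-interacting);
* *inactive genes* — constant means (not regulated; baselines span the
  full range, so some fall below the detection threshold, emulating
  undetected probes).

A companion generator produces gene-set collections over a synthetic
strength background for exercising the AIC analysis: null terms (plain
background draws), mean-shifted terms, variance-inflated terms, and
mode-dominated terms built from an experiment's truth table.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import modes as modes_mod
from .catalog import Catalog, build_catalog
from .classify import ExpressionExperiment

__all__ = [
    "SimulationConfig",
    "GeneSetSimulationConfig",
    "simulate_experiment",
    "simulate_geneset_collection",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic factorial experiment."""

    genes_per_profile: int = 2
    n_additive: int = 200
    n_inactive: int = 300
    n_replicates: int = 3
    sigma: float = 0.2
    baseline_range: tuple[float, float] = (2.0, 16.0)
    additive_effect: float = 1.5  # max |Δe| of single-signal increments, log2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")


def simulate_experiment(
    config: SimulationConfig, catalog: Catalog | None = None
) -> tuple[ExpressionExperiment, pd.DataFrame]:
    """Generate an experiment plus its gene-level truth table.

    The truth table has one row per gene with columns ``kind``
    (profile/additive/inactive), ``profile_id``, ``mode`` and ``s`` (the
    noiseless interaction strength of the planted means).
    """
    rng = np.random.default_rng(config.seed)
    if catalog is None:
        catalog = build_catalog()
    lo, hi = config.baseline_range
    a = config.additive_effect

    names: list[str] = []
    means: list[np.ndarray] = []
    truth_rows: list[dict] = []

    for p in catalog.profiles:
        mode = modes_mod.assign_mode(p)
        proto = np.asarray(p.prototype, dtype=float)
        s = proto[3] - proto[1] - proto[2] + proto[0]
        for j in range(config.genes_per_profile):
            names.append(f"ip_{p.id}_{j}")
            means.append(proto)
            truth_rows.append(
                {"kind": "profile", "profile_id": p.id, "mode": mode, "s": s}
            )
    for i in range(config.n_additive):
        e0 = rng.uniform(lo + 2 * a, hi - 2 * a)
        dx, dy = rng.uniform(-a, a, size=2)
        names.append(f"add_{i:04d}")
        means.append(np.array([e0, e0 + dx, e0 + dy, e0 + dx + dy]))
        truth_rows.append(
            {"kind": "additive", "profile_id": "", "mode": "", "s": 0.0}
        )
    for i in range(config.n_inactive):
        e0 = rng.uniform(lo, hi)
        names.append(f"bg_{i:04d}")
        means.append(np.full(4, e0))
        truth_rows.append(
            {"kind": "inactive", "profile_id": "", "mode": "", "s": 0.0}
        )

    mean_mat = np.vstack(means)  # genes × 4 (CTRL, X, Y, XY)
    nrep = config.n_replicates
    samples = [
        f"{cond}_r{k+1}"
        for cond in ("CTRL", "X", "Y", "XY")
        for k in range(nrep)
    ]
    expanded = np.repeat(mean_mat, nrep, axis=1)
    noise = rng.normal(0.0, config.sigma, size=expanded.shape)
    matrix = pd.DataFrame(expanded + noise, index=names, columns=samples)
    design = pd.DataFrame(
        {
            "condition": [s.split("_")[0] for s in samples],
            "replicate": [int(s.split("_r")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(truth_rows, index=pd.Index(names, name="gene"))
    return ExpressionExperiment(matrix, design), truth


@dataclass(frozen=True)
class GeneSetSimulationConfig:
    """Study conditions for a synthetic strength background + gene sets."""

    n_background: int = 5000
    term_size: int = 50
    n_null_terms: int = 5
    n_shifted_terms: int = 5
    n_inflated_terms: int = 5
    shift: float = 3.0  # planted mean shift, in units of sigma_b
    inflation: float = 2.0  # planted s.d. multiplier
    mu_b: float = 0.0
    sigma_b: float = 0.5
    seed: int = 0


def simulate_geneset_collection(
    config: GeneSetSimulationConfig,
    mode_genes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.Series, dict[str, list[str]], pd.DataFrame]:
    """Generate background strengths, a gene-set collection and its truth.

    Background strengths are N(μ_b, σ_b²) over genes ``G000000...``.
    Null terms are untouched random subsets; shifted terms have their
    members' strengths redrawn from N(μ_b + shift·σ_b, σ_b²); inflated
    terms from N(μ_b, (inflation·σ_b)²).  When ``mode_genes`` (mode name →
    member gene ids, e.g. from an experiment truth table) is given, one
    extra term per mode is emitted whose members are exactly those genes;
    such terms live in the caller's gene universe, not the synthetic
    background.

    Returns (strengths, term → members, truth frame with the planted term
    type and parameters).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_background
    genes = np.array([f"G{i:06d}" for i in range(n)])
    s = rng.normal(config.mu_b, config.sigma_b, size=n)

    terms: dict[str, list[str]] = {}
    truth_rows: list[dict] = []

    # draw all synthetic terms disjointly so planted effects never leak
    # into one another (a "null" term containing later-shifted genes would
    # not be null)
    n_terms = (
        config.n_null_terms + config.n_shifted_terms + config.n_inflated_terms
    )
    total = n_terms * config.term_size
    if total > n:
        raise ValueError("background too small for the requested terms")
    pool = iter(rng.choice(n, size=total, replace=False))

    def draw_members() -> np.ndarray:
        return np.array([next(pool) for _ in range(config.term_size)])

    for i in range(config.n_null_terms):
        members = draw_members()
        terms[f"NULL_{i:03d}"] = list(genes[members])
        truth_rows.append({"term": f"NULL_{i:03d}", "type": "null",
                           "shift": 0.0, "inflation": 1.0})
    for i in range(config.n_shifted_terms):
        members = draw_members()
        s[members] = rng.normal(
            config.mu_b + config.shift * config.sigma_b,
            config.sigma_b,
            size=members.size,
        )
        terms[f"SHIFT_{i:03d}"] = list(genes[members])
        truth_rows.append({"term": f"SHIFT_{i:03d}", "type": "shifted",
                           "shift": config.shift, "inflation": 1.0})
    for i in range(config.n_inflated_terms):
        members = draw_members()
        s[members] = rng.normal(
            config.mu_b, config.inflation * config.sigma_b, size=members.size
        )
        terms[f"INFL_{i:03d}"] = list(genes[members])
        truth_rows.append({"term": f"INFL_{i:03d}", "type": "inflated",
                           "shift": 0.0, "inflation": config.inflation})
    if mode_genes is not None:
        for mode, members in mode_genes.items():
            name = f"MODE_{mode}"
            terms[name] = list(members)
            truth_rows.append({"term": name, "type": "mode_dominated",
                               "shift": 0.0, "inflation": 1.0})

    strengths = pd.Series(s, index=pd.Index(genes, name="gene"), name="strength")
    truth = pd.DataFrame(
        truth_rows, columns=["term", "type", "shift", "inflation"]
    ).set_index("term")
    return strengths, terms, truth
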