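"""Interaction strength (Bliss factor) and AIC gene-set differential analysis.

For each gene the interaction strength is the deviation from additive
(Bliss-independent) integration of the two signals on the log2 scale,

    s = <Δe_XY> − (<Δe_X> + <Δe_Y>) = <e_XY> − <e_X> − <e_Y> + <e_0>,

averaged over replicates/donors.  s is exactly 0 for an additive gene,
positive for synergistic deviations and negative for antagonistic ones.

Across the background — every gene that passes independent filtering —
the distribution of s is well approximated by a Gaussian with maximum-
likelihood parameters (μ_b, σ_b).  For a gene set (annotation term) with
m ≥ 10 members, the set's s values are fitted likewise (μ_p, σ_p), and
four nested Gaussian configurations are compared by the Akaike
information criterion, AIC = 2k − 2 lnL:

1. one shared Gaussian (μ, σ), k = 2;
2. separate means, shared σ, k = 3;
3. shared mean, separate σ's, k = 3 (shared-μ ML found by fixed-point
   iteration);
4. separate means and σ's, k = 4.

Scenario 1 winning means the term behaves like the background; scenarios
2/4 flag a mean shift (direction = sign of μ_p − μ_b); scenarios 3/4 a
spread change.  By default the term members stay part of the background
(the background is the full filtered gene universe), so the joint
likelihood runs over n + m values; a disjoint-background variant is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import modes as modes_mod

__all__ = [
    "GaussianFit",
    "TermResult",
    "interaction_strength",
    "strength_table",
    "fit_background",
    "term_aic",
    "enrich",
    "mode_dominance",
]

_LOG2PI = math.log(2 * math.pi)
#: variance floor guarding degenerate (constant) inputs in likelihoods
_VAR_FLOOR = 1e-300


@dataclass(frozen=True)
class GaussianFit:
    """Maximum-likelihood Gaussian fit (σ̂² is the 1/n estimator)."""

    mu: float
    sigma: float
    n: int

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class TermResult:
    """AIC comparison of one annotation term against the background."""

    term: str
    m: int
    aic: tuple[float, float, float, float]
    scenario: int  # 1..4, argmin AIC (ties -> smallest)
    mu_b: float
    sigma_b: float
    mu_p: float
    sigma_p: float
    direction: int  # sign of mu_p − mu_b

    @property
    def aic_margin(self) -> float:
        """How far the null scenario is beaten: AIC₁ − min AIC (≥ 0 when a
        non-null scenario wins)."""
        return self.aic[0] - min(self.aic)


def interaction_strength(groups: Mapping[str, Sequence[float]]) -> float:
    """Interaction strength s from per-condition replicate values.

    s = mean(XY) − mean(X) − mean(Y) + mean(CTRL); exactly 0 for a gene
    whose condition means are additive, invariant to shifting all four
    means by a constant.
    """
    try:
        m = {c: float(np.mean(np.asarray(groups[c], dtype=float)))
             for c in ("CTRL", "X", "Y", "XY")}
    except KeyError as e:
        raise ValueError(f"missing condition {e.args[0]!r}") from e
    return m["XY"] - m["X"] - m["Y"] + m["CTRL"]


def strength_table(experiment) -> pd.Series:
    """Per-gene interaction strengths for a whole experiment."""
    cm = experiment.condition_means()
    return (cm["XY"] - cm["X"] - cm["Y"] + cm["CTRL"]).rename("strength")


def fit_background(strengths: Iterable[float]) -> GaussianFit:
    """ML Gaussian fit of the background strength distribution."""
    x = np.asarray(list(strengths), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 strengths to fit a Gaussian")
    return GaussianFit(float(x.mean()), float(x.std(ddof=0)), int(x.size))


def _neg2ll(x: np.ndarray, mu: float, var: float) -> float:
    var = max(var, _VAR_FLOOR)
    return x.size * (_LOG2PI + math.log(var)) + float(
        ((x - mu) ** 2).sum() / var
    )


def _shared_mu_ml(b: np.ndarray, p: np.ndarray, iters: int = 200) -> float:
    # ML of a common mean with group-specific variances: fixed-point
    # iteration of the precision-weighted mean.
    mu = float(np.concatenate([b, p]).mean())
    for _ in range(iters):
        vb = max(float(((b - mu) ** 2).mean()), _VAR_FLOOR)
        vp = max(float(((p - mu) ** 2).mean()), _VAR_FLOOR)
        new = (b.size * b.mean() / vb + p.size * p.mean() / vp) / (
            b.size / vb + p.size / vp
        )
        if abs(new - mu) < 1e-12:
            mu = new
            break
        mu = new
    return mu


def term_aic(
    term: str,
    members: Sequence[str],
    strengths: pd.Series,
    min_size: int = 10,
    disjoint_background: bool = False,
) -> TermResult | None:
    """Compare a term's strength distribution with the background by AIC.

    ``strengths`` indexes the full background (all filtered genes);
    ``members`` are intersected with it.  Terms with fewer than
    ``min_size`` members in the background are skipped (returns None).
    With ``disjoint_background`` the term genes are removed from the
    background group before fitting.
    """
    idx = strengths.index
    present = [g for g in dict.fromkeys(members) if g in idx]
    m = len(present)
    if m < min_size:
        return None
    p = strengths.loc[present].to_numpy(dtype=float)
    if disjoint_background:
        b = strengths.drop(index=present).to_numpy(dtype=float)
    else:
        b = strengths.to_numpy(dtype=float)
    n = b.size
    pooled = np.concatenate([b, p])

    # scenario 1: shared mu, sigma (k=2)
    mu1 = float(pooled.mean())
    v1 = float(pooled.var(ddof=0))
    aic1 = _neg2ll(pooled, mu1, v1) + 2 * 2
    # scenario 2: separate means, shared sigma (k=3)
    mu_b, mu_p = float(b.mean()), float(p.mean())
    v2 = float(
        (((b - mu_b) ** 2).sum() + ((p - mu_p) ** 2).sum()) / (n + m)
    )
    aic2 = _neg2ll(b, mu_b, v2) + _neg2ll(p, mu_p, v2) + 2 * 3
    # scenario 3: shared mean, separate sigmas (k=3)
    mu3 = _shared_mu_ml(b, p)
    vb3 = float(((b - mu3) ** 2).mean())
    vp3 = float(((p - mu3) ** 2).mean())
    aic3 = _neg2ll(b, mu3, vb3) + _neg2ll(p, mu3, vp3) + 2 * 3
    # scenario 4: separate means and sigmas (k=4)
    vb4 = float(b.var(ddof=0))
    vp4 = float(p.var(ddof=0))
    aic4 = _neg2ll(b, mu_b, vb4) + _neg2ll(p, mu_p, vp4) + 2 * 4

    aics = (aic1, aic2, aic3, aic4)
    scenario = int(np.argmin(aics)) + 1
    return TermResult(
        term=term,
        m=m,
        aic=aics,
        scenario=scenario,
        mu_b=mu_b,
        sigma_b=math.sqrt(vb4),
        mu_p=mu_p,
        sigma_p=math.sqrt(vp4),
        direction=int(np.sign(mu_p - mu_b)),
    )


def enrich(
    strengths: pd.Series,
    genesets: Mapping[str, Sequence[str]],
    calls: pd.DataFrame | None = None,
    min_size: int = 10,
    disjoint_background: bool = False,
) -> pd.DataFrame:
    """AIC gene-set analysis over a GMT-style collection.

    Returns one row per term of size ≥ ``min_size``, sorted by decreasing
    AIC margin over the null scenario.  When a classification ``calls``
    frame (with columns gene/mode) is supplied, each term also reports
    its dominant interaction mode and dominance fraction.
    """
    rows = []
    for term, members in genesets.items():
        res = term_aic(
            term, members, strengths,
            min_size=min_size, disjoint_background=disjoint_background,
        )
        if res is None:
            continue
        row = {
            "term": res.term,
            "m": res.m,
            "AIC1": res.aic[0],
            "AIC2": res.aic[1],
            "AIC3": res.aic[2],
            "AIC4": res.aic[3],
            "scenario": res.scenario,
            "mu_p": res.mu_p,
            "sigma_p": res.sigma_p,
            "direction": res.direction,
            "aic_margin": res.aic_margin,
        }
        if calls is not None:
            dom = mode_dominance(members, calls)
            row["dominant_mode"] = dom["dominant_mode"] or ""
            row["dominance"] = dom["dominance"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["aic_margin", "term"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def mode_dominance(
    members: Sequence[str], calls: pd.DataFrame
) -> dict:
    """Per-mode fractions of a term's interaction genes.

    ``calls`` needs columns ``gene`` and ``mode``.  The dominant mode is
    the argmax fraction, ties broken by mode name; terms without any
    interaction gene report NaN dominance.
    """
    sub = calls[calls["gene"].isin(set(members)) & (calls["mode"] != "")]
    sub = sub[sub["mode"].notna()]
    total = len(sub)
    fractions = {name: 0.0 for name in modes_mod.MODE_NAMES}
    if total == 0:
        return {
            "fractions": fractions,
            "dominant_mode": None,
            "dominance": float("nan"),
            "n_interaction": 0,
        }
    counts = sub["mode"].value_counts()
    for name, cnt in counts.items():
        fractions[name] = cnt / total
    dominant = min(
        (name for name in fractions),
        key=lambda name: (-fractions[name], name),
    )
    return {
        "fractions": fractions,
        "dominant_mode": dominant,
        "dominance": fractions[dominant],
        "n_interaction": total,
    }
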