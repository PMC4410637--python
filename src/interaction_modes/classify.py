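"""Mapping replicated factorial expression data onto interaction profiles.

The workflow takes a log2 expression matrix measured in the four
conditions CTRL, X, Y, XY with ≥2 replicates each and proceeds in four
steps:

1. pre-processing — collapse multiple probe sets per gene to the one with
   the highest average signal, and drop genes never detected (no condition
   with every replicate above the detection threshold, 4 on the log2
   scale);
2. selection of regulated genes by one-way ANOVA across the four
   conditions, Benjamini–Hochberg corrected at FDR 5%;
3. selection of non-additive genes among the regulated ones by the
   interaction term of a 2×2 factorial (presence-of-X × presence-of-Y)
   ANOVA, again BH corrected at FDR 5%;
4. classification — each non-additive gene is encoded as a six-component
   comparison vector from pooled-variance t confidence intervals of the
   pairwise condition differences and matched against the catalog of 82
   theoretical profiles; genes whose vector matches no profile (because
   of statistical inconsistencies: intransitive vectors, additive-only
   rankings, or a vector infeasible under the observed interaction sign)
   are assigned to the nearest prototype by correlation distance among
   profiles of the observed sign ("learned" profiles).

All per-gene statistics are computed vectorised over the matrix; the
result is a table of :class:`GeneInteractionCall` records plus summary
counts, including the per-mode gene distribution normalised by the number
of theoretical profiles each mode contains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from . import catalog as cat
from . import modes as modes_mod
from .catalog import Catalog, ComparisonVector

__all__ = [
    "ExpressionExperiment",
    "GeneInteractionCall",
    "ClassificationResult",
    "collapse_probesets",
    "detection_filter",
    "one_way_anova",
    "interaction_anova",
    "select_regulated",
    "select_nonadditive",
    "ci_comparison_vector",
    "match_profile",
    "learn_profile",
    "classify_genes",
]

#: floor added to residual mean squares so noiseless fixtures keep a
#: defined F statistic
_VARIANCE_FLOOR = 1e-12


@dataclass
class ExpressionExperiment:
    """A log2 expression matrix with its factorial sample design.

    Parameters
    ----------
    matrix
        genes × samples DataFrame of log2 expression values.
    design
        DataFrame indexed by sample id with columns ``condition`` (one of
        CTRL/X/Y/XY) and ``replicate``.
    symbols
        Optional per-row gene symbol (for probe-set collapse), indexed
        like ``matrix``.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.design.index.has_duplicates:
            dup = self.design.index[self.design.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in design")
        missing = set(self.matrix.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)}")
        unknown = set(self.design["condition"]) - set(cat.CONDITIONS)
        if unknown:
            raise ValueError(
                f"unknown condition label(s) {sorted(unknown)}; "
                f"expected one of {cat.CONDITIONS}"
            )
        self.design = self.design.loc[list(self.matrix.columns)]
        absent = [
            c for c in cat.CONDITIONS
            if (self.design["condition"] == c).sum() == 0
        ]
        if absent:
            raise ValueError(f"condition(s) missing from design: {absent}")
        if not np.all(np.isfinite(self.matrix.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def condition_columns(self) -> dict[str, list[str]]:
        return {
            c: list(self.design.index[self.design["condition"] == c])
            for c in cat.CONDITIONS
        }

    def replicate_counts(self) -> dict[str, int]:
        return {c: len(cols) for c, cols in self.condition_columns.items()}

    def condition_arrays(self, gene: str) -> dict[str, np.ndarray]:
        """Replicate values of one gene, keyed by condition."""
        row = self.matrix.loc[gene]
        return {
            c: row[cols].to_numpy(dtype=float)
            for c, cols in self.condition_columns.items()
        }

    def condition_means(self) -> pd.DataFrame:
        """genes × 4 DataFrame of condition means, columns CTRL,X,Y,XY."""
        return pd.DataFrame(
            {
                c: self.matrix[cols].mean(axis=1)
                for c, cols in self.condition_columns.items()
            }
        )

    def subset(self, genes: Sequence[str]) -> "ExpressionExperiment":
        sym = self.symbols.loc[list(genes)] if self.symbols is not None else None
        return ExpressionExperiment(
            self.matrix.loc[list(genes)], self.design.copy(), sym
        )


@dataclass(frozen=True)
class GeneInteractionCall:
    """Classification outcome for one non-additive gene."""

    gene: str
    one_way_p: float
    one_way_q: float
    interaction_p: float
    interaction_q: float
    comparison_vector: tuple[int, int, int, int, int, int]
    profile_id: str | None
    mode: str | None
    origin: str  # "matched", "learned" or "unclassified"
    strength: float


@dataclass
class ClassificationResult:
    """Calls plus the per-stage summary of the classification workflow."""

    calls: list[GeneInteractionCall]
    regulated: pd.DataFrame  # gene-indexed one-way p/q
    nonadditive: pd.DataFrame  # gene-indexed interaction p/q (regulated genes)
    strengths: pd.Series  # interaction strength of every filtered gene
    summary: dict = field(default_factory=dict)

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "gene": c.gene,
                    "one_way_p": c.one_way_p,
                    "one_way_q": c.one_way_q,
                    "interaction_p": c.interaction_p,
                    "interaction_q": c.interaction_q,
                    **{f"c{i+1}": v for i, v in enumerate(c.comparison_vector)},
                    "profile_id": c.profile_id or "",
                    "mode": c.mode or "",
                    "origin": c.origin,
                    "strength": c.strength,
                }
            )
        cols = [
            "gene", "one_way_p", "one_way_q", "interaction_p", "interaction_q",
            "c1", "c2", "c3", "c4", "c5", "c6",
            "profile_id", "mode", "origin", "strength",
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# pre-processing

def collapse_probesets(exp: ExpressionExperiment) -> ExpressionExperiment:
    """Keep, per gene symbol, only the probe set with the highest mean.

    Ties on the mean are broken toward the lexicographically smaller
    feature id.  Without symbol annotation the experiment is returned
    unchanged with a warning.
    """
    if exp.symbols is None:
        warnings.warn("no gene-symbol annotation; probe-set collapse skipped")
        return exp
    means = exp.matrix.mean(axis=1)
    order = pd.DataFrame(
        {"symbol": exp.symbols, "mean": means}, index=exp.matrix.index
    )
    # sort by (symbol, -mean, feature id); stable sort keeps lexicographic
    # tie-break on equal means
    order = order.sort_index().sort_values("mean", ascending=False, kind="stable")
    keep = order.groupby("symbol", sort=False).head(1).index
    keep = [g for g in exp.matrix.index if g in set(keep)]
    out = exp.subset(keep)
    out.matrix.index = [exp.symbols[g] for g in keep]
    out.symbols = None
    return out


def detection_filter(
    exp: ExpressionExperiment, threshold: float = 4.0
) -> ExpressionExperiment:
    """Keep genes detected in at least one condition.

    A gene is detected in a condition when *every* replicate of that
    condition is strictly above the log2 detection threshold (default 4,
    calibrated for Affymetrix HG U133 Plus 2.0 intensities).
    """
    detected = np.zeros(len(exp.matrix), dtype=bool)
    for cols in exp.condition_columns.values():
        detected |= (exp.matrix[cols] > threshold).all(axis=1).to_numpy()
    return exp.subset(list(exp.matrix.index[detected]))


# ---------------------------------------------------------------------------
# ANOVA steps

def _group_stats(exp: ExpressionExperiment):
    groups = exp.condition_columns
    ns = np.array([len(groups[c]) for c in cat.CONDITIONS])
    if (ns < 2).any():
        bad = [c for c, n in zip(cat.CONDITIONS, ns) if n < 2]
        raise ValueError(f"need ≥2 replicates per condition; short: {bad}")
    x = exp.matrix
    means = np.column_stack(
        [x[groups[c]].mean(axis=1).to_numpy() for c in cat.CONDITIONS]
    )
    sse = np.zeros(len(x))
    for j, c in enumerate(cat.CONDITIONS):
        arr = x[groups[c]].to_numpy(dtype=float)
        sse += ((arr - means[:, [j]]) ** 2).sum(axis=1)
    return means, ns, sse


def one_way_anova(exp: ExpressionExperiment) -> pd.DataFrame:
    """Per-gene fixed-effects one-way ANOVA across the four conditions.

    Returns a gene-indexed frame with columns ``F`` and ``p``.  The
    residual mean square is floored at 1e−12 so that noiseless synthetic
    data keeps a defined statistic.
    """
    means, ns, sse = _group_stats(exp)
    n_tot = ns.sum()
    grand = (means * ns).sum(axis=1) / n_tot
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    df_b, df_w = len(ns) - 1, n_tot - len(ns)
    msw = sse / df_w + _VARIANCE_FLOOR
    f = (ssb / df_b) / msw
    p = st.f.sf(f, df_b, df_w)
    return pd.DataFrame({"F": f, "p": p}, index=exp.matrix.index)


def interaction_anova(exp: ExpressionExperiment) -> pd.DataFrame:
    """Per-gene 2×2 factorial interaction test.

    Factors are presence-of-X and presence-of-Y; the interaction F test
    at 2×2 is the squared t test of the interaction contrast
    L = m_XY − m_X − m_Y + m_CTRL against the pooled within-condition
    residual (df = N − 4).  Returns columns ``contrast``, ``F`` and ``p``.
    """
    means, ns, sse = _group_stats(exp)
    df_w = ns.sum() - len(ns)
    msw = sse / df_w + _VARIANCE_FLOOR
    # condition order CTRL, X, Y, XY → contrast +1 −1 −1 +1
    contrast = means[:, 3] - means[:, 1] - means[:, 2] + means[:, 0]
    se2 = msw * (1.0 / ns).sum()
    f = contrast**2 / se2
    p = st.f.sf(f, 1, df_w)
    return pd.DataFrame(
        {"contrast": contrast, "F": f, "p": p}, index=exp.matrix.index
    )


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def select_regulated(
    exp: ExpressionExperiment, fdr: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Differentially expressed genes at the given BH FDR.

    Returns the selected gene list and a gene-indexed frame with the
    one-way ANOVA ``p`` and BH-adjusted ``q`` for every tested gene.
    """
    if len(exp.matrix) == 0:
        return [], pd.DataFrame(columns=["p", "q"])
    res = one_way_anova(exp)
    res["q"] = _bh(res["p"].to_numpy())
    selected = list(res.index[res["q"] <= fdr])
    return selected, res[["p", "q"]]


def select_nonadditive(
    exp: ExpressionExperiment,
    regulated: Sequence[str],
    fdr: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Non-additive genes among the regulated set at the given BH FDR.

    The interaction p value of the 2×2 factorial ANOVA is BH-corrected
    across the regulated genes only (sequential filtering).  Returns the
    selected genes and a frame with ``contrast``, ``p`` and ``q``.
    """
    if len(regulated) == 0:
        return [], pd.DataFrame(columns=["contrast", "p", "q"])
    sub = exp.subset(regulated)
    res = interaction_anova(sub)
    res["q"] = _bh(res["p"].to_numpy())
    selected = list(res.index[res["q"] <= fdr])
    return selected, res[["contrast", "p", "q"]]


# ---------------------------------------------------------------------------
# per-gene classification

def ci_comparison_vector(
    groups: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    equiv_tol: float = 0.0,
) -> tuple[int, int, int, int, int, int]:
    """Six-component comparison vector from confidence intervals.

    For each of the six ordered condition pairs, a two-sided pooled-
    variance t interval at level 1−``alpha`` for the difference of means
    is computed from the two groups: 0 when the interval contains zero,
    ±1 when it lies entirely on one side.  A mean difference with
    absolute value ≤ ``equiv_tol`` is additionally coded 0 (practical-
    equivalence tolerance for low-noise data; default 0 keeps the pure CI
    rule).  The result may be intransitive; such vectors fail catalog
    matching downstream.
    """
    vals = {c: np.asarray(groups[c], dtype=float) for c in cat.CONDITIONS}
    for c, v in vals.items():
        if v.size < 2:
            raise ValueError(f"condition {c} has <2 replicates")
    order = ("CTRL", "X", "Y", "XY")
    comps = []
    for i, j in cat.COMPARISON_PAIRS:
        a, b = vals[order[i]], vals[order[j]]
        na, nb = a.size, b.size
        diff = a.mean() - b.mean()
        df = na + nb - 2
        sp2 = ((a.var(ddof=1) * (na - 1)) + (b.var(ddof=1) * (nb - 1))) / df
        half = st.t.ppf(1 - alpha / 2, df) * np.sqrt(
            max(sp2, _VARIANCE_FLOOR) * (1 / na + 1 / nb)
        )
        if abs(diff) <= equiv_tol or abs(diff) <= half:
            comps.append(0)
        else:
            comps.append(1 if diff > 0 else -1)
    return tuple(comps)


def match_profile(
    vec: Sequence[int], sign: int, catalog: Catalog
) -> str | None:
    """Catalog profile id whose ranking equals ``vec`` under the observed
    interaction sign, or None (intransitive / additive-only / wrong-sign
    vectors, and degenerate sign 0, all return None)."""
    if sign == 0:
        return None
    p = catalog.match(
        ComparisonVector(*vec), cat.POSITIVE if sign > 0 else cat.NEGATIVE
    )
    return p.id if p is not None else None


def learn_profile(
    means: Sequence[float], sign: int, catalog: Catalog
) -> str | None:
    """Nearest catalog profile by correlation distance, sign-restricted.

    The 4-vector of condition means is compared with the prototype of
    every profile whose interaction sign matches the observed sign of the
    interaction contrast, using d = 1 − Pearson r; the nearest wins, ties
    broken by profile id.  A constant mean profile has no defined
    correlation and returns None (unclassifiable).
    """
    m = np.asarray(means, dtype=float)
    if sign == 0 or np.allclose(m, m[0]):
        return None
    target = cat.POSITIVE if sign > 0 else cat.NEGATIVE
    best: tuple[float, str] | None = None
    mc = m - m.mean()
    denom_m = np.linalg.norm(mc)
    for p in catalog.profiles_with_sign(target):
        proto = np.asarray(p.prototype) - np.mean(p.prototype)
        r = float(mc @ proto / (denom_m * np.linalg.norm(proto)))
        d = 1.0 - r
        if best is None or (d, p.id) < best:
            best = (d, p.id)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# full workflow

def classify_genes(
    exp: ExpressionExperiment,
    catalog: Catalog | None = None,
    fdr: float = 0.05,
    alpha: float = 0.05,
    equiv_tol: float = 0.0,
    detection_threshold: float | None = 4.0,
    collapse: bool = True,
) -> ClassificationResult:
    """Run the full workflow from the expression matrix to mode calls.

    Steps: optional probe-set collapse, detection filter, one-way ANOVA
    selection (BH at ``fdr``), 2×2 interaction selection (BH at ``fdr``),
    CI-vector profile matching at level 1−``alpha`` with nearest-
    neighbour fallback.  ``equiv_tol`` is the practical-equivalence
    tolerance passed to :func:`ci_comparison_vector`.

    The summary reports per-stage gene counts, per-mode counts, the mode
    distribution normalised by the number of theoretical profiles per
    mode, and the co-occurrence of the opposite restore/inhibit modes.
    """
    if catalog is None:
        catalog = cat.build_catalog()
    n_input = len(exp.matrix)
    if collapse and exp.symbols is not None:
        exp = collapse_probesets(exp)
    if detection_threshold is not None:
        exp = detection_filter(exp, detection_threshold)
    n_filtered = len(exp.matrix)

    regulated, oneway = select_regulated(exp, fdr)
    nonadd, twoway = select_nonadditive(exp, regulated, fdr)

    cond_means = exp.condition_means()
    strengths = (
        cond_means["XY"] - cond_means["X"] - cond_means["Y"] + cond_means["CTRL"]
    ).rename("strength")

    calls: list[GeneInteractionCall] = []
    for gene in nonadd:
        groups = exp.condition_arrays(gene)
        vec = ci_comparison_vector(groups, alpha=alpha, equiv_tol=equiv_tol)
        s = float(strengths.loc[gene])
        sign = int(np.sign(twoway.loc[gene, "contrast"]))
        pid = match_profile(vec, sign, catalog)
        if pid is not None:
            origin = "matched"
        else:
            pid = learn_profile(cond_means.loc[gene].to_numpy(), sign, catalog)
            origin = "learned" if pid is not None else "unclassified"
        mode = (
            modes_mod.assign_mode(catalog.by_id[pid]) if pid is not None else None
        )
        calls.append(
            GeneInteractionCall(
                gene=gene,
                one_way_p=float(oneway.loc[gene, "p"]),
                one_way_q=float(oneway.loc[gene, "q"]),
                interaction_p=float(twoway.loc[gene, "p"]),
                interaction_q=float(twoway.loc[gene, "q"]),
                comparison_vector=vec,
                profile_id=pid,
                mode=mode,
                origin=origin,
                strength=s,
            )
        )

    per_mode = {name: 0 for name in modes_mod.MODE_NAMES}
    for c in calls:
        if c.mode is not None:
            per_mode[c.mode] += 1
    ppm = modes_mod.profiles_per_mode(catalog)
    normalized = {name: per_mode[name] / ppm[name] for name in per_mode}
    opp = _opposite_cooccurrence(per_mode)
    summary = {
        "n_input": n_input,
        "n_filtered": n_filtered,
        "n_regulated": len(regulated),
        "n_nonadditive": len(nonadd),
        "per_mode": per_mode,
        "normalized_per_mode": normalized,
        "opposite_mode_cooccurrence": opp,
        "fdr": fdr,
        "alpha": alpha,
    }
    return ClassificationResult(
        calls=calls,
        regulated=oneway,
        nonadditive=twoway,
        strengths=strengths,
        summary=summary,
    )


def _opposite_cooccurrence(per_mode: dict[str, int]) -> dict[str, float]:
    """Fraction of the dominant member within each opposite-mode pair.

    Values near 1 mean the opposite modes exclude each other (one of the
    pair dominates); reported descriptively, not tested.
    """
    out = {}
    for a, b in (("x_restores_y", "y_restores_x"), ("x_inhibits_y", "y_inhibits_x")):
        tot = per_mode[a] + per_mode[b]
        out[f"{a}|{b}"] = max(per_mode[a], per_mode[b]) / tot if tot else float("nan")
    return out
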