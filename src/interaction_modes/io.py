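"""Readers and writers for the tool's file formats.

Formats handled:

* expression matrix — TSV, first column the gene/probe id, header row of
  sample ids;
* sample sheet — CSV/TSV with columns ``sample_id``, ``condition``
  (CTRL/X/Y/XY, or arbitrary labels remapped via ``labels``) and
  ``replicate``;
* probe → gene map — two-column TSV (feature id, gene symbol);
* gene sets — GMT (term, description, member genes per line; symbols are
  upper-cased on read);
* catalog — versioned JSON;
* calls / enrichment — TSV with fixed column order.

A :class:`RunReport` accompanies every CLI run as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import modes as modes_mod
from .catalog import (
    Catalog,
    ComparisonVector,
    InteractionProfile,
    CONDITIONS,
)
from .classify import ClassificationResult, ExpressionExperiment

__all__ = [
    "RunReport",
    "read_expression",
    "read_gmt",
    "read_strengths",
    "write_catalog",
    "read_catalog",
    "write_calls",
    "read_calls",
    "write_strengths",
    "write_enrichment",
]

CATALOG_SCHEMA_VERSION = 1

#: fixed calls.tsv column order
CALLS_COLUMNS = [
    "gene", "one_way_p", "one_way_q", "interaction_p", "interaction_q",
    "c1", "c2", "c3", "c4", "c5", "c6",
    "profile_id", "mode", "origin", "strength",
]


@dataclass
class RunReport:
    """JSON-serializable record of one tool invocation."""

    tool: str = "interaction-modes"
    version: str = "0.1.0"
    command: str = ""
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_expression(
    expr_path: str | Path,
    design_path: str | Path,
    labels: Mapping[str, str] | None = None,
    symbols_path: str | Path | None = None,
) -> ExpressionExperiment:
    """Load an expression matrix and its sample sheet.

    ``labels`` maps the design's condition names onto the canonical
    CTRL/X/Y/XY (e.g. ``{"medium": "CTRL", "IL-3": "X", "Flu": "Y",
    "IL-3+Flu": "XY"}``).  Windows line endings are accepted.  Errors
    name the offending sample or condition.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    bad = expr.columns[expr.dtypes == object]
    if len(bad):
        raise ValueError(f"non-numeric expression values in column(s) {list(bad)}")
    design = _read_table(design_path)
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"sample sheet lacks column(s) {sorted(missing)}")
    design = design.set_index("sample_id")
    if labels:
        unmapped = set(design["condition"]) - set(labels)
        if unmapped:
            raise ValueError(
                f"condition label(s) {sorted(unmapped)} not covered by --labels"
            )
        design["condition"] = design["condition"].map(labels)
    symbols = None
    if symbols_path is not None:
        m = pd.read_csv(symbols_path, sep="\t", header=None,
                        names=["feature", "symbol"])
        symbols = m.set_index("feature")["symbol"].reindex(expr.index)
    return ExpressionExperiment(expr, design, symbols)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection; member symbols are upper-cased."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs ≥3 fields): {line[:60]!r}")
        term, _desc, *members = parts
        sets[term] = [m.upper() for m in members if m]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([term, "synthetic"] + list(members))
        for term, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_strengths(path: str | Path) -> pd.Series:
    """Read a two-column (gene, strength) TSV."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]].rename("strength")


def write_strengths(strengths: pd.Series, path: str | Path) -> None:
    strengths.rename("strength").rename_axis("gene").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# catalog JSON

def catalog_to_dict(catalog: Catalog) -> dict:
    profiles = []
    for p in catalog.profiles:
        profiles.append(
            {
                "id": p.id,
                "ranking": list(p.ranking),
                "sign": p.sign,
                "prototype": list(p.prototype),
                "mode": modes_mod.assign_mode(p),
                "edge_case": modes_mod.is_edge_case(p),
            }
        )
    return {
        "schema_version": CATALOG_SCHEMA_VERSION,
        "conditions": list(CONDITIONS),
        "bounds": list(catalog.bounds),
        "profiles": profiles,
        "rankings": [
            {"vector": list(v), "label": lab}
            for v, lab in sorted(catalog.labels.items())
        ],
        "mode_counts": modes_mod.mode_counts(catalog),
    }


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    Path(path).write_text(json.dumps(catalog_to_dict(catalog), indent=1) + "\n")


def read_catalog(path: str | Path) -> Catalog:
    data = json.loads(Path(path).read_text())
    if data.get("schema_version") != CATALOG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported catalog schema {data.get('schema_version')!r}"
        )
    profiles = tuple(
        InteractionProfile(
            id=p["id"],
            ranking=ComparisonVector(*p["ranking"]),
            sign=p["sign"],
            prototype=tuple(p["prototype"]),
        )
        for p in data["profiles"]
    )
    labels = {
        ComparisonVector(*r["vector"]): r["label"] for r in data["rankings"]
    }
    return Catalog(profiles, labels, tuple(data["bounds"]))


# ---------------------------------------------------------------------------
# calls / enrichment tables

def write_calls(result: ClassificationResult, path: str | Path) -> None:
    frame = result.calls_frame()
    assert list(frame.columns) == CALLS_COLUMNS
    frame.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
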