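"""Read and validate edge tables, gene tables, gene sets and expression.

The weighted gene network is represented as a :class:`networkx.Graph` whose
edges carry a ``confidence`` attribute in (0, 1].  Edge tables follow the
STRING convention: two gene symbols plus a combined confidence score, given
either on the native 0-1000 integer scale or already normalised to [0, 1]
(auto-detected: any score above 1 implies the 0-1000 dialect).  Gene sets
use the GMT dialect.  Gene identity is the case-sensitive symbol string;
inputs are assumed to be pre-mapped to symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "ComponentReport",
    "read_edge_table",
    "read_gene_sets",
    "read_gene_table",
    "read_expression",
    "write_edge_table",
    "write_gene_sets",
    "giant_component",
    "VALID_CATEGORIES",
    "VALID_RISK_LEVELS",
]

VALID_CATEGORIES = {"1", "2", "3", "S", "unknown"}
VALID_RISK_LEVELS = {"high", "medium", "low", "unknown"}
HIGH_RISK_CATEGORIES = {"1", "2"}


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


@dataclass(frozen=True)
class ComponentReport:
    n_components: int
    fractions: tuple[float, ...]
    giant_fraction: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_edge_table(path: str | Path, threshold: float = 0.7) -> nx.Graph:
    """Build the confidence-filtered weighted network from a TSV edge list.

    Edges with normalised confidence strictly above ``threshold`` are
    retained.  Symmetric duplicates collapse keeping the maximum confidence;
    self-loops are dropped with a logged count.  An empty post-filter network
    raises rather than returning silently.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    path = Path(path)
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and len(parts) >= 3:
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header row
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable score {parts[2]!r}") from exc
            records.append((parts[0], parts[1], score))
    if not records:
        raise ValueError(f"{path}: no parseable edge rows")

    # dialect auto-detection: any score > 1 implies the 0-1000 STRING scale
    scale = 1000.0 if any(s > 1 for _, _, s in records) else 1.0

    g = nx.Graph()
    n_self = 0
    for a, b, score in records:
        conf = score / scale
        if a == b:
            n_self += 1
            continue
        if conf <= threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    if n_self:
        logger.info("dropped %d self-loop rows from %s", n_self, path)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"{path}: no edges exceed confidence threshold {threshold}"
        )
    return g


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member symbols."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = parts[0], parts[1]
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the per-gene annotation table and validate its invariants.

    Columns: symbol, category (1/2/3/S/unknown), risk_level, constraint,
    gene_length_kb, brain_expression, pathway_count, druggability (may be
    missing).  Risk level must equal "high" exactly for categories 1-2.
    """
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "category": str})
    required = {
        "symbol", "category", "risk_level", "constraint",
        "gene_length_kb", "brain_expression", "pathway_count",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    if df["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in gene table")
    bad_cat = set(df["category"]) - VALID_CATEGORIES
    if bad_cat:
        raise ValueError(f"unknown categories: {sorted(bad_cat)}")
    high = df["category"].isin(HIGH_RISK_CATEGORIES)
    if not (df.loc[high, "risk_level"] == "high").all() or (
        df.loc[~high, "risk_level"] == "high"
    ).any():
        raise ValueError("risk_level 'high' must coincide with categories 1-2")
    if ((df["constraint"] < 0) | (df["constraint"] > 1)).any():
        raise ValueError("constraint scores must lie in [0, 1]")
    if "druggability" in df.columns:
        d = df["druggability"].dropna()
        if ((d < 0) | (d > 1)).any():
            raise ValueError("druggability must lie in [0, 1]")
    return df.set_index("symbol", drop=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample expression matrix (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene symbols in expression matrix")
    return df


# ---------------------------------------------------------------------------
# writers (shared with the synthetic generator)
# ---------------------------------------------------------------------------

def write_edge_table(network: nx.Graph, path: str | Path) -> None:
    """Write a STRING-style TSV edge list (scores scaled to 0-1000)."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['confidence'] * 1000:.10g}\n")


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def giant_component(network: nx.Graph) -> tuple[nx.Graph, ComponentReport]:
    """Largest connected component plus a component-count report.

    Ties between equally large components break toward the component whose
    lexicographically smallest member symbol sorts first.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(
        nx.connected_components(network),
        key=lambda c: (-len(c), min(c)),
    )
    n = network.number_of_nodes()
    fractions = tuple(len(c) / n for c in comps)
    report = ComponentReport(len(comps), fractions, fractions[0])
    return network.subgraph(comps[0]).copy(), report
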