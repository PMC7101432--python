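"""Functional annotation of gene modules against a local pathway database.

A :class:`PathwayDB` holds GMT gene sets plus a two-level hierarchy mapping
each pathway to one of a small number of top-level ("main") pathways, the
local stand-in for a Reactome-style hierarchy. Modules are annotated by
hypergeometric over-representation of their mapped genes and the
significantly altered pathways are rolled up to top-level percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "PathwayDB",
    "load_gmt",
    "load_hierarchy",
    "write_gmt",
    "map_probes_to_genes",
    "enrich_module",
    "rollup_top_level",
    "summarize_modules",
]


@dataclass
class PathwayDB:
    """Gene sets with a pathway -> top-level-pathway hierarchy."""

    gene_sets: dict[str, frozenset[str]]
    hierarchy: dict[str, str]  # pathway -> top-level pathway

    def __post_init__(self) -> None:
        unknown = set(self.hierarchy) - set(self.gene_sets)
        if unknown:
            raise ValueError(f"hierarchy refers to unknown pathways: {sorted(unknown)[:5]}")
        missing = set(self.gene_sets) - set(self.hierarchy)
        if missing:
            raise ValueError(f"pathways missing from hierarchy: {sorted(missing)[:5]}")

    @property
    def top_levels(self) -> list[str]:
        return sorted(set(self.hierarchy.values()))

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.gene_sets.values():
            out |= s
        return frozenset(out)


def load_gmt(path: str) -> dict[str, frozenset[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate pathway names and empty gene lists are rejected; gene symbols
    are uppercase-normalized.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has no genes")
            name = parts[0]
            genes = [g.strip().upper() for g in parts[2:] if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene list for {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = frozenset(genes)
    return sets


def write_gmt(gene_sets: dict[str, frozenset[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def load_hierarchy(path: str) -> dict[str, str]:
    """Read a pathway -> top-level TSV with columns pathway_id, top_level_id."""
    df = pd.read_csv(path, sep="\t")
    if not {"pathway_id", "top_level_id"} <= set(df.columns):
        raise ValueError("hierarchy TSV needs columns pathway_id, top_level_id")
    if df["pathway_id"].duplicated().any():
        raise ValueError("pathway mapped to more than one top-level pathway")
    return dict(zip(df["pathway_id"].astype(str), df["top_level_id"].astype(str)))


def load_pathway_db(gmt_path: str, hierarchy_path: str) -> PathwayDB:
    return PathwayDB(load_gmt(gmt_path), load_hierarchy(hierarchy_path))


def map_probes_to_genes(
    probes: list[str], annotation: pd.DataFrame
) -> tuple[list[str], float]:
    """Map probe ids to unique gene symbols via an annotation table.

    ``annotation`` has columns probe_id, gene (empty/missing gene = not
    annotated). Returns (sorted unique genes, mapped-probe fraction).
    """
    ann = annotation.dropna(subset=["gene"])
    ann = ann[ann["gene"].astype(str).str.len() > 0]
    lut = dict(zip(ann["probe_id"].astype(str), ann["gene"].astype(str).str.upper()))
    mapped = [lut[p] for p in probes if p in lut]
    coverage = len(mapped) / len(probes) if probes else 0.0
    return sorted(set(mapped)), coverage


def enrich_module(
    module_genes: list[str],
    db: PathwayDB,
    universe: list[str],
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a module's genes per pathway.

    For a universe of N genes, a pathway with K universe genes and a module
    with n universe genes overlapping in k, the p-value is the upper tail
    P(X >= k) of Hypergeometric(N, K, n). P-values are BH-adjusted across
    pathways; a pathway is "altered" when p_BH < alpha and overlap >=
    ``min_overlap``.
    """
    uni = set(g.upper() for g in universe)
    if not uni:
        raise ValueError("empty gene universe")
    mod = set(g.upper() for g in module_genes) & uni
    N, n = len(uni), len(mod)
    rows = []
    for name, genes in db.gene_sets.items():
        K = len(genes & uni)
        k = len(genes & mod)
        if K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "overlap": k, "pathway_size": K, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["altered"] = (out["p_bh"] < alpha) & (out["overlap"] >= min_overlap)
    return out.sort_values(["p", "pathway"])


def rollup_top_level(altered_pathways: list[str], db: PathwayDB) -> pd.DataFrame:
    """Percentage of altered pathways under each top-level pathway.

    Each altered pathway counts once toward its (unique) top-level parent;
    percentages sum to 100 whenever at least one pathway is altered. Only
    top-levels with nonzero counts are reported.
    """
    for p in altered_pathways:
        if p not in db.hierarchy:
            raise ValueError(f"altered pathway not in hierarchy: {p!r}")
    counts: dict[str, int] = {}
    for p in altered_pathways:
        top = db.hierarchy[p]
        counts[top] = counts.get(top, 0) + 1
    total = len(altered_pathways)
    rows = [
        {"top_level": top, "count": c, "percent": 100.0 * c / total}
        for top, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def summarize_modules(
    module_probe_map: dict[int, list[str]],
    annotation: pd.DataFrame,
    db: PathwayDB,
    universe: list[str] | None = None,
    alpha: float = 0.05,
    min_overlap: int = 2,
    min_altered_report: int = 10,
) -> pd.DataFrame:
    """Per-module functional roll-up.

    ``universe`` defaults to all annotated genes on the array that have a
    pathway mapping. Returns one row per module with mapped-gene coverage,
    the altered-pathway count, the dominant top-level pathway and its
    percentage, plus dominance flags at 50% and 30% and a reporting flag for
    modules with more than ``min_altered_report`` altered pathways.
    """
    if universe is None:
        all_genes, _ = map_probes_to_genes(list(annotation["probe_id"].astype(str)), annotation)
        universe = sorted(set(all_genes) & db.genes)
    rows = []
    for module, probes in sorted(module_probe_map.items()):
        genes, coverage = map_probes_to_genes(probes, annotation)
        enr = enrich_module(genes, db, universe, alpha=alpha, min_overlap=min_overlap)
        altered = list(enr.index[enr["altered"]])
        if altered:
            roll = rollup_top_level(altered, db)
            dom_top = str(roll.iloc[0]["top_level"])
            dom_pct = float(roll.iloc[0]["percent"])
        else:
            dom_top, dom_pct = "", float("nan")
        rows.append(
            {
                "module": module,
                "n_probes": len(probes),
                "n_genes_mapped": len(genes),
                "gene_coverage": coverage,
                "n_altered_pathways": len(altered),
                "dominant_top_level": dom_top,
                "dominant_percent": dom_pct,
                "dominant_gt50": bool(altered) and dom_pct > 50.0,
                "dominant_ge30": bool(altered) and dom_pct >= 30.0,
                "reportable": len(altered) > min_altered_report,
            }
        )
    return pd.DataFrame(rows).set_index("module")
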