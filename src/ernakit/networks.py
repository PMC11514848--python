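"""eRNA interactome networks.

Two complementary network types link eRNAs to protein-coding genes (PCGs):

* a **co-expression network** — Spearman rank correlation between every
  (eRNA, PCG) pair across samples, with multiple-testing control
  (Benjamini-Hochberg by default) and user thresholds on |rho| and q;
* an **eRNA-centric regulatory network** — TF/RBP peaks falling inside eRNA
  regions, and enhancer-promoter loops whose one anchor overlaps an eRNA and
  whose other anchor overlaps a gene promoter.

Networks can be intersected (shared nodes, shared unordered edges) to obtain
high-confidence interactions supported by both evidence types.

Edge tables are plain pandas DataFrames with columns
``source, target, kind, rho, p, q, evidence``; co-expression edges are stored
with lexicographically ordered endpoints so the tables are canonical for an
undirected graph (node roles record which endpoint is the eRNA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .identify import ErnaCall
from .intervals import GenomicInterval, LoopCall, overlap_length

logger = logging.getLogger("ernakit")

__all__ = [
    "EDGE_COLUMNS",
    "empty_edge_table",
    "Network",
    "spearman_edges",
    "spearman_exact_p",
    "adjust_bh",
    "adjust_pvalues",
    "build_coexpression_network",
    "coexpression_network",
    "regulatory_overlaps",
    "loop_edges",
    "intersect_networks",
]

EDGE_COLUMNS = ["source", "target", "kind", "rho", "p", "q", "evidence"]


def empty_edge_table() -> pd.DataFrame:
    return pd.DataFrame(columns=EDGE_COLUMNS)


@dataclass
class Network:
    """Undirected network: node id -> role ({erna, pcg, tf, rbp}) plus an edge table."""

    nodes: dict[str, str] = field(default_factory=dict)
    edges: pd.DataFrame = field(default_factory=empty_edge_table)

    def __post_init__(self) -> None:
        ids = set(self.nodes)
        endpoints = set(self.edges["source"]) | set(self.edges["target"])
        if not endpoints <= ids:
            raise ValueError(f"edge endpoints missing from nodes: {sorted(endpoints - ids)}")

    def edge_pairs(self) -> set[frozenset[str]]:
        return {
            frozenset((s, t))
            for s, t in zip(self.edges["source"], self.edges["target"])
        }

    def neighbors(self, node_id: str) -> set[str]:
        out: set[str] = set()
        for s, t in zip(self.edges["source"], self.edges["target"]):
            if s == node_id:
                out.add(t)
            elif t == node_id:
                out.add(s)
        return out

    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for pair in self.edge_pairs():
            for n in pair:
                deg[n] += 1
        return deg


# ---------------------------------------------------------------------------
# Spearman co-expression
# ---------------------------------------------------------------------------

def _midranks(matrix: np.ndarray) -> np.ndarray:
    return stats.rankdata(matrix, axis=1)


def spearman_edges(
    erna_expr: pd.DataFrame,
    pcg_expr: pd.DataFrame,
    p_method: str = "t",
) -> pd.DataFrame:
    """All (eRNA, PCG) Spearman correlations with two-sided p-values.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).
    ``p_method='t'`` uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 df (p = 0 at rho = +/-1); ``p_method='exact'`` enumerates the full
    permutation distribution (n <= 9 only).  Features with zero variance get
    rho = p = NaN and are excluded downstream.
    """
    if list(erna_expr.columns) != list(pcg_expr.columns):
        raise ValueError("expression matrices must share an identical ordered sample list")
    n = erna_expr.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    if p_method not in ("t", "exact"):
        raise ValueError(f"unknown p_method {p_method!r}")
    if p_method == "exact" and n > 9:
        raise ValueError("exact permutation p-values are limited to n <= 9 samples")

    ra = _midranks(erna_expr.to_numpy(dtype=float))
    rb = _midranks(pcg_expr.to_numpy(dtype=float))
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra_c**2).sum(axis=1))
    sb = np.sqrt((rb_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra_c @ rb_c.T) / np.outer(sa, sb)
    rho = np.where(np.isfinite(rho), np.clip(rho, -1.0, 1.0), np.nan)
    # snap float roundoff so perfectly monotone pairs report rho = +/-1, p = 0
    rho = np.where(np.abs(rho) >= 1.0 - 1e-13, np.sign(rho), rho)

    if p_method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
        p = np.where(np.isnan(rho), np.nan, p)
    else:
        p = np.full_like(rho, np.nan)
        for i in range(ra.shape[0]):
            for j in range(rb.shape[0]):
                if not np.isnan(rho[i, j]):
                    p[i, j] = _exact_perm_p(ra[i], rb[j])

    ernas = list(erna_expr.index)
    pcgs = list(pcg_expr.index)
    rows = {
        "source": np.repeat(ernas, len(pcgs)),
        "target": np.tile(pcgs, len(ernas)),
        "kind": "coexpr",
        "rho": rho.ravel(),
        "p": p.ravel(),
        "q": np.nan,
        "evidence": f"spearman:{p_method}",
    }
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def _rank_corr(ra: np.ndarray, rb: np.ndarray) -> float:
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = math.sqrt(float((ra_c**2).sum() * (rb_c**2).sum()))
    return float(np.dot(ra_c, rb_c)) / denom


def _exact_perm_p(ra: np.ndarray, rb: np.ndarray) -> float:
    observed = abs(_rank_corr(ra, rb))
    count = total = 0
    for perm in permutations(rb):
        total += 1
        if abs(_rank_corr(ra, np.asarray(perm))) >= observed - 1e-12:
            count += 1
    return count / total


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for the Spearman correlation of two vectors.

    Enumerates all n! orderings (n <= 9); p is the fraction of permutations
    whose |rho| is at least the observed |rho|.  At n = 4 this can differ
    noticeably from the t approximation (e.g. rho = 0.8: exact p = 1/3 while
    the t approximation gives ~0.20).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) > 9:
        raise ValueError("exact permutation p-values are limited to n <= 9")
    return _exact_perm_p(stats.rankdata(x), stats.rankdata(y))


# ---------------------------------------------------------------------------
# multiple-testing control
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Adjust p-values ('bh' step-up FDR or 'bonferroni'); NaNs propagate.

    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
        if sm_method is None:
            raise ValueError(f"unknown adjustment method {method!r}")
        q[finite] = multipletests(p[finite], method=sm_method)[1]
    return q


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (see :func:`adjust_pvalues`)."""
    return adjust_pvalues(p, method="bh")


def build_coexpression_network(
    edges: pd.DataFrame, rho_min: float = 0.3, q_max: float = 0.05
) -> Network:
    """Threshold a scored edge table into a network: |rho| >= rho_min and q <= q_max.

    Nodes are the endpoints of kept edges only; co-expression edges are
    canonicalized to source < target.  Endpoint roles are inferred from the
    original orientation (source column = eRNA, target column = PCG).
    """
    keep = (edges["rho"].abs() >= rho_min) & (edges["q"] <= q_max)
    kept = edges.loc[keep.fillna(False)].copy()
    if kept.empty:
        logger.warning("no edges pass |rho| >= %g and q <= %g", rho_min, q_max)
        return Network()
    nodes: dict[str, str] = {}
    for s, t in zip(kept["source"], kept["target"]):
        nodes.setdefault(s, "erna")
        nodes.setdefault(t, "pcg")
    flip = kept["source"] > kept["target"]
    kept.loc[flip, ["source", "target"]] = kept.loc[flip, ["target", "source"]].to_numpy()
    kept = kept.drop_duplicates(subset=["source", "target", "kind"]).reset_index(drop=True)
    return Network(nodes, kept)


def coexpression_network(
    erna_expr: pd.DataFrame,
    pcg_expr: pd.DataFrame,
    rho_min: float = 0.3,
    q_max: float = 0.05,
    adjust: str = "bh",
    adjust_scope: str = "global",
    p_method: str = "t",
) -> Network:
    """Convenience: correlate, adjust and threshold in one call.

    ``adjust_scope='global'`` adjusts across all computed pairs;
    ``'per-erna'`` adjusts each eRNA's family of PCG tests separately.
    """
    edges = spearman_edges(erna_expr, pcg_expr, p_method=p_method)
    if adjust_scope == "global":
        edges["q"] = adjust_pvalues(edges["p"], method=adjust)
    elif adjust_scope == "per-erna":
        edges["q"] = edges.groupby("source")["p"].transform(
            lambda s: adjust_pvalues(s, method=adjust)
        )
    else:
        raise ValueError(f"unknown adjust_scope {adjust_scope!r}")
    return build_coexpression_network(edges, rho_min=rho_min, q_max=q_max)


# ---------------------------------------------------------------------------
# eRNA-centric regulatory network
# ---------------------------------------------------------------------------

def regulatory_overlaps(
    ernas: list[ErnaCall],
    peak_sets: list[tuple[str, str, list[GenomicInterval]]],
) -> pd.DataFrame:
    """TF/RBP peak overlap edges: one edge per (eRNA, regulator) with >= 1 peak.

    ``peak_sets`` items are (regulator_id, kind in {tf, rbp}, peak intervals);
    evidence records the number of overlapping peaks.
    """
    rows = []
    for call in ernas:
        span = call.transcript.span
        for regulator, kind, peaks in peak_sets:
            if kind not in ("tf", "rbp"):
                raise ValueError(f"peak set kind must be 'tf' or 'rbp', got {kind!r}")
            count = sum(1 for p in peaks if overlap_length(span, p) > 0)
            if count:
                rows.append(
                    {
                        "source": call.erna_id,
                        "target": regulator,
                        "kind": kind,
                        "rho": np.nan,
                        "p": np.nan,
                        "q": np.nan,
                        "evidence": str(count),
                    }
                )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def loop_edges(
    ernas: list[ErnaCall],
    loops: list[LoopCall],
    genes: list[tuple[str, str, int]],
    promoter_flank: int = 2000,
) -> tuple[pd.DataFrame, list[tuple[str, LoopCall]]]:
    """Enhancer-promoter loop edges linking eRNAs to genes.

    ``genes`` items are (gene_id, chrom, tss position); a gene's promoter is
    ``[tss - promoter_flank, tss + promoter_flank)``.  A loop contributes an
    (eRNA, gene) edge when one anchor overlaps the eRNA span (>= 1 bp) and the
    other overlaps the promoter.  Loops that touch an eRNA without reaching
    any promoter are returned in the side list of eRNA-mediated loops.
    """
    if promoter_flank < 0:
        raise ValueError("promoter_flank must be >= 0")
    promoters = [
        (gid, GenomicInterval(chrom, max(0, tss - promoter_flank), tss + promoter_flank))
        for gid, chrom, tss in genes
    ]
    pair_counts: dict[tuple[str, str], int] = {}
    mediated: list[tuple[str, LoopCall]] = []
    for loop in loops:
        for call in ernas:
            span = call.transcript.span
            hit1 = overlap_length(span, loop.anchor1) > 0
            hit2 = overlap_length(span, loop.anchor2) > 0
            if not (hit1 or hit2):
                continue
            mediated.append((call.erna_id, loop))
            for other, hit in ((loop.anchor2, hit1), (loop.anchor1, hit2)):
                if not hit:
                    continue
                for gid, prom in promoters:
                    if overlap_length(other, prom) > 0:
                        key = (call.erna_id, gid)
                        pair_counts[key] = pair_counts.get(key, 0) + 1
    rows = [
        {
            "source": erna,
            "target": gid,
            "kind": "loop",
            "rho": np.nan,
            "p": np.nan,
            "q": np.nan,
            "evidence": str(count),
        }
        for (erna, gid), count in sorted(pair_counts.items())
    ]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS), mediated


def regulatory_network(
    ernas: list[ErnaCall],
    peak_sets: list[tuple[str, str, list[GenomicInterval]]] | None = None,
    loops: list[LoopCall] | None = None,
    genes: list[tuple[str, str, int]] | None = None,
    promoter_flank: int = 2000,
) -> Network:
    """Assemble the eRNA-centric regulatory network from peaks and loops."""
    tables = []
    kinds: dict[str, str] = {}
    if peak_sets:
        peaks = regulatory_overlaps(ernas, peak_sets)
        tables.append(peaks)
        kinds.update({rid: kind for rid, kind, _ in peak_sets})
    if loops is not None:
        loop_tab, _ = loop_edges(ernas, loops, genes or [], promoter_flank)
        tables.append(loop_tab)
    edges = (
        pd.concat(tables, ignore_index=True) if tables else empty_edge_table()
    )
    nodes: dict[str, str] = {}
    erna_ids = {c.erna_id for c in ernas}
    for s, t in zip(edges["source"], edges["target"]):
        nodes.setdefault(s, "erna" if s in erna_ids else kinds.get(s, "pcg"))
        nodes.setdefault(t, "erna" if t in erna_ids else kinds.get(t, "pcg"))
    return Network(nodes, edges)


# ---------------------------------------------------------------------------
# network intersection
# ---------------------------------------------------------------------------

def intersect_networks(a: Network, b: Network) -> Network:
    """High-confidence intersection: shared node ids and shared unordered edges.

    Edge kinds may differ between the inputs; both kinds are recorded in the
    evidence column.  An empty intersection is a valid result.
    """
    node_ids = set(a.nodes) & set(b.nodes)
    nodes = {n: a.nodes[n] for n in node_ids}

    def by_pair(net: Network) -> dict[frozenset[str], pd.Series]:
        out: dict[frozenset[str], pd.Series] = {}
        for _, row in net.edges.iterrows():
            out.setdefault(frozenset((row["source"], row["target"])), row)
        return out

    pairs_a, pairs_b = by_pair(a), by_pair(b)
    rows = []
    for pair in sorted(pairs_a.keys() & pairs_b.keys(), key=sorted):
        ra, rb = pairs_a[pair], pairs_b[pair]
        kind = ra["kind"] if ra["kind"] == rb["kind"] else "mixed"
        rows.append(
            {
                "source": ra["source"],
                "target": ra["target"],
                "kind": kind,
                "rho": ra["rho"],
                "p": ra["p"],
                "q": ra["q"],
                "evidence": f"{ra['kind']}|{rb['kind']}",
            }
        )
    return Network(nodes, pd.DataFrame(rows, columns=EDGE_COLUMNS))


def write_network(net: Network, edges_path, nodes_path=None) -> None:
    """Write the edge table (TSV) and optionally a node/role table."""
    net.edges.to_csv(edges_path, sep="\t", index=False)
    if nodes_path is not None:
        pd.DataFrame(
            sorted(net.nodes.items()), columns=["id", "role"]
        ).to_csv(nodes_path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    return edges[EDGE_COLUMNS]
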