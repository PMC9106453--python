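"""ceRNA (sponge) network inference from correlation-filtered triples.

A (circRNA, miRNA, mRNA) triple is a sponge hypothesis when five conditions
hold jointly: the circRNA and mRNA are positively correlated; the miRNA is
negatively correlated with both; and the miRNA has a predicted binding site
on both the circRNA and the mRNA.  Surviving triples are aggregated into
circRNA–mRNA pairs ranked by a ceRNA score, the top-K pairs are kept
(K = 200 by default), and a tripartite network (circ–miR sponge edges,
miR–mRNA targeting edges) is assembled for export to Cytoscape-readable
formats.

The ceRNA score of a pair is repo-defined (the source procedure names a
score without a formula): ``|shared miRNAs| × r(circ, mRNA) × mean over
shared miRNAs of |r(miR, circ)|·|r(miR, mRNA)|`` — it grows with the number
of strong shared miRNAs and vanishes when any leg is null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionBundle
from .targets import DuplexSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CeRNAConfig:
    """Thresholds for the triple filter and pair selection.

    The correlation cutoffs (|r| ≥ 0.3 at p ≤ 0.05) are the package's
    defaults for "significantly correlated"; all are config-exposed.
    ``min_sites_per_pair`` demands that many non-overlapping predicted sites
    per (miRNA, target) leg before the binding condition counts.
    """

    r_min_pos: float = 0.3
    r_max_neg: float = -0.3
    p_max: float = 0.05
    top_k: int = 200
    min_shared_mirnas: int = 1
    min_sites_per_pair: int = 1

    def __post_init__(self):
        if not (self.r_min_pos > 0 > self.r_max_neg):
            raise ValueError("require r_min_pos > 0 > r_max_neg")
        if self.r_min_pos > 1 or self.r_max_neg < -1:
            raise ValueError("correlation cutoffs must lie in [-1, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_shared_mirnas < 1 or self.min_sites_per_pair < 1:
            raise ValueError("minimum counts must be >= 1")

    @classmethod
    def planted_recovery(cls) -> "CeRNAConfig":
        """Calibration for recovering planted sponge axes from simulated data.

        Pairs it with target prediction at a 7mer-m8 minimum seed class; the
        two-site requirement matches the simulator's two planted sites per
        axis and suppresses chance single-site seed matches in random
        sequence.  Frozen once; see the methods note.
        """
        return cls(min_sites_per_pair=2)


@dataclass(frozen=True)
class LayerCorrelations:
    """Cross-layer correlation matrices (r and p) shared by the triple filter.

    ``circ_mrna`` is circ×mrna, ``mir_circ`` mir×circ, ``mir_mrna`` mir×mrna.
    Zero-variance features are excluded (logged) before computation.
    """

    circ_mrna_r: pd.DataFrame
    circ_mrna_p: pd.DataFrame
    mir_circ_r: pd.DataFrame
    mir_circ_p: pd.DataFrame
    mir_mrna_r: pd.DataFrame
    mir_mrna_p: pd.DataFrame
    n_samples: int
    method: str


def _cross_corr(X: pd.DataFrame, Y: pd.DataFrame, method: str):
    """All-pairs correlation of rows of X with rows of Y, plus two-sided p.

    Pearson r via standardised cross-products; Spearman as Pearson on
    average ranks; p from the t approximation with n−2 df (the same form
    scipy uses for these statistics).
    """
    n = X.shape[1]
    xa, ya = X.to_numpy(dtype=float), Y.to_numpy(dtype=float)
    if method == "spearman":
        xa = stats.rankdata(xa, axis=1)
        ya = stats.rankdata(ya, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    xc = xa - xa.mean(axis=1, keepdims=True)
    yc = ya - ya.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc ** 2).sum(axis=1))
    ys = np.sqrt((yc ** 2).sum(axis=1))
    r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |r| == 1 exactly
    return (pd.DataFrame(r, index=X.index, columns=Y.index),
            pd.DataFrame(p, index=X.index, columns=Y.index))


def _drop_zero_variance(df: pd.DataFrame, layer: str) -> pd.DataFrame:
    keep = df.std(axis=1, ddof=0) > 0
    if not keep.all():
        logger.warning("%s: excluding %d zero-variance feature(s)",
                       layer, int((~keep).sum()))
    return df.loc[keep]


def layer_correlations(bundle: ExpressionBundle,
                       method: str = "pearson") -> LayerCorrelations:
    """Full cross-layer correlation tables over all samples pooled."""
    n = len(bundle.design.sample_ids)
    if n < 3:
        raise ValueError("need >=3 shared samples for correlations")
    circ = _drop_zero_variance(bundle.circ, "circ")
    mir = _drop_zero_variance(bundle.mir, "mir")
    mrna = _drop_zero_variance(bundle.mrna, "mrna")
    cm_r, cm_p = _cross_corr(circ, mrna, method)
    mc_r, mc_p = _cross_corr(mir, circ, method)
    mm_r, mm_p = _cross_corr(mir, mrna, method)
    return LayerCorrelations(cm_r, cm_p, mc_r, mc_p, mm_r, mm_p, n, method)


TRIPLE_COLUMNS = ["circ_id", "mir_id", "mrna_id",
                  "r_circ_mrna", "p_circ_mrna", "r_mir_circ", "p_mir_circ",
                  "r_mir_mrna", "p_mir_mrna",
                  "n_sites_circ", "n_sites_mrna",
                  "site_score_circ", "site_score_mrna",
                  "energy_circ", "energy_mrna"]


def _site_index(sites: list[DuplexSite]):
    """Per (miRNA, target): site count, best score, summed pseudo-energy."""
    idx: dict[tuple[str, str], list[DuplexSite]] = {}
    for s in sites:
        idx.setdefault((s.mirna_id, s.target_id), []).append(s)
    return {
        k: (len(v), max(s.score for s in v), sum(s.energy_proxy for s in v))
        for k, v in idx.items()
    }


def infer_triples(corrs: LayerCorrelations, sites: list[DuplexSite],
                  cfg: CeRNAConfig = CeRNAConfig()) -> pd.DataFrame:
    """Apply the five-way sponge filter; returns one row per surviving triple.

    Conditions: r(circ, mRNA) ≥ r_min_pos with p ≤ p_max; r(miR, circ) and
    r(miR, mRNA) ≤ r_max_neg with p ≤ p_max; ≥ ``min_sites_per_pair``
    predicted sites of the miRNA on the circRNA and on the mRNA.  Output is
    sorted by (circ_id, mrna_id, mir_id).
    """
    site_idx = _site_index(sites)
    circ_ids = list(corrs.circ_mrna_r.index)
    mrna_ids = list(corrs.circ_mrna_r.columns)
    pos_ok = ((corrs.circ_mrna_r.to_numpy() >= cfg.r_min_pos)
              & (corrs.circ_mrna_p.to_numpy() <= cfg.p_max))
    rows = []
    for mir in corrs.mir_circ_r.index:
        mc_r = corrs.mir_circ_r.loc[mir]
        mc_p = corrs.mir_circ_p.loc[mir]
        mm_r = corrs.mir_mrna_r.loc[mir]
        mm_p = corrs.mir_mrna_p.loc[mir]
        circ_ok = np.array([
            (mc_r[c] <= cfg.r_max_neg) and (mc_p[c] <= cfg.p_max)
            and site_idx.get((mir, c), (0,))[0] >= cfg.min_sites_per_pair
            for c in circ_ids])
        if not circ_ok.any():
            continue
        mrna_ok = np.array([
            (mm_r[g] <= cfg.r_max_neg) and (mm_p[g] <= cfg.p_max)
            and site_idx.get((mir, g), (0,))[0] >= cfg.min_sites_per_pair
            for g in mrna_ids])
        if not mrna_ok.any():
            continue
        mask = pos_ok & np.outer(circ_ok, mrna_ok)
        for ci, gi in zip(*np.nonzero(mask)):
            c, g = circ_ids[ci], mrna_ids[gi]
            nc, sc, ec = site_idx[(mir, c)]
            ng, sg, eg = site_idx[(mir, g)]
            rows.append((c, mir, g,
                         corrs.circ_mrna_r.iat[ci, gi], corrs.circ_mrna_p.iat[ci, gi],
                         mc_r[c], mc_p[c], mm_r[g], mm_p[g],
                         nc, ng, sc, sg, ec, eg))
    df = pd.DataFrame(rows, columns=TRIPLE_COLUMNS)
    return df.sort_values(["circ_id", "mrna_id", "mir_id"]).reset_index(drop=True)


PAIR_COLUMNS = ["circ_id", "mrna_id", "r", "p", "shared_mirnas", "n_shared",
                "score", "enrichment_p", "energy"]


def score_pairs(triples: pd.DataFrame, universe_mirna_count: int,
                cfg: CeRNAConfig = CeRNAConfig()) -> pd.DataFrame:
    """Aggregate triples into scored circRNA–mRNA ceRNA pairs.

    score = |shared| × r(circ, mRNA) × mean(|r(miR, circ)|·|r(miR, mRNA)|);
    enrichment_p is the hypergeometric upper tail of the shared-miRNA overlap
    between the circRNA's and the mRNA's bound miRNA sets in a universe of
    ``universe_mirna_count`` miRNAs.
    """
    if triples.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    bound_by_circ = triples.groupby("circ_id")["mir_id"].agg(set).to_dict()
    bound_by_mrna = triples.groupby("mrna_id")["mir_id"].agg(set).to_dict()
    for name, bound in (("circ", bound_by_circ), ("mrna", bound_by_mrna)):
        worst = max(len(v) for v in bound.values())
        if universe_mirna_count < worst:
            raise ValueError(
                f"miRNA universe ({universe_mirna_count}) smaller than a "
                f"{name} bound set ({worst})")
    rows = []
    for (c, g), sub in triples.groupby(["circ_id", "mrna_id"], sort=True):
        shared = tuple(sorted(sub["mir_id"]))
        if len(shared) < cfg.min_shared_mirnas:
            continue
        r_cm = float(sub["r_circ_mrna"].iloc[0])
        p_cm = float(sub["p_circ_mrna"].iloc[0])
        legs = (sub["r_mir_circ"].abs() * sub["r_mir_mrna"].abs()).mean()
        score = len(shared) * r_cm * float(legs)
        k_circ = len(bound_by_circ[c])
        k_mrna = len(bound_by_mrna[g])
        enr = float(stats.hypergeom.sf(len(shared) - 1, universe_mirna_count,
                                       k_circ, k_mrna))
        energy = float(sub["energy_circ"].sum() + sub["energy_mrna"].sum())
        rows.append((c, g, r_cm, p_cm, ",".join(shared), len(shared),
                     score, enr, energy))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def select_top_pairs(pairs: pd.DataFrame, top_k: int = 200) -> pd.DataFrame:
    """Keep the ``top_k`` pairs by (score desc, enrichment_p asc, ids asc)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if pairs.empty:
        return pairs.copy()
    ordered = pairs.sort_values(
        by=["score", "enrichment_p", "circ_id", "mrna_id"],
        ascending=[False, True, True, True], kind="mergesort")
    return ordered.head(top_k).reset_index(drop=True)


def build_network(pairs: pd.DataFrame, triples: pd.DataFrame) -> nx.Graph:
    """Tripartite graph from the selected pairs' triples.

    Nodes carry ``kind`` ∈ {circRNA, miRNA, mRNA}; edges carry ``relation``
    (sponge for circ–miR, targets for miR–mRNA), the leg correlation ``r``
    and the best duplex ``score`` of that leg.  circ–mRNA and within-layer
    edges never appear.
    """
    net = nx.Graph()
    if pairs.empty:
        warnings.warn("empty pair selection: returning an empty network")
        return net
    selected = set(zip(pairs["circ_id"], pairs["mrna_id"]))
    sub = triples[[(c, g) in selected for c, g in
                   zip(triples["circ_id"], triples["mrna_id"])]]
    for row in sub.itertuples(index=False):
        net.add_node(row.circ_id, kind="circRNA")
        net.add_node(row.mir_id, kind="miRNA")
        net.add_node(row.mrna_id, kind="mRNA")
        net.add_edge(row.circ_id, row.mir_id, relation="sponge",
                     r=float(row.r_mir_circ), score=float(row.site_score_circ))
        net.add_edge(row.mir_id, row.mrna_id, relation="targets",
                     r=float(row.r_mir_mrna), score=float(row.site_score_mrna))
    return net


def core_circrnas(net: nx.Graph, n: int = 5) -> list[tuple[str, int]]:
    """Top-n circRNA hubs by degree (ties broken lexicographically)."""
    circs = [(node, net.degree(node)) for node, d in net.nodes(data=True)
             if d.get("kind") == "circRNA"]
    circs.sort(key=lambda t: (-t[1], t[0]))
    return circs[:n]


def export_network(net: nx.Graph, path, fmt: str) -> None:
    """Write the network as SIF, GraphML or an edge TSV (Cytoscape-readable)."""
    path = str(path)
    if fmt == "sif":
        lines = sorted(f"{u}\t{d['relation']}\t{v}"
                       for u, v, d in net.edges(data=True))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\trelation\ttarget\tr\tscore\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{d['relation']}\t{v}\t{d['r']:.6f}\t{d['score']:.6f}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(path, fmt: str) -> nx.Graph:
    """Read back an exported network (round-trip partner of export_network)."""
    path = str(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        net = nx.Graph()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                u, rel, v = line.rstrip("\n").split("\t")
                net.add_edge(u, v, relation=rel)
        return net
    raise ValueError(f"unknown import format {fmt!r}")
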