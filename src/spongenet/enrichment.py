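"""Hypergeometric over-representation of gene sets (GO/KEGG-style ORA).

Given a query gene list (e.g. circRNA target genes) and a GMT collection,
each set's overlap with the query is tested with the exact hypergeometric
upper tail P(X ≥ k), BH-adjusted across sets.  The background universe
defaults to the union of collection genes and is configurable, since the
appropriate background depends on the platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


class GMTParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes <= self.universe:
                raise ValueError(f"set {name!r} has genes outside the universe")

    @classmethod
    def from_sets(cls, sets: dict[str, set[str]],
                  universe: set[str] | None = None) -> "GeneSetCollection":
        clean = {}
        for name, genes in sets.items():
            if not genes:
                warnings.warn(f"dropping empty gene set {name!r}")
                continue
            clean[name] = frozenset(genes)
        if universe is None:
            universe = set().union(*clean.values()) if clean else set()
        else:
            clean = {n: g & frozenset(universe) for n, g in clean.items()}
            clean = {n: g for n, g in clean.items() if g}
        return cls(clean, frozenset(universe))


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes; tab-separated).

    Duplicate genes within a set are counted once; malformed lines (fewer
    than 3 fields) raise with the offending line number; an empty file
    yields an empty collection with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            name, _desc, *genes = fields
            sets[name] = {g for g in genes if g}
    if not sets:
        warnings.warn(f"empty GMT file {path}")
    return GeneSetCollection.from_sets(sets)


def write_gmt(sets: dict[str, set[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


ENRICH_COLUMNS = ["set_name", "k", "K", "n", "N", "p", "q", "fold_enrichment"]


def enrich(query, collection: GeneSetCollection,
           universe_override=None, top: int | None = None) -> pd.DataFrame:
    """Hypergeometric ORA of a query gene set against a collection.

    Query genes outside the universe are dropped with a warning; an empty
    query after restriction is an error.  Upper tail includes the observed
    overlap (P(X ≥ k)), so p ∈ (0, 1].  Rows sorted by p (then set name);
    ``top`` truncates the report (e.g. top 30 pathways).
    """
    universe = frozenset(universe_override) if universe_override is not None \
        else collection.universe
    query = set(query)
    dropped = query - universe
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside the universe dropped")
    query &= universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name] & universe
        K = len(genes)
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N) if K else 0.0
        rows.append((name, k, K, n, N, p, fe))
    df = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "q"])
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df = df[ENRICH_COLUMNS]
    df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return df.head(top) if top is not None else df
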