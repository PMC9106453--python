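"""Independent brute-force oracles used to check the implementation.

These deliberately use different algorithms from the package: memoised
recursion over the alignment space, explicit triple loops over the sponge
predicates, and exhaustive subset enumeration for the hypergeometric tail.
"""

from functools import lru_cache
from itertools import combinations

from spongenet.targets import DuplexScoring

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def oracle_duplex_score(mirna: str, window: str, sc: DuplexScoring) -> float:
    """Best local duplex score by recursive enumeration of the alignment space.

    Explores, from every start cell, all ways to extend with a substitution,
    a gap in the target, or a gap in the miRNA, stopping anywhere (local
    alignment).  Affine gaps: open for the first gap column, extend after.
    """
    rw = window[::-1]
    m, n = len(mirna), len(rw)

    def col(i: int, j: int) -> float:
        a, b = mirna[i - 1], rw[j - 1]
        if (a, b) in _WC:
            s = sc.match_wc
        elif (a, b) in _GU:
            s = sc.match_gu
        else:
            s = sc.mismatch
        if sc.seed_start <= i <= sc.seed_end:
            s *= sc.seed_weight
        return s

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: str) -> float:
        best = 0.0  # stop here
        if i < m and j < n:
            best = max(best, col(i + 1, j + 1) + ext(i + 1, j + 1, "M"))
        if i < m:
            pen = sc.gap_extend if state == "X" else sc.gap_open
            best = max(best, pen + ext(i + 1, j, "X"))
        if j < n:
            pen = sc.gap_extend if state == "Y" else sc.gap_open
            best = max(best, pen + ext(i, j + 1, "Y"))
        return best

    return max(ext(i, j, "S") for i in range(m + 1) for j in range(n + 1))


def brute_force_triples(corrs, site_pairs, cfg):
    """Triple loop applying the five sponge predicates literally.

    ``site_pairs`` maps (mir_id, target_id) -> number of predicted sites.
    Returns sorted (circ, mir, mrna) tuples.
    """
    out = []
    for circ in corrs.circ_mrna_r.index:
        for mrna in corrs.circ_mrna_r.columns:
            if not (corrs.circ_mrna_r.loc[circ, mrna] >= cfg.r_min_pos
                    and corrs.circ_mrna_p.loc[circ, mrna] <= cfg.p_max):
                continue
            for mir in corrs.mir_circ_r.index:
                if not (corrs.mir_circ_r.loc[mir, circ] <= cfg.r_max_neg
                        and corrs.mir_circ_p.loc[mir, circ] <= cfg.p_max):
                    continue
                if not (corrs.mir_mrna_r.loc[mir, mrna] <= cfg.r_max_neg
                        and corrs.mir_mrna_p.loc[mir, mrna] <= cfg.p_max):
                    continue
                if site_pairs.get((mir, circ), 0) < cfg.min_sites_per_pair:
                    continue
                if site_pairs.get((mir, mrna), 0) < cfg.min_sites_per_pair:
                    continue
                out.append((circ, mir, mrna))
    return sorted(out)


def hypergeom_upper_tail_by_enumeration(N: int, K: int, n: int, k: int,
                                        success_set=None) -> float:
    """P(X >= k) by enumerating all n-subsets of an N-element universe."""
    universe = list(range(N))
    successes = set(universe[:K]) if success_set is None else set(success_set)
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total
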