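"""miRNA target prediction: seed matching and duplex complementarity scoring.

A self-contained miRanda-style predictor: canonical seed-site scanning
(6mer / 7mer-A1 / 7mer-m8 / 8mer, no G:U inside the seed) followed by a
local antiparallel alignment of the miRNA against a target window, scoring
Watson–Crick pairs, G:U wobbles, mismatches and affine gaps, with seed
columns (miRNA positions 2–8) up-weighted.  Thermodynamic folding is out of
scope; a linear pseudo-energy maps scores onto a ΔG-like axis so that
downstream ranking by "energy" is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

#: canonical site hierarchy, weakest to strongest
SEED_TYPES = ("none", "6mer", "7mer-A1", "7mer-m8", "8mer")
_SEED_RANK = {t: i for i, t in enumerate(SEED_TYPES)}


class SequenceError(ValueError):
    """Raised for sequences outside the strict ACGU RNA alphabet."""


def validate_rna(seq: str) -> str:
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid RNA characters {sorted(bad)} (DNA? use dna_ok)")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over the RNA alphabet (A<->U, C<->G)."""
    validate_rna(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC_PAIRS


def find_seed_matches(mirna: str, target: str,
                      require: str = "6mer") -> list[tuple[int, str]]:
    """Scan a target (5'->3') for canonical seed sites of a miRNA.

    The seed is miRNA positions 2–7 (1-based, from the 5' end); a site is an
    exact Watson–Crick complement of it on the target (G:U disallowed inside
    the seed).  Classification follows the field convention:

    - 6mer: positions 2–7 paired
    - 7mer-m8: 6mer plus position 8 paired
    - 7mer-A1: 6mer plus an A on the target opposite position 1
    - 8mer: both extensions

    Returns ``(start, seed_type)`` with ``start`` the 0-based target offset of
    the full matched span, strongest classification per locus, filtered to
    classes at least as strong as ``require``.
    """
    validate_rna(mirna)
    validate_rna(target)
    if len(mirna) < 8:
        raise SequenceError("miRNA must be >= 8 nt for seed classification")
    if require not in _SEED_RANK or require == "none":
        raise ValueError(f"require must be one of {SEED_TYPES[1:]}")
    core = reverse_complement(mirna[1:7])        # matches positions 2-7
    m8_partner = _COMPLEMENT[mirna[7]]           # target base pairing position 8
    hits: list[tuple[int, str]] = []
    p = target.find(core)
    while p != -1:
        has_m8 = p >= 1 and target[p - 1] == m8_partner
        has_a1 = p + 6 < len(target) and target[p + 6] == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", p - 1
        elif has_m8:
            stype, start = "7mer-m8", p - 1
        elif has_a1:
            stype, start = "7mer-A1", p
        else:
            stype, start = "6mer", p
        if _SEED_RANK[stype] >= _SEED_RANK[require]:
            hits.append((start, stype))
        p = target.find(core, p + 1)
    return hits


def seed_site_span(start: int, seed_type: str) -> tuple[int, int]:
    """0-based half-open target span covered by a classified seed site."""
    length = {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8}[seed_type]
    return start, start + length


@dataclass(frozen=True)
class DuplexScoring:
    """Alignment parameters for miRNA:target duplex scoring.

    Defaults follow miRanda conventions: +5 Watson–Crick, +2 G:U wobble,
    −3 mismatch, affine gaps (−9 open, −4 extend), seed columns ×2, and a
    linear score→pseudo-ΔG map (kcal/mol-like units, negative slope).
    """

    match_wc: float = 5.0
    match_gu: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_weight: float = 2.0
    seed_start: int = 2   # 1-based miRNA positions weighted ...
    seed_end: int = 8     # ... inclusive
    score_threshold: float = 70.0
    energy_per_score: float = -0.25

    def __post_init__(self):
        if not (self.match_wc > self.match_gu > 0 > self.mismatch):
            raise ValueError("require match_wc > match_gu > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.seed_weight < 1:
            raise ValueError("seed_weight must be >= 1")
        if self.energy_per_score >= 0:
            raise ValueError("energy_per_score must be negative")

    def column_score(self, mirna_pos: int, a: str, b: str) -> float:
        """Score of pairing miRNA base ``a`` (1-based ``mirna_pos``) with ``b``."""
        if (a, b) in _WC_PAIRS:
            s = self.match_wc
        elif (a, b) in _GU_PAIRS:
            s = self.match_gu
        else:
            s = self.mismatch
        if self.seed_start <= mirna_pos <= self.seed_end:
            s *= self.seed_weight
        return s


@dataclass(frozen=True)
class DuplexAlignment:
    score: float
    #: substitution columns as (miRNA position 1-based, window index 0-based,
    #: original 5'->3' window orientation)
    pairs: tuple[tuple[int, int], ...]
    target_start: int
    target_end: int


def duplex_align(mirna: str, target_window: str,
                 scoring: DuplexScoring = DuplexScoring(),
                 max_window: int = 80) -> DuplexAlignment:
    """Best local alignment of a miRNA against the reverse of a target window.

    Antiparallel geometry: the miRNA 5'->3' is aligned to the window read
    3'->5', so consecutive alignment columns walk leftward on the target.
    Gotoh affine-gap local alignment; seed columns weighted per ``scoring``.
    Ties broken toward the leftmost target start, then the shortest alignment.
    """
    validate_rna(mirna)
    validate_rna(target_window)
    if max_window is not None and len(target_window) > max_window:
        raise ValueError(f"window longer than {max_window} nt")
    rw = target_window[::-1]
    m, n = len(mirna), len(rw)
    NEG = float("-inf")
    # H: best ending in substitution; X: gap in target (consumes miRNA);
    # Y: gap in miRNA (consumes target)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = (0.0, -1, -1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = scoring.column_score(i, mirna[i - 1], rw[j - 1])
            h = max(H[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0) + sub
            H[i][j] = h
            X[i][j] = max(H[i - 1][j] + scoring.gap_open,
                          X[i - 1][j] + scoring.gap_extend,
                          Y[i - 1][j] + scoring.gap_open)
            Y[i][j] = max(H[i][j - 1] + scoring.gap_open,
                          Y[i][j - 1] + scoring.gap_extend,
                          X[i][j - 1] + scoring.gap_open)
            # local alignments end on a substitution column (gaps only lose)
            if h > best[0]:
                best = (h, i, j)
            elif h == best[0] and h > 0:
                # prefer larger j (leftmost original-window start)
                if j > best[2] or (j == best[2] and i < best[1]):
                    best = (h, i, j)
    score, bi, bj = best
    if bi < 0:
        return DuplexAlignment(0.0, (), 0, 0)
    # traceback from (bi, bj) in state H; deterministic preference H > X > Y
    pairs: list[tuple[int, int]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            pairs.append((i, n - j))  # map reversed index back to window coords
            prev = (H[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            i, j = i - 1, j - 1
            if max(prev) <= 0.0:
                break  # local alignment starts here
            state = "HXY"[prev.index(max(prev))]
        elif state == "X":
            prev = (H[i - 1][j] + scoring.gap_open,
                    X[i - 1][j] + scoring.gap_extend,
                    Y[i - 1][j] + scoring.gap_open)
            state = "HXY"[prev.index(X[i][j])]
            i -= 1
        else:  # Y
            prev = (H[i][j - 1] + scoring.gap_open,
                    Y[i][j - 1] + scoring.gap_extend,
                    X[i][j - 1] + scoring.gap_open)
            state = "HYX"[prev.index(Y[i][j])]
            j -= 1
    pairs.reverse()
    tpos = [w for _, w in pairs]
    return DuplexAlignment(score, tuple(pairs), min(tpos), max(tpos) + 1)


@dataclass(frozen=True)
class DuplexSite:
    """One predicted miRNA binding site on a target sequence."""

    mirna_id: str
    target_id: str
    target_start: int  # 0-based half-open on the target, 5'->3'
    target_end: int
    score: float
    energy_proxy: float  # pseudo-ΔG, <= 0
    seed_type: str

    def __post_init__(self):
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("invalid site coordinates")
        if self.seed_type not in _SEED_RANK:
            raise ValueError(f"unknown seed type {self.seed_type!r}")


def _windows_without_seed(length: int, width: int = 60, stride: int = 30):
    start = 0
    while start < length:
        yield start, min(start + width, length)
        if start + width >= length:
            break
        start += stride


def predict_targets(mirnas: dict[str, str], targets: dict[str, str],
                    scoring: DuplexScoring = DuplexScoring(),
                    seed_required: bool = True, require: str = "6mer",
                    window_pad: int = 25) -> list[DuplexSite]:
    """Predict binding sites for every (miRNA, target) pair.

    Pipeline per pair: seed scan -> align the miRNA within ±``window_pad`` nt
    of each seed hit -> keep alignments scoring at least
    ``scoring.score_threshold``.  Overlapping sites for a pair are merged,
    keeping the best score.  With ``seed_required=False`` the whole target is
    tiled with windows instead, so every pair reports its best alignment when
    the threshold is lowered to −inf.
    """
    if not mirnas or not targets:
        raise ValueError("empty sequence set")
    sites: list[DuplexSite] = []
    for mid in sorted(mirnas):
        mseq = mirnas[mid]
        for tid in sorted(targets):
            tseq = targets[tid]
            candidates: list[DuplexSite] = []
            if seed_required:
                hits = find_seed_matches(mseq, tseq, require=require)
                spans = [(max(0, s - window_pad),
                          min(len(tseq), seed_site_span(s, st)[1] + window_pad), st)
                         for s, st in hits]
            else:
                spans = [(a, b, None) for a, b in _windows_without_seed(len(tseq))]
            for wstart, wend, stype in spans:
                aln = duplex_align(mseq, tseq[wstart:wend], scoring,
                                   max_window=None)
                if not aln.pairs or aln.score < scoring.score_threshold:
                    continue
                start, end = wstart + aln.target_start, wstart + aln.target_end
                if stype is None:
                    stypes = [st for s, st in find_seed_matches(mseq, tseq)
                              if start <= s < end]
                    stype = max(stypes, key=lambda t: _SEED_RANK[t]) if stypes else "none"
                candidates.append(DuplexSite(
                    mid, tid, start, end, aln.score,
                    scoring.energy_per_score * aln.score, stype))
            sites.extend(_merge_overlaps(candidates))
    return sites


def _merge_overlaps(candidates: list[DuplexSite]) -> list[DuplexSite]:
    """Collapse overlapping sites of one (miRNA, target) pair to the best."""
    kept: list[DuplexSite] = []
    for site in sorted(candidates, key=lambda s: (-s.score, s.target_start)):
        if all(site.target_end <= k.target_start or site.target_start >= k.target_end
               for k in kept):
            kept.append(site)
    kept.sort(key=lambda s: s.target_start)
    return kept


def sites_to_frame(sites: list[DuplexSite]):
    """Tabulate predicted sites (one row per site) for TSV export."""
    import pandas as pd
    return pd.DataFrame(
        [(s.mirna_id, s.target_id, s.target_start, s.target_end,
          s.seed_type, s.score, s.energy_proxy) for s in sites],
        columns=["mirna_id", "target_id", "start", "end",
                 "seed_type", "score", "energy_proxy"],
    )


def sites_to_bed6(sites: list[DuplexSite], path) -> None:
    """Write sites as BED6 on the target coordinates (score column = duplex
    score, strand '+': sites are reported on the target's own 5'->3' axis)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.target_id, s.target_start,
                                              s.mirna_id)):
            fh.write(f"{s.target_id}\t{s.target_start}\t{s.target_end}\t"
                     f"{s.mirna_id}\t{s.score:g}\t+\n")


def frame_to_sites(df) -> list[DuplexSite]:
    return [DuplexSite(r.mirna_id, r.target_id, int(r.start), int(r.end),
                       float(r.score), float(r.energy_proxy), r.seed_type)
            for r in df.itertuples(index=False)]
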