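"""Synthetic tri-omic data with planted ceRNA (sponge) axes.

The generator emulates a log2-intensity chipset profiling circRNA, miRNA and
mRNA in the same blood samples across injury-severity groups (control, mild,
moderate, severe).  Each planted axis (circ, miR, mRNA) encodes the sponge
model: as severity increases the circRNA rises, the *free* miRNA falls
(sequestration), and the de-repressed mRNA rises — exactly the correlation
signs the ceRNA triple filter selects on.  Sequences for planted axes carry
exact 7mer-m8 seed-complementary sites so the duplex scorer can find them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .targets import reverse_complement, validate_rna

GROUPS = ("control", "mild", "moderate", "severe")
SEVERITY_RANK = {g: i for i, g in enumerate(GROUPS)}


class DesignError(ValueError):
    """Raised for sample designs that cannot support the analysis."""


class GenerationError(ValueError):
    """Raised when a ground truth is internally inconsistent."""


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-group assignment with a severity rank per group.

    Severity rank is a function of group only (control=0 ... severe=3),
    mirroring a GCS-based stratification of injury severity.
    """

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        if len(self.sample_ids) != len(self.groups):
            raise DesignError("sample_ids and groups must be aligned")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DesignError("sample ids must be unique")
        for g in self.groups:
            if g not in SEVERITY_RANK:
                raise DesignError(f"unknown group {g!r}; expected one of {GROUPS}")
        counts = pd.Series(self.groups).value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise DesignError(
                f"every group needs >=2 samples (replicates for DE); got {bad}"
            )

    @property
    def severity_rank(self) -> np.ndarray:
        return np.array([SEVERITY_RANK[g] for g in self.groups])

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise DesignError(f"group {group!r} absent from design")
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.groups,
             "severity_rank": self.severity_rank}
        )

    def to_tsv(self, path) -> None:
        self.to_frame()[["sample_id", "group"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(df["sample_id"].astype(str)), tuple(df["group"]))


def make_design(n_per_group: int, groups=GROUPS, seed: int = 0) -> SampleDesign:
    """Balanced design: ``n_per_group`` samples in each group.

    Deterministic for fixed inputs; `seed` is accepted for interface symmetry
    with the stochastic generators but sample naming does not depend on it.
    """
    if n_per_group < 2:
        raise DesignError("n_per_group must be >= 2: DE needs replicates")
    sample_ids, labels = [], []
    for g in groups:
        if g not in SEVERITY_RANK:
            raise DesignError(f"unknown group {g!r}")
        for i in range(n_per_group):
            sample_ids.append(f"{g}_{i + 1}")
            labels.append(g)
    return SampleDesign(tuple(sample_ids), tuple(labels))


@dataclass(frozen=True)
class SpongeAxis:
    circ_id: str
    mir_id: str
    mrna_id: str
    delta: float  # log2 units added per severity-rank step (0 = null axis)


@dataclass(frozen=True)
class GroundTruth:
    """Planted sponge axes plus the noise model of the simulated chipset."""

    axes: tuple[SpongeAxis, ...]
    n_circ: int = 120
    n_mir: int = 40
    n_mrna: int = 120
    baseline_mean: float = 8.0  # log2-intensity
    noise_sd: float = 0.5       # log2 units

    def __post_init__(self):
        circs = self.circ_ids
        mirs = self.mir_ids
        mrnas = self.mrna_ids
        for ax in self.axes:
            if ax.circ_id not in circs or ax.mir_id not in mirs or ax.mrna_id not in mrnas:
                raise GenerationError(f"axis member outside feature universe: {ax}")
            if ax.delta < 0:
                raise GenerationError("axis delta must be >= 0")
        pairs = [(ax.mir_id, ax.mrna_id) for ax in self.axes]
        if len(set(pairs)) != len(pairs):
            raise GenerationError(
                "a miRNA may not appear in two axes with the same mRNA"
            )
        trip = [(ax.circ_id, ax.mir_id, ax.mrna_id) for ax in self.axes]
        if len(set(trip)) != len(trip):
            raise GenerationError("duplicate axis")

    @property
    def circ_ids(self) -> list[str]:
        return [f"circ_{i:04d}" for i in range(self.n_circ)]

    @property
    def mir_ids(self) -> list[str]:
        return [f"miR_{i:04d}" for i in range(self.n_mir)]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"mRNA_{i:04d}" for i in range(self.n_mrna)]

    @classmethod
    def random(cls, n_axes: int, n_circ: int = 120, n_mir: int = 40,
               n_mrna: int = 120, delta: float = 1.0, baseline_mean: float = 8.0,
               noise_sd: float = 0.5, seed: int = 0) -> "GroundTruth":
        """Draw ``n_axes`` disjoint sponge axes uniformly from the universe."""
        if n_axes > min(n_circ, n_mir, n_mrna):
            raise GenerationError("more axes than available features")
        rng = np.random.default_rng(seed)
        ci = rng.choice(n_circ, size=n_axes, replace=False)
        mi = rng.choice(n_mir, size=n_axes, replace=False)
        gi = rng.choice(n_mrna, size=n_axes, replace=False)
        axes = tuple(
            SpongeAxis(f"circ_{c:04d}", f"miR_{m:04d}", f"mRNA_{g:04d}", float(delta))
            for c, m, g in zip(sorted(ci), sorted(mi), sorted(gi))
        )
        return cls(axes, n_circ=n_circ, n_mir=n_mir, n_mrna=n_mrna,
                   baseline_mean=baseline_mean, noise_sd=noise_sd)

    def to_json(self, path) -> None:
        obj = {
            "n_circ": self.n_circ, "n_mir": self.n_mir, "n_mrna": self.n_mrna,
            "baseline_mean": self.baseline_mean, "noise_sd": self.noise_sd,
            "axes": [
                {"circ_id": a.circ_id, "mir_id": a.mir_id,
                 "mrna_id": a.mrna_id, "delta": a.delta}
                for a in self.axes
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        axes = tuple(SpongeAxis(a["circ_id"], a["mir_id"], a["mrna_id"],
                                float(a["delta"])) for a in obj["axes"])
        return cls(axes, n_circ=obj["n_circ"], n_mir=obj["n_mir"],
                   n_mrna=obj["n_mrna"], baseline_mean=obj["baseline_mean"],
                   noise_sd=obj["noise_sd"])


@dataclass
class ExpressionBundle:
    """Three feature×sample log2 matrices sharing one sample axis."""

    circ: pd.DataFrame
    mir: pd.DataFrame
    mrna: pd.DataFrame
    design: SampleDesign = field(repr=False)

    def __post_init__(self):
        cols = list(self.design.sample_ids)
        for name, df in (("circ", self.circ), ("mir", self.mir), ("mrna", self.mrna)):
            if list(df.columns) != cols:
                raise GenerationError(f"{name} columns must equal design samples in order")
            if df.index.duplicated().any():
                raise GenerationError(f"duplicate feature ids in {name} layer")
            if not np.isfinite(df.to_numpy()).all():
                raise GenerationError(f"non-finite values in {name} layer")

    def to_tsv_dir(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (("circ", self.circ), ("mir", self.mir), ("mrna", self.mrna)):
            df.to_csv(outdir / f"{name}_expression.tsv", sep="\t",
                      index_label="feature_id", float_format="%.6f")
        self.design.to_tsv(outdir / "design.tsv")

    @classmethod
    def from_tsv_dir(cls, indir) -> "ExpressionBundle":
        from pathlib import Path
        indir = Path(indir)
        design = SampleDesign.from_tsv(indir / "design.tsv")
        mats = {
            name: pd.read_csv(indir / f"{name}_expression.tsv", sep="\t",
                              index_col="feature_id")
            for name in ("circ", "mir", "mrna")
        }
        return cls(mats["circ"], mats["mir"], mats["mrna"], design)


def simulate_bundle(truth: GroundTruth, design: SampleDesign, seed: int = 0) -> ExpressionBundle:
    """Draw a tri-omic bundle from the planted-axis generative model.

    Non-axis features are i.i.d. Normal(baseline_mean, noise_sd) on the log2
    scale.  For each axis with effect ``delta``, the per-sample mean shifts by
    ``delta * severity_rank``: +, −, + for circRNA, free miRNA and mRNA.
    Independent RNG streams per layer are split from the single seed.
    """
    ranks = design.severity_rank.astype(float)
    n = len(ranks)
    streams = np.random.SeedSequence(seed).spawn(3)
    layers = {}
    specs = (
        ("circ", truth.circ_ids, truth.n_circ, {a.circ_id: +a.delta for a in truth.axes}),
        ("mir", truth.mir_ids, truth.n_mir, {a.mir_id: -a.delta for a in truth.axes}),
        ("mrna", truth.mrna_ids, truth.n_mrna, {a.mrna_id: +a.delta for a in truth.axes}),
    )
    for (name, ids, nfeat, effects), ss in zip(specs, streams):
        rng = np.random.default_rng(ss)
        mat = rng.normal(truth.baseline_mean, truth.noise_sd, size=(nfeat, n))
        for fid, eff in effects.items():
            mat[ids.index(fid)] += eff * ranks
        layers[name] = pd.DataFrame(mat, index=ids, columns=list(design.sample_ids))
    return ExpressionBundle(layers["circ"], layers["mir"], layers["mrna"], design)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def simulate_sequences(truth: GroundTruth, site_per_axis: int = 2,
                       length_target: int = 300, mirna_length: int = 22,
                       seed: int = 0) -> dict[str, dict[str, str]]:
    """RNA sequences for every feature, with planted seed sites on axis targets.

    Returns ``{"mir": {...}, "circ": {...}, "mrna": {...}}``.  Each planted
    axis's circRNA and mRNA carries ``site_per_axis`` non-overlapping exact
    complements of the axis miRNA's 7mer-m8 seed (miRNA positions 2-8).
    Non-axis sequences are uniform random with no engineered sites.
    Byte-identical output for a fixed seed.
    """
    if length_target < 30:
        raise GenerationError("length_target must be >= 30")
    if mirna_length < 8:
        raise GenerationError("mirna_length must be >= 8")
    # planted sites are spaced >= 60 nt apart so each stays a distinct,
    # independently detectable locus (alignment windows never bridge two)
    spacing = 60 if length_target >= 60 * site_per_axis else 7
    if (site_per_axis - 1) * spacing + 7 > length_target:
        raise GenerationError("site_per_axis does not fit in length_target")
    rng = np.random.default_rng(seed)
    mirs = {fid: _random_rna(rng, mirna_length) for fid in truth.mir_ids}
    circs = {fid: _random_rna(rng, length_target) for fid in truth.circ_ids}
    mrnas = {fid: _random_rna(rng, length_target) for fid in truth.mrna_ids}
    for ax in truth.axes:
        site = reverse_complement(mirs[ax.mir_id][1:8])  # 7mer-m8 complement
        for pool, fid in ((circs, ax.circ_id), (mrnas, ax.mrna_id)):
            seq = list(pool[fid])
            # sample starts with guaranteed pairwise spacing: draw sorted
            # offsets into the slack left after reserving the spacing gaps
            slack = length_target - 7 - (site_per_axis - 1) * spacing
            offsets = np.sort(rng.integers(0, slack + 1, size=site_per_axis))
            starts = [int(u + i * spacing) for i, u in enumerate(offsets)]
            for p in starts:
                seq[p:p + 7] = site
            pool[fid] = "".join(seq)
    for pool in (mirs, circs, mrnas):
        for s in pool.values():
            validate_rna(s)
    return {"mir": mirs, "circ": circs, "mrna": mrnas}


def write_fasta(records: dict[str, str], path) -> None:
    """Write a SequenceSet as FASTA (U alphabet), ids in insertion order."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path, dna_ok: bool = False) -> dict[str, str]:
    """Read FASTA into an id→RNA dict; rejects T unless ``dna_ok`` converts it."""
    from Bio.SeqIO import parse
    out: dict[str, str] = {}
    for rec in parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if "T" in s:
            if not dna_ok:
                raise ValueError(
                    f"{rec.id}: DNA alphabet (T) found; pass dna_ok=True to convert"
                )
            s = s.replace("T", "U")
        validate_rna(s)
        out[rec.id] = s
    return out


# --- immune-mixture simulation -------------------------------------------------

@dataclass(frozen=True)
class SignatureMatrix:
    """Reference expression of marker genes (rows) per immune cell type (cols)."""

    data: pd.DataFrame

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature expression must be non-negative")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("signature has an all-zero cell-type column")
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            import warnings
            warnings.warn("signature matrix is column-rank deficient; "
                          "fractions may not be identifiable")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


DEFAULT_CELL_TYPES = ("NK", "T_CD4", "T_CD8", "B", "Monocyte", "Neutrophil")


def make_signature(n_genes: int = 120, cell_types=DEFAULT_CELL_TYPES,
                   marker_high: float = 50.0, background: float = 2.0,
                   seed: int = 0) -> SignatureMatrix:
    """Block-marker signature: each cell type gets an exclusive marker block.

    Genes are split evenly across cell types; a marker gene expresses at
    ``marker_high`` (lognormal-jittered) in its own type and near
    ``background`` elsewhere, giving a well-conditioned deconvolution basis.
    """
    k = len(cell_types)
    if n_genes < 10 * 1:
        raise ValueError("need at least 10 genes for a usable signature")
    rng = np.random.default_rng(seed)
    mat = background * rng.lognormal(0.0, 0.3, size=(n_genes, k))
    block = n_genes // k
    for j in range(k):
        rows = slice(j * block, (j + 1) * block if j < k - 1 else n_genes)
        mat[rows, j] = marker_high * rng.lognormal(0.0, 0.2, size=mat[rows, j].shape)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    return SignatureMatrix(pd.DataFrame(mat, index=genes, columns=list(cell_types)))


def simulate_mixture(signature: SignatureMatrix, fractions, noise_sd: float,
                     seed: int = 0) -> pd.Series:
    """Bulk profile = signature @ fractions + Normal(0, noise_sd) per gene."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 1 or len(fractions) != len(signature.cell_types):
        raise ValueError("fractions must be a vector over the signature cell types")
    if (fractions < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1 within 1e-8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    bulk = signature.data.to_numpy() @ fractions
    bulk = bulk + rng.normal(0.0, noise_sd, size=len(bulk))
    return pd.Series(bulk, index=signature.genes)


def group_fractions(design: SampleDesign, cell_types=DEFAULT_CELL_TYPES,
                    nk_cell: str = "NK", nk_base: float = 0.25,
                    nk_drop_per_rank: float = 0.05, jitter_sd: float = 0.02,
                    seed: int = 0) -> pd.DataFrame:
    """Per-sample true fractions with NK declining as severity rises.

    Emulates the clinical observation that circulating NK-cell share falls
    with injury severity; the remaining mass is spread over the other types.
    """
    if nk_cell not in cell_types:
        raise ValueError(f"{nk_cell!r} not in cell_types")
    rng = np.random.default_rng(seed)
    rows = []
    others = [c for c in cell_types if c != nk_cell]
    for sid, rank in zip(design.sample_ids, design.severity_rank):
        nk = nk_base - nk_drop_per_rank * rank
        nk = max(nk + rng.normal(0.0, jitter_sd), 0.01)
        rest = np.abs(rng.normal(1.0, 0.15, size=len(others)))
        rest = (1.0 - nk) * rest / rest.sum()
        frac = {nk_cell: nk, **dict(zip(others, rest))}
        rows.append([frac[c] for c in cell_types])
    df = pd.DataFrame(rows, index=list(design.sample_ids), columns=list(cell_types))
    return df.div(df.sum(axis=1), axis=0)
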