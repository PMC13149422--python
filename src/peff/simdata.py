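"""Synthetic inputs for the whole pipeline, with analytic ground truth.

The generator emulates the study design end to end: a toy reference
genome with annotated genes, a panel of accessions segregating for
planted presence/absence (PAV) alleles plus private background SNPs,
GBS-like single-end reads with i.i.d. substitution errors, phenotypes
driven by a k-mer fixed effect plus a kinship-structured polygenic term,
and binary rhizotron root masks whose length/extent/hull geometry is
known in closed form.

Presence/absence alleles are modelled as segments that are part of the
reference sequence and *deleted* in non-carrier accessions.  Carriers
therefore share a block of diagnostic k-mers with the reference, so a
fragment assembled from those k-mers maps exactly back to the planted
locus — mirroring how a real pangenome-style presence/absence variant
whose allele happens to be represented in the reference assembly would
behave.  (The deletion haplotype additionally gains a handful of novel
junction k-mers, which associate with the opposite sign and map
nowhere, as unplaced loci do in practice.)

Accessions are simulated as single haplotypes by default; real genebank
accessions are population mixtures, and a two-haplotype pooling hook
(``pool_pairs``) is provided for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from shapely.ops import unary_union

from . import io as _io
from .kmers import (
    DEFAULT_K,
    codes_to_kmers,
    decode_codes,
    encode_sequence,
    sequence_kmer_codes,
)

log = logging.getLogger(__name__)

MM_PER_INCH = 25.4


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Toy reference: contig sequences plus non-overlapping gene intervals.

    Coordinates are 1-based inclusive (GFF3 convention).
    """

    contigs: list[tuple[str, str]]
    genes: pd.DataFrame  # gene_id, contig, start, end, strand

    def __post_init__(self) -> None:
        lengths = self.contig_lengths()
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        for row in self.genes.itertuples(index=False):
            if row.start > row.end:
                raise ValueError(f"gene {row.gene_id}: start > end")
            if row.contig not in lengths or row.end > lengths[row.contig] or row.start < 1:
                raise ValueError(f"gene {row.gene_id} outside its contig")

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs}

    def sequence(self, contig: str) -> str:
        for name, seq in self.contigs:
            if name == contig:
                return seq
        raise KeyError(contig)

    def codes(self, contig: str) -> np.ndarray:
        return encode_sequence(self.sequence(contig))

    def write_fasta(self, path) -> None:
        _io.write_fasta(dict(self.contigs), path)

    def write_gff3(self, path) -> None:
        _io.write_gff3(self.genes, path)


def generate_reference(
    n_contigs: int,
    contig_length: int,
    n_genes: int,
    gene_length: int,
    seed: int,
) -> ReferenceGenome:
    """Uniform-random reference with non-overlapping gene intervals.

    Genes are distributed as evenly as possible across contigs; raises
    if they cannot be packed without overlap.
    """
    if n_contigs < 1 or contig_length < 1:
        raise ValueError("need at least one contig of positive length")
    if n_genes * gene_length > n_contigs * contig_length:
        raise ValueError(
            f"cannot pack {n_genes} genes × {gene_length} bp into "
            f"{n_contigs} × {contig_length} bp"
        )
    per_contig = [n_genes // n_contigs + (1 if i < n_genes % n_contigs else 0)
                  for i in range(n_contigs)]
    if any(g * gene_length > contig_length for g in per_contig):
        raise ValueError("cannot pack genes without overlap under even distribution")

    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    rows = []
    gene_no = 0
    for ci in range(n_contigs):
        name = f"contig{ci + 1}"
        seq = decode_codes(rng.integers(0, 4, size=contig_length).astype(np.uint8))
        contigs.append((name, seq))
        g = per_contig[ci]
        if g:
            slack = contig_length - g * gene_length
            gaps = np.sort(rng.integers(0, slack + 1, size=g))
            for j in range(g):
                start = int(gaps[j]) + j * gene_length + 1
                rows.append({
                    "gene_id": f"gene{gene_no + 1:04d}",
                    "contig": name,
                    "start": start,
                    "end": start + gene_length - 1,
                    "strand": rng.choice(["+", "-"]),
                })
                gene_no += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end", "strand"])
    return ReferenceGenome(contigs, genes)


# ---------------------------------------------------------------------------
# population with planted presence/absence alleles
# ---------------------------------------------------------------------------

@dataclass
class CausalLocus:
    """A presence/absence segment of the reference.

    Carriers retain ``length`` reference bases starting at ``start``
    (1-based); non-carriers have them deleted.  ``beta`` is the
    phenotype effect of carrying the presence allele.
    """

    contig: str
    start: int
    length: int
    freq: float
    beta: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.freq <= 1.0:
            raise ValueError("presence frequency must lie in (0, 1]")
        if self.length < 1:
            raise ValueError("segment length must be positive")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class PopulationSpec:
    n_accessions: int
    causal_loci: list[CausalLocus]
    snp_rate: float = 0.0
    seed: int = 0
    pool_pairs: bool = False

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("need at least one accession")
        if not 0.0 <= self.snp_rate <= 0.05:
            raise ValueError("snp_rate outside plausible range [0, 0.05]")


@dataclass
class Population:
    spec: PopulationSpec
    accessions: list[str]
    haplotypes: dict[str, list[dict[str, np.ndarray]]]  # acc -> haplotype(s) -> contig codes
    truth: pd.DataFrame  # accessions × loci carriage (0/1)

    def haplotype_length(self, accession: str) -> int:
        return sum(c.size for c in self.haplotypes[accession][0].values())

    def sequences(self, accession: str) -> dict[str, str]:
        return {name: decode_codes(codes)
                for name, codes in self.haplotypes[accession][0].items()}


def _validate_loci(ref: ReferenceGenome, loci: Sequence[CausalLocus], k: int) -> None:
    lengths = ref.contig_lengths()
    by_contig: dict[str, list[CausalLocus]] = {}
    for loc in loci:
        if loc.contig not in lengths:
            raise ValueError(f"locus on unknown contig {loc.contig}")
        if loc.start < 1 or loc.end > lengths[loc.contig]:
            raise ValueError(f"locus {loc.name or loc.start} outside contig")
        by_contig.setdefault(loc.contig, []).append(loc)
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda l: l.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping causal loci on {contig}")


def simulate_population(ref: ReferenceGenome, spec: PopulationSpec, k: int = DEFAULT_K) -> Population:
    """Draw carriage Bernoulli(freq) per locus and build accession haplotypes.

    Each haplotype is the reference with non-carried segments deleted
    and private SNPs applied at ``snp_rate`` per base.
    """
    _validate_loci(ref, spec.causal_loci, k)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_accessions
    accessions = [f"acc{i + 1:04d}" for i in range(n)]
    loci = list(spec.causal_loci)
    for i, loc in enumerate(loci):
        if not loc.name:
            loc.name = f"locus{i + 1:02d}"

    carriage = np.zeros((n, len(loci)), dtype=np.int8)
    for j, loc in enumerate(loci):
        carriage[:, j] = (rng.random(n) < loc.freq) if loc.freq < 1.0 else 1

    ref_codes = {name: encode_sequence(seq) for name, seq in ref.contigs}
    n_haps = 2 if spec.pool_pairs else 1
    haplotypes: dict[str, list[dict[str, np.ndarray]]] = {}
    for i, acc in enumerate(accessions):
        haps = []
        for _ in range(n_haps):
            contigs: dict[str, np.ndarray] = {}
            for name, base in ref_codes.items():
                codes = base.copy()
                if spec.snp_rate > 0:
                    pos = np.flatnonzero(rng.random(codes.size) < spec.snp_rate)
                    if pos.size:
                        codes[pos] = (codes[pos] + rng.integers(1, 4, size=pos.size)) % 4
                drop = np.zeros(codes.size, dtype=bool)
                for j, loc in enumerate(loci):
                    if loc.contig == name and carriage[i, j] == 0:
                        drop[loc.start - 1:loc.end] = True
                contigs[name] = codes[~drop] if drop.any() else codes
            haps.append(contigs)
        haplotypes[acc] = haps

    truth = pd.DataFrame(carriage, index=accessions, columns=[l.name for l in loci])
    truth.index.name = "accession"
    return Population(spec, accessions, haplotypes, truth)


def diagnostic_kmers(ref: ReferenceGenome, locus: CausalLocus, k: int = DEFAULT_K) -> set[str]:
    """Canonical k-mers diagnostic for the presence allele of ``locus``.

    These are the k-mers overlapping the segment that occur exactly once
    in the reference and are absent from the deletion haplotype — the
    markers whose presence pattern equals the carriage column.
    """
    contig = ref.codes(locus.contig)
    s0 = locus.start - 1
    region = contig[max(0, s0 - k + 1): min(contig.size, s0 + locus.length + k - 1)]
    region_codes, _ = sequence_kmer_codes(region, k)

    all_codes = []
    for name, _seq in ref.contigs:
        c, _ = sequence_kmer_codes(ref.codes(name), k)
        all_codes.append(c)
    ref_all = np.concatenate(all_codes)
    uniq, counts = np.unique(ref_all, return_counts=True)
    once = set(uniq[counts == 1].tolist())

    deleted = np.concatenate([contig[:s0], contig[s0 + locus.length:]])
    del_codes, _ = sequence_kmer_codes(deleted, k)
    del_set = set(np.unique(del_codes).tolist())

    diag = [c for c in np.unique(region_codes).tolist() if c in once and c not in del_set]
    return set(codes_to_kmers(np.array(diag, dtype=np.uint64), k))


# ---------------------------------------------------------------------------
# GBS-like reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < DEFAULT_K:
            raise ValueError(f"read_length must be >= k = {DEFAULT_K}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")


@dataclass
class ReadSet:
    """Fixed-length single-end reads as a 2-D base-code array."""

    codes: np.ndarray  # (n_reads, read_length) uint8

    def __len__(self) -> int:
        return self.codes.shape[0]

    def sequences(self) -> list[str]:
        return [decode_codes(row) for row in self.codes]

    def to_fastq(self, path, prefix: str = "read") -> None:
        _io.write_fastq(self.sequences(), path, prefix=prefix)


def _reads_from_haplotype(
    hap: Mapping[str, np.ndarray], params: ReadSimParams, rng: np.random.Generator,
    coverage: float,
) -> np.ndarray:
    L = params.read_length
    blocks = []
    for codes in hap.values():
        if codes.size < L:
            raise ValueError("read_length exceeds haplotype contig length")
        n_reads = int(round(coverage * codes.size / L))
        if n_reads == 0:
            continue
        starts = rng.integers(0, codes.size - L + 1, size=n_reads)
        reads = codes[starts[:, None] + np.arange(L)]
        flip = rng.random(n_reads) < 0.5
        reads[flip] = 3 - reads[flip, ::-1]
        if params.error_rate > 0:
            err = rng.random(reads.shape) < params.error_rate
            n_err = int(err.sum())
            if n_err:
                reads[err] = (reads[err] + rng.integers(1, 4, size=n_err)) % 4
        blocks.append(reads)
    return np.concatenate(blocks) if blocks else np.empty((0, L), dtype=np.uint8)


def simulate_reads_for_accession(
    population: Population, accession: str, params: ReadSimParams,
    rng: np.random.Generator,
) -> ReadSet:
    haps = population.haplotypes[accession]
    cov = params.coverage / len(haps)
    blocks = [_reads_from_haplotype(h, params, rng, cov) for h in haps]
    return ReadSet(np.concatenate(blocks))


def iter_gbs_reads(
    population: Population, params: ReadSimParams
) -> Iterator[tuple[str, ReadSet]]:
    """Yield (accession, reads); per-accession streams are independently
    seeded children of ``params.seed`` so iteration order is immaterial."""
    children = np.random.SeedSequence(params.seed).spawn(len(population.accessions))
    for acc, child in zip(population.accessions, children):
        yield acc, simulate_reads_for_accession(
            population, acc, params, np.random.default_rng(child)
        )


def simulate_gbs_reads(
    population: Population, params: ReadSimParams
) -> dict[str, ReadSet]:
    """Materialise all read sets (convenience for small simulations)."""
    return dict(iter_gbs_reads(population, params))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenoSimParams:
    """Generative twin of the association model.

    Accession value = μ + Σ β·carriage + g with g ~ N(0, σ²_g·K); each
    replicate observation adds the LP treatment shift (if any) and
    i.i.d. N(0, σ²_e) noise.
    """

    mu: float = 4.82
    betas: Sequence[float] = ()
    sigma_g2: float = 0.5
    sigma_e2: float = 1.0
    treatment_effect: float = -1.14
    n_replicates: int = 3
    seed: int = 0
    trait: str = "SDM"
    treatments: Sequence[str] = ("HP", "LP")
    clip_at: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _check_psd(K: np.ndarray) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    w = np.linalg.eigvalsh(K)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -1e-8 * scale:
        raise ValueError("kinship is not positive semi-definite")
    return K


def simulate_phenotypes(
    truth: pd.DataFrame,
    kinship: np.ndarray,
    params: PhenoSimParams,
) -> pd.DataFrame:
    """Long-format phenotype table (accession, treatment, replicate, trait, value)."""
    n = len(truth)
    K = _check_psd(kinship)
    if K.shape[0] != n:
        raise ValueError("kinship dimension does not match accessions")
    betas = np.asarray(params.betas, dtype=float)
    if betas.size != truth.shape[1]:
        raise ValueError("need one beta per causal locus column")
    rng = np.random.default_rng(params.seed)

    genetic = np.zeros(n)
    if params.sigma_g2 > 0:
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        genetic = V @ (np.sqrt(w) * rng.standard_normal(n)) * np.sqrt(params.sigma_g2)
    base = params.mu + truth.to_numpy(dtype=float) @ betas + genetic

    rows = []
    sd_e = np.sqrt(params.sigma_e2)
    for treatment in params.treatments:
        shift = params.treatment_effect if treatment == "LP" else 0.0
        for rep in range(1, params.n_replicates + 1):
            values = base + shift + (rng.standard_normal(n) * sd_e if sd_e > 0 else 0.0)
            if params.clip_at is not None:
                values = np.maximum(values, params.clip_at)
            for acc, val in zip(truth.index, values):
                rows.append((acc, treatment, rep, params.trait, float(val)))
    return pd.DataFrame(
        rows, columns=["accession", "treatment", "replicate", "trait", "value"]
    )


def simulate_pa_matrix(
    n_samples: int,
    n_kmers: int,
    seed: int,
    freq_range: tuple[float, float] = (0.05, 0.95),
    k: int = DEFAULT_K,
):
    """Random unlinked presence/absence marker panel (for calibration work).

    Column frequencies are uniform on ``freq_range``; monomorphic draws
    are redrawn so every column is testable.
    """
    from .kmers import KmerMatrix, canonicalize

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_kmers)
    presence = (rng.random((n_samples, n_kmers)) < freqs).astype(np.uint8)
    for j in range(n_kmers):
        while presence[:, j].min() == presence[:, j].max():
            presence[:, j] = (rng.random(n_samples) < freqs[j]).astype(np.uint8)

    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < n_kmers:
        km = decode_codes(rng.integers(0, 4, size=k).astype(np.uint8))
        canon = canonicalize(km)
        if canon not in seen:
            seen.add(canon)
            labels.append(canon)
    order = np.argsort(np.array(labels))
    cols = [labels[i] for i in order]
    presence = presence[:, order]
    samples = [f"acc{i + 1:04d}" for i in range(n_samples)]
    return KmerMatrix(cols, samples, presence)


# ---------------------------------------------------------------------------
# root masks
# ---------------------------------------------------------------------------

@dataclass
class RootMaskTruth:
    """Closed-form geometry of a rendered mask, in mm at the given dpi."""

    length_mm: float
    area_mm2: float
    rooting_width_mm: float
    rooting_depth_mm: float
    hull_area_mm2: float
    hull_width_mm: float
    hull_height_mm: float


def render_root_mask(
    segments: Sequence[tuple[float, float, float, float, float]],
    shape: tuple[int, int],
    dpi: float = 600.0,
) -> tuple[np.ndarray, RootMaskTruth]:
    """Rasterise stroked segments and return the mask with analytic truth.

    ``segments`` are (x0, y0, x1, y1, width_px) in pixel coordinates
    (x = column, y = row, pixel centres at integers).  Strokes are
    capsules (round caps): a pixel is foreground when its centre lies
    within width/2 of the segment.  Truth geometry comes from the exact
    union of the capsules: total length is the sum of segment lengths,
    extents are the union bounding box, and hull area is the convex
    hull of the union, all scaled by 25.4/dpi.
    """
    if dpi <= 0:
        raise ValueError("dpi must be positive")
    H, W = shape
    if not segments:
        raise ValueError("need at least one segment")
    geoms = []
    total_len_px = 0.0
    for x0, y0, x1, y1, width in segments:
        if width <= 0:
            raise ValueError("zero-width segment")
        r = width / 2.0
        for x, y in ((x0, y0), (x1, y1)):
            if not (-0.5 + r <= x <= W - 0.5 - r and -0.5 + r <= y <= H - 0.5 - r):
                raise ValueError("segment stroke extends outside the canvas")
        total_len_px += float(np.hypot(x1 - x0, y1 - y0))
        geoms.append(LineString([(x0, y0), (x1, y1)]).buffer(r, quad_segs=64))

    mask = np.zeros((H, W), dtype=bool)
    for (x0, y0, x1, y1, width) in segments:
        r = width / 2.0
        cmin = max(int(np.floor(min(x0, x1) - r - 1)), 0)
        cmax = min(int(np.ceil(max(x0, x1) + r + 1)), W - 1)
        rmin = max(int(np.floor(min(y0, y1) - r - 1)), 0)
        rmax = min(int(np.ceil(max(y0, y1) + r + 1)), H - 1)
        ys, xs = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
        dx, dy = x1 - x0, y1 - y0
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            dist2 = (xs - x0) ** 2 + (ys - y0) ** 2
        else:
            t = np.clip(((xs - x0) * dx + (ys - y0) * dy) / seg2, 0.0, 1.0)
            dist2 = (xs - (x0 + t * dx)) ** 2 + (ys - (y0 + t * dy)) ** 2
        mask[rmin:rmax + 1, cmin:cmax + 1] |= dist2 <= r * r

    union = unary_union(geoms)
    hull = union.convex_hull
    s = MM_PER_INCH / dpi
    minx, miny, maxx, maxy = union.bounds
    hminx, hminy, hmaxx, hmaxy = hull.bounds
    truth = RootMaskTruth(
        length_mm=total_len_px * s,
        area_mm2=union.area * s * s,
        rooting_width_mm=(maxx - minx) * s,
        rooting_depth_mm=(maxy - miny) * s,
        hull_area_mm2=hull.area * s * s,
        hull_width_mm=(hmaxx - hminx) * s,
        hull_height_mm=(hmaxy - hminy) * s,
    )
    return mask, truth
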