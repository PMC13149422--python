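"""Canonical k-mer counting and presence/absence genotype matrices.

Reads are decomposed into overlapping k-mers (k = 31 by default, odd k
only so no k-mer equals its own reverse complement).  Each k-mer is
collapsed with its reverse complement onto the lexicographically smaller
*canonical* form so that both strands count as one marker.  Per sample,
canonical k-mers with a total count below a floor (default 5) are
discarded; the retained sets from all samples are combined into a binary
presence/absence matrix, which after minor-allele-frequency filtering is
the genotype matrix of the association analysis.

Internally k-mers are packed 2 bits/base into uint64 codes.  Because the
alphabet is ordered A < C < G < T, numeric order of codes equals
lexicographic order of the strings, so canonicalisation and sorting can
stay in integer space; strings are only materialised at the API surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_K = 31
DEFAULT_MIN_COUNT = 5

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENTINEL = np.array([4], dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0123 as uint8; any other character becomes the sentinel 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def canonicalize(kmer: str, k: int | None = None) -> str:
    """Return the lexicographic minimum of a k-mer and its reverse complement.

    Idempotent.  Raises on ambiguous bases (k-mers containing N are
    skipped upstream during counting; they are a hard error here).
    """
    if k is not None and len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got length {len(kmer)}")
    if any(c not in "ACGTacgt" for c in kmer):
        raise ValueError(f"k-mer contains a non-ACGT base: {kmer!r}")
    kmer = kmer.upper()
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def kmer_to_code(kmer: str) -> int:
    codes = encode_sequence(kmer)
    if (codes >= 4).any():
        raise ValueError(f"k-mer contains a non-ACGT base: {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def codes_to_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Vectorised decode of packed k-mer codes to strings."""
    if len(codes) == 0:
        return []
    c = np.asarray(codes, dtype=np.uint64).copy()
    idx = np.empty((len(c), k), dtype=np.uint8)
    for j in range(k - 1, -1, -1):
        idx[:, j] = (c & np.uint64(3)).astype(np.uint8)
        c >>= np.uint64(2)
    raw = _BASES[idx].view(f"S{k}").ravel()
    return [b.decode() for b in raw]


def _check_k(k: int) -> None:
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k > 31:
        raise ValueError("k > 31 does not fit a 2-bit packed uint64 code")


def _window_codes_1d(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement codes of every valid window.

    ``b`` is a uint8 base-code array (sentinel 4 separates reads /
    marks ambiguous bases); windows containing a sentinel are dropped.
    """
    n = b.size
    if n < k:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty
    m = n - k + 1
    two_bit = (b & np.uint8(3)).astype(np.uint64)
    comp = (np.uint8(3) - (b & np.uint8(3))).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd += two_bit[j:j + m] << np.uint64(2 * (k - 1 - j))
        rc += comp[j:j + m] << np.uint64(2 * j)
    bad = np.concatenate(([0], np.cumsum((b >= 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd[valid], rc[valid]


def _window_codes_2d(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling-hash window codes for fixed-length reads (rows of ``b``)."""
    n, L = b.shape
    if L < k or n == 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty
    m = L - k + 1
    bc = (b & np.uint8(3)).astype(np.uint64)
    comp = np.uint64(3) - bc
    mask = np.uint64((1 << (2 * k)) - 1)
    two = np.uint64(2)
    top = np.uint64(2 * (k - 1))
    fwd = np.empty((n, m), dtype=np.uint64)
    rc = np.empty((n, m), dtype=np.uint64)
    f = np.zeros(n, dtype=np.uint64)
    r = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        f = ((f << two) | bc[:, j]) & mask
        r |= comp[:, j] << np.uint64(2 * j)
    fwd[:, 0] = f
    rc[:, 0] = r
    for i in range(1, m):
        f = ((f << two) | bc[:, i + k - 1]) & mask
        r = (r >> two) | (comp[:, i + k - 1] << top)
        fwd[:, i] = f
        rc[:, i] = r
    bad = np.zeros((n, L + 1), dtype=np.int16)
    np.cumsum(b >= 4, axis=1, out=bad[:, 1:])
    valid = (bad[:, k:] - bad[:, :-k]) == 0
    return fwd[valid], rc[valid]


def sequence_kmer_codes(seq_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes and observed-as-canonical flags for one sequence."""
    fwd, rc = _window_codes_1d(np.asarray(seq_codes, dtype=np.uint8), k)
    canon = np.minimum(fwd, rc)
    return canon, fwd <= rc


def _chunk_rows(arr2d: np.ndarray, rows_per_chunk: int) -> Iterable[np.ndarray]:
    for i in range(0, arr2d.shape[0], rows_per_chunk):
        yield arr2d[i:i + rows_per_chunk].ravel()


def _coerce_read_codes(reads) -> Iterable[np.ndarray]:
    """Yield uint8 base-code arrays from the accepted read containers."""
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        for seq in read_fastq(reads):
            yield encode_sequence(seq)
        return
    codes2d = getattr(reads, "codes", None)
    if codes2d is not None:
        for row in np.asarray(codes2d):
            yield np.asarray(row, dtype=np.uint8)
        return
    for item in reads:
        if isinstance(item, str):
            yield encode_sequence(item)
        else:
            yield np.asarray(item, dtype=np.uint8)


@dataclass
class KmerCounts:
    """Per-sample canonical k-mer tallies split by observed orientation.

    ``count_given`` counts observations in canonical orientation,
    ``count_revcomp`` observations as the reverse complement of the
    canonical form; the per-sample retention floor applies to their sum.
    """

    k: int
    codes: np.ndarray          # sorted canonical uint64 codes
    count_given: np.ndarray    # int64, aligned with codes
    count_revcomp: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def total(self) -> np.ndarray:
        return self.count_given + self.count_revcomp

    def kmers(self) -> list[str]:
        return codes_to_kmers(self.codes, self.k)

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            km: (int(g), int(r))
            for km, g, r in zip(self.kmers(), self.count_given, self.count_revcomp)
        }

    def __contains__(self, kmer: str) -> bool:
        code = kmer_to_code(canonicalize(kmer, self.k))
        i = np.searchsorted(self.codes, np.uint64(code))
        return bool(i < len(self.codes) and self.codes[i] == np.uint64(code))


def count_sample_kmers(
    reads,
    k: int = DEFAULT_K,
    min_count: int = DEFAULT_MIN_COUNT,
    chunk_bases: int = 4_000_000,
) -> KmerCounts:
    """Count canonical k-mers of one sample with a per-sample count floor.

    ``reads`` may be a FASTQ path, an iterable of sequence strings, or a
    :class:`~peff.simdata.ReadSet`.  Windows containing ambiguous bases
    are skipped (tallied to the log); reads shorter than k contribute
    nothing.  Only canonical k-mers whose orientation-summed count
    reaches ``min_count`` are retained.
    """
    _check_k(k)
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    parts: list[tuple[np.ndarray, np.ndarray]] = []
    n_skipped = 0

    def tally(fwd: np.ndarray, rc: np.ndarray) -> None:
        canon = np.minimum(fwd, rc)
        keys = (canon << np.uint64(1)) | (fwd <= rc).astype(np.uint64)
        uniq, counts = np.unique(keys, return_counts=True)
        parts.append((uniq, counts))

    codes2d = getattr(reads, "codes", reads if isinstance(reads, np.ndarray) else None)
    if codes2d is not None and getattr(codes2d, "ndim", 0) == 2:
        # fixed-length reads: vectorised rolling hash across read rows
        arr = np.asarray(codes2d, dtype=np.uint8)
        rows = max(chunk_bases // max(arr.shape[1], 1), 1)
        for i in range(0, arr.shape[0], rows):
            block = arr[i:i + rows]
            fwd, rc = _window_codes_2d(block, k)
            total = block.shape[0] * max(block.shape[1] - k + 1, 0)
            n_skipped += total - fwd.size
            tally(fwd, rc)
    else:
        buf: list[np.ndarray] = []
        buffered = 0

        def flush() -> None:
            nonlocal buffered, n_skipped
            if not buf:
                return
            block = np.concatenate(buf)
            buf.clear()
            buffered = 0
            fwd, rc = _window_codes_1d(block, k)
            total_windows = max(block.size - k + 1, 0)
            n_skipped += total_windows - fwd.size
            tally(fwd, rc)

        for arr in _coerce_read_codes(reads):
            buf.append(arr)
            buf.append(_SENTINEL)
            buffered += arr.size + 1
            if buffered >= chunk_bases:
                flush()
        flush()

    if not parts:
        empty = np.empty(0, dtype=np.uint64)
        zero = np.empty(0, dtype=np.int64)
        return KmerCounts(k, empty, zero, zero)

    keys = np.concatenate([p[0] for p in parts])
    counts = np.concatenate([p[1] for p in parts]).astype(np.int64)
    codes = keys >> np.uint64(1)
    flag = (keys & np.uint64(1)).astype(bool)
    uniq, inverse = np.unique(codes, return_inverse=True)
    given = np.zeros(len(uniq), dtype=np.int64)
    revc = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(given, inverse[flag], counts[flag])
    np.add.at(revc, inverse[~flag], counts[~flag])
    keep = (given + revc) >= min_count
    if n_skipped:
        log.info("skipped %d windows containing ambiguous bases", n_skipped)
    return KmerCounts(k, uniq[keep], given[keep], revc[keep])


@dataclass
class StrandAssignment:
    """Cross-sample orientation resolution for canonical k-mers.

    For every canonical k-mer the canonical-orientation and
    reverse-complement observation counts are summed across samples; the
    reported string is the orientation with the larger aggregate count,
    ties keeping the canonical (lexicographically smaller) form.
    """

    k: int
    codes: np.ndarray            # sorted canonical uint64 codes
    keep_canonical: np.ndarray   # bool, aligned with codes

    def oriented_kmers(self) -> list[str]:
        canon = codes_to_kmers(self.codes, self.k)
        return [
            km if keep else reverse_complement(km)
            for km, keep in zip(canon, self.keep_canonical)
        ]

    def orient(self, canonical_kmer: str) -> str:
        code = np.uint64(kmer_to_code(canonical_kmer))
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code and not self.keep_canonical[i]:
            return reverse_complement(canonical_kmer)
        return canonical_kmer


class StrandTally:
    """Incremental cross-sample orientation tally (streaming counterpart
    of :func:`assign_strand`, for sample-by-sample pipelines)."""

    def __init__(self) -> None:
        self.k: int | None = None
        self._codes = np.empty(0, dtype=np.uint64)
        self._given = np.empty(0, dtype=np.int64)
        self._revc = np.empty(0, dtype=np.int64)

    def update(self, counts: KmerCounts) -> None:
        if self.k is None:
            self.k = counts.k
        elif counts.k != self.k:
            raise ValueError("mixed k among samples")
        codes = np.concatenate([self._codes, counts.codes])
        given = np.concatenate([self._given, counts.count_given])
        revc = np.concatenate([self._revc, counts.count_revcomp])
        uniq, inverse = np.unique(codes, return_inverse=True)
        g = np.zeros(len(uniq), dtype=np.int64)
        r = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(g, inverse, given)
        np.add.at(r, inverse, revc)
        self._codes, self._given, self._revc = uniq, g, r

    def finalize(self) -> StrandAssignment:
        if self.k is None:
            raise ValueError("no samples tallied")
        return StrandAssignment(self.k, self._codes, self._given >= self._revc)


def assign_strand(tallies: Sequence[KmerCounts]) -> StrandAssignment:
    """Resolve reported k-mer orientation by majority vote across samples."""
    if not tallies:
        raise ValueError("need tallies from at least one sample")
    k = tallies[0].k
    if any(t.k != k for t in tallies):
        raise ValueError("mixed k among samples")
    codes = np.concatenate([t.codes for t in tallies])
    given = np.concatenate([t.count_given for t in tallies])
    revc = np.concatenate([t.count_revcomp for t in tallies])
    uniq, inverse = np.unique(codes, return_inverse=True)
    g = np.zeros(len(uniq), dtype=np.int64)
    r = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(g, inverse, given)
    np.add.at(r, inverse, revc)
    return StrandAssignment(k, uniq, g >= r)


@dataclass
class KmerMatrix:
    """Accessions × k-mers binary presence/absence matrix.

    ``kmers`` holds the reported (orientation-resolved) strings in
    lexicographic column order; ``presence`` is uint8 in {0, 1} with one
    row per sample.  Column frequency is the presence column mean.
    """

    kmers: list[str]
    samples: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.shape != (len(self.samples), len(self.kmers)):
            raise ValueError("presence shape does not match samples × kmers")
        if self.presence.size and self.presence.max() > 1:
            raise ValueError("presence entries must be 0/1")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.kmers:
            lengths = {len(s) for s in self.kmers}
            if len(lengths) != 1:
                raise ValueError("mixed k-mer lengths in matrix")
            canon = {canonicalize(s) for s in self.kmers}
            if len(canon) != len(self.kmers):
                raise ValueError("duplicate k-mers after canonicalisation")

    @property
    def k(self) -> int:
        return len(self.kmers[0]) if self.kmers else 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    @property
    def freq(self) -> np.ndarray:
        return self.presence.mean(axis=0) if self.n_kmers else np.empty(0)

    @property
    def maf(self) -> np.ndarray:
        f = self.freq
        return np.minimum(f, 1.0 - f)

    def canonical_kmers(self) -> list[str]:
        return [canonicalize(s) for s in self.kmers]

    def select_columns(self, index: np.ndarray) -> "KmerMatrix":
        index = np.asarray(index)
        kms = [self.kmers[i] for i in np.flatnonzero(index)] if index.dtype == bool \
            else [self.kmers[i] for i in index]
        return KmerMatrix(kms, list(self.samples), self.presence[:, index])

    def subset_samples(self, ids: Sequence[str]) -> "KmerMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in ids]
        return KmerMatrix(list(self.kmers), list(ids), self.presence[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.samples, columns=self.kmers)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "sample"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KmerMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.columns), list(frame.index), frame.to_numpy(dtype=np.uint8))

    def to_bitset(self, prefix) -> None:
        """Compact row-major bitset with a JSON sidecar of k-mers/samples."""
        import json

        prefix = Path(prefix)
        np.packbits(self.presence, axis=1).tofile(prefix.with_suffix(".bits"))
        sidecar = {"k": self.k, "kmers": self.kmers, "samples": self.samples}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_bitset(cls, prefix) -> "KmerMatrix":
        import json

        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        n, m = len(meta["samples"]), len(meta["kmers"])
        row_bytes = (m + 7) // 8
        packed = np.fromfile(prefix.with_suffix(".bits"), dtype=np.uint8)
        packed = packed.reshape(n, row_bytes)
        presence = np.unpackbits(packed, axis=1)[:, :m]
        return cls(meta["kmers"], meta["samples"], presence)


def _sample_codes(entry, k: int | None) -> tuple[np.ndarray, int]:
    if isinstance(entry, KmerCounts):
        return entry.codes, entry.k
    if isinstance(entry, np.ndarray) and entry.dtype == np.uint64:
        if k is None:
            raise ValueError("raw code arrays require an explicit k")
        return np.unique(entry), k
    strings = list(entry)
    if not strings:
        return np.empty(0, dtype=np.uint64), k or 0
    kk = len(strings[0])
    codes = np.unique(
        np.array([kmer_to_code(canonicalize(s, kk)) for s in strings], dtype=np.uint64)
    )
    return codes, kk


def build_pa_matrix(
    samples: Mapping[str, object] | Iterable[tuple[str, object]],
    strand: StrandAssignment | None = None,
    k: int | None = None,
) -> KmerMatrix:
    """Combine per-sample retained k-mer sets into a presence/absence matrix.

    ``samples`` maps sample id to a :class:`KmerCounts`, an iterable of
    k-mer strings, or a uint64 canonical-code array (with explicit
    ``k``).  Columns are the union of retained k-mers in lexicographic
    order of the reported string; presence is set membership.
    """
    pairs = list(samples.items()) if isinstance(samples, Mapping) else list(samples)
    ids = [s for s, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample id")
    if len(ids) < 2:
        raise ValueError("need at least two samples")

    per_sample: list[np.ndarray] = []
    for _, entry in pairs:
        codes, kk = _sample_codes(entry, k)
        if kk and k is None:
            k = kk
        elif kk and k is not None and kk != k:
            raise ValueError("mixed k among samples")
        per_sample.append(codes)
    if k is None:
        raise ValueError("no k-mers in any sample")

    union = np.unique(np.concatenate(per_sample)) if per_sample else np.empty(0, np.uint64)
    presence = np.zeros((len(ids), len(union)), dtype=np.uint8)
    for i, codes in enumerate(per_sample):
        presence[i, np.searchsorted(union, codes)] = 1

    strings = codes_to_kmers(union, k)
    if strand is not None:
        idx = np.searchsorted(strand.codes, union)
        flip = np.zeros(len(union), dtype=bool)
        in_range = idx < len(strand.codes)
        hit = in_range.copy()
        hit[in_range] = strand.codes[idx[in_range]] == union[in_range]
        flip[hit] = ~strand.keep_canonical[idx[hit]]
        strings = [
            reverse_complement(s) if f else s for s, f in zip(strings, flip)
        ]
        order = np.argsort(np.array(strings))
        strings = [strings[i] for i in order]
        presence = presence[:, order]
    # without strand resolution, numeric code order is already lexicographic
    return KmerMatrix(strings, ids, presence)


def filter_maf(matrix: KmerMatrix, maf_min: float = 0.01) -> KmerMatrix:
    """Drop k-mers with minor allele frequency below ``maf_min``.

    MAF is min(f, 1−f) of the binary presence frequency.  Monomorphic
    columns (f = 0 or 1) are always dropped — a constant predictor is
    untestable — so a k-mer present in every sample never survives even
    at ``maf_min = 0``.  Column order is preserved.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    f = matrix.freq
    keep = (f > 0.0) & (f < 1.0) & (np.minimum(f, 1.0 - f) >= maf_min)
    return matrix.select_columns(keep)
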