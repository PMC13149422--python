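"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — dictionaries, explicit loops,
exhaustive enumeration — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_kmer_counts(reads, k, min_count) -> dict[str, tuple[int, int]]:
    """Dictionary k-mer counter: canonical -> (as-canonical, as-revcomp)."""
    tally: dict[str, list[int]] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            window = read[i:i + k]
            if any(c not in "ACGT" for c in window):
                continue
            rc = revcomp(window)
            canon = min(window, rc)
            slot = tally.setdefault(canon, [0, 0])
            slot[0 if window == canon else 1] += 1
    return {
        km: (g, r) for km, (g, r) in tally.items() if g + r >= min_count
    }


def chain_overlap_oracle(kmers: list[str]) -> str:
    """Reconstruct the single source sequence of a tiled k-mer chain.

    Builds the all-pairs (k−1)-overlap graph over both orientations,
    asserts it is one simple path, and follows it from the unique head.
    Only valid for inputs that tile one sequence without branches.
    """
    k = len(kmers[0])
    oriented = set()
    for km in kmers:
        oriented.add(km)
        oriented.add(revcomp(km))
    succ: dict[str, set[str]] = {s: set() for s in oriented}
    for a, b in itertools.permutations(oriented, 2):
        if a[1:] == b[:-1] and min(a, revcomp(a)) != min(b, revcomp(b)):
            succ[a].add(b)
    canon = {min(s, revcomp(s)) for s in oriented}
    heads = [
        s for s in sorted(oriented)
        if len([p for p in oriented if s in succ[p]]) == 0
    ]
    assert heads, "no chain head found"
    seq = None
    for head in heads:
        out = head
        seen = {min(head, revcomp(head))}
        cur = head
        while succ[cur]:
            nxts = [n for n in succ[cur] if min(n, revcomp(n)) not in seen]
            if len(nxts) != 1:
                break
            cur = nxts[0]
            seen.add(min(cur, revcomp(cur)))
            out += cur[-1]
        if len(seen) == len(canon):
            seq = out
            break
    assert seq is not None, "k-mers do not form one unambiguous chain"
    return min(seq, revcomp(seq))


def ols_ml_lrt(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio test of one regressor vs intercept-only, by
    direct ML fits of two ordinary normal models."""
    from scipy import stats

    y = np.asarray(y, float)
    n = y.size
    rss0 = float(np.sum((y - y.mean()) ** 2))
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    lrt = n * np.log(rss0 / rss1)
    return lrt, float(stats.chi2.sf(lrt, df=1))


def brute_complete_linkage(points: np.ndarray, n_clusters: int) -> set[frozenset]:
    """Agglomerative complete linkage by explicit pairwise maxima."""
    clusters: list[list[int]] = [[i] for i in range(len(points))]

    def dist(a: list[int], b: list[int]) -> float:
        return max(
            float(np.linalg.norm(points[i] - points[j])) for i in a for j in b
        )

    while len(clusters) > n_clusters:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if d < best_d - 1e-12:
                    best_d = d
                    best = (i, j)
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def pdistance_dedup_oracle(frame, threshold: float, rounds: int) -> list[str]:
    """Quadratic reference implementation of redundancy pruning."""
    current = frame.copy()
    for _ in range(rounds):
        ids = list(current.index)
        X = current.to_numpy(dtype=float)
        drop: set[str] = set()
        groups: list[set[str]] = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                both = ~(np.isnan(X[i]) | np.isnan(X[j]))
                if both.sum() == 0:
                    continue
                d = np.mean(X[i, both] != X[j, both])
                if 1.0 - d >= threshold:
                    hit = None
                    for g in groups:
                        if ids[i] in g or ids[j] in g:
                            hit = g
                            break
                    if hit is None:
                        groups.append({ids[i], ids[j]})
                    else:
                        hit.update({ids[i], ids[j]})
        merged = True
        while merged:
            merged = False
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    if groups[a] & groups[b]:
                        groups[a] |= groups[b]
                        del groups[b]
                        merged = True
                        break
                if merged:
                    break
        for g in groups:
            miss = {acc: int(np.isnan(current.loc[acc].to_numpy(float)).sum())
                    for acc in g}
            keep = min(sorted(g), key=lambda a: (miss[a], a))
            drop |= g - {keep}
        if not drop:
            break
        current = current.drop(index=sorted(drop))
    return list(current.index)
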