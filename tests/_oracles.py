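"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: events are enumerated by
literal pairwise application of the definitions, distances by a linear scan
over all intervals, and hypergeometric tails by exhaustive enumeration of
draw counts.  They are slow and simple on purpose.
"""

from __future__ import annotations

from itertools import permutations
from math import comb


def brute_force_event_ids(gene) -> set[str]:
    """All (type, coords) events of a gene group by scanning transcript pairs."""
    strand = gene.strand
    chrom = gene.chrom
    out: set[tuple[str, tuple[int, ...]]] = set()
    for ta, tb in permutations(gene.transcripts, 2):
        A = [(e.start, e.end) for e in ta.exons]
        B = [(e.start, e.end) for e in tb.exons]
        # SE: ta includes an internal exon, tb splices the flanks directly
        for i in range(1, len(A) - 1):
            e1, (s2, e2), s3 = A[i - 1][1], A[i], A[i + 1][0]
            for j in range(len(B) - 1):
                if B[j][1] == e1 and B[j + 1][0] == s3:
                    out.add(("SE", (e1, s2, e2, s3)))
        # RI: ta has one exon spanning what tb splits into two
        for s1, e2 in A:
            for j in range(len(B) - 1):
                if B[j][0] == s1 and B[j + 1][1] == e2:
                    out.add(("RI", (s1, B[j][1], B[j + 1][0], e2)))
        # A5/A3: junction pairs sharing one boundary within overlapping exons
        for i in range(len(A) - 1):
            for j in range(len(B) - 1):
                (ea, sa), (eb, sb) = (A[i][1], A[i + 1][0]), (B[j][1], B[j + 1][0])
                if sa == sb and ea != eb and _overlap(A[i], B[j]):
                    etype = "A5" if strand == "+" else "A3"
                    out.add((etype, (min(ea, eb), max(ea, eb), sa)))
                if ea == eb and sa != sb and _overlap(A[i + 1], B[j + 1]):
                    etype = "A3" if strand == "+" else "A5"
                    out.add((etype, (ea, min(sa, sb), max(sa, sb))))
        # MX: distinct non-overlapping middles between identical flanks
        for i in range(1, len(A) - 1):
            for j in range(1, len(B) - 1):
                if A[i - 1][1] == B[j - 1][1] and A[i + 1][0] == B[j + 1][0]:
                    ma, mb = A[i], B[j]
                    if ma == mb:
                        continue
                    lo, hi = sorted([ma, mb])
                    if lo[1] < hi[0]:
                        out.add(("MX", (A[i - 1][1], lo[0], lo[1], hi[0], hi[1],
                                        A[i + 1][0])))
        # AF/AL: non-overlapping terminal exons spliced to a shared boundary
        if len(A) >= 2 and len(B) >= 2:
            if A[1][0] == B[1][0] and A[0] != B[0] and not _overlap(A[0], B[0]):
                lo, hi = sorted([A[0], B[0]])
                etype = "AF" if strand == "+" else "AL"
                out.add((etype, (lo[0], lo[1], hi[0], hi[1], A[1][0])))
            if A[-2][1] == B[-2][1] and A[-1] != B[-1] and not _overlap(A[-1], B[-1]):
                lo, hi = sorted([A[-1], B[-1]])
                etype = "AL" if strand == "+" else "AF"
                out.add((etype, (A[-2][1], lo[0], lo[1], hi[0], hi[1])))
    return {
        f"{gene.gene_id};{etype}:{chrom}:{'-'.join(map(str, coords))}:{strand}"
        for etype, coords in out
    }


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def brute_force_nearest(tss: int, strand: str, intervals) -> int | None:
    """Signed nearest distance by scanning every interval; downstream wins ties."""
    best = None  # (gap, downstream_preference, signed)
    for iv in intervals:
        if iv.start <= tss < iv.end:
            gap, signed = 0, 0
        else:
            gap = min(abs(tss - iv.start), abs(tss - (iv.end - 1)))
            edge = iv.start if abs(tss - iv.start) <= abs(tss - (iv.end - 1)) else iv.end - 1
            downstream = (edge > tss) if strand == "+" else (edge < tss)
            signed = gap if downstream else -gap
        key = (gap, 0 if signed >= 0 else 1)
        if best is None or key < best[0]:
            best = (key, signed)
    return None if best is None else best[1]


def brute_force_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total
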