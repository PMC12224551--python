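"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the libraries the implementation uses (no
biopython aligner, no networkx): exhaustive alignment enumeration, direct
double-loop mutual-best matching, and set-merging connected components.
Only usable at tiny problem sizes.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def enumerate_alignments(a: str, b: str):
    """Yield all global alignments of a and b as lists of ops.

    An op is ('M', i, j), ('I', j) (gap in a) or ('D', i) (gap in b).
    """

    def rec(i: int, j: int, ops: list):
        if i == len(a) and j == len(b):
            yield list(ops)
            return
        if i < len(a) and j < len(b):
            ops.append(("M", i, j))
            yield from rec(i + 1, j + 1, ops)
            ops.pop()
        if i < len(a):
            ops.append(("D", i))
            yield from rec(i + 1, j, ops)
            ops.pop()
        if j < len(b):
            ops.append(("I", j))
            yield from rec(i, j + 1, ops)
            ops.pop()

    yield from rec(0, 0, [])


def score_alignment(a, b, ops, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    score = 0
    prev = None
    for op in ops:
        kind = op[0]
        if kind == "M":
            score += match if a[op[1]] == b[op[2]] else mismatch
        else:
            score += gap_extend if prev == kind else gap_open
        prev = kind
    return score


def alignment_identity(a, b, ops) -> Fraction:
    identities = sum(1 for op in ops if op[0] == "M" and a[op[1]] == b[op[2]])
    return Fraction(identities, len(ops))


def optimal_identities(a: str, b: str, **scoring) -> tuple[float, set[Fraction]]:
    """Max global-alignment score and identities of all optimal alignments."""
    best_score = None
    idents: set[Fraction] = set()
    for ops in enumerate_alignments(a, b):
        s = score_alignment(a, b, ops, **scoring)
        if best_score is None or s > best_score:
            best_score = s
            idents = {alignment_identity(a, b, ops)}
        elif s == best_score:
            idents.add(alignment_identity(a, b, ops))
    return best_score, idents


def mutual_best_pairs(identity: dict[tuple[str, str], float],
                      tags_a: list[str], tags_b: list[str],
                      min_identity: float = 0.0) -> set[tuple[str, str]]:
    """Direct mutual-best matching on a given identity matrix
    (ties toward the lexicographically smaller partner)."""
    pairs = set()
    for ta in tags_a:
        best_b = max(sorted(tags_b), key=lambda t: identity[(ta, t)])
        best_a = max(sorted(tags_a), key=lambda t: identity[(t, best_b)])
        if best_a == ta and identity[(ta, best_b)] >= min_identity:
            pairs.add((ta, best_b))
    return pairs


def connected_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    """Set-merging components, independent of any graph library."""
    comps: list[set[str]] = [{n} for n in nodes]
    for u, v in edges:
        cu = next(c for c in comps if u in c)
        cv = next(c for c in comps if v in c)
        if cu is not cv:
            comps.remove(cv)
            cu |= cv
    return comps


def adjacent_pair_count(order_a: list[int], order_b: list[int]) -> int:
    """Count pairs adjacent in order_a that are adjacent (either direction)
    in order_b, by direct enumeration."""
    count = 0
    for x, y in zip(order_a, order_a[1:]):
        for u, v in zip(order_b, order_b[1:]):
            if {x, y} == {u, v}:
                count += 1
                break
    return count


def interval_overlap_pairs(
    intervals_a: dict[str, tuple[str, int, int]],
    intervals_b: dict[str, tuple[str, int, int]],
    min_frac: float = 0.5,
):
    """All (a, b) pairs with reciprocal overlap >= min_frac, by brute force."""
    out = set()
    for ta, (ca, sa, ea) in intervals_a.items():
        for tb, (cb, sb, eb) in intervals_b.items():
            if ca != cb:
                continue
            ov = min(ea, eb) - max(sa, sb) + 1
            if ov <= 0:
                continue
            if ov / (ea - sa + 1) >= min_frac and ov / (eb - sb + 1) >= min_frac:
                out.add((ta, tb))
    return out


def greedy_cluster_oracle(proteins, identity_fn, min_identity, min_coverage):
    """Re-derive greedy length-descending centroid clustering directly."""
    ordered = sorted(proteins, key=lambda p: (-len(p[2]), p[0], p[1]))
    centroids = []  # (family_ordinal, seq)
    assignment = {}
    for genome, tag, seq in ordered:
        placed = None
        for k, cseq in centroids:
            ident, cov_short = identity_fn(seq, cseq)
            aligned = cov_short * min(len(seq), len(cseq))
            if (
                ident >= min_identity
                and aligned / len(seq) >= min_coverage
                and aligned / len(cseq) >= min_coverage
            ):
                placed = k
                break
        if placed is None:
            placed = len(centroids) + 1
            centroids.append((placed, seq))
        assignment[(genome, tag)] = placed
    return assignment
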