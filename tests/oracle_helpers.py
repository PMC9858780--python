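"""Independent oracles used by the test suite.

These are deliberately naive re-implementations (brute-force matchers,
plain dynamic programming, exhaustive partition search) kept separate
from the library code paths they validate.
"""

import numpy as np
from Bio.Align import substitution_matrices


def naive_scan(sequence: str, pattern_string: str) -> list[int]:
    """Brute-force position-by-position bracket-pattern matcher."""
    positions = []
    i = 0
    while i < len(pattern_string):
        c = pattern_string[i]
        if c == "[":
            j = pattern_string.index("]", i)
            positions.append(set(pattern_string[i + 1 : j]))
            i = j + 1
        elif c == "x":
            positions.append(None)
            i += 1
        else:
            positions.append({c})
            i += 1
    hits = []
    for start in range(len(sequence) - len(positions) + 1):
        for offset, allowed in enumerate(positions):
            ch = sequence[start + offset]
            if allowed is None:
                continue
            if ch not in allowed:
                break
        else:
            hits.append(start)
    return hits


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Plain Gotoh local alignment: gap of length k costs open + k*extend."""
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = -1e9
    match = np.zeros((n + 1, m + 1))
    gap_a = np.full((n + 1, m + 1), neg)
    gap_b = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            gap_a[i][j] = max(
                match[i - 1][j] - (gap_open + gap_extend), gap_a[i - 1][j] - gap_extend
            )
            gap_b[i][j] = max(
                match[i][j - 1] - (gap_open + gap_extend), gap_b[i][j - 1] - gap_extend
            )
            match[i][j] = max(
                0.0, s + max(match[i - 1][j - 1], gap_a[i - 1][j - 1], gap_b[i - 1][j - 1])
            )
            best = max(best, match[i][j], gap_a[i][j], gap_b[i][j])
    return best


def set_partitions(nodes: list):
    """All set partitions of a node list (Bell-number enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]


def exhaustive_max_modularity(graph) -> float:
    """Global maximum Newman-Girvan modularity over all partitions."""
    from divscan.cluster import _partition_modularity

    best = -np.inf
    for part in set_partitions(sorted(graph.nodes())):
        q = _partition_modularity(graph, part)
        if q > best:
            best = q
    return best
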