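"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the identity oracle is a
plain-Python tuple DP, the clustering oracle is a boolean transitive
closure, the D-assignment oracle enumerates every substring, and the probe
oracle slides a probe position by position.
"""

from __future__ import annotations


def nw_identity_oracle(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap: int = -2) -> float:
    """Needleman-Wunsch with free end gaps; identity over core columns.

    Cell values are (score, matches, -columns) tuples maximised
    lexicographically, matching the package's documented tie-break.
    'N' matches nothing.
    """
    la, lb = len(a), len(b)
    H = [[(0, 0, 0)] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            ai, bj = a[i - 1], b[j - 1]
            is_match = ai == bj and ai != "N" and bj != "N"
            d = H[i - 1][j - 1]
            diag = (d[0] + (match if is_match else mismatch),
                    d[1] + (1 if is_match else 0), d[2] - 1)
            u = H[i - 1][j]
            up = (u[0] + gap, u[1], u[2] - 1)
            l = H[i][j - 1]
            left = (l[0] + gap, l[1], l[2] - 1)
            H[i][j] = max(diag, up, left)
    best = max([H[la][j] for j in range(lb + 1)] +
               [H[i][lb] for i in range(la + 1)])
    _, m, neg_c = best
    c = -neg_c
    return 100.0 * m / c if c else 0.0


def transitive_closure_components(matrix, threshold: float) -> list[set[int]]:
    """Connected components of the >threshold graph by boolean closure."""
    n = len(matrix)
    adj = [[matrix[i][j] > threshold or i == j for j in range(n)]
           for i in range(n)]
    for k in range(n):
        for i in range(n):
            if adj[i][k]:
                for j in range(n):
                    if adj[k][j]:
                        adj[i][j] = True
    seen: set[int] = set()
    components = []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if adj[i][j]}
        seen |= comp
        components.append(comp)
    return components


def lcs_overlap_oracle(core: str, d_seq: str, lo: int, hi: int) -> int:
    """Length of the longest common substring of core and d_seq whose
    occurrence in core overlaps [lo, hi), by exhaustive enumeration."""
    d_subs = {d_seq[i:j] for i in range(len(d_seq))
              for j in range(i + 1, len(d_seq) + 1)}
    best = 0
    n = len(core)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j > lo and i < hi and core[i:j] in d_subs:
                best = max(best, j - i)
    return best


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def probe_scan_oracle(read: str, probe: str):
    """Best full-probe ungapped placement of probe in read, both strands.

    Returns (identity_percent, start, strand) with coordinates on the
    strand-normalized (+) orientation, preferring '+' then lower offset on
    ties (the same preference order as the vectorized scan).
    """
    best = (-1.0, 0, "+")
    m = len(probe)
    for strand in ("+", "-"):
        target = read if strand == "+" else _rc(read)
        for off in range(len(target) - m + 1):
            matches = sum(1 for k in range(m)
                          if target[off + k] == probe[k] and probe[k] != "N"
                          and target[off + k] != "N")
            ident = 100.0 * matches / m
            if ident > best[0]:
                best = (ident, off, strand)
    return best
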