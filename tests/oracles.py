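"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (full-matrix dynamic programming, exhaustive
scans) kept separate from the package so they cannot share bugs with the code
paths they check.
"""

from symbiocheck.align import SUBST, encode_aa


def sw_score_bruteforce(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score by full affine DP (gap of k costs
    gap_open + k*gap_extend)."""
    A, B = encode_aa(a), encode_aa(b)
    m, n = len(A), len(B)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            F[i][j] = max(F[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + SUBST[A[i - 1], B[j - 1]],
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def best_adapter_clip_bruteforce(seq: str, adapters, min_overlap: int, rate: float):
    """Leftmost adapter match position by exhaustive sliding-window scan,
    iterated to a fixpoint (truncation can expose new terminal prefixes)."""

    def one_pass(s: str) -> int:
        L = len(s)
        best = L
        for adapter in adapters:
            alen = len(adapter)
            for off in range(0, L - min_overlap + 1):
                comp = min(alen, L - off)
                budget = int(rate * comp)
                mm = sum(
                    1 for x, y in zip(s[off : off + comp], adapter[:comp]) if x != y
                )
                if mm <= budget and off < best:
                    best = off
        return best

    pos = len(seq)
    while True:
        new = one_pass(seq[:pos])
        if new >= pos:
            return pos
        pos = new


def primer_best_site_bruteforce(primer: str, template: str):
    """Exhaustive both-strand scan returning the minimal mismatch count."""
    from symbiocheck.align import revcomp
    from symbiocheck.primers import _iupac_match

    best = len(primer) + 1
    for probe in (primer.upper(), revcomp(primer.upper())):
        for off in range(len(template) - len(primer) + 1):
            mm = sum(
                0 if _iupac_match(p, t) else 1
                for p, t in zip(probe, template[off : off + len(primer)])
            )
            best = min(best, mm)
    return best
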