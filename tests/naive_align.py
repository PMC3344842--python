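"""Independent brute-force alignment oracles used only by the tests.

Deliberately simple quadratic implementations, written without reference to
the package's aligner internals.
"""

NEG = float("-inf")


def sw_naive_score(a, b, score, gap_open=11, gap_extend=1):
    """Full-matrix affine-gap Smith-Waterman score.

    ``score(x, y)`` returns the substitution score; a gap of length L costs
    ``gap_open + L * gap_extend``.
    """
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def blosum62_scorer(stop_to_min=True):
    """Substitution scorer backed by Biopython's BLOSUM62.

    With ``stop_to_min`` the stop symbol scores the matrix minimum against
    everything, matching the package's scoring extension.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    floor = min(mat[k] for k in mat.keys())

    def score(x, y):
        if stop_to_min and ("*" in (x, y)):
            return floor
        return mat[x, y]

    return score


def enumerate_kmers(text, k):
    """All (offset, k-mer) pairs of a string."""
    return [(i, text[i : i + k]) for i in range(len(text) - k + 1)]
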