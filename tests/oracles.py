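"""Independent oracles used only by the test suite.

Deliberately implemented with different algorithms than the package:
superposition via Horn's quaternion eigenvalue method (the package uses
SVD Kabsch) and motif matching via naive recursive expansion (the
package uses an iterative shortest-first matcher).
"""

import numpy as np


def horn_superposed_rmsd(A, B):
    """Optimal-superposition RMSD via Horn's quaternion method."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    S = A0.T @ B0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(N)[-1]
    sq = (np.sum(A0 ** 2) + np.sum(B0 ** 2) - 2.0 * lam) / len(A)
    return float(np.sqrt(max(sq, 0.0)))


def brute_match_lengths(seq, positions, start=0, k=0):
    """All total match lengths of a positional pattern at ``start``.

    ``positions`` is the compiled tuple ((allowed, lo, hi), ...); every
    expansion of every variable position is enumerated recursively.
    """
    if k == len(positions):
        return {0}
    allowed, lo, hi = positions[k]
    lengths = set()
    for n in range(lo, hi + 1):
        chunk = seq[start:start + n]
        if len(chunk) < n or any(c not in allowed for c in chunk):
            continue
        for rest in brute_match_lengths(seq, positions, start + n, k + 1):
            lengths.add(n + rest)
    return lengths


def brute_scan(seq, positions):
    """(start0, shortest_length) for every matching start (0-based)."""
    out = []
    min_len = sum(lo for _, lo, _ in positions)
    for start in range(0, len(seq) - min_len + 1):
        lengths = brute_match_lengths(seq, positions, start)
        if lengths:
            out.append((start, min(lengths)))
    return out
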