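"""Independent brute-force re-derivations used as oracles.

Everything here materializes the defining subsequences explicitly and tests
the definitions literally, trading efficiency for obviousness; nothing is
shared with the implementation under test.
"""

import numpy as np


def brute_run_label(values, i, N, dimension):
    """Run-mode label of trial ``i`` from raw per-session value lists."""
    if i - N < 0:
        return None
    window = values[i - N:i]
    if dimension == "outcome":
        if all(v for v in window):
            return "C"
        if all(not v for v in window):
            return "E"
        return None
    letters = {"S" if v == values[i] else "D" for v in window}
    return letters.pop() if len(letters) == 1 else None


def brute_sequence_label(value_lists, dims, i, H):
    """Sequence-mode label: per past trial (oldest first), letters per dim."""
    if i - H < 0:
        return None
    out = []
    for j in range(i - H, i):
        for d in dims:
            v = value_lists[d]
            if d == "outcome":
                out.append("C" if v[j] else "E")
            else:
                out.append("S" if v[j] == v[i] else "D")
    return "".join(out)


def brute_single_event(values, i, lag, relation):
    if i - lag < 0:
        return False
    same = values[i - lag] == values[i]
    return same if relation == "S" else not same


def brute_tachometric_counts(pts, corrects, centers, width):
    """Naive double loop over trials and bins, half-open [c-w/2, c+w/2)."""
    n = np.zeros(len(centers), dtype=int)
    k = np.zeros(len(centers), dtype=int)
    for j, c in enumerate(centers):
        for pt, ok in zip(pts, corrects):
            if c - width / 2 <= pt < c + width / 2:
                n[j] += 1
                k[j] += int(ok)
    return n, k


def agresti_coull_closed_form(k, n, conf=0.95):
    from scipy.stats import norm
    z = norm.ppf(0.5 + conf / 2.0)
    n_t = n + z * z
    p_t = (k + z * z / 2.0) / n_t
    half = z * np.sqrt(p_t * (1 - p_t) / n_t)
    return max(p_t - half, 0.0), min(p_t + half, 1.0)


def conditional_independence_joint(prior, pa1, pb1, rng):
    """Random P(A,B,C) with binary A, B satisfying P(A,B|C)=P(A|C)P(B|C).

    ``pa1`` and ``pb1`` are P(A=1|C=c) and P(B=1|C=c) for c in {0, 1}.
    Returns the 2x2x2 joint table indexed [a, b, c].
    """
    joint = np.zeros((2, 2, 2))
    pc = (1 - prior, prior)
    for c in (0, 1):
        for a in (0, 1):
            for b in (0, 1):
                pa = pa1[c] if a == 1 else 1 - pa1[c]
                pb = pb1[c] if b == 1 else 1 - pb1[c]
                joint[a, b, c] = pa * pb * pc[c]
    return joint


def direct_p_c_given_ab(joint, a, b):
    """P(C=1|A=a,B=b) by direct summation of the joint table."""
    return joint[a, b, 1] / joint[a, b, :].sum()


def p_c_given_marginal(joint, axis, value):
    """P(C=1|A=value) (axis 0) or P(C=1|B=value) (axis 1) by summation."""
    if axis == 0:
        num = joint[value, :, 1].sum()
        den = joint[value, :, :].sum()
    else:
        num = joint[:, value, 1].sum()
        den = joint[:, value, :].sum()
    return num / den
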