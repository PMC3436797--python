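"""Naive dense reference implementation of the flow recurrence.

Used only as an independent oracle in tests: plain numpy arrays and
explicit per-column loops, no sharing of code with the sparse engine.
"""

import numpy as np


def dense_canonical(A):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    M = np.zeros((n, n))
    for j in range(n):
        s = A[:, j].sum()
        assert s > 0, "isolated node"
        M[:, j] = A[:, j] / s
    return M


def _normalize(M):
    out = np.zeros_like(M)
    for j in range(M.shape[1]):
        s = M[:, j].sum()
        assert s > 0
        out[:, j] = M[:, j] / s
    return out


def _argmaxes(M):
    # first (lowest-index) maximum per column
    return np.array([int(np.argmax(M[:, j])) for j in range(M.shape[1])])


def dense_step(M, M_G, r, b, beta, counts, prune_threshold):
    """One Regularize -> Inflate(penalty) -> Prune iteration, densely."""
    n = M.shape[0]
    counts = np.asarray(counts, dtype=float)

    # balance: reweight regularizer rows by (current attractor mass)^-b
    masses = np.ones(n)
    if b != 0:
        tally = np.zeros(n)
        for a in _argmaxes(M):
            tally[a] += 1
        masses = np.maximum(tally, 1.0)
        M_R = _normalize(M_G * (masses[:, None] ** -b))
    else:
        M_R = M_G

    P = _normalize(M @ M_R)

    # inflate with per-row penalty exponents; underflowed columns fall back
    # to a point mass on the pre-inflation maximum
    exps = r * beta ** counts
    Q = np.zeros_like(P)
    for j in range(n):
        col = P[:, j]
        new = np.zeros(n)
        for i in range(n):
            if col[i] > 0:
                with np.errstate(over="ignore", under="ignore"):
                    v = col[i] ** exps[i]
                new[i] = v if np.isfinite(v) else 0.0
        if new.sum() <= 0:
            new = np.zeros(n)
            new[int(np.argmax(col))] = 1.0
        Q[:, j] = new / new.sum()

    # prune: drop entries below threshold, always keeping the column max
    R_ = np.zeros_like(Q)
    for j in range(n):
        col = Q[:, j].copy()
        keep = (col >= prune_threshold) | (col == col.max())
        col[~keep] = 0.0
        R_[:, j] = col / col.sum()
    return R_


def dense_flow_trajectory(A, r, b, beta, counts, prune_threshold,
                          max_steps, convergence_tol):
    """All iterates of the flow recurrence, densely.

    Stops on convergence (max-abs change below tol) or at max_steps; a
    detected period-2 oscillation contributes one final iterate equal to
    the column-normalized average of the two alternating states.
    """
    M_G = dense_canonical(A)
    states = [M_G]
    out = []
    for _ in range(max_steps):
        new = dense_step(states[-1], M_G, r, b, beta, counts, prune_threshold)
        out.append(new)
        if np.abs(new - states[-1]).max() <= convergence_tol:
            break
        if len(states) >= 2 and np.abs(new - states[-2]).max() <= convergence_tol:
            out.append(_normalize((new + states[-1]) / 2.0))
            break
        states.append(new)
    return out
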