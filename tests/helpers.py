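"""Independent reference implementations (oracles) used only by the tests.

These deliberately avoid the package's own code paths: the RMSD oracle uses
the Horn quaternion method instead of SVD Kabsch, the Butina oracle is a
direct transcription of the sphere-exclusion procedure, and the pruning
oracle is a naive O(n^2) exhaustive check.
"""

import numpy as np


def quaternion_rmsd(A, B):
    """Minimal RMSD via Horn's quaternion method (no reflections)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx, Sxy, Sxz = (A[:, 0] * B[:, 0]).sum(), (A[:, 0] * B[:, 1]).sum(), (A[:, 0] * B[:, 2]).sum()
    Syx, Syy, Syz = (A[:, 1] * B[:, 0]).sum(), (A[:, 1] * B[:, 1]).sum(), (A[:, 1] * B[:, 2]).sum()
    Szx, Szy, Szz = (A[:, 2] * B[:, 0]).sum(), (A[:, 2] * B[:, 1]).sum(), (A[:, 2] * B[:, 2]).sum()
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (A * A).sum() + (B * B).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / len(A)))


def brute_force_butina(dist, threshold):
    """Direct transcription of sphere-exclusion clustering for tiny inputs."""
    n = len(dist)
    neighbors = [
        {j for j in range(n) if dist[i][j] <= threshold} | {i} for i in range(n)
    ]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            c = len(neighbors[i] & unassigned)
            if c > best_count:
                best, best_count = i, c
        cluster = sorted(neighbors[best] & unassigned)
        cluster.remove(best)
        clusters.append([best] + cluster)
        unassigned -= set(clusters[-1])
    return clusters


def exhaustive_prune_rmsd(members, rmsd_fn, threshold):
    """O(n^2) reference: keep a member iff it clears every retained one."""
    retained = []
    for m in members:
        if all(rmsd_fn(m.structure, k.structure) >= threshold for k in retained):
            retained.append(m)
    return retained


def direct_js(p, q):
    """Direct-summation Jensen-Shannon divergence, base 2."""
    p = np.asarray(p, float)
    p = p / p.sum()
    q = np.asarray(q, float)
    q = q / q.sum()
    m = (p + q) / 2
    total = 0.0
    for a, b in ((p, m), (q, m)):
        for ai, bi in zip(a, b):
            if ai > 0:
                total += 0.5 * ai * np.log2(ai / bi)
    return total


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
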