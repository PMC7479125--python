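"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive: explicit subgraph enumeration and full sorts, kept
structurally unrelated to the package's vectorized implementations.
"""

import numpy as np
from scipy import stats as sps


def phi_bruteforce(weights: np.ndarray) -> dict:
    """Weighted rich-club phi(k) by explicit subgraph enumeration."""
    n = weights.shape[0]
    deg = [int(sum(1 for j in range(n) if weights[i, j] > 0)) for i in range(n)]
    all_w = sorted(
        (weights[i, j] for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0),
        reverse=True,
    )
    out = {}
    for k in range(max(deg, default=0)):
        members = [i for i in range(n) if deg[i] > k]
        if len(members) < 2:
            continue
        e, w = 0, 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if weights[members[a], members[b]] > 0:
                    e += 1
                    w += weights[members[a], members[b]]
        if e == 0:
            continue
        out[k] = w / sum(all_w[:e])
    return out


def partial_spearman_bruteforce(x, y, cov):
    """Explicit rank + residual + Pearson, step by step."""
    def ranks(v):
        return sps.rankdata(v)

    def resid(v, Z):
        Z1 = np.column_stack([np.ones(len(v)), Z])
        beta = np.linalg.pinv(Z1) @ v
        return v - Z1 @ beta

    rx = resid(ranks(x), cov)
    ry = resid(ranks(y), cov)
    return float(np.corrcoef(rx, ry)[0, 1])
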