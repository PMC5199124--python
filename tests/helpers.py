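"""Shared independent oracles for the test suite."""

import math

import numpy as np


def brute_force_kl(x1, x2, pseudo=0.5):
    """Exhaustive-loop reimplementation of the ensemble KL distance."""
    pooled = np.vstack([x1, x2])
    z = (pooled - pooled.mean(axis=0)) / np.where(
        pooled.std(axis=0) > 0, pooled.std(axis=0), 1.0)
    labels = [0] * len(x1) + [1] * len(x2)
    same = 0
    for i in range(len(z)):
        best, best_d = None, np.inf
        for j in range(len(z)):
            if j == i:
                continue
            d = math.sqrt(float(np.sum((z[i] - z[j]) ** 2)))
            if d < best_d:
                best, best_d = j, d
        same += labels[best] == labels[i]
    m = len(z)
    n1, n2 = len(x1), len(x2)
    p_null = (n1 * (n1 - 1) + n2 * (n2 - 1)) / (m * (m - 1))
    diff = m - same
    if same == 0 or diff == 0:
        p_obs = (same + pseudo) / (m + 2 * pseudo)
    else:
        p_obs = same / m
    return (p_obs * math.log(p_obs / p_null)
            + (1 - p_obs) * math.log((1 - p_obs) / (1 - p_null)))
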