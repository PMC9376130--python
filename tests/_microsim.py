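"""Independent individual-level microsimulation oracle.

Samples each newborn's path cycle by cycle from the same one-cycle
transition matrices the cohort trace multiplies through, so the cohort
trace's occupancy fractions can be checked against empirical state counts
without sharing any accumulation code with the engine.
"""

import numpy as np


def microsimulate(matrices: np.ndarray, n: int, seed: int, start_state: int = 0) -> np.ndarray:
    """State counts (horizon+1, n_states) of n individuals."""
    horizon, n_states, _ = matrices.shape
    rng = np.random.default_rng(seed)
    state = np.full(n, start_state, dtype=np.int64)
    counts = np.zeros((horizon + 1, n_states))
    counts[0, start_state] = n
    for k in range(horizon):
        cum = np.cumsum(matrices[k], axis=1)
        u = rng.random(n)
        state = (u[:, None] > cum[state]).sum(axis=1)
        counts[k + 1] = np.bincount(state, minlength=n_states)
    return counts


def max_z_vs_trace(occupancy: np.ndarray, counts: np.ndarray, n: int) -> float:
    """Largest |cohort fraction - empirical fraction| in Monte-Carlo SE units."""
    p = occupancy  # fractions (start mass 1)
    se = np.sqrt(np.maximum(p * (1.0 - p), 0.0) / n)
    err = np.abs(p - counts / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(err == 0.0, 0.0, err / np.maximum(se, 1e-300))
    return float(z.max())
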