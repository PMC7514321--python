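"""Shannon-level baselines: entropy, KL divergence, predictive and effective
information of a TPM.

All logarithms are base 2 and all results are in bits.  Effective information
treats the TPM perturbationally: a uniform distribution is imposed on the
prior state, so the measure reflects the causal constraints of the mechanisms
alone, independent of any observed state statistics.
"""

from __future__ import annotations

import numpy as np

from .tpm_core import Tpm

__all__ = ["entropy", "kld", "predictive_information", "effective_information"]


def entropy(dist: np.ndarray) -> float:
    """Shannon entropy ``-sum p log2 p`` in bits, with ``0 log2 0 := 0``."""
    p = np.asarray(dist, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-12):
        raise ValueError("input must be a probability distribution")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def kld(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence ``sum p log2 (p/q)`` in bits.

    Requires ``q > 0`` wherever ``p > 0``; otherwise the divergence is
    infinite and a ``ValueError`` is raised rather than returning ``inf``,
    since a repertoire comparison in this framework should never leave the
    support of the reference distribution.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share a support")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("infinite divergence: support of p not contained in q")
    return float((p[mask] * np.log2(p[mask] / q[mask])).sum())


def predictive_information(tpm: Tpm, prior: np.ndarray) -> float:
    """Mutual information ``I(V_{t-1}; V_t)`` under a given prior, in bits.

    Computed as the prior-weighted average KL divergence of each TPM row from
    the prior-weighted mixture of rows ``p(V_t)``.
    """
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (tpm.n_states,):
        raise ValueError("prior must be a distribution over the 2^n prior states")
    if abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < -1e-12):
        raise ValueError("prior must be a probability distribution")
    sbs = tpm.state_by_state
    mixture = prior @ sbs
    total = 0.0
    for r in np.flatnonzero(prior > 0):
        total += prior[r] * kld(sbs[r], mixture)
    return float(total)


def effective_information(tpm: Tpm) -> float:
    """Effective information ``EI(S)``: predictive information with a uniform
    prior imposed on the 2^n prior states, in bits."""
    uniform = np.full(tpm.n_states, 1.0 / tpm.n_states)
    return predictive_information(tpm, uniform)
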