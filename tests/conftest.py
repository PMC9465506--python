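"""Shared fixtures and independent oracles.

The oracle implementations here deliberately avoid the package's likelihood
code paths: history probabilities are computed by marginalising over the
latent death time, so agreement with the chi-recursion likelihood is a real
cross-check.
"""

from __future__ import annotations

import io
import itertools

import numpy as np
import pytest

from cjsdecline import RecordSet, read_records


@pytest.fixture
def small_csv() -> str:
    """Nine records, two species, six localities, years 1880-2010.

    Hand-countable: 4 records of Adscita statices; localities L1..L6;
    one blank year; 7 records inside 1900-2019 (dated, in-window)."""
    return (
        "species,locality_id,country,year\n"
        "Adscita statices,L1,Austria,1905\n"
        "Adscita statices,L1,Austria,1963\n"
        "Adscita statices,L2,Austria,1880\n"
        "Adscita statices,L3,Germany,2005\n"
        "Jordanita globulariae,L3,Germany,1985\n"
        "Jordanita globulariae,L4,Germany,1955\n"
        "Jordanita globulariae,L5,France,2010\n"
        "Jordanita globulariae,L6,France,\n"
        "Jordanita globulariae,L6,France,1930\n"
    )


@pytest.fixture
def small_records(small_csv) -> RecordSet:
    return read_records(io.StringIO(small_csv))


def direct_simulate_histories(n, T, phi, p, rng):
    """Minimal independent generator: Bernoulli survival chains plus
    Bernoulli detection, all entries at occasion 1."""
    phi = np.broadcast_to(np.asarray(phi, float), (T - 1,))
    p_occ = np.broadcast_to(np.asarray(p, float), (T,))
    alive = np.zeros((n, T), dtype=bool)
    alive[:, 0] = True
    for k in range(T - 1):
        alive[:, k + 1] = alive[:, k] & (rng.random(n) < phi[k])
    det = alive & (rng.random((n, T)) < p_occ[None, :])
    return det[det.any(axis=1)].astype(np.int8)


def oracle_history_logprob(h, phi, p) -> float:
    """P(history | first detection) by summing over the latent death time.

    ``p[k]`` is detection at occasion k+1 (the package's index convention),
    but the arithmetic here is plain forward products over the latent alive
    span — no chi recursion.
    """
    h = np.asarray(h)
    T = h.size
    det = np.flatnonzero(h)
    f, last = det[0], det[-1]
    total = 0.0
    for k in range(last, T):  # k = last occasion alive
        surv = np.prod([phi[i] for i in range(f, k)])
        if k < T - 1:
            surv *= 1.0 - phi[k]
        obs = 1.0
        for j in range(f + 1, T):
            if j <= k:
                obs *= p[j - 1] if h[j] else 1.0 - p[j - 1]
            elif h[j]:
                obs = 0.0
        total += surv * obs
    return float(np.log(total)) if total > 0 else -np.inf


def oracle_suffix_probs(T, f, phi, p):
    """Probabilities of all 2^(T-1-f) suffix histories after first detection
    at occasion f (0-based); should sum to one."""
    probs = {}
    for suffix in itertools.product([0, 1], repeat=T - 1 - f):
        h = np.zeros(T, dtype=int)
        h[f] = 1
        h[f + 1 :] = suffix
        lp = oracle_history_logprob(h, phi, p)
        probs[suffix] = 0.0 if lp == -np.inf else float(np.exp(lp))
    return probs
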