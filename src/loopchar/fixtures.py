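"""Random signed-network generator for oracle testing.

Produces specs for smooth networks in the d(f - x) form: random signed
Hill regulations, no self-edges, positive degradation rates drawn
log-uniformly from [0.1, 10]. All randomness flows through a single seeded
generator, so a spec is a pure function of (n, edge_prob, seed).
"""

from __future__ import annotations

import numpy as np

__all__ = ["random_network_spec"]


def random_network_spec(n: int, edge_prob: float = 0.5, seed: int = 0) -> dict:
    """Specification of a random signed regulatory network.

    Each ordered pair (i, j), i != j, carries an edge with probability
    ``edge_prob``; each edge is a Hill repression or activation with random
    ceiling, scale and integer coefficient. A species' incoming terms are
    summed; species with no input get a small constant production so the
    fixed point stays interior.
    """
    if not (2 <= n <= 12):
        raise ValueError("n must be between 2 and 12")
    if not (0 < edge_prob <= 1):
        raise ValueError("edge_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    species = [f"s{i+1}" for i in range(n)]
    degradation = {
        s: float(np.exp(rng.uniform(np.log(0.1), np.log(10.0)))) for s in species
    }
    production = {}
    for j, tgt in enumerate(species):
        terms = []
        for i, src in enumerate(species):
            if i == j or rng.random() >= edge_prob:
                continue
            kind = "hill_repress" if rng.random() < 0.5 else "hill_activate"
            terms.append(
                {
                    "kind": kind,
                    "inputs": [src],
                    "params": {
                        "v": float(rng.uniform(0.5, 3.0)),
                        "K": float(rng.uniform(0.5, 2.0)),
                        "h": float(rng.integers(1, 5)),
                    },
                }
            )
        if not terms:
            terms.append({"kind": "constant", "inputs": [], "params": {"c": float(rng.uniform(0.2, 1.0))}})
        production[tgt] = {"sum": terms} if len(terms) > 1 else terms[0]
    return {
        "name": f"random-n{n}-p{edge_prob}-seed{seed}",
        "species": species,
        "degradation": degradation,
        "production": production,
    }
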