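"""Goodness of fit via auxiliary statistics.

A fitted model is judged by whether simulated networks reproduce features
the estimation targets do not pin down directly: the indegree and
outdegree distributions and the triad census (counts of the 16
directed-triad isomorphism classes, 003 ... 300 in M-A-N notation).  The
observed auxiliary vector is compared with a simulated reference cloud by
Mahalanobis distance with a Monte-Carlo p-value.  Distributions are
emitted as tidy CSV; plotting is left to the caller.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from . import kernels

#: M-A-N labels of the 16 directed triad classes, in conventional order.
TRIAD_LABELS = ("003", "012", "102", "021D", "021U", "021C", "111D", "111U",
                "030T", "030C", "201", "120D", "120U", "120C", "210", "300")

_EDGES = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _canonical_class_table() -> np.ndarray:
    """Map each 6-bit triple edge code to its isomorphism class index.

    Built once by explicit canonicalisation over the 6 vertex permutations
    of one representative per class — independent of any closed-form
    census formula.  Edge bit k encodes _EDGES[k] among vertices (a, b, c)
    = (0, 1, 2).
    """
    def canon_of(code: int) -> int:
        adj3 = [[0] * 3 for _ in range(3)]
        for k, (a, b) in enumerate(_EDGES):
            if code >> k & 1:
                adj3[a][b] = 1
        return min(
            sum((1 << k)
                for k, (a, b) in enumerate(_EDGES) if adj3[p[a]][p[b]])
            for p in permutations(range(3))
        )

    # one representative triple per class, in TRIAD_LABELS order
    rep = {
        "003": 0,                    # empty
        "012": 1,                    # a->b
        "102": 3,                    # a<->b
        "021D": 1 | 4,               # a->b, a->c (out-star)
        "021U": 2 | 8,               # b->a, c->a (in-star)
        "021C": 1 | 16,              # a->b->c
        "111D": 3 | 32,              # a<->b, c->b
        "111U": 3 | 16,              # a<->b, b->c
        "030T": 1 | 4 | 16,          # a->b, a->c, b->c (transitive)
        "030C": 1 | 16 | 8,          # a->b->c->a (cycle)
        "201": 3 | 12,               # a<->b, a<->c
        "120D": 1 | 4 | 48,          # out-star plus b<->c
        "120U": 2 | 8 | 48,          # in-star plus b<->c
        "120C": 1 | 8 | 48,          # c->a->b plus b<->c
        "210": 3 | 4 | 48,           # a<->b, b<->c, a->c
        "300": 63,                   # complete
    }
    class_of_canon = {canon_of(code): i for i, code in enumerate(rep.values())}
    assert len(class_of_canon) == 16
    return np.array([class_of_canon[canon_of(code)] for code in range(64)],
                    dtype=np.int64)


_CLASS_TABLE = _canonical_class_table()


def triad_census(adjacency: np.ndarray) -> np.ndarray:
    """Counts of all C(n,3) unordered triples in the 16 directed-triad classes."""
    adj = np.ascontiguousarray(adjacency, dtype=np.int8)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("triad census needs at least 3 actors")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")
    return kernels.triad_census_kernel(adj, _CLASS_TABLE)


def degree_distributions(adjacency: np.ndarray, indegree_cap: int = 15,
                         outdegree_cap: int = kernels.CAP) -> tuple[np.ndarray, np.ndarray]:
    """Histograms of indegree (0..cap, top bin pooled) and outdegree (0..10)."""
    adj = np.asarray(adjacency)
    indeg = np.minimum(adj.sum(axis=0), indegree_cap)
    outdeg = np.minimum(adj.sum(axis=1), outdegree_cap)
    return (np.bincount(indeg, minlength=indegree_cap + 1),
            np.bincount(outdeg, minlength=outdegree_cap + 1))


def auxiliary_vector(adjacency: np.ndarray, indegree_cap: int = 15) -> np.ndarray:
    """Concatenated auxiliary statistics: indegree, outdegree, triad census."""
    ind, outd = degree_distributions(adjacency, indegree_cap=indegree_cap)
    return np.concatenate([ind, outd, triad_census(adjacency)]).astype(float)


def gof_test(observed_aux: np.ndarray,
             simulated_aux: np.ndarray) -> tuple[float, float]:
    """Mahalanobis distance of the observed auxiliary vector and MC p-value.

    The p-value is the proportion of simulated replicates at least as far
    from the simulated mean (under the simulated covariance, pseudo-inverted
    when rank-deficient) as the observation.
    """
    sims = np.asarray(simulated_aux, dtype=float)
    obs = np.asarray(observed_aux, dtype=float)
    R, q = sims.shape
    if R < q + 2:
        raise ValueError("need at least q + 2 simulated replicates")
    mean = sims.mean(axis=0)
    cov = np.atleast_2d(np.cov(sims, rowvar=False))
    prec = np.linalg.pinv(cov)
    d = obs - mean
    d_obs = float(np.sqrt(max(0.0, d @ prec @ d)))
    # reference distances are computed leave-one-out: a replicate helps
    # estimate the mean and covariance it is measured against, which biases
    # its in-sample distance low and the Monte-Carlo p-value toward zero
    d_sim = np.empty(R)
    for r in range(R):
        rest = np.delete(sims, r, axis=0)
        m_r = rest.mean(axis=0)
        p_r = np.linalg.pinv(np.atleast_2d(np.cov(rest, rowvar=False)))
        dr = sims[r] - m_r
        d_sim[r] = np.sqrt(max(0.0, dr @ p_r @ dr))
    p = float(np.mean(d_sim >= d_obs))
    return d_obs, p


def gof_frame(observed_aux: np.ndarray, simulated_aux: np.ndarray,
              names: list[str] | None = None) -> pd.DataFrame:
    """Tidy frame (replicate, statistic, value) with an observed-row flag."""
    sims = np.asarray(simulated_aux, dtype=float)
    q = sims.shape[1]
    names = names or [f"aux_{k}" for k in range(q)]
    rows = []
    for stat, name in enumerate(names):
        rows.append({"replicate": -1, "statistic": name,
                     "value": float(observed_aux[stat]), "observed": True})
        for r in range(sims.shape[0]):
            rows.append({"replicate": r, "statistic": name,
                         "value": sims[r, stat], "observed": False})
    return pd.DataFrame(rows)
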