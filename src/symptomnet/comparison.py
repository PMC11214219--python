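"""Permutation Network Comparison Test (NCT) for two groups.

Three hypotheses are tested by re-estimating both networks under random
relabelings of participants:

* global strength invariance: |sum of absolute edge weights| difference;
* network structure invariance: M = max absolute edge-weight difference;
* per-edge differences, with Holm correction by default.

Designs: independent groups (pooled labels reshuffled preserving group
sizes) or paired (each participant's two records swapped with probability
1/2, mirroring an admission/discharge comparison).  All p-values use the
add-one rule p = (#{null >= observed} + 1) / (iterations + 1).  Permuted
samples that produce a degenerate (constant) variable are rejected and
redrawn, with the rejection count reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ggm import PartialCorrelationNetwork
from .stability import _as_xy, _auto_method, _estimate, _method_code

__all__ = ["NCTResult", "global_strength", "nct"]


def global_strength(network) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    w = network.weights if isinstance(network, PartialCorrelationNetwork) else np.asarray(network)
    return float(np.abs(np.triu(w, 1)).sum())


@dataclass
class NCTResult:
    node_names: list[str]
    observed_strength_diff: float
    p_strength: float
    observed_structure_M: float
    p_structure: float
    edge_table: pd.DataFrame  # node_i, node_j, weight_a, weight_b, diff, p, p_corrected
    iterations: int
    paired: bool
    seed: int | None
    n_redraws: int
    correction: str
    weights_a: np.ndarray = field(repr=False, default=None)
    weights_b: np.ndarray = field(repr=False, default=None)

    def significant_edges(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.edge_table[self.edge_table["p_corrected"] < alpha]

    def as_dict(self) -> dict:
        return {
            "observed_strength_diff": self.observed_strength_diff,
            "p_strength": self.p_strength,
            "observed_structure_M": self.observed_structure_M,
            "p_structure": self.p_structure,
            "iterations": self.iterations,
            "paired": self.paired,
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "correction": self.correction,
            "edges": self.edge_table.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


def nct(
    group_a,
    group_b,
    iterations: int = 1000,
    paired: bool = False,
    seed: int | None = None,
    method: str | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    correction: str = "holm",
) -> NCTResult:
    """Two-group permutation network comparison.

    Networks are fully re-estimated (correlation -> EBIC-glasso with the
    penalty re-selected) for the observed groups and within every
    permutation.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    XA, names_a = _as_xy(group_a)
    XB, names_b = _as_xy(group_b)
    if names_a != names_b:
        raise ValueError("groups must share the same variables in the same order")
    if paired and XA.shape[0] != XB.shape[0]:
        raise ValueError("paired design requires equal group sizes")
    names = names_a
    p = XA.shape[1]
    method = method or _auto_method(np.vstack([XA, XB]))
    mcode = _method_code(method)

    wa = _estimate(XA, mcode, n_lambda, lambda_ratio, gamma)
    wb = _estimate(XB, mcode, n_lambda, lambda_ratio, gamma)
    if wa is None or wb is None:
        raise ValueError("degenerate variable in one of the groups")

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    obs_edges = np.array([abs(wa[i, j] - wb[i, j]) for i, j in pairs])
    obs_strength = abs(global_strength(wa) - global_strength(wb))
    obs_m = float(obs_edges.max()) if obs_edges.size else 0.0

    rng = np.random.default_rng(seed)
    nA, nB = XA.shape[0], XB.shape[0]
    pooled = np.vstack([XA, XB])
    null_strength = np.empty(iterations)
    null_m = np.empty(iterations)
    null_edges = np.empty((iterations, len(pairs)))
    redraws = 0
    max_redraws = 10 * iterations + 100
    it = 0
    while it < iterations:
        if paired:
            swap = rng.random(nA) < 0.5
            A2 = np.where(swap[:, None], XB, XA)
            B2 = np.where(swap[:, None], XA, XB)
        else:
            perm = rng.permutation(nA + nB)
            A2 = pooled[perm[:nA]]
            B2 = pooled[perm[nA:]]
        w1 = _estimate(np.ascontiguousarray(A2), mcode, n_lambda, lambda_ratio, gamma)
        w2 = _estimate(np.ascontiguousarray(B2), mcode, n_lambda, lambda_ratio, gamma)
        if w1 is None or w2 is None:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate permutations")
            continue
        diffs = np.array([abs(w1[i, j] - w2[i, j]) for i, j in pairs])
        null_edges[it] = diffs
        null_m[it] = diffs.max() if diffs.size else 0.0
        null_strength[it] = abs(global_strength(w1) - global_strength(w2))
        it += 1

    k = iterations
    p_strength = (np.sum(null_strength >= obs_strength - 1e-15) + 1.0) / (k + 1.0)
    p_m = (np.sum(null_m >= obs_m - 1e-15) + 1.0) / (k + 1.0)
    p_edges = (np.sum(null_edges >= obs_edges[None, :] - 1e-15, axis=0) + 1.0) / (k + 1.0)
    if correction == "none":
        p_corr = p_edges
    else:
        p_corr = multipletests(p_edges, method=correction)[1]

    edge_table = pd.DataFrame(
        {
            "node_i": [names[i] for i, _ in pairs],
            "node_j": [names[j] for _, j in pairs],
            "weight_a": [wa[i, j] for i, j in pairs],
            "weight_b": [wb[i, j] for i, j in pairs],
            "diff": obs_edges,
            "p": p_edges,
            "p_corrected": p_corr,
        }
    )
    return NCTResult(
        node_names=names,
        observed_strength_diff=float(obs_strength),
        p_strength=float(p_strength),
        observed_structure_M=obs_m,
        p_structure=float(p_m),
        edge_table=edge_table,
        iterations=iterations,
        paired=paired,
        seed=seed,
        n_redraws=redraws,
        correction=correction,
        weights_a=wa,
        weights_b=wb,
    )
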