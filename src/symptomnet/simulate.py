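"""Ground-truth networks and synthetic ordinal questionnaire data.

The generative model is the one the whole pipeline assumes: construct-level
latents follow a multivariate normal whose precision matrix encodes a known
sparse partial-correlation network; observed responses are discretizations
of those latents (or of item-level composites loading on them).

The study-shaped emulator mirrors a battery measuring five constructs in
n=207 adolescents: five scales with item counts {16, 20, 20, 20, 22} and
category counts {4, 7, 5, 5, 4}.  Its default truth network uses moderate
partial correlations (0.15-0.4) with a negative-perfectionism/rumination
hub and a cognitive-flexibility node whose ties are all negative —
qualitatively the pattern reported for such batteries, chosen as an
illustrative ground truth, not as estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import PartialCorrelationNetwork, precision_to_pcor
from .scales import CONSTRUCT_ORDER, InstrumentSchema, LikertResponseTable, ScaleScoreTable, study_schema

__all__ = [
    "TruthNetwork",
    "EmulatorSpec",
    "make_truth_network",
    "default_truth_network",
    "simulate_scores",
    "simulate_items",
]


@dataclass
class TruthNetwork:
    """A known sparse partial-correlation structure with its exact implied
    correlation matrix."""

    p: int
    structure: str
    weights: np.ndarray          # true partial correlations (zero diagonal)
    precision: np.ndarray        # the generating precision matrix
    correlation: np.ndarray      # implied correlation (from inverted precision)
    seed: int | None = None
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_names:
            self.node_names = [f"V{i + 1}" for i in range(self.p)]

    def as_network(self) -> PartialCorrelationNetwork:
        return PartialCorrelationNetwork(self.weights.copy(), list(self.node_names))

    @property
    def support(self) -> np.ndarray:
        return (self.weights != 0) & ~np.eye(self.p, dtype=bool)


def _finish_truth(theta: np.ndarray, structure: str, seed, names=None) -> TruthNetwork:
    p = theta.shape[0]
    min_eig = np.linalg.eigvalsh(theta)[0]
    if min_eig < 0.05:
        # inflate the diagonal just enough to make the precision comfortably PD
        theta = theta + (0.05 - min_eig) * np.eye(p)
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    net = precision_to_pcor(theta)
    return TruthNetwork(p, structure, net.weights, theta, corr, seed, list(names) if names else [])


def make_truth_network(
    p: int,
    structure: str = "chain",
    weight_magnitude: float = 0.3,
    negative_node: int | None = None,
    seed: int | None = None,
    edge_prob: float = 0.4,
    custom_weights: np.ndarray | None = None,
    node_names: list[str] | None = None,
) -> TruthNetwork:
    """Build a ground-truth network with a requested sparsity pattern.

    structure: ``chain`` (p-1 edges along 1-2-...-p), ``hub`` (node 0 tied
    to all others), ``random`` (each edge present with ``edge_prob``), or
    ``custom`` (pass ``custom_weights``, a symmetric zero-diagonal matrix of
    target partial correlations).  ``negative_node`` makes every edge of
    that node negative.  If the implied precision is not positive definite
    its diagonal is inflated, which shrinks the realized weights slightly
    below the requested magnitude; the returned ``weights`` are always the
    exact partial correlations of the final precision matrix.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not (0 <= weight_magnitude < 0.9):
        raise ValueError("weight_magnitude must be in [0, 0.9)")
    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    if structure == "chain":
        for i in range(p - 1):
            W[i, i + 1] = W[i + 1, i] = weight_magnitude
    elif structure == "hub":
        for j in range(1, p):
            W[0, j] = W[j, 0] = weight_magnitude
    elif structure == "random":
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < edge_prob:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    W[i, j] = W[j, i] = sign * weight_magnitude
    elif structure == "custom":
        if custom_weights is None:
            raise ValueError("custom structure requires custom_weights")
        W = np.asarray(custom_weights, dtype=float).copy()
        if not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
            raise ValueError("custom_weights must be symmetric with zero diagonal")
    else:
        raise ValueError(f"unknown structure {structure!r}")
    if negative_node is not None:
        W[negative_node, :] = -np.abs(W[negative_node, :])
        W[:, negative_node] = -np.abs(W[:, negative_node])
    theta = np.eye(p) - W  # unit-diagonal precision: theta_ij = -w_ij
    if np.linalg.eigvalsh(theta)[0] <= 0 and weight_magnitude >= 0.5:
        raise ValueError(
            "requested magnitudes do not admit a positive-definite precision; "
            "try a smaller weight_magnitude"
        )
    return _finish_truth(theta, structure, seed, node_names)


def default_truth_network() -> TruthNetwork:
    """The emulator's 5-construct truth: a negative-perfectionism/rumination
    hub, weaker procrastination ties, an all-negative cognitive-flexibility
    node and a weakly attached positive-perfectionism node."""
    names = list(CONSTRUCT_ORDER)
    i = {c: k for k, c in enumerate(names)}
    W = np.zeros((5, 5))

    def set_edge(a, b, v):
        W[i[a], i[b]] = W[i[b], i[a]] = v

    set_edge("NegativePerfectionism", "Rumination", 0.40)
    set_edge("Procrastination", "NegativePerfectionism", 0.25)
    set_edge("Procrastination", "Rumination", 0.20)
    set_edge("CognitiveFlexibility", "Procrastination", -0.30)
    set_edge("CognitiveFlexibility", "Rumination", -0.15)
    set_edge("PositivePerfectionism", "NegativePerfectionism", 0.15)
    return make_truth_network(5, "custom", 0.4, custom_weights=W, node_names=names)


def _equiprobable_discretize(z: np.ndarray, categories: int, lo: int = 1) -> np.ndarray:
    from scipy.special import ndtri

    cuts = ndtri(np.arange(1, categories) / categories)
    return (np.digitize(z, cuts) + lo).astype(float)


def simulate_scores(
    truth: TruthNetwork,
    n: int,
    categories: int = 0,
    seed: int | None = None,
    node_names: list[str] | None = None,
) -> ScaleScoreTable:
    """Draw n observations from the truth's implied correlation.

    ``categories = 0`` returns the continuous latents; ``categories >= 2``
    discretizes each variable through equiprobable standard-normal
    thresholds into codes 1..categories.
    """
    if n < truth.p + 1:
        raise ValueError("n must exceed p")
    if categories == 1:
        raise ValueError("categories must be 0 (continuous) or >= 2")
    if np.linalg.eigvalsh(truth.correlation)[0] <= 0:
        raise ValueError("implied correlation is not positive definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.correlation)
    Z = rng.standard_normal((n, truth.p)) @ L.T
    if categories >= 2:
        Z = _equiprobable_discretize(Z, categories)
    names = node_names or truth.node_names
    df = pd.DataFrame(Z, columns=names, index=[f"S{i + 1}" for i in range(n)])
    return ScaleScoreTable(df)


@dataclass
class EmulatorSpec:
    """Study-shaped generator configuration (defaults mirror the battery:
    n=207, five constructs, 98 items, instrument-specific category counts)."""

    n: int = 207
    truth: TruthNetwork = field(default_factory=default_truth_network)
    loading: float = 0.65
    schema: InstrumentSchema = field(default_factory=study_schema)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 < self.loading <= 1):
            raise ValueError("loading must be in (0, 1]")


def simulate_items(spec: EmulatorSpec) -> LikertResponseTable:
    """Generate a participant x item Likert table from the emulator spec.

    Construct latents are drawn from the truth network's implied
    correlation; each item is ``loading * latent + sqrt(1 - loading^2) *
    noise`` discretized through equiprobable thresholds into the item's
    category bounds.
    """
    rng = np.random.default_rng(spec.seed)
    subscales = spec.schema.subscales
    if spec.truth.p != len(subscales):
        raise ValueError("truth network size does not match schema subscale count")
    name_to_idx = {c: k for k, c in enumerate(spec.truth.node_names or subscales)}
    L = np.linalg.cholesky(spec.truth.correlation)
    latents = rng.standard_normal((spec.n, spec.truth.p)) @ L.T
    lam = spec.loading
    noise_sd = np.sqrt(1.0 - lam * lam)

    cols = {}
    for it in spec.schema.items:
        z = lam * latents[:, name_to_idx[it.subscale]]
        if noise_sd > 0:
            z = z + noise_sd * rng.standard_normal(spec.n)
        k = it.maximum - it.minimum + 1
        cols[it.item_id] = _equiprobable_discretize(z, k, lo=it.minimum) if k >= 2 else z
    arr = np.column_stack([cols[iid] for iid in spec.schema.item_ids])
    return LikertResponseTable(
        responses=arr,
        item_ids=list(spec.schema.item_ids),
        item_scale_map={it.item_id: it.subscale for it in spec.schema.items},
        category_bounds={it.item_id: (it.minimum, it.maximum) for it in spec.schema.items},
        participant_ids=[f"S{i + 1}" for i in range(spec.n)],
    )
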