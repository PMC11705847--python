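"""Synthetic community generators with known parameters.

Each generator is the generative inverse of one downstream estimator, so the
package carries its own parameter-recovery tests: the neutral sampler feeds
the neutral-model fit, the gradient-selection sampler feeds the phylogenetic
turnover index, the block-drift sampler feeds the taxonomic null model, and
the planted-module sampler feeds network module detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core_io import OtuTable, PhyloTree, SampleMetadata

__all__ = [
    "SimulationSpec",
    "simulate_tree",
    "simulate_neutral",
    "simulate_selection",
    "simulate_dispersal_limited",
    "simulate_modular_network_data",
]


@dataclass
class SimulationSpec:
    """Declarative description of one simulated dataset."""

    scenario: str
    n_taxa: int
    n_samples: int
    depth: int
    seed: int
    params: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _taxon_names(n: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree scaled to unit root-to-tip height.

    Lineages split at rate 1 per lineage with exponential waiting times; all
    tips are extant, so the tree is ultrametric by construction.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    # node bookkeeping: children lists and birth times; the root splits at
    # time 0 so every tip sits exactly one tree height from the root
    children: dict[int, list[int]] = {0: [1, 2], 1: [], 2: []}
    birth = {0: 0.0, 1: 0.0, 2: 0.0}
    active = [1, 2]
    t = 0.0
    next_id = 3
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        parent = active.pop(rng.integers(k))
        for _ in range(2):
            children[parent].append(next_id)
            children[next_id] = []
            birth[next_id] = t
            active.append(next_id)
            next_id += 1
    height = t + rng.exponential(1.0 / n_taxa)  # extend all tips to the present
    names = _taxon_names(n_taxa)
    # node creation order tracks topology (siblings get adjacent ids), so
    # names are assigned in random order to keep labels exchangeable
    order = rng.permutation(n_taxa)
    tip_name = {node: names[order[i]] for i, node in enumerate(sorted(active))}

    # a node's outgoing branch spans its own split time to its children's
    # split time (or the present for tips); children share a birth time
    def newick(node: int, parent_birth: float) -> str:
        if not children[node]:
            return f"{tip_name[node]}:{(height - parent_birth) / height:.12f}"
        child_birth = birth[children[node][0]]
        inner = ",".join(newick(c, child_birth) for c in children[node])
        if node == 0:
            return f"({inner});"
        return f"({inner}):{(child_birth - parent_birth) / height:.12f}"

    return PhyloTree.from_newick(newick(0, 0.0))


def _metacommunity_abundances(n_taxa: int, decay: float = 5.0) -> np.ndarray:
    """Geometric (log-series-like) rank abundance distribution, sums to 1."""
    ranks = np.arange(n_taxa)
    p = np.exp(-decay * ranks / n_taxa)
    return p / p.sum()


def simulate_neutral(
    n_taxa: int,
    n_samples: int,
    depth: int,
    Nm_true: float,
    seed: int,
) -> tuple[OtuTable, np.ndarray]:
    """Stationary Sloan-style neutral sampling.

    Metacommunity relative abundances ``p`` follow a geometric rank curve;
    each sample's latent composition is drawn component-wise from
    Beta(Nm*p_i, Nm*(1-p_i)). A taxon is present when its latent abundance
    clears the detection limit d = 1/depth — exactly the detection rule the
    occurrence-frequency fit inverts — and reads are then allocated among
    present taxa proportionally to their latent abundances (each present
    taxon keeps at least one read). Returns the table and ``p``.
    """
    if Nm_true <= 0:
        raise ValueError("Nm_true must be positive")
    p = _metacommunity_abundances(n_taxa)
    if (p >= 1).any():
        raise ValueError("degenerate metacommunity: some p_i >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    a = Nm_true * p
    b = Nm_true * (1.0 - p)
    d = 1.0 / depth
    for j in range(n_samples):
        latent = rng.beta(a, b)
        present = latent > d
        k = int(present.sum())
        if k == 0:  # pragma: no cover - vanishingly unlikely
            present[np.argmax(latent)] = True
            k = 1
        x = latent[present]
        counts[present, j] = rng.multinomial(depth - k, x / x.sum()) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare taxa may never be sampled
        table = OtuTable(counts, _taxon_names(n_taxa), _sample_names(n_samples))
    return table, p


def _sample_names(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def brownian_traits(tree: PhyloTree, rate: float, seed: int) -> dict[str, float]:
    """Evolve a trait along the tree by Brownian motion (root value 0)."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    tip_values: dict[str, float] = {}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(rate * bl)
            )
        if node.is_leaf():
            tip_values[node.taxon.label] = values[id(node)]
    return tip_values


def simulate_selection(
    tree: PhyloTree,
    n_samples: int,
    depth: int,
    niche_sd: float,
    env_range: tuple[float, float] = (-2.0, 2.0),
    trait_rate: float = 4.0,
    seed: int = 0,
    env_values: np.ndarray | None = None,
    sample_noise_sd: float = 1.0,
) -> tuple[OtuTable, SampleMetadata]:
    """Deterministic (niche-based) assembly along an environmental gradient.

    Niche optima evolve on the tree by Brownian motion, so they are
    phylogenetically conserved; expected abundance of taxon i in sample j is
    proportional to a Gaussian kernel exp(-(env_j - opt_i)^2 / (2 niche_sd^2)),
    jittered by per-sample lognormal noise (`sample_noise_sd` on the log
    scale) so replicate samples at the same environment draw different
    members of the same clade rather than identical communities. By default
    sample environments are split evenly between the two ends of `env_range`
    (pass `env_values` for an arbitrary design).
    """
    if niche_sd <= 0:
        raise ValueError("niche_sd must be positive")
    if tree.n_tips < 3:
        raise ValueError("tree must have >= 3 tips")
    rng = np.random.default_rng(seed)
    optima_map = brownian_traits(tree, trait_rate, seed=int(rng.integers(2**31)))
    taxa = tree.tip_labels
    optima = np.asarray([optima_map[t] for t in taxa])
    if env_values is None:
        lo, hi = env_range
        env = np.asarray([lo] * (n_samples // 2) + [hi] * (n_samples - n_samples // 2))
    else:
        env = np.asarray(env_values, dtype=float)
        if env.shape != (n_samples,):
            raise ValueError("env_values must have length n_samples")
    log_kernel = -((env[None, :] - optima[:, None]) ** 2) / (2 * niche_sd**2)
    noise = rng.normal(0.0, sample_noise_sd, size=log_kernel.shape)
    weights = np.exp(log_kernel + noise)
    counts = np.zeros((len(taxa), n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = weights[:, j]
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("no taxon has support at some environment value")
        counts[:, j] = rng.multinomial(depth, w / total)
    sample_ids = _sample_names(n_samples)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "env": env,
                "group": [f"env_{'lo' if e <= np.median(env) else 'hi'}" for e in env],
            }
        )
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = OtuTable(counts, taxa, sample_ids)
    return table, meta


def simulate_dispersal_limited(
    n_taxa: int,
    n_blocks: int,
    samples_per_block: int,
    depth: int,
    drift_strength: float,
    seed: int,
) -> tuple[OtuTable, SampleMetadata]:
    """Spatially structured drift with no selection and no phylogenetic signal.

    Every block inherits a shared ancestral composition and drifts away from
    it multiplicatively on the log scale (block-level shift of magnitude
    `drift_strength`), with weak within-block sample noise. Strong drift
    makes between-block pairs look dispersal-limited and within-block pairs
    homogenized.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if drift_strength <= 0:
        raise ValueError("drift_strength must be positive")
    rng = np.random.default_rng(seed)
    ancestor = np.log(_metacommunity_abundances(n_taxa))
    n_samples = n_blocks * samples_per_block
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    sample_ids = []
    blocks = []
    j = 0
    for b in range(n_blocks):
        block_shift = rng.normal(0.0, drift_strength, size=n_taxa)
        for s in range(samples_per_block):
            noise = rng.normal(0.0, drift_strength / 20.0, size=n_taxa)
            w = np.exp(ancestor + block_shift + noise)
            counts[:, j] = rng.multinomial(depth, w / w.sum())
            sample_ids.append(f"B{b + 1}_S{s + 1:02d}")
            blocks.append(f"block_{b + 1}")
            j += 1
    meta = SampleMetadata(pd.DataFrame({"sample_id": sample_ids, "block": blocks}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = OtuTable(counts, _taxon_names(n_taxa), sample_ids)
    return table, meta


def simulate_modular_network_data(
    n_modules: int,
    taxa_per_module: int,
    n_samples: int,
    rho_within: float,
    seed: int,
    depth: int = 10_000,
) -> OtuTable:
    """Block-correlated abundances: a planted-partition generator.

    Taxa in a module share a latent Gaussian factor with loading
    sqrt(rho_within), so within-module pairwise (rank) correlation is about
    `rho_within` while across-module taxa are independent. Latents map to
    counts by exponentiation and multinomial sampling at `depth`.
    """
    if not (0 <= rho_within < 1):
        raise ValueError("rho_within must be in [0, 1)")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    n_taxa = n_modules * taxa_per_module
    factors = rng.normal(size=(n_modules, n_samples))
    eps = rng.normal(size=(n_taxa, n_samples))
    module_of = np.repeat(np.arange(n_modules), taxa_per_module)
    latent = np.sqrt(rho_within) * factors[module_of] + np.sqrt(1 - rho_within) * eps
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        w = np.exp(latent[:, j])
        counts[:, j] = rng.multinomial(depth, w / w.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return OtuTable(counts, _taxon_names(n_taxa), _sample_names(n_samples))
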