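"""Null models partitioning community assembly into ecological processes.

Phylogenetic turnover (beta mean-nearest-taxon distance) is standardized
against a tip-shuffle null to give the beta nearest-taxon index; taxonomic
turnover is standardized by a Raup-Crick permutation of Bray-Curtis
dissimilarity. Pairs are then classified into heterogeneous selection (HeS),
homogeneous selection (HoS), dispersal limitation (DL), homogenizing
dispersal (HD) and drift (DR), and a phylogenetic normalized stochasticity
ratio summarizes per-group stochasticity on a 0-1 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import DistanceMatrix, OtuTable, PhyloTree

__all__ = [
    "cophenetic",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "classify_processes",
    "pnst",
    "AssemblyResult",
    "NstResult",
    "PROCESSES",
]

PROCESSES = ("HeS", "HoS", "DL", "HD", "DR")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def cophenetic(tree: PhyloTree, taxa=None) -> DistanceMatrix:
    """Patristic distances between tree tips (thin wrapper for symmetry with
    the rest of the module's API)."""
    return tree.cophenetic(taxa)


def _abundance_weights(table: OtuTable, weighted: bool) -> np.ndarray:
    if weighted:
        return table.relative_abundance()
    pres = table.presence()
    richness = pres.sum(axis=0).astype(float)
    return pres / richness


def _bmntd_from_arrays(
    weights: np.ndarray, presence: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """beta-MNTD for all sample pairs.

    weights: taxa x samples (zero where absent); presence: boolean taxa x
    samples; d: taxa x taxa phylogenetic distances. For pair (k, l):
    0.5 * (sum_i w_ik min_{j in l} d_ij + sum_j w_jl min_{i in k} d_ji).
    """
    n_taxa, n_samples = weights.shape
    # nearest[i, l] = min distance from taxon i to any taxon present in l
    nearest = np.empty((n_taxa, n_samples))
    for l in range(n_samples):
        nearest[:, l] = d[:, presence[:, l]].min(axis=1)
    a = weights.T @ nearest  # a[k, l] = sum_i w_ik * nearest[i, l]
    out = 0.5 * (a + a.T)
    np.fill_diagonal(out, 0.0)
    return out


def bmntd(
    table: OtuTable, phylo_dist: DistanceMatrix, weighted: bool = True
) -> DistanceMatrix:
    """Abundance-weighted beta mean nearest taxon distance between samples."""
    missing = set(table.taxon_ids) - set(phylo_dist.ids)
    if missing:
        raise ValueError(f"taxa absent from phylogenetic distances: {sorted(missing)[:5]}")
    if (table.sample_totals() == 0).any():
        raise ValueError("empty community")
    d = phylo_dist.submatrix(table.taxon_ids).data
    w = _abundance_weights(table, weighted)
    out = _bmntd_from_arrays(w, table.presence(), d)
    return DistanceMatrix(out, list(table.sample_ids))


def _null_bmntd_stack(
    weights: np.ndarray,
    presence: np.ndarray,
    d: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null beta-MNTD distributions from shuffling taxon labels across tips.

    Permuting tip labels is equivalent to conjugating the distance matrix by
    a permutation, which is applied here to the taxon axis of the table.
    """
    n_taxa = d.shape[0]
    stack = np.empty((n_null, weights.shape[1], weights.shape[1]))
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        stack[r] = _bmntd_from_arrays(weights[perm], presence[perm], d)
    return stack


def bnti(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    phylo_dist: DistanceMatrix | None = None,
) -> DistanceMatrix:
    """Beta nearest taxon index: (observed - null mean) / null sd per pair.

    The null shuffles taxon labels across the tips of the tree pruned to the
    table's taxa ("taxa.labels" convention). Pairs with zero null variance
    are undefined (NaN, with a warning).
    """
    if n_null < 100:
        warnings.warn("n_null < 100 gives an unstable null sd", stacklevel=2)
    if phylo_dist is None:
        phylo_dist = tree.cophenetic(table.taxon_ids)
    d = phylo_dist.submatrix(table.taxon_ids).data
    w = _abundance_weights(table, weighted)
    pres = table.presence()
    obs = _bmntd_from_arrays(w, pres, d)
    rng = np.random.default_rng(seed)
    stack = _null_bmntd_stack(w, pres, d, n_null, rng)
    null_mean = stack.mean(axis=0)
    null_sd = stack.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - null_mean) / null_sd
    z[null_sd == 0] = np.nan
    np.fill_diagonal(z, 0.0)
    n_undef = int(np.isnan(z[np.triu_indices(z.shape[0], 1)]).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} pairs have zero-variance nulls; beta-NTI undefined",
            stacklevel=2,
        )
    # standardized scores are not distances; wrap without sign constraint
    return DistanceMatrix.unchecked(z, table.sample_ids)


def _null_communities(
    richness: np.ndarray,
    totals: np.ndarray,
    occupancy_w: np.ndarray,
    abundance_w: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One null realization per sample: draw the observed richness of taxa
    with probability proportional to regional occupancy (Gumbel top-k
    weighted sampling without replacement), then fill to the observed total
    with probabilities proportional to regional relative abundance."""
    n_taxa = len(occupancy_w)
    n_samples = len(richness)
    out = np.zeros((n_samples, n_taxa), dtype=np.int64)
    logw = np.log(occupancy_w)
    for s in range(n_samples):
        keys = logw + rng.gumbel(size=n_taxa)
        chosen = np.argpartition(keys, -richness[s])[-richness[s]:]
        probs = abundance_w[chosen]
        probs = probs / probs.sum()
        k = richness[s]
        # one individual per chosen taxon guarantees the drawn richness
        counts = rng.multinomial(totals[s] - k, probs) + 1
        out[s, chosen] = counts
    return out


def raup_crick_bray(
    table: OtuTable, n_null: int = 999, seed: int = 0
) -> DistanceMatrix:
    """Raup-Crick standardized Bray-Curtis dissimilarity in [-1, 1].

    RC = ((#{null < obs} + 0.5 #{null = obs}) / n_null - 0.5) * 2, with the
    null assembling each community at its observed richness and total
    abundance from the regional pool.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    counts = table.counts.T.astype(float)  # samples x taxa
    obs_bc = squareform(pdist(counts, metric="braycurtis"))
    richness = table.presence().sum(axis=0)
    totals = table.sample_totals()
    occupancy = table.presence().sum(axis=1).astype(float)
    regional = table.taxon_totals().astype(float)
    rng = np.random.default_rng(seed)
    n = table.n_samples
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    for _ in range(n_null):
        null = _null_communities(richness, totals, occupancy, regional, rng)
        null_bc = squareform(pdist(null.astype(float), metric="braycurtis"))
        less += null_bc < obs_bc - 1e-12
        equal += np.abs(null_bc - obs_bc) <= 1e-12
    rc = ((less + 0.5 * equal) / n_null - 0.5) * 2.0
    np.fill_diagonal(rc, 0.0)
    return DistanceMatrix.unchecked(np.clip(rc, -1.0, 1.0), table.sample_ids)


@dataclass
class AssemblyResult:
    pairs: pd.DataFrame          # sample_a, sample_b, bnti, rc_bray, process
    fractions: dict[str, float]  # over classified pairs; sums to 1
    counts: dict[str, int]
    n_excluded: int              # pairs with undefined beta-NTI
    metadata: dict = field(default_factory=dict)

    def fractions_by_group(self, groups: dict[str, str]) -> dict:
        """Process fractions restricted to within-group pairs, per group."""
        out = {}
        df = self.pairs.dropna(subset=["process"])
        ga = df["sample_a"].map(groups)
        gb = df["sample_b"].map(groups)
        for g in sorted(set(groups.values())):
            sub = df[(ga == g) & (gb == g)]
            if len(sub) == 0:
                continue
            out[g] = {p: float((sub["process"] == p).mean()) for p in PROCESSES}
        return out


def classify_processes(bnti_mat: DistanceMatrix, rc_mat: DistanceMatrix) -> AssemblyResult:
    """Five-process classification per community pair.

    beta-NTI > +2 -> HeS; beta-NTI < -2 -> HoS; otherwise RC > +0.95 -> DL;
    RC < -0.95 -> HD; |RC| <= 0.95 -> DR. Selection takes precedence over
    the Raup-Crick split. Pairs with undefined beta-NTI are excluded from
    the fractions and counted.
    """
    if bnti_mat.ids != rc_mat.ids:
        raise ValueError("beta-NTI and RC matrices must share sample order")
    ids = bnti_mat.ids
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            b = bnti_mat.data[i, j]
            r = rc_mat.data[i, j]
            if np.isnan(b):
                proc = None
            elif b > BNTI_THRESHOLD:
                proc = "HeS"
            elif b < -BNTI_THRESHOLD:
                proc = "HoS"
            elif r > RC_THRESHOLD:
                proc = "DL"
            elif r < -RC_THRESHOLD:
                proc = "HD"
            else:
                proc = "DR"
            rows.append(
                {"sample_a": ids[i], "sample_b": ids[j], "bnti": b, "rc_bray": r, "process": proc}
            )
    df = pd.DataFrame(rows)
    classified = df.dropna(subset=["process"])
    n_excluded = len(df) - len(classified)
    counts = {p: int((classified["process"] == p).sum()) for p in PROCESSES}
    total = max(len(classified), 1)
    fractions = {p: counts[p] / total for p in PROCESSES}
    return AssemblyResult(
        pairs=df,
        fractions=fractions,
        counts=counts,
        n_excluded=n_excluded,
        metadata={
            "bnti_threshold": BNTI_THRESHOLD,
            "rc_threshold": RC_THRESHOLD,
            "partition_level": "whole-community pairs (no per-clade binning)",
        },
    )


@dataclass
class NstResult:
    pair_stochasticity: pd.DataFrame  # sample_a, sample_b, group, mst
    group_pnst: dict[str, float]
    comparison: dict | None
    metadata: dict = field(default_factory=dict)


def pnst(
    table: OtuTable,
    tree: PhyloTree,
    groups: np.ndarray,
    n_null: int = 999,
    seed: int = 0,
    phylo_dist: DistanceMatrix | None = None,
) -> NstResult:
    """Phylogenetic normalized stochasticity ratio per group.

    Uses beta-MNTD as the dissimilarity with the same tip-shuffle null as
    the beta-NTI computation, and the modified stochasticity-ratio (MST)
    normalization: with observed dissimilarity G, null mean E and the
    dataset-wide maximum Dmax,
      MST = (Dmax - G) / (Dmax - E)   if G >= E (divergent side)
      MST = G / E                     if G <  E (convergent side)
    so 1 = fully stochastic and 0 = fully deterministic. Group pNST is the
    mean MST over that group's within-group pairs.
    """
    labels = np.asarray(groups)
    if labels.shape[0] != table.n_samples:
        raise ValueError("group labels must align with samples")
    uniq, cnt = np.unique(labels, return_counts=True)
    small = uniq[cnt < 3]
    if len(small):
        raise ValueError(f"groups with < 3 samples: {list(small)}")
    if phylo_dist is None:
        phylo_dist = tree.cophenetic(table.taxon_ids)
    d = phylo_dist.submatrix(table.taxon_ids).data
    w = _abundance_weights(table, weighted=True)
    pres = table.presence()
    obs = _bmntd_from_arrays(w, pres, d)
    rng = np.random.default_rng(seed)
    stack = _null_bmntd_stack(w, pres, d, n_null, rng)
    e = stack.mean(axis=0)
    iu = np.triu_indices(table.n_samples, 1)
    dmax = max(float(obs[iu].max()), float(stack[:, iu[0], iu[1]].max()))
    rows = []
    per_group: dict[str, list[float]] = {str(g): [] for g in uniq}
    for i, j in zip(*iu):
        if labels[i] != labels[j]:
            continue
        g_obs, e_ij = obs[i, j], e[i, j]
        if g_obs >= e_ij:
            mst = (dmax - g_obs) / (dmax - e_ij) if dmax > e_ij else 1.0
        else:
            mst = g_obs / e_ij if e_ij > 0 else 1.0
        mst = float(np.clip(mst, 0.0, 1.0))
        rows.append(
            {
                "sample_a": table.sample_ids[i],
                "sample_b": table.sample_ids[j],
                "group": str(labels[i]),
                "mst": mst,
            }
        )
        per_group[str(labels[i])].append(mst)
    group_pnst = {g: float(np.mean(v)) for g, v in per_group.items() if v}
    comparison = None
    if len(uniq) == 2:
        from .diversity import group_compare

        vals = np.asarray([r["mst"] for r in rows])
        labs = np.asarray([r["group"] for r in rows])
        if all((labs == str(g)).sum() >= 2 for g in uniq):
            comparison = group_compare(vals, labs, design="two_group")
    return NstResult(
        pair_stochasticity=pd.DataFrame(rows),
        group_pnst=group_pnst,
        comparison=comparison,
        metadata={
            "dissimilarity": "beta-MNTD (abundance-weighted)",
            "null": "tip-label shuffle",
            "variant": "MST (modified stochasticity ratio) normalization",
            "n_null": n_null,
            "seed": seed,
        },
    )
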