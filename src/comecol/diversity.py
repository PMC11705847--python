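"""Alpha/beta diversity, ordination, group tests, SIMPER, niche breadth."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DistanceMatrix, OtuTable, ValidationError

__all__ = [
    "shannon",
    "rclr_aitchison_dist",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
    "simper",
    "levins_breadth",
    "community_breadth",
    "group_compare",
]


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p over positive entries (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero vector has undefined Shannon index")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def rclr_transform(table: OtuTable) -> np.ndarray:
    """Robust clr per sample: ln x centered on the mean log of that sample's
    nonzero counts; zeros become NaN (treated as missing, not imputed)."""
    x = table.counts.astype(float)
    logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
    mean_log = np.nanmean(logx, axis=0, keepdims=True)
    return logx - mean_log


def rclr_aitchison_dist(table: OtuTable) -> DistanceMatrix:
    """Robust Aitchison distance between samples.

    Euclidean distance between rclr vectors over the taxa nonzero in BOTH
    samples, rescaled by sqrt(n_taxa / n_shared) to correct for overlap size.
    Pairs sharing fewer than 2 taxa are undefined (NaN, with a warning).
    """
    present = table.presence()
    if (present.sum(axis=0) < 2).any():
        raise ValidationError("every sample needs >= 2 nonzero taxa for rclr")
    r = rclr_transform(table)
    n_taxa, n_samples = table.shape
    d = np.zeros((n_samples, n_samples))
    undefined = []
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            shared = present[:, i] & present[:, j]
            n_shared = int(shared.sum())
            if n_shared < 2:
                undefined.append((table.sample_ids[i], table.sample_ids[j]))
                d[i, j] = d[j, i] = np.nan
                continue
            diff = r[shared, i] - r[shared, j]
            d[i, j] = d[j, i] = np.sqrt((diff**2).sum() * n_taxa / n_shared)
    if undefined:
        warnings.warn(
            f"{len(undefined)} sample pairs share < 2 taxa; distances undefined",
            stacklevel=2,
        )
    return DistanceMatrix(d, list(table.sample_ids))


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    sample_ids: list[str]


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric MDS of a distance matrix.

    Negative eigenvalues are zeroed before computing proportions explained,
    so reported proportions are non-negative and sum to <= 1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.isnan(dist.data).any():
        raise ValidationError("distance matrix contains undefined entries")
    n = dist.n
    d2 = dist.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating k from {k}", stacklevel=2
        )
        k = max(n_pos, 1)
    clipped = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(clipped[:k])
    total = clipped.sum()
    prop = clipped[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(coords, eigval[:k], prop, list(dist.ids))


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    groups = np.unique(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with whole-sample label permutation."""
    labels = np.asarray(groups)
    if labels.shape[0] != dist.n:
        raise ValueError("group labels must align with the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    for g, c in zip(uniq, counts):
        if c < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if np.isnan(dist.data).any():
        raise ValidationError("distance matrix contains undefined entries")
    d2 = dist.data**2
    f_obs, r2 = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_f(d2, perm)
        if f_perm >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def simper(table: OtuTable, groups: np.ndarray) -> pd.DataFrame:
    """Per-taxon decomposition of mean between-group Bray-Curtis.

    For each between-group sample pair the contribution of taxon k is
    |p_ik - p_jk| / sum_k (p_ik + p_jk) on relative abundances; contributions
    are averaged over all between-group pairs and reported with percentage
    and cumulative percentage, sorted descending.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("simper compares exactly 2 groups per call")
    rel = table.relative_abundance()
    ia = np.flatnonzero(labels == uniq[0])
    ib = np.flatnonzero(labels == uniq[1])
    contribs = np.zeros(table.n_taxa)
    n_pairs = 0
    for i in ia:
        for j in ib:
            denom = (rel[:, i] + rel[:, j]).sum()
            contribs += np.abs(rel[:, i] - rel[:, j]) / denom
            n_pairs += 1
    contribs /= n_pairs
    total = contribs.sum()
    df = pd.DataFrame(
        {
            "taxon": table.taxon_ids,
            "mean_contrib": contribs,
            "pct": 100 * contribs / total,
        }
    ).sort_values("mean_contrib", ascending=False, kind="mergesort")
    df["cum_pct"] = df["pct"].cumsum()
    return df.reset_index(drop=True)


def levins_breadth(table: OtuTable) -> pd.DataFrame:
    """Levins niche breadth B = 1 / sum_i P_i^2 per taxon, with P_i the
    share of the taxon's total count found in sample i."""
    totals = table.taxon_totals().astype(float)
    p = table.counts / totals[:, None]
    b = 1.0 / (p**2).sum(axis=1)
    return pd.DataFrame({"taxon": table.taxon_ids, "breadth": b})


def community_breadth(table: OtuTable, groups: np.ndarray) -> dict:
    """Community-level niche breadth per sample group: the abundance-weighted
    mean of per-taxon Levins breadth within each group's samples."""
    b = levins_breadth(table)["breadth"].to_numpy()
    labels = np.asarray(groups)
    rel = table.relative_abundance()
    out = {}
    for g in np.unique(labels):
        w = rel[:, labels == g].mean(axis=1)
        out[g] = float((b * w).sum() / w.sum())
    return out


def _dunn_test(values: np.ndarray, labels: np.ndarray, adjust: str) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction."""
    ranks = stats.rankdata(values)
    n = len(values)
    uniq = np.unique(labels)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    rows = []
    k = len(uniq)
    n_comp = k * (k - 1) // 2
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            ga, gb = uniq[a_i], uniq[b_i]
            ra = ranks[labels == ga]
            rb = ranks[labels == gb]
            na, nb = len(ra), len(rb)
            se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / na + 1 / nb))
            z = (ra.mean() - rb.mean()) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * n_comp, 1.0)
    elif adjust == "bh":
        order = np.argsort(df["p_raw"].to_numpy())
        p_sorted = df["p_raw"].to_numpy()[order]
        m = len(p_sorted)
        adj = np.minimum.accumulate((p_sorted * m / np.arange(1, m + 1))[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        df["p_adj"] = out
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    design: str = "two_group",
    adjust: str = "bonferroni",
) -> dict:
    """Rank-based group comparison.

    two_group: Wilcoxon rank-sum (Mann-Whitney) two-sided test.
    multi_group: Kruskal-Wallis H plus all pairwise Dunn z tests with
    multiplicity-adjusted p-values. Significance stars at 0.05/0.01/0.001.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise ValueError(f"groups with < 2 observations: {list(bad)}")
    if design == "two_group":
        if len(uniq) != 2:
            raise ValueError("two_group design needs exactly 2 labels")
        a = values[labels == uniq[0]]
        b = values[labels == uniq[1]]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {
            "test": "wilcoxon_rank_sum",
            "statistic": float(stat),
            "p_value": float(p),
            "stars": _stars(p),
        }
    if design == "multi_group":
        if len(uniq) < 3:
            raise ValueError("multi_group design needs >= 3 labels")
        samples = [values[labels == g] for g in uniq]
        h, p = stats.kruskal(*samples)
        dunn = _dunn_test(values, labels, adjust)
        dunn["stars"] = dunn["p_adj"].map(_stars)
        return {
            "test": "kruskal_wallis",
            "statistic": float(h),
            "p_value": float(p),
            "stars": _stars(p),
            "posthoc": dunn,
        }
    raise ValueError(f"unknown design {design!r}")
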