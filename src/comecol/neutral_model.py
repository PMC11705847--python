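"""Sloan neutral community model: fit, bootstrap CIs, prediction bands.

The model predicts an OTU's occurrence frequency across samples from its
mean relative abundance via F(p; m) = 1 - BetaCDF(d; N m p, N m (1-p)),
with N the mean sample depth and detection limit d = 1/N. The migration
probability m is estimated by bounded least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import OtuTable

__all__ = ["NcmFit", "fit_ncm", "ncm_bootstrap", "ncm_partition", "predicted_frequency"]


def predicted_frequency(p: np.ndarray, m: float, N: float) -> np.ndarray:
    """Neutral expectation of occurrence frequency at mean abundance p."""
    p = np.asarray(p, dtype=float)
    d = 1.0 / N
    return 1.0 - stats.beta.cdf(d, N * m * p, N * m * (1.0 - p))


@dataclass
class NcmFit:
    m: float
    N: float
    Nm: float
    r2: float
    p_mean: np.ndarray          # per-OTU mean relative abundance
    freq_obs: np.ndarray        # per-OTU occurrence frequency
    freq_pred: np.ndarray
    taxon_ids: list[str]
    n_samples: int
    ci: dict | None = None      # filled by ncm_bootstrap
    band: dict | None = None    # lower/upper curve CI at each p, via bootstrap
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "taxon": self.taxon_ids,
                "p_mean": self.p_mean,
                "freq_obs": self.freq_obs,
                "freq_pred": self.freq_pred,
            }
        )
        if self.band is not None:
            df["pred_lower"] = self.band["lower"]
            df["pred_upper"] = self.band["upper"]
        if self.labels is not None:
            df["band"] = self.labels
        return df


def _fit_m(p: np.ndarray, f: np.ndarray, N: float) -> float:
    def sse(m: float) -> float:
        resid = f - predicted_frequency(p, m, N)
        return float((resid**2).sum())

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    if not np.isfinite(res.fun):
        raise RuntimeError(f"neutral-model fit failed: SSE not finite (m={res.x})")
    return float(res.x)


def fit_ncm(table: OtuTable, min_samples: int = 10, min_taxa: int = 20) -> NcmFit:
    """Least-squares fit of the neutral occurrence-frequency curve."""
    if table.n_samples < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    if table.n_taxa < min_taxa:
        raise ValueError(f"need >= {min_taxa} taxa")
    rel = table.relative_abundance()
    p = rel.mean(axis=1)
    f = table.presence().mean(axis=1)
    N = float(table.sample_totals().mean())
    m = _fit_m(p, f, N)
    pred = predicted_frequency(p, m, N)
    sse = float(((f - pred) ** 2).sum())
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn(
            "saturated occupancy: every OTU occurs in every sample", stacklevel=2
        )
        r2 = 0.0 if sse == 0 else -np.inf
    else:
        r2 = 1.0 - sse / sst
    return NcmFit(
        m=m,
        N=N,
        Nm=N * m,
        r2=r2,
        p_mean=p,
        freq_obs=f,
        freq_pred=pred,
        taxon_ids=list(table.taxon_ids),
        n_samples=table.n_samples,
    )


def _wilson(freq: np.ndarray, n: int, z: float = 1.959963984540054) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion estimated from n samples."""
    freq = np.clip(np.asarray(freq, dtype=float), 0.0, 1.0)
    denom = 1.0 + z**2 / n
    center = (freq + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(freq * (1 - freq) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def ncm_bootstrap(
    table: OtuTable,
    reps: int = 1000,
    seed: int = 0,
    fit: NcmFit | None = None,
    max_failure_rate: float = 0.1,
) -> NcmFit:
    """Bootstrap (resampling OTUs with replacement) 95% CIs for m, Nm, R2
    and the frequency curve.

    The curve band at each OTU's abundance combines the bootstrap spread of
    the fitted curve with the Wilson interval for an occupancy estimated
    from n_samples observations, so a neutral community lands mostly within
    the band.
    """
    if fit is None:
        fit = fit_ncm(table)
    rng = np.random.default_rng(seed)
    n = len(fit.p_mean)
    ms, r2s = [], []
    curves = []
    failures = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        p_b, f_b = fit.p_mean[idx], fit.freq_obs[idx]
        try:
            m_b = _fit_m(p_b, f_b, fit.N)
        except RuntimeError:
            failures += 1
            continue
        pred_b = predicted_frequency(p_b, m_b, fit.N)
        sse = float(((f_b - pred_b) ** 2).sum())
        sst = float(((f_b - f_b.mean()) ** 2).sum())
        r2s.append(1.0 - sse / sst if sst > 0 else -np.inf)
        ms.append(m_b)
        curves.append(predicted_frequency(fit.p_mean, m_b, fit.N))
    if failures > max_failure_rate * reps:
        raise RuntimeError(f"{failures}/{reps} bootstrap refits failed")
    ms = np.asarray(ms)
    r2s = np.asarray(r2s)
    curves = np.asarray(curves)
    lo_curve = np.percentile(curves, 2.5, axis=0)
    hi_curve = np.percentile(curves, 97.5, axis=0)
    band_lo, _ = _wilson(lo_curve, fit.n_samples)
    _, band_hi = _wilson(hi_curve, fit.n_samples)
    fit.ci = {
        "m": (float(np.percentile(ms, 2.5)), float(np.percentile(ms, 97.5))),
        "Nm": (
            float(np.percentile(ms, 2.5) * fit.N),
            float(np.percentile(ms, 97.5) * fit.N),
        ),
        "r2": (float(np.percentile(r2s, 2.5)), float(np.percentile(r2s, 97.5))),
        "reps": int(len(ms)),
    }
    fit.band = {"lower": band_lo, "upper": band_hi}
    return fit


def ncm_partition(fit: NcmFit) -> dict:
    """Label each OTU above / within / below the 95% prediction band."""
    if fit.band is None:
        raise ValueError("run ncm_bootstrap first to get the prediction band")
    eps = 1e-9  # guard against round-off at the band's saturated ends
    labels = np.where(
        fit.freq_obs > fit.band["upper"] + eps,
        "above",
        np.where(fit.freq_obs < fit.band["lower"] - eps, "below", "within"),
    )
    fit.labels = labels
    n = len(labels)
    counts = {k: int((labels == k).sum()) for k in ("above", "within", "below")}
    fractions = {k: counts[k] / n for k in counts}
    return {"counts": counts, "fractions": fractions}
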