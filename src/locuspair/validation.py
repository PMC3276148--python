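"""Posterior predictive model validation.

Given a fitted ABC posterior, draw parameters from it (respecting the
regression-adjustment weights), re-simulate the full locus set for each
draw, and compare the observed data with the resulting predictive
distributions: per-statistic lower-tail probabilities, per-locus outlier
flags, and a two-component PCA with 95% coverage ellipses per model, the
observed data projected onto each model's components.

The extended summary set used here is the across-locus mean and variance
of Watterson's theta, pi, Tajima's D, haplotype number and haplotype
diversity (per population for two-population models, plus per-locus F_ST
and shared/fixed/private counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .coalescent import (
    HaplotypeMatrix,
    binary_summaries,
    binary_twopop_counts,
    count_haplotypes,
)
from .diversity import segment_stats

CHI2_95_DF2 = 5.991464547107979  # 95% quantile of chi-square with 2 df


# ---------------------------------------------------------------------------
# extended per-locus statistics


def _locus_stats_binary(hap: HaplotypeMatrix) -> np.ndarray:
    """theta_W, pi (per site), Tajima's D, N_h, H_e for one binary locus."""
    n = hap.n
    theta, D, nh = binary_summaries(hap)
    if hap.S == 0:
        pi = 0.0
        he = 0.0
    else:
        c = hap.matrix.sum(axis=0).astype(float)
        pi = float((c * (n - c)).sum()) / (n * (n - 1) / 2.0) / hap.L
        m = np.ascontiguousarray(hap.matrix)
        _, freq = np.unique(m.view([("", m.dtype)] * m.shape[1]),
                            return_counts=True)
        p = freq / n
        he = n / (n - 1.0) * (1.0 - float((p**2).sum()))
    return np.array([theta, pi, D, float(nh), he])


def _locus_stats(locus) -> np.ndarray:
    if isinstance(locus, Alignment):
        st = segment_stats(locus)
        return np.array([st.theta_per_site, st.pi_per_site, st.tajima_D,
                         float(st.N_h), st.H_e])
    return _locus_stats_binary(locus)


_BASE = ["theta", "pi", "D", "Nh", "He"]


def extended_names(two_pop: bool) -> list[str]:
    if not two_pop:
        return [f"{m}_{s}" for s in _BASE for m in ("mean", "var")]
    names = [f"{m}_{s}_{p}" for p in ("1", "2") for s in _BASE
             for m in ("mean", "var")]
    names += [f"{m}_{s}" for s in ("fst", "shared", "fixed", "private")
              for m in ("mean", "var")]
    return names


def _mean_var(col: np.ndarray) -> tuple[float, float]:
    ok = col[~np.isnan(col)]
    if ok.size < 2:
        return (float(ok[0]) if ok.size else math.nan), math.nan
    return float(ok.mean()), float(ok.var(ddof=1))


def extended_summaries(loci, two_pop: bool) -> np.ndarray:
    """Across-locus mean and variance of the extended per-locus set."""
    if not two_pop:
        per = np.array([_locus_stats(locus) for locus in loci])
        out = []
        for j in range(per.shape[1]):
            out.extend(_mean_var(per[:, j]))
        return np.array(out)
    rows = []
    for hap in loci:
        m1 = hap.pop_labels == 0
        m2 = hap.pop_labels == 1
        sub1 = HaplotypeMatrix(hap.matrix[m1], hap.positions,
                               hap.pop_labels[m1], hap.L)
        sub2 = HaplotypeMatrix(hap.matrix[m2], hap.positions,
                               hap.pop_labels[m2], hap.L)
        sh, fx, p1, p2, fst = binary_twopop_counts(hap)
        rows.append(np.concatenate([
            _locus_stats_binary(sub1), _locus_stats_binary(sub2),
            [fst, float(sh), float(fx), float(p1 + p2)],
        ]))
    per = np.array(rows)
    out = []
    for j in range(per.shape[1]):
        out.extend(_mean_var(per[:, j]))
    return np.array(out)


def per_locus_stats(loci, two_pop: bool) -> np.ndarray:
    """(loci x stats) matrix of per-locus extended statistics."""
    if not two_pop:
        return np.array([_locus_stats(locus) for locus in loci])
    rows = []
    for hap in loci:
        m1 = hap.pop_labels == 0
        m2 = hap.pop_labels == 1
        sub1 = HaplotypeMatrix(hap.matrix[m1], hap.positions,
                               hap.pop_labels[m1], hap.L)
        sub2 = HaplotypeMatrix(hap.matrix[m2], hap.positions,
                               hap.pop_labels[m2], hap.L)
        sh, fx, p1, p2, fst = binary_twopop_counts(hap)
        rows.append(np.concatenate([
            _locus_stats_binary(sub1), _locus_stats_binary(sub2),
            [fst, float(sh), float(fx), float(p1 + p2)],
        ]))
    return np.array(rows)


def extended_observed(model) -> np.ndarray:
    return extended_summaries(model.observed_loci, model.two_pop)


# ---------------------------------------------------------------------------
# posterior predictive simulation


@dataclass
class PredictiveTable:
    model: str
    table: np.ndarray          # draws x extended summaries
    names: list[str]
    per_locus: np.ndarray      # draws x loci x per-locus stats


def posterior_predictive(results, model_name: str, n_draws: int = 1000,
                         rng: np.random.Generator | None = None,
                         extended: bool = True) -> PredictiveTable:
    """Simulate the locus set under parameters resampled (with weights)
    from the fitted posterior of one model."""
    if rng is None:
        rng = np.random.default_rng()
    abc = results.model
    spec = next(m for m in abc.models if m.name == model_name)
    draws = results.posteriors[model_name]
    w = results.weights[model_name]
    if len(draws) < 1:
        raise ValueError("posterior is empty")
    p = np.asarray(w, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(draws), size=n_draws, replace=True, p=p)
    names = extended_names(abc.two_pop)
    table = np.empty((n_draws, len(names)))
    per_locus = np.empty((n_draws, len(abc.locus_specs),
                          14 if abc.two_pop else 5))
    for k, i in enumerate(idx):
        rec = draws.iloc[int(i)].to_dict()
        loci = abc.simulate_draw(spec, rec, rng)
        table[k] = extended_summaries(loci, abc.two_pop)
        per_locus[k] = per_locus_stats(loci, abc.two_pop)
    return PredictiveTable(model_name, table, names, per_locus)


# ---------------------------------------------------------------------------
# tail probabilities and outlier loci


@dataclass
class PpcReport:
    model: str
    names: list[str]
    observed: np.ndarray
    p_low: np.ndarray          # P(simulated < observed | model), ties half
    flagged: np.ndarray        # significant at alpha = 0.05 (two-tailed)
    locus_p_low: np.ndarray | None = None   # loci x per-locus stats
    outlier_loci: list[int] = field(default_factory=list)


def tail_probabilities(simulated: np.ndarray, observed: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Lower-tail probabilities per statistic with ties counted half, and
    two-tailed flags at alpha = 0.05 (p < 0.025 or p > 0.975)."""
    sims = np.asarray(simulated, dtype=float)
    if sims.shape[0] < 1:
        raise ValueError("empty simulated table")
    obs = np.asarray(observed, dtype=float)
    valid = ~np.isnan(sims)
    n = valid.sum(axis=0).astype(float)
    less = np.nansum(sims < obs, axis=0)
    equal = np.nansum(sims == obs, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (less + 0.5 * equal) / n
    p = np.where(np.isnan(obs), np.nan, p)
    flagged = (p < 0.025) | (p > 0.975)
    return p, flagged & ~np.isnan(p)


def ppc_report(results, model_name: str, n_draws: int = 1000,
               rng: np.random.Generator | None = None) -> PpcReport:
    """Full posterior predictive check: global tail probabilities plus
    per-locus outlier flags (a locus is an outlier when any of its
    statistics falls in either 2.5% tail)."""
    pred = posterior_predictive(results, model_name, n_draws, rng)
    abc = results.model
    obs = extended_observed(abc)
    p, flagged = tail_probabilities(pred.table, obs)
    obs_locus = per_locus_stats(abc.observed_loci, abc.two_pop)
    n_loci, n_stats = obs_locus.shape
    locus_p = np.empty((n_loci, n_stats))
    for li in range(n_loci):
        locus_p[li], _ = tail_probabilities(pred.per_locus[:, li, :],
                                            obs_locus[li])
    with np.errstate(invalid="ignore"):
        out_mask = (locus_p < 0.025) | (locus_p > 0.975)
    outliers = sorted(set(np.nonzero(out_mask)[0].tolist()))
    return PpcReport(model_name, pred.names, obs, p, flagged,
                     locus_p, outliers)


def locus_outliers(observed_per_locus: np.ndarray,
                   simulated_per_locus: np.ndarray) -> list[int]:
    """Outlier loci from explicit per-locus tables: observed (loci x
    stats) against simulated (draws x loci x stats)."""
    n_loci = observed_per_locus.shape[0]
    flagged = []
    for li in range(n_loci):
        p, _ = tail_probabilities(simulated_per_locus[:, li, :],
                                  observed_per_locus[li])
        with np.errstate(invalid="ignore"):
            if np.any((p < 0.025) | (p > 0.975)):
                flagged.append(li)
    return flagged


# ---------------------------------------------------------------------------
# PCA envelopes


@dataclass
class ModelEnvelope:
    model: str
    loadings: np.ndarray       # columns: PC1, PC2
    center: np.ndarray         # column means of the standardized table
    explained: np.ndarray
    score_cov: np.ndarray      # 2x2 covariance of PC scores
    score_mean: np.ndarray
    observed_scores: np.ndarray
    inside: bool
    kept_columns: np.ndarray

    def ellipse_points(self, n: int = 200) -> np.ndarray:
        """Boundary of the 95% coverage ellipse in PC space."""
        vals, vecs = np.linalg.eigh(self.score_cov)
        angles = np.linspace(0, 2 * math.pi, n)
        circle = np.stack([np.cos(angles), np.sin(angles)])
        pts = vecs @ (np.sqrt(np.maximum(vals, 0) * CHI2_95_DF2)[:, None] * circle)
        return (pts.T + self.score_mean)

    def mahalanobis2(self, scores: np.ndarray) -> float:
        diff = scores - self.score_mean
        return float(diff @ np.linalg.solve(self.score_cov, diff))


def pca_envelope(tables: dict[str, np.ndarray], observed: np.ndarray,
                 min_rows: int = 200) -> dict[str, ModelEnvelope]:
    """Per-model two-component PCA of simulated summary tables with a 95%
    bivariate-normal coverage ellipse, and the observed summaries
    projected with each model's loadings.

    Summaries are standardized to zero mean / unit variance over the
    pooled rows; constant or undefined columns are dropped.
    """
    pooled = np.vstack(list(tables.values()))
    obs = np.asarray(observed, dtype=float)
    keep = (
        np.isfinite(pooled).all(axis=0)
        & (np.nanstd(pooled, axis=0) > 0)
        & np.isfinite(obs)
    )
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable summary statistics")
    mu = pooled[:, keep].mean(axis=0)
    sd = pooled[:, keep].std(axis=0)
    out: dict[str, ModelEnvelope] = {}
    for name, table in tables.items():
        if table.shape[0] < min_rows:
            raise ValueError(
                f"model {name}: need >= {min_rows} simulated rows")
        Z = (table[:, keep] - mu) / sd
        zc = Z - Z.mean(axis=0)
        U, s, Vt = np.linalg.svd(zc, full_matrices=False)
        loadings = Vt[:2].T
        scores = zc @ loadings
        obs_z = (obs[keep] - mu) / sd - Z.mean(axis=0)
        obs_scores = obs_z @ loadings
        cov = np.cov(scores.T)
        env = ModelEnvelope(
            model=name,
            loadings=loadings,
            center=Z.mean(axis=0),
            explained=(s[:2] ** 2) / (s**2).sum(),
            score_cov=cov,
            score_mean=scores.mean(axis=0),
            observed_scores=obs_scores,
            inside=False,
            kept_columns=np.flatnonzero(keep),
        )
        env.inside = env.mahalanobis2(obs_scores) <= CHI2_95_DF2
        out[name] = env
    return out


def plot_envelopes(envelopes: dict[str, ModelEnvelope], path: str) -> None:
    """Draw the 95% coverage ellipse of each model with the observed data
    projected onto that model's components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    styles = ["-", "--", ":", "-."]
    for (name, env), ls in zip(envelopes.items(), styles):
        pts = env.ellipse_points()
        ax.plot(pts[:, 0], pts[:, 1], ls=ls, label=name, color="black")
        ax.scatter(*env.observed_scores, marker="o", s=40,
                   facecolors="none", edgecolors="black")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
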