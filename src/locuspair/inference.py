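"""Approximate Bayesian computation of demographic history.

The engine follows the classical rejection + regression-adjustment recipe:
draw parameters from their priors, simulate the full locus set under the
coalescent for each draw, reduce data to summary statistics, retain the
proportion P_delta of draws closest to the observed summaries in
(MAD-standardized) Euclidean distance, and correct the retained draws by a
local-linear regression of parameters on summaries recentred at the
observed point (an optional feed-forward neural-network regression is
provided as well).  Model posterior probabilities come from a weighted
multinomial logistic regression of model labels on summaries over the
pooled accepted draws; a plain rejection-proportion estimator is reported
alongside.

The user-facing surface is ``DemographicABC`` (a model object built from
observed data and candidate demographies) whose ``fit`` returns
``ABCResults`` with posterior modes, 95% credible intervals, model
probabilities and a printable summary table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .alignment import Alignment
from .coalescent import (
    BottleneckParams,
    GrowthParams,
    HaplotypeMatrix,
    LocusSpec,
    NeutralParams,
    NoSplitParams,
    SplitParams,
    binary_summaries,
    binary_twopop_counts,
    simulate_locus,
)
from .diversity import harmonic, segment_stats
from .units import effective_size, round_sig, split_time_years

__all__ = [
    "Prior", "ModelSpec", "DemographicABC", "ABCResults",
    "sample_priors", "summarize_single", "summarize_twopop",
    "abc_reject", "regression_adjust", "model_probabilities",
    "posterior_summary", "neutral_model", "growth_model",
    "bottleneck_model", "split_model", "no_split_model",
    "SINGLE_SUMMARY_NAMES", "TWOPOP_SUMMARY_NAMES",
]


# ---------------------------------------------------------------------------
# priors


@dataclass
class Prior:
    """A uniform or log-uniform prior for one scalar parameter."""

    name: str
    kind: str  # "uniform" | "log-uniform"
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "log-uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not self.min < self.max:
            raise ValueError(f"prior {self.name}: min must be < max")
        if self.kind == "log-uniform" and self.min <= 0:
            raise ValueError(f"prior {self.name}: log-uniform requires min > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.min, self.max, n)
        return np.exp(rng.uniform(math.log(self.min), math.log(self.max), n))

    # regression adjustment operates on an unconstrained scale and
    # back-transforms, keeping adjusted draws inside the prior support
    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "log-uniform":
            return np.log(x)
        span = self.max - self.min
        u = np.clip((x - self.min) / span, 1e-9, 1 - 1e-9)
        return np.log(u / (1 - u))

    def back_transform(self, z: np.ndarray) -> np.ndarray:
        # adjusted draws are clipped to the prior support: the posterior
        # cannot extend beyond it, and unbounded log-scale extrapolation
        # from small accepted sets otherwise escapes it by orders of
        # magnitude
        if self.kind == "log-uniform":
            return np.clip(np.exp(z), self.min, self.max)
        u = 1.0 / (1.0 + np.exp(-z))
        return self.min + (self.max - self.min) * u


def sample_priors(priors: Sequence[Prior], n_draws: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """i.i.d. draws from a list of priors, one column per parameter."""
    return pd.DataFrame({p.name: p.sample(n_draws, rng) for p in priors})


# ---------------------------------------------------------------------------
# model specifications


@dataclass
class ModelSpec:
    """A named demographic model: priors plus a factory turning one prior
    draw into a coalescent parameter set."""

    name: str
    priors: list[Prior]
    make_params: Callable[[dict], object]
    two_pop: bool = False

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.priors]


_THETA_RHO = [
    Prior("theta", "log-uniform", 1e-4, 1.0),
    Prior("rho", "log-uniform", 1e-4, 1.0),
]


def neutral_model() -> ModelSpec:
    return ModelSpec(
        "neutral", list(_THETA_RHO),
        lambda d: NeutralParams(theta=d["theta"], rho=d["rho"]),
    )


def growth_model() -> ModelSpec:
    return ModelSpec(
        "growth",
        list(_THETA_RHO) + [Prior("alpha", "log-uniform", 1e-3, 10.0)],
        lambda d: GrowthParams(theta=d["theta"], rho=d["rho"], alpha=d["alpha"]),
    )


def bottleneck_model(f: float = 0.02) -> ModelSpec:
    return ModelSpec(
        "bottleneck",
        list(_THETA_RHO) + [
            Prior("t_b", "uniform", 0.0, 10.0),
            Prior("d", "uniform", 0.0, 10.0),
        ],
        lambda d: BottleneckParams(theta=d["theta"], rho=d["rho"],
                                   t_b=d["t_b"], d=d["d"], f=f),
    )


def _split_priors(migration: bool) -> list[Prior]:
    priors = list(_THETA_RHO) + [
        Prior("N2", "log-uniform", 0.1, 10.0),
        Prior("N_anc", "log-uniform", 0.1, 10.0),
    ]
    if migration:
        priors.append(Prior("M", "log-uniform", 1e-3, 10.0))
    priors.append(Prior("t_s", "uniform", 0.0, 10.0))
    return priors


def split_model(migration: bool = True) -> ModelSpec:
    name = "split_migration" if migration else "split_no_migration"
    return ModelSpec(
        name, _split_priors(migration),
        lambda d: SplitParams(theta=d["theta"], rho=d["rho"], N2=d["N2"],
                              N_anc=d["N_anc"], M=d.get("M", 0.0),
                              t_s=d["t_s"]),
        two_pop=True,
    )


def no_split_model() -> ModelSpec:
    priors = list(_THETA_RHO) + [
        Prior("N_anc", "log-uniform", 0.1, 10.0),
        Prior("t_s", "uniform", 0.0, 10.0),
    ]
    return ModelSpec(
        "no_split", priors,
        lambda d: NoSplitParams(theta=d["theta"], rho=d["rho"],
                                N_anc=d["N_anc"], t_s=d["t_s"]),
        two_pop=True,
    )


# ---------------------------------------------------------------------------
# summary statistics

SINGLE_SUMMARY_NAMES = [
    "mean_theta", "var_theta", "mean_D", "var_D", "mean_Nh", "var_Nh",
]

TWOPOP_SUMMARY_NAMES = [
    "mean_theta_1", "mean_theta_2", "mean_theta_all",
    "mean_D_1", "mean_D_2", "mean_D_all",
    "mean_Nh_1", "mean_Nh_2", "mean_Nh_all",
    "fst", "shared", "fixed", "private",
]


def _mean_var(values: list[float]) -> tuple[float, float]:
    vals = [v for v in values if not math.isnan(v)]
    if len(vals) < 2:
        return (vals[0] if vals else math.nan), math.nan
    arr = np.asarray(vals)
    return float(arr.mean()), float(arr.var(ddof=1))


def summarize_single(loci: Sequence) -> np.ndarray:
    """Across-locus mean and variance (n-1 denominator) of Watterson's
    theta, Tajima's D and the number of haplotypes.

    Loci with S = 0 have undefined Tajima's D and are excluded from the D
    mean/variance; the same rule applies to observed and simulated data.
    Accepts HaplotypeMatrix or Alignment loci.
    """
    if len(loci) < 2:
        raise ValueError("need >= 2 loci for across-locus variances")
    thetas, Ds, Nhs = [], [], []
    for locus in loci:
        if isinstance(locus, Alignment):
            st = segment_stats(locus)
            thetas.append(st.theta_per_site)
            Ds.append(st.tajima_D)
            Nhs.append(float(st.N_h))
        else:
            t, d, nh = binary_summaries(locus)
            thetas.append(t)
            Ds.append(d)
            Nhs.append(float(nh))
    mt, vt = _mean_var(thetas)
    md, vd = _mean_var(Ds)
    mh, vh = _mean_var(Nhs)
    return np.array([mt, vt, md, vd, mh, vh])


def _count_stats(c: np.ndarray, n: int, L: int) -> tuple[float, float]:
    """(Watterson's theta per site, Tajima's D) from derived-allele column
    counts of one sample."""
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    theta = S / (harmonic(n - 1) * L)
    if S == 0:
        return theta, math.nan
    pi_total = float((c * (n - c)).sum()) / (n * (n - 1) / 2.0)
    from .diversity import tajimas_d_from_counts

    return theta, tajimas_d_from_counts(n, S, pi_total)


def summarize_twopop(loci: Sequence[HaplotypeMatrix]) -> np.ndarray:
    """Two-species summary vector: average Watterson's theta, Tajima's D
    and haplotype number in each population and combined (9 statistics),
    the across-locus mean Hudson F_ST, and the total numbers of shared,
    fixed and private polymorphisms."""
    if len(loci) < 1:
        raise ValueError("need >= 1 locus")
    from .coalescent import count_haplotypes

    cols = {k: [] for k in range(9)}
    fsts: list[float] = []
    shared = fixed = private = 0
    for hap in loci:
        mask1 = hap.pop_labels == 0
        mask2 = hap.pop_labels == 1
        n1 = int(mask1.sum())
        n2 = int(mask2.sum())
        if n1 == 0 or n2 == 0:
            raise ValueError("each locus must sample both populations")
        n = n1 + n2
        if hap.S:
            c1 = hap.matrix[mask1].sum(axis=0).astype(float)
            ca = hap.matrix.sum(axis=0).astype(float)
            c2 = ca - c1
        else:
            c1 = c2 = ca = np.zeros(0)
        t1, d1 = _count_stats(c1, n1, hap.L)
        t2, d2 = _count_stats(c2, n2, hap.L)
        ta, da = _count_stats(ca, n, hap.L)
        h1 = count_haplotypes(hap.matrix[mask1]) if hap.S else 1
        h2 = count_haplotypes(hap.matrix[mask2]) if hap.S else 1
        ha = count_haplotypes(hap.matrix) if hap.S else 1
        for k, v in enumerate((t1, t2, ta, d1, d2, da,
                               float(h1), float(h2), float(ha))):
            cols[k].append(v)
        if hap.S:
            seg1 = (c1 > 0) & (c1 < n1)
            seg2 = (c2 > 0) & (c2 < n2)
            shared += int((seg1 & seg2).sum())
            fixed += int((~seg1 & ~seg2 & ((c1 > 0) != (c2 > 0))).sum())
            private += int((seg1 & ~seg2).sum()) + int((seg2 & ~seg1).sum())
            hw1 = float((c1 * (n1 - c1)).sum()) / (n1 * (n1 - 1) / 2.0)
            hw2 = float((c2 * (n2 - c2)).sum()) / (n2 * (n2 - 1) / 2.0)
            hb = float((c1 * (n2 - c2) + c2 * (n1 - c1)).sum()) / (n1 * n2)
            if hb > 0:
                fsts.append(1.0 - 0.5 * (hw1 + hw2) / hb)

    def mean(vals):
        ok = [v for v in vals if not math.isnan(v)]
        return float(np.mean(ok)) if ok else math.nan

    return np.array([
        mean(cols[0]), mean(cols[1]), mean(cols[2]),
        mean(cols[3]), mean(cols[4]), mean(cols[5]),
        mean(cols[6]), mean(cols[7]), mean(cols[8]),
        mean(fsts), float(shared), float(fixed), float(private),
    ])


# ---------------------------------------------------------------------------
# rejection, adjustment, model choice


def abc_reject(
    observed: np.ndarray,
    simulated: np.ndarray,
    p_delta: float,
    standardize: str = "mad",
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the ceil(p_delta * N) draws closest to the observed summary
    vector in Euclidean distance after per-statistic standardization.

    Returns (accepted row indices, their distances).  Statistics with zero
    spread (MAD or SD 0) are dropped with a warning; simulated rows with
    undefined statistics get infinite distance and are never retained
    before any defined row.
    """
    if not 0 < p_delta <= 1:
        raise ValueError("p_delta must be in (0, 1]")
    if standardize not in ("none", "sd", "mad"):
        raise ValueError("standardize must be none|sd|mad")
    sims = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sims.shape[1] != obs.size:
        raise ValueError("summary dimension mismatch")
    if standardize == "none":
        scale = np.ones(obs.size)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if standardize == "mad":
                med = np.nanmedian(sims, axis=0)
                scale = np.nanmedian(np.abs(sims - med), axis=0)
            else:
                scale = np.nanstd(sims, axis=0)
    usable = (scale > 0) & np.isfinite(scale) & np.isfinite(obs)
    if not usable.all():
        dropped = np.flatnonzero(~usable)
        warnings.warn(
            f"dropping degenerate summary statistics at columns {dropped.tolist()}"
        )
    if not usable.any():
        raise ValueError("no usable summary statistics")
    z = (sims[:, usable] - obs[usable]) / scale[usable]
    dist = np.sqrt((z**2).sum(axis=1))
    dist = np.where(np.isnan(dist), np.inf, dist)
    k = math.ceil(p_delta * sims.shape[0])
    idx = np.argpartition(dist, k - 1)[:k]
    idx = idx[np.argsort(dist[idx], kind="stable")]
    return idx, dist[idx]


def epanechnikov_weights(distances: np.ndarray) -> np.ndarray:
    """Kernel weights on acceptance distances, w = 1 - (d/d_max)^2 (the
    boundary draw keeps a small positive weight)."""
    d = np.asarray(distances, dtype=float)
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** 2
    return np.maximum(w, 1e-6)


def regression_adjust(
    params: pd.DataFrame,
    summaries: np.ndarray,
    observed: np.ndarray,
    distances: np.ndarray,
    priors: Sequence[Prior],
    method: str = "loclinear",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Post-rejection regression adjustment.

    ``loclinear``: weighted local-linear regression of each (transformed)
    parameter on the summaries, residuals recentred at the observed
    summaries (Epanechnikov weights on distance).  ``ffnn``: single-hidden-
    layer feed-forward network regression with the same recentring logic.
    Falls back to the unadjusted draws with a warning when the local design
    is rank-deficient.  Returns (adjusted parameters, weights).
    """
    if len(params) < 50:
        raise ValueError("need >= 50 accepted draws for adjustment")
    if method not in ("loclinear", "ffnn", "rejection"):
        raise ValueError("method must be loclinear|ffnn|rejection")
    w = epanechnikov_weights(distances)
    if method == "rejection":
        return params.copy(), w

    S = np.asarray(summaries, dtype=float)
    obs = np.asarray(observed, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(S).all(axis=0) & (S.std(axis=0) > 0)
    S = S[:, keep]
    obs = obs[keep]
    mu, sd = S.mean(axis=0), S.std(axis=0)
    Sz = (S - mu) / sd
    obs_z = (obs - mu) / sd
    prior_by_name = {p.name: p for p in priors}

    adjusted = {}
    if method == "loclinear":
        X = np.column_stack([np.ones(len(Sz)), Sz])
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        for name in params.columns:
            prior = prior_by_name[name]
            y = prior.transform(params[name].to_numpy())
            beta, _, rank, _ = np.linalg.lstsq(Xw, y * sw, rcond=None)
            if rank < X.shape[1]:
                warnings.warn(
                    f"rank-deficient regression design for {name}; "
                    "falling back to rejection-only draws"
                )
                adjusted[name] = params[name].to_numpy()
                continue
            pred = X @ beta
            pred_obs = beta[0] + obs_z @ beta[1:]
            adjusted[name] = prior.back_transform(y - pred + pred_obs)
    else:  # ffnn
        from sklearn.neural_network import MLPRegressor

        for name in params.columns:
            prior = prior_by_name[name]
            y = prior.transform(params[name].to_numpy())
            net = MLPRegressor(hidden_layer_sizes=(8,), max_iter=2000,
                               random_state=0)
            net.fit(Sz, y)
            pred = net.predict(Sz)
            pred_obs = net.predict(obs_z[None, :])[0]
            adjusted[name] = prior.back_transform(y - pred + pred_obs)
    return pd.DataFrame(adjusted), w


def model_probabilities(
    tables: dict[str, tuple[np.ndarray, np.ndarray]],
    observed: np.ndarray,
    p_delta: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Posterior model probabilities from per-model simulated summary
    tables (each the same number of draws).

    The logistic training set retains the P_delta closest draws per model
    (balanced classes); the rejection-proportion estimator applies a single
    pooled distance threshold (P_delta of the pooled table, standardized
    over the pooled rows) and reports the per-model share of the pooled
    accepted set.  Returns (logistic probabilities, rejection-proportion
    probabilities).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 models")
    sizes = {len(t[1]) for t in tables.values()}
    if len(sizes) != 1:
        raise ValueError("models must have equal draw counts")
    names = list(tables)
    rows, labels, dists = [], [], []
    for mi, name in enumerate(names):
        sims = np.asarray(tables[name][1], dtype=float)
        idx, d = abc_reject(observed, sims, p_delta)
        rows.append(sims[idx])
        labels.append(np.full(len(idx), mi))
        dists.append(d)

    # pooled-threshold rejection proportions
    pooled = np.vstack([np.asarray(tables[n][1], dtype=float) for n in names])
    pool_idx, _ = abc_reject(observed, pooled, p_delta)
    per = sizes.pop()
    owner = pool_idx // per
    rej = {name: float((owner == mi).mean()) for mi, name in enumerate(names)}

    X = np.vstack(rows)
    y = np.concatenate(labels)
    w = epanechnikov_weights(np.concatenate(dists))
    obs = np.asarray(observed, dtype=float)
    keep = np.isfinite(obs) & np.isfinite(X).all(axis=0) & (X.std(axis=0) > 0)
    X = X[:, keep]
    obs = obs[keep]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xz = (X - mu) / sd
    obs_z = (obs - mu) / sd
    if len(np.unique(y)) < 2:
        warnings.warn("all accepted draws come from one model")
        probs = {name: float(name == names[int(y[0])]) for name in names}
        return probs, rej
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=2000)
    clf.fit(Xz, y, sample_weight=w)
    p = clf.predict_proba(obs_z[None, :])[0]
    probs = {name: 0.0 for name in names}
    for cls, pi in zip(clf.classes_, p):
        probs[names[int(cls)]] = float(pi)
    return probs, rej


def weighted_quantile(values: np.ndarray, q: Sequence[float],
                      weights: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, v)


def posterior_summary(values: np.ndarray, weights: np.ndarray | None = None,
                      grid_size: int = 512,
                      prior: Prior | None = None) -> tuple[float, float, float]:
    """(mode, 2.5% quantile, 97.5% quantile) of a weighted posterior
    sample; the mode is the argmax of a weighted Gaussian KDE (Silverman
    bandwidth) on a 512-point grid spanning the draws.

    When the parameter's prior is given, the KDE runs on the prior's
    unconstrained transform of the draws (log for log-uniform, logit for
    uniform) and the located mode is back-transformed: the density of a
    strongly skewed positive parameter is then estimated on its natural
    scale.  Quantiles are computed directly (they are transform-
    invariant)."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("empty posterior sample")
    if weights is None:
        weights = np.ones_like(values)
    if np.ptp(values) == 0:
        v = float(values[0])
        return v, v, v
    work = prior.transform(values) if prior is not None else values
    finite = np.isfinite(work)
    kde = gaussian_kde(work[finite], bw_method="silverman",
                       weights=np.asarray(weights)[finite])
    grid = np.linspace(work[finite].min(), work[finite].max(), grid_size)
    mode = float(grid[np.argmax(kde(grid))])
    if prior is not None:
        mode = float(prior.back_transform(np.array([mode]))[0])
    lo, hi = weighted_quantile(values, [0.025, 0.975], weights)
    return mode, float(lo), float(hi)


# ---------------------------------------------------------------------------
# model object / results object


@dataclass
class ReferenceTable:
    """Simulated parameter draws and their summary statistics."""

    model: str
    params: pd.DataFrame
    summaries: np.ndarray
    summary_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.params.copy()
        for j, name in enumerate(self.summary_names):
            out[name] = self.summaries[:, j]
        return out


class DemographicABC:
    """ABC model: observed multilocus data plus candidate demographies.

    Parameters
    ----------
    observed_loci : list of HaplotypeMatrix or Alignment
        One entry per locus.  Two-population models need HaplotypeMatrix
        loci with population labels (or Alignments are not supported for
        the two-population summary set).
    models : list of ModelSpec
        Candidate demographies compared and fitted jointly.
    locus_specs : list of LocusSpec
        Sample sizes and lengths used in the simulations, normally taken
        from the observed loci.
    """

    def __init__(self, observed_loci, models: Sequence[ModelSpec],
                 locus_specs: Sequence[LocusSpec], p_delta: float = 0.001):
        if not models:
            raise ValueError("need at least one model")
        two_pop = {m.two_pop for m in models}
        if len(two_pop) != 1:
            raise ValueError("cannot mix single- and two-population models")
        self.two_pop = two_pop.pop()
        self.models = list(models)
        self.locus_specs = list(locus_specs)
        self.p_delta = p_delta
        self.summary_names = (
            TWOPOP_SUMMARY_NAMES if self.two_pop else SINGLE_SUMMARY_NAMES
        )
        self.observed_loci = list(observed_loci)
        self.observed_summary = self._summarize(self.observed_loci)

    @classmethod
    def from_alignments(cls, alignments: Sequence[Alignment],
                        models: Sequence[ModelSpec],
                        p_delta: float = 0.001) -> "DemographicABC":
        specs = [LocusSpec((a.n,), a.L) for a in alignments]
        return cls(alignments, models, specs, p_delta)

    def _summarize(self, loci) -> np.ndarray:
        if self.two_pop:
            return summarize_twopop(loci)
        return summarize_single(loci)

    def simulate_draw(self, model: ModelSpec, draw: dict,
                      rng: np.random.Generator) -> list[HaplotypeMatrix]:
        params = model.make_params(draw)
        return [simulate_locus(params, spec, rng) for spec in self.locus_specs]

    def simulate_reference(self, model: ModelSpec, n_draws: int,
                           rng: np.random.Generator) -> ReferenceTable:
        """Build the reference table for one model: prior draws plus
        simulated summary vectors (loci i.i.d. given the parameters)."""
        draws = sample_priors(model.priors, n_draws, rng)
        summaries = np.empty((n_draws, len(self.summary_names)))
        records = draws.to_dict("records")
        for i, rec in enumerate(records):
            loci = self.simulate_draw(model, rec, rng)
            summaries[i] = self._summarize(loci)
        return ReferenceTable(model.name, draws, summaries, list(self.summary_names))

    def fit(self, n_draws: int = 10_000, seed: int | None = None,
            rng: np.random.Generator | None = None,
            method: str = "loclinear",
            references: dict[str, ReferenceTable] | None = None) -> "ABCResults":
        """Run rejection + adjustment for every candidate model.

        ``references`` may carry pre-simulated tables (e.g. shared across
        analyses); missing models are simulated here with ``n_draws``.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        references = dict(references or {})
        for model in self.models:
            if model.name not in references:
                references[model.name] = self.simulate_reference(model, n_draws, rng)
        posteriors: dict[str, pd.DataFrame] = {}
        weights: dict[str, np.ndarray] = {}
        accepted: dict[str, pd.DataFrame] = {}
        for model in self.models:
            ref = references[model.name]
            idx, dist = abc_reject(self.observed_summary, ref.summaries,
                                   self.p_delta)
            acc_params = ref.params.iloc[idx].reset_index(drop=True)
            accepted[model.name] = acc_params.assign(delta=dist)
            try:
                adj, w = regression_adjust(
                    acc_params, ref.summaries[idx], self.observed_summary,
                    dist, model.priors, method=method)
            except ValueError:
                adj, w = acc_params.copy(), epanechnikov_weights(dist)
            posteriors[model.name] = adj
            weights[model.name] = w
        if len(self.models) >= 2:
            probs, rej = model_probabilities(
                {m.name: (references[m.name].params.to_numpy(),
                          references[m.name].summaries)
                 for m in self.models},
                self.observed_summary, self.p_delta)
        else:
            probs = {self.models[0].name: 1.0}
            rej = dict(probs)
        return ABCResults(self, references, accepted, posteriors, weights,
                          probs, rej)


class ABCResults:
    """Fitted ABC posteriors: adjusted draws, weights and model
    probabilities, with Tables-7/8-style reporting."""

    def __init__(self, model: DemographicABC,
                 references: dict[str, ReferenceTable],
                 accepted: dict[str, pd.DataFrame],
                 posteriors: dict[str, pd.DataFrame],
                 weights: dict[str, np.ndarray],
                 model_probs: dict[str, float],
                 rejection_probs: dict[str, float]):
        self.model = model
        self.references = references
        self.accepted = accepted
        self.posteriors = posteriors
        self.weights = weights
        self.model_probabilities = model_probs
        self.rejection_probabilities = rejection_probs

    def posterior_summary(self, model_name: str, param: str) -> tuple[float, float, float]:
        """(mode, lo95, hi95) for one parameter of one model."""
        draws = self.posteriors[model_name][param].to_numpy()
        spec = next(m for m in self.model.models if m.name == model_name)
        prior = next(p for p in spec.priors if p.name == param)
        return posterior_summary(draws, self.weights[model_name], prior=prior)

    def best_model(self) -> str:
        return max(self.model_probabilities, key=self.model_probabilities.get)

    def summary(self) -> str:
        """Printable report: per model, parameter modes with 95% credible
        intervals and the posterior model probability."""
        lines = ["ABC posterior estimates", "=" * 23]
        for spec in self.model.models:
            name = spec.name
            lines.append(f"\nModel: {name}   P = {self.model_probabilities[name]:.2f} "
                         f"(rejection estimate {self.rejection_probabilities[name]:.2f})")
            for param in spec.param_names:
                mode, lo, hi = self.posterior_summary(name, param)
                lines.append(f"  {param:>8}: {mode:.4g} ({lo:.4g}-{hi:.4g})")
        return "\n".join(lines)

    # unit conversions -----------------------------------------------------
    def effective_size(self, model_name: str = None, mu_per_year: float = 1e-9,
                       g_years: float = 10.0) -> float:
        """Ne = theta/(4 mu g) from the posterior mode of theta."""
        name = model_name or self.best_model()
        mode, _, _ = self.posterior_summary(name, "theta")
        return effective_size(mode, mu_per_year, g_years)

    def split_time(self, model_name: str = None, mu_per_year: float = 1e-9,
                   g_years: float = 10.0, Ne: float | None = None) -> tuple[float, float, float]:
        """Posterior (mode, lo95, hi95) of the split time in years, each
        rounded to 2 significant figures."""
        name = model_name or self.best_model()
        if Ne is None:
            Ne = self.effective_size(name, mu_per_year, g_years)
        mode, lo, hi = self.posterior_summary(name, "t_s")
        return tuple(
            round_sig(split_time_years(t, Ne, g_years), 2)
            for t in (mode, lo, hi)
        )

    # posterior predictive hooks (implemented in .validation) --------------
    def posterior_predictive(self, model_name: str, n_draws: int = 1000,
                             rng: np.random.Generator | None = None,
                             extended: bool = True):
        from .validation import posterior_predictive

        return posterior_predictive(self, model_name, n_draws=n_draws,
                                    rng=rng, extended=extended)

    def ppc_report(self, model_name: str, n_draws: int = 1000,
                   rng: np.random.Generator | None = None):
        from .validation import ppc_report

        return ppc_report(self, model_name, n_draws=n_draws, rng=rng)

    def pca_envelope(self, tables: dict[str, np.ndarray] | None = None,
                     n_draws: int = 1000,
                     rng: np.random.Generator | None = None):
        from .validation import extended_observed, pca_envelope

        if tables is None:
            if rng is None:
                rng = np.random.default_rng()
            tables = {
                spec.name: self.posterior_predictive(spec.name, n_draws, rng).table
                for spec in self.model.models
            }
        return pca_envelope(tables, extended_observed(self.model))
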