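"""Preliminary and model-checking analytics around the network fits.

Covers the screening and checking activities an NMA analyst performs before
and after the main model: pairwise heterogeneity (Cochran Q, I-squared,
tau-squared), global Wald tests of proportional hazards from
treatment-ln(time) interaction coefficients, a summed per-trial Wald test of
linearity for a 3-level ordinal covariate, splitting direct from indirect
evidence through a loop inconsistency parameter, and the half-standard-error
agreement criterion for within- versus across-trial interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import IPDDataset
from .design import ModelConfig, build_design
from .inference import MCMCSettings, PosteriorDraws, PosteriorSummary, fit
from .mcmc import ml_estimate
from .network import NetworkSpec, build_network
from .survival import log_likelihood_arrays

__all__ = [
    "HeterogeneityResult",
    "PairwiseResult",
    "AgreementAssessment",
    "InconsistencySplit",
    "pairwise_estimates",
    "heterogeneity",
    "global_ph_test",
    "linearity_test",
    "direct_indirect_split",
    "agreement",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q with derived I-squared (%) and DerSimonian-Laird tau-squared."""

    Q: float
    df: int
    p_value: float
    I2: float
    tau2: float


@dataclass
class PairwiseResult:
    """Per-trial and pooled estimates for one treatment comparison."""

    comparison: tuple[str, str]
    per_trial: pd.DataFrame  # trial, estimate, se, lower, upper, weight
    pooled_estimate: float
    pooled_se: float
    pooled_lower: float
    pooled_upper: float

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot data (trial, estimate, lower, upper, weight)."""
        return self.per_trial[["trial", "estimate", "lower", "upper", "weight"]]


@dataclass(frozen=True)
class AgreementAssessment:
    """Half-standard-error agreement check for one treatment contrast."""

    contrast: str
    delta_within: float
    delta_across: float
    se_within: float
    se_across: float
    difference: float
    threshold: float
    agree: bool


@dataclass
class InconsistencySplit:
    """Direct / indirect / network evidence split for one loop."""

    loop: tuple[str, ...]
    closing_edge: tuple[str, str]
    table: pd.DataFrame           # rows: direct, indirect, network, omega
    omega_draws: np.ndarray
    direct_draws: np.ndarray
    indirect_draws: np.ndarray


def _summ(arr: np.ndarray) -> dict:
    return {
        "mean": float(arr.mean()),
        "lower": float(np.percentile(arr, 2.5)),
        "upper": float(np.percentile(arr, 97.5)),
    }


def _single_comparison_fit(dataset: IPDDataset, pair: tuple[str, str],
                           n_knots: int, mode: str,
                           settings: MCMCSettings | None,
                           ph: bool = False):
    """FTE fit of one comparison restricted to its informative trials."""
    a, b = pair
    trials = [t for t, arms in dataset.trials.items() if a in arms and b in arms]
    if not trials:
        raise ValueError(f"no trial compares {a!r} with {b!r}")
    mask = dataset.table["trial"].isin(trials) & dataset.table["treatment"].isin(pair)
    sub = dataset.subset(mask.to_numpy())
    net = build_network(sub, reference=a)
    config = ModelConfig(n_knots=n_knots, ph_interactions=ph)
    design = build_design(sub, net, config)
    if mode == "ml":
        theta, cov = ml_estimate(design)
        return design, theta, cov, None
    draws = fit(design, settings=settings)
    return design, None, None, draws


def pairwise_estimates(dataset: IPDDataset, comparison: tuple[str, str],
                       n_knots: int = 2, mode: str = "ml",
                       settings: MCMCSettings | None = None) -> PairwiseResult:
    """Per-trial and pooled log hazard ratios for one comparison.

    Per-trial estimates come from trial-specific flexible-parametric fits
    (maximum likelihood; trials with sparse events fall back to a Weibull
    baseline automatically).  The pooled estimate is the one-stage
    fixed-treatment-effect model restricted to the comparison's trials,
    fitted by maximum likelihood (``mode="ml"``, Wald interval) or by MCMC
    (``mode="bayes"``, credible interval).
    """
    a, b = comparison
    trials = [t for t, arms in dataset.trials.items() if a in arms and b in arms]
    if not trials:
        raise ValueError(f"no trial compares {a!r} with {b!r}")

    rows = []
    for t in trials:
        mask = (dataset.table["trial"] == t) & dataset.table["treatment"].isin(comparison)
        sub = dataset.subset(mask.to_numpy())
        net = build_network(sub, reference=a)
        design = build_design(sub, net, ModelConfig(n_knots=n_knots))
        theta, cov = ml_estimate(design)
        k = design.col(f"beta[{b}]")
        est, se = float(theta[k]), float(np.sqrt(cov[k, k]))
        rows.append({"trial": t, "estimate": est, "se": se,
                     "lower": est - 1.96 * se, "upper": est + 1.96 * se,
                     "weight": 1.0 / se**2})
    per_trial = pd.DataFrame(rows)
    per_trial["weight"] = per_trial["weight"] / per_trial["weight"].sum() * 100.0

    design, theta, cov, draws = _single_comparison_fit(
        dataset, comparison, n_knots, mode, settings
    )
    if mode == "ml":
        k = design.col(f"beta[{b}]")
        est, se = float(theta[k]), float(np.sqrt(cov[k, k]))
        lo, hi = est - 1.96 * se, est + 1.96 * se
    else:
        arr = draws.flat(f"beta[{b}]")
        est, se = float(arr.mean()), float(arr.std(ddof=1))
        lo, hi = float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))
    return PairwiseResult(
        comparison=comparison, per_trial=per_trial,
        pooled_estimate=est, pooled_se=se, pooled_lower=lo, pooled_upper=hi,
    )


def heterogeneity(estimates) -> HeterogeneityResult:
    """Inverse-variance heterogeneity statistics from per-trial (y_i, se_i).

    Q = sum w_i (y_i - yhat)^2 with w_i = 1/se_i^2 and yhat the
    inverse-variance pooled mean; I2 = max(0, (Q - df)/Q) * 100;
    tau2 is the DerSimonian-Laird moment estimator
    max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    est = [(float(y), float(se)) for y, se in estimates]
    if len(est) < 2:
        raise ValueError("heterogeneity needs at least 2 estimates")
    y = np.array([e[0] for e in est])
    se = np.array([e[1] for e in est])
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    yhat = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - yhat) ** 2))
    df = len(y) - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p_value=p, I2=I2, tau2=tau2)


def global_ph_test(draws: PosteriorDraws) -> tuple[float, int, float]:
    """Global Wald test of proportional hazards.

    Uses the posterior mean and covariance of the treatment-ln(time)
    interaction coefficients phi: chi2 = phihat' V^-1 phihat on dim(phi)
    degrees of freedom.
    """
    phi_names = [draws.raw.names[i] for i in draws.design.phi_cols]
    if not phi_names:
        raise ValueError("fit contains no treatment-ln(time) interaction terms")
    mat = np.stack([draws.flat(n) for n in phi_names])  # (k, draws)
    m = mat.mean(axis=1)
    V = np.cov(mat) if len(phi_names) > 1 else np.array([[mat.var(ddof=1)]])
    V = np.atleast_2d(V)
    # pseudo-inverse guards the degenerate zero-variance case (chi2 -> 0)
    chi2 = float(m @ np.linalg.pinv(V) @ m)
    df = len(phi_names)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _ml_flat(X0: np.ndarray, Xd: np.ndarray, x: np.ndarray, d: np.ndarray,
             init: np.ndarray):
    """ML fit of a bespoke flat design matrix; returns (theta, cov)."""

    def negll(theta):
        eta = X0 @ theta
        deta = Xd @ theta
        v = log_likelihood_arrays(d, eta, deta, x).value
        return 1e12 if not np.isfinite(v) else -v

    def neggrad(theta):
        eta = X0 @ theta
        deta = Xd @ theta
        ev = d > 0
        if np.any(deta[ev] <= 0):
            pen = np.where(ev & (deta <= 1e-8), -1.0, 0.0)
            return Xd.T @ pen
        w = d - np.exp(eta)
        r = np.zeros_like(deta)
        r[ev] = 1.0 / deta[ev]
        return -(X0.T @ w + Xd.T @ (d * r))

    res = optimize.minimize(negll, init, jac=neggrad, method="L-BFGS-B",
                            options={"maxiter": 500})
    theta = res.x
    eps = 1e-5
    g0 = neggrad(theta)
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        tp = theta.copy()
        tp[i] += eps
        H[:, i] = (neggrad(tp) - g0) / eps
    H = 0.5 * (H + H.T)
    w_, V_ = np.linalg.eigh(H)
    w_ = np.clip(w_, 1e-10, None)
    return theta, (V_ / w_) @ V_.T


def linearity_test(dataset: IPDDataset, covariate: str,
                   n_knots: int = 0) -> tuple[float, int, float]:
    """Summed per-trial Wald test of linearity for a 3-level ordinal covariate.

    In every trial observing patients at all three ordered levels, the model
    is refitted with a free offset for the middle level on top of the linear
    coding; the 1-df Wald chi-squared statistics are summed across trials
    (trials are independent) and referred to a chi-squared distribution with
    as many degrees of freedom as qualifying trials.
    """
    spec = dataset.covariate_spec(covariate)
    z_all = dataset.table[covariate]
    levels = np.unique(z_all.dropna())
    if len(levels) != 3:
        raise ValueError(
            f"linearity test expects a 3-level ordinal covariate; "
            f"observed levels {levels}"
        )
    mid = levels[1]

    total_chi2 = 0.0
    df = 0
    for trial_id in dataset.trial_ids:
        mask = (dataset.table["trial"] == trial_id) & z_all.notna()
        g = dataset.table[mask]
        if np.unique(g[covariate]).size < 3 or g["treatment"].nunique() < 2:
            continue  # cannot contribute a within-trial departure estimate
        sub = dataset.subset(mask.to_numpy())
        present = [t for t in sub.treatments if t in set(sub.table["treatment"])]
        net = build_network(sub, reference=present[0])
        design = build_design(
            sub, net, ModelConfig(covariate=covariate, covariate_mode="common",
                                  n_knots=n_knots)
        )
        z = design.z_obs
        X0 = design.X0 + z[:, None] * design.M
        X0 = np.column_stack([X0, (z == mid).astype(float)])
        Xd = np.column_stack([design.Xd, np.zeros(len(z))])
        init = np.zeros(X0.shape[1])
        init[design.col(f"gamma[{trial_id},1]")] = 1.0
        theta, cov = _ml_flat(X0, Xd, design.x, design.d, init)
        psi, var = theta[-1], cov[-1, -1]
        total_chi2 += float(psi**2 / var)
        df += 1
    if df == 0:
        raise ValueError(
            "no trial observes all 3 covariate levels with >= 2 arms; "
            "the linearity test has no qualifying trial"
        )
    return total_chi2, df, float(stats.chi2.sf(total_chi2, df))


def direct_indirect_split(dataset: IPDDataset, network: NetworkSpec,
                          loop: tuple[str, ...],
                          config: ModelConfig | None = None,
                          settings: MCMCSettings | None = None) -> InconsistencySplit:
    """Split one loop's evidence via an inconsistency parameter.

    Refits the model with omega attached to the loop's closing edge: that
    edge's trials then estimate direct = (own contrast) + omega while the
    rest of the network identifies the indirect contrast; by construction
    direct - indirect = omega for every draw.  The network estimate comes
    from the omega-free fit.
    """
    loop = tuple(loop)
    if loop not in network.loops:
        raise ValueError(f"{loop} is not a loop of this network")
    base = config if config is not None else ModelConfig()
    import dataclasses as _dc
    cfg_omega = _dc.replace(base, inconsistency=(loop,))
    cfg_plain = _dc.replace(base, inconsistency=())

    d_omega = build_design(dataset, network, cfg_omega)
    edge = d_omega.closing_edge_of[loop]
    u, v = edge
    draws_omega = fit(d_omega, settings=settings)
    draws_plain = fit(build_design(dataset, network, cfg_plain), settings=settings)

    omega_name = f"omega[{'-'.join(loop)}]"
    om = draws_omega.flat(omega_name)
    indirect = draws_omega.contrast_draws(u, v).reshape(-1)
    direct = indirect + om
    net_est = draws_plain.contrast_draws(u, v).reshape(-1)

    table = pd.DataFrame(
        [
            {"evidence": "direct", **_summ(direct)},
            {"evidence": "indirect", **_summ(indirect)},
            {"evidence": "network", **_summ(net_est)},
            {"evidence": "omega", **_summ(om)},
        ]
    ).set_index("evidence")
    return InconsistencySplit(
        loop=loop, closing_edge=edge, table=table,
        omega_draws=om, direct_draws=direct, indirect_draws=indirect,
    )


def agreement(summary: PosteriorSummary, network: NetworkSpec,
              criterion: str = "across") -> list[AgreementAssessment]:
    """Half-standard-error agreement between within- and across-trial
    interactions.

    For each basic contrast the verdict is *agree* iff
    |delta_within - delta_across| <= 0.5 * SE, where the SE is backed out of
    the 95% interval width as (upper - lower)/(2 * 1.96).  By default the SE
    of the across-trial interaction is used; ``criterion`` may instead name
    ``"within"`` or ``"pooled"`` (root mean square of the two).  The boundary
    counts as agreement.
    """
    if criterion not in ("across", "within", "pooled"):
        raise ValueError("criterion must be across|within|pooled")
    if "deltaA" in summary.table.index:  # common-effects fit: one shared TCI
        pairs = [("all contrasts", "deltaA", "deltaB")]
    else:
        pairs = [(f"{network.reference} vs {t}", f"deltaA[{t}]", f"deltaB[{t}]")
                 for _, t in network.basic_parameters]
    out = []
    for label, name_a, name_b in pairs:
        try:
            ra = summary.row(name_a)
            rb = summary.row(name_b)
        except KeyError as exc:
            raise ValueError(
                "agreement assessment needs a separated-interaction fit "
                f"(missing {exc})"
            ) from exc
        se_a = (ra["upper"] - ra["lower"]) / (2 * 1.959963984540054)
        se_b = (rb["upper"] - rb["lower"]) / (2 * 1.959963984540054)
        se = {"across": se_b, "within": se_a,
              "pooled": float(np.sqrt(0.5 * (se_a**2 + se_b**2)))}[criterion]
        diff = abs(ra["mean"] - rb["mean"])
        thr = 0.5 * se
        out.append(
            AgreementAssessment(
                contrast=label,
                delta_within=float(ra["mean"]), delta_across=float(rb["mean"]),
                se_within=float(se_a), se_across=float(se_b),
                difference=float(diff), threshold=float(thr),
                agree=bool(diff <= thr),
            )
        )
    return out
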