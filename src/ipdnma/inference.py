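"""Posterior fitting, summaries, model comparison and treatment rankings.

Wraps the sampler in :mod:`ipdnma.mcmc` and derives the quantities an
analyst reports: posterior means with equal-tailed 95% credible intervals,
the deviance information criterion (DIC), all pairwise treatment contrasts
through the consistency equations, the ecological-bias contrast
delta_B - delta_A of the separated interaction model, per-covariate-level
treatment rankings, and split-R-hat / effective-sample-size convergence
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .design import ModelDesign, PriorSpec
from .mcmc import MCMCSettings, RawDraws, run_mcmc
from .network import NetworkSpec

__all__ = [
    "MCMCSettings",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "dic",
    "derived_contrasts",
    "ecological_bias",
    "rank_treatments",
    "convergence",
]


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, sd and equal-tailed 95% CrI, plus DIC."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, lower, upper
    dic: float
    pd: float
    dbar: float

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class PosteriorDraws:
    """Sampled posterior: global parameter draws plus latent covariates."""

    design: ModelDesign
    raw: RawDraws
    settings: MCMCSettings

    @property
    def names(self) -> list[str]:
        return self.raw.names

    @property
    def n_chains(self) -> int:
        return self.raw.draws.shape[0]

    def array(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        return self.raw.draws[:, :, self.raw.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.array(name).reshape(-1)

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Per-draw logHR of contrast a -> b via the consistency equations."""
        coefs = self.design.network.contrast_coefficients(a, b)
        out = np.zeros(self.raw.draws.shape[:2])
        for k, c in coefs.items():
            _, treat = self.design.network.basic_parameters[k]
            out = out + c * self.array(f"beta[{treat}]")
        return out

    def imputed_means(self) -> dict[int, float]:
        """Posterior mean of each latent covariate, keyed by table row index."""
        if self.design.imputation is None or self.raw.z_draws is None:
            return {}
        means = self.raw.z_draws.mean(axis=(0, 1))
        return {
            int(i): float(m)
            for i, m in zip(self.design.imputation.missing_idx, means)
        }

    def summary(self, params: list[str] | None = None) -> PosteriorSummary:
        names = params if params is not None else self.raw.names
        rows = []
        for name in names:
            a = self.flat(name)
            rows.append(
                {
                    "mean": a.mean(),
                    "sd": a.std(ddof=1),
                    "lower": np.percentile(a, 2.5),
                    "upper": np.percentile(a, 97.5),
                }
            )
        table = pd.DataFrame(rows, index=pd.Index(names, name="parameter"))
        d, p, dbar = dic(self)
        return PosteriorSummary(table=table, dic=d, pd=p, dbar=dbar)

    def to_dataframe(self) -> pd.DataFrame:
        """Long export: chain, iteration, parameter, value."""
        C, N, G = self.raw.draws.shape
        frames = []
        for c in range(C):
            df = pd.DataFrame(self.raw.draws[c], columns=self.raw.names)
            df.insert(0, "iter", np.arange(N))
            df.insert(0, "chain", c)
            frames.append(df.melt(id_vars=["chain", "iter"],
                                  var_name="parameter", value_name="value"))
        return pd.concat(frames, ignore_index=True)


def fit(design: ModelDesign, priors: PriorSpec | None = None,
        settings: MCMCSettings | None = None) -> PosteriorDraws:
    """Sample the posterior of a model design.

    Identical ``settings`` (including seed) give bit-identical draws.
    """
    if priors is None:
        priors = design.config.priors
    if settings is None:
        settings = MCMCSettings()
    raw = run_mcmc(design, priors, settings)
    return PosteriorDraws(design=design, raw=raw, settings=settings)


def dic(draws: PosteriorDraws) -> tuple[float, float, float]:
    """Deviance information criterion: (DIC, pD, Dbar).

    Dbar is the posterior mean deviance; pD = Dbar - D(posterior mean of the
    parameters entering the likelihood); DIC = Dbar + pD.  A negative pD is
    reported as computed (it can occur with DIC), not corrected.
    """
    dbar = float(draws.raw.deviance.mean())
    theta_bar = draws.raw.draws.mean(axis=(0, 1))[: draws.design.n_cols]
    z_bar = None
    if draws.raw.z_draws is not None:
        z_bar = draws.raw.z_draws.mean(axis=(0, 1))
    d_at_mean = draws.design.deviance(theta_bar, z_bar)
    p_d = dbar - d_at_mean
    return dbar + p_d, p_d, dbar


def derived_contrasts(draws: PosteriorDraws,
                      network: NetworkSpec | None = None) -> pd.DataFrame:
    """Posterior summaries of every pairwise contrast via consistency."""
    net = network if network is not None else draws.design.network
    rows = []
    treatments = net.treatments
    for i, a in enumerate(treatments):
        for b in treatments[i + 1:]:
            arr = draws.contrast_draws(a, b).reshape(-1)
            rows.append(
                {
                    "contrast": f"{a} vs {b}",
                    "mean": arr.mean(),
                    "sd": arr.std(ddof=1),
                    "lower": np.percentile(arr, 2.5),
                    "upper": np.percentile(arr, 97.5),
                }
            )
    return pd.DataFrame(rows).set_index("contrast")


def _interaction_names(draws: PosteriorDraws, kind: str) -> list[str]:
    """Hyper-level interaction parameter names per basic contrast."""
    names = []
    for _, treat in draws.design.network.basic_parameters:
        name = f"{kind}[{treat}]"
        if name in draws.raw.names:
            names.append(name)
    return names


def ecological_bias(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-contrast summary of delta_B - delta_A (across minus within).

    Only defined for a separated-interaction fit; the difference quantifies
    how far the aggregate (trial-level) interaction departs from the
    randomisation-protected patient-level one.
    """
    if draws.design.config.interaction_mode != "separated":
        raise ValueError(
            "ecological bias requires a separated-interaction fit"
        )
    if draws.design.config.interaction_effects == "common":
        pairs = [("all contrasts", "deltaA", "deltaB")]
    else:
        ref = draws.design.network.reference
        pairs = [(f"{ref} vs {t}", f"deltaA[{t}]", f"deltaB[{t}]")
                 for _, t in draws.design.network.basic_parameters]
    rows = []
    for label, name_a, name_b in pairs:
        a = draws.flat(name_a)
        b = draws.flat(name_b)
        diff = b - a
        rows.append(
            {
                "contrast": label,
                "mean": diff.mean(),
                "sd": diff.std(ddof=1) if diff.std(ddof=1) > 0 else 0.0,
                "lower": np.percentile(diff, 2.5),
                "upper": np.percentile(diff, 97.5),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")


def rank_treatments(draws: PosteriorDraws, covariate_levels,
                    interaction: str = "within") -> dict[float, pd.DataFrame]:
    """Ranking probabilities P(treatment has rank r) per covariate level.

    At covariate level z* the effect of treatment k versus the reference is
    beta_k plus the fitted interaction times z* — by default the within-trial
    (randomisation-protected) interaction ``delta_A``; ``interaction`` may
    also be ``"across"`` or ``"combined"`` to rank on those coefficients.
    Lower logHR ranks better (rank 1 = best).  Each row of the returned
    matrix sums to exactly 1.
    """
    cfg = draws.design.config
    levels = list(covariate_levels)
    if len(levels) > 1 and cfg.interaction_mode == "none" and cfg.covariate_mode == "none":
        raise ValueError(
            "ranking at multiple covariate levels needs covariate/interaction terms"
        )
    kind = {"within": "deltaA", "across": "deltaB", "combined": "delta"}[interaction]
    net = draws.design.network
    treatments = list(net.treatments)
    C, N = draws.raw.draws.shape[:2]
    out: dict[float, pd.DataFrame] = {}
    for z in levels:
        effects = np.zeros((len(treatments), C * N))
        for i, t in enumerate(treatments):
            if t == net.reference:
                continue
            eff = draws.flat(f"beta[{t}]").copy()
            for dname in (f"{kind}[{t}]", kind):  # independent, then common
                if dname in draws.raw.names:
                    eff = eff + z * draws.flat(dname)
                    break
            effects[i] = eff
        order = np.argsort(np.argsort(effects, axis=0, kind="stable"), axis=0)
        n_draws = effects.shape[1]
        counts = np.zeros((len(treatments), len(treatments)), dtype=np.int64)
        for i in range(len(treatments)):
            counts[i] = np.bincount(order[i], minlength=len(treatments))
        probs = counts / n_draws
        out[z] = pd.DataFrame(
            probs,
            index=pd.Index(treatments, name="treatment"),
            columns=[f"rank_{r + 1}" for r in range(len(treatments))],
        )
    return out


def convergence(draws: PosteriorDraws, params: list[str] | None = None,
                rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (needs >= 2 chains).

    Parameters with R-hat above ``rhat_threshold`` are flagged.
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    names = params if params is not None else draws.raw.names
    data = {n: draws.array(n) for n in names}
    idata = az.from_dict(posterior={n: v for n, v in data.items()})
    rhat = az.rhat(idata, method="split")
    ess = az.ess(idata)
    rows = []
    for n in names:
        r = float(rhat[n].values)
        rows.append(
            {"rhat": r, "ess": float(ess[n].values), "flagged": bool(r > rhat_threshold)}
        )
    return pd.DataFrame(rows, index=pd.Index(names, name="parameter"))
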