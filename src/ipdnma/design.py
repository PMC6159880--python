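"""Model configuration and design: from modelling choices to a fittable posterior.

The one-stage model for patient i in trial j on the log cumulative hazard
scale is

    ln H_j(t | x_ij) = s_j(ln t) + sum_k beta_k trt_kij + covariate terms,

where the treatment indicators are coded *within trial* against the trial's
own baseline arm and mapped through the network consistency equations: a
trial comparing B with C (reference A) gives its C-arm records the column
pattern beta_C - beta_B.  Treatment-covariate interactions come in two
parameterisations:

* separated — within-trial terms delta_Ak * trt_k * (z_ij - zbar_j) and
  across-trial terms delta_Bk * trt_k * zbar_j, with the covariate main
  effect centred as alpha_j (z_ij - zbar_j).  The contrast
  delta_Bk - delta_Ak measures ecological bias.
* combined — a single delta_k * trt_k * z_ij with raw alpha_j z_ij.

Missing covariate values can be imputed inside the model: each missing z_ij
becomes a latent variable with a trial-specific truncated-normal prior on
the covariate's declared support.

Everything the sampler needs is assembled here into three n-by-p matrices:
``X0`` (covariate-free column values), ``M`` (per-record multipliers of the
covariate value, so the realised design is ``X0 + diag(z) M``) and ``Xd``
(column derivatives with respect to ln t, used for the hazard).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CovariateSpec, IPDDataset
from .network import NetworkSpec
from .spline import KnotSet, basis, basis_derivative, select_knots
from .survival import LogLikelihoodResult, log_likelihood_arrays

__all__ = [
    "ModelConfig",
    "PriorSpec",
    "ModelDesign",
    "build_design",
    "attach_imputation",
    "effective_trial_means",
]

TREATMENT_EFFECTS = ("fixed", "random")
COVARIATE_MODES = ("none", "common", "fixed_trial", "random_trial")
INTERACTION_MODES = ("none", "separated", "combined")
INTERACTION_STRUCTURES = ("common", "random_trial")


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters.

    Location parameters (spline, treatment, covariate, interaction,
    inconsistency and PH coefficients) get vague Normal(0, ``normal_variance``)
    priors.  The random-treatment-effect between-trial covariance gets a
    Wishart prior on the precision with ``wishart_df`` degrees of freedom
    (default: the dimension) and identity scale; scalar random-effect
    standard deviations get Uniform(0, ``sd_upper``).
    """

    normal_variance: float = 1.0e3
    sd_upper: float = 2.0
    wishart_df: float | None = None  # None -> dimension
    wishart_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.normal_variance <= 0 or self.sd_upper <= 0 or self.wishart_scale <= 0:
            raise ValueError("prior variances/scales must be positive")


@dataclass
class ModelConfig:
    """All modelling choices for one fit."""

    covariate: str | None = None
    treatment_effects: str = "fixed"
    covariate_mode: str = "none"
    interaction_mode: str = "none"
    interaction_structure: str = "common"
    interaction_effects: str = "independent"  # or "common": one TCI coefficient
    # shared by every treatment contrast (regression coefficients equal)
    inconsistency: tuple[tuple[str, ...], ...] = ()
    closing_edges: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)
    ph_interactions: bool = False
    imputation: str = "off"  # off | truncated_normal
    trial_means: Mapping[str, float] | None = None  # None -> from data
    complete_case: bool = False
    n_knots: int = 2
    knots_override: Mapping[str, int] = field(default_factory=dict)
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.treatment_effects not in TREATMENT_EFFECTS:
            raise ValueError(f"treatment_effects must be one of {TREATMENT_EFFECTS}")
        if self.covariate_mode not in COVARIATE_MODES:
            raise ValueError(f"covariate_mode must be one of {COVARIATE_MODES}")
        if self.interaction_mode not in INTERACTION_MODES:
            raise ValueError(f"interaction_mode must be one of {INTERACTION_MODES}")
        if self.interaction_structure not in INTERACTION_STRUCTURES:
            raise ValueError(
                f"interaction_structure must be one of {INTERACTION_STRUCTURES}"
            )
        if self.interaction_effects not in ("independent", "common"):
            raise ValueError("interaction_effects must be independent|common")
        if self.imputation not in ("off", "truncated_normal"):
            raise ValueError("imputation must be 'off' or 'truncated_normal'")
        if self.interaction_mode != "none" and self.covariate_mode == "none":
            raise ValueError("an interaction needs a covariate in the model")
        if self.covariate_mode != "none" and self.covariate is None:
            raise ValueError("covariate_mode set but no covariate named")

    # -- plain-text round trip (key = value; lists comma-separated) --------

    def to_text(self) -> str:
        lines = []
        for key in (
            "covariate", "treatment_effects", "covariate_mode", "interaction_mode",
            "interaction_structure", "interaction_effects", "ph_interactions",
            "imputation", "complete_case", "n_knots",
        ):
            lines.append(f"{key} = {getattr(self, key)}")
        loops = ";".join("-".join(loop) for loop in self.inconsistency)
        lines.append(f"inconsistency = {loops}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelConfig":
        kwargs: dict = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("ph_interactions", "complete_case"):
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif key == "n_knots":
                kwargs[key] = int(value)
            elif key == "inconsistency":
                kwargs[key] = tuple(
                    tuple(part.split("-")) for part in value.split(";") if part
                )
            elif key == "covariate":
                kwargs[key] = None if value in ("", "None") else value
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class ScalarHierarchy:
    """A set of hierarchical scalar coefficient groups sharing one SD.

    Each group's per-trial columns are draws from Normal(group mean, sd^2);
    the group means and the shared sd are hyper-parameters of the fit.
    """

    label: str
    group_names: list[str]          # hyper-mean parameter names
    group_cols: list[list[int]]     # column indices per group


@dataclass
class RTEBlock:
    """Random-treatment-effects deviation layout.

    ``u_cols[j, k]`` is the column index of trial j's deviation on basic
    contrast k; deviations u_j ~ MVN(0, Sigma) with a Wishart prior on
    Sigma^-1 (conjugate Gibbs update in the sampler).
    """

    u_cols: np.ndarray  # (J, q) int


@dataclass
class ImputationBlock:
    """Latent missing-covariate layout for truncated-normal imputation."""

    missing_idx: np.ndarray          # record rows with missing covariate
    missing_trial: np.ndarray        # local trial index (into trial_list) per latent
    trial_list: list[str]            # trials with >= 1 missing value
    trial_obs: list[np.ndarray]      # observed covariate values per such trial
    bounds: tuple[float, float]


@dataclass
class ModelDesign:
    """Concrete parameter blocks and per-record design columns for one fit."""

    config: ModelConfig
    network: NetworkSpec
    colnames: list[str]
    X0: np.ndarray
    M: np.ndarray
    Xd: np.ndarray
    x: np.ndarray                # ln t per record
    d: np.ndarray                # event indicator per record
    trial_of_record: np.ndarray  # index into trial_ids
    trial_ids: list[str]
    knots: dict[str, KnotSet]
    z_obs: np.ndarray            # covariate per record (NaN where missing/latent)
    beta_cols: list[int]
    prior_sd: np.ndarray         # per-column vague prior sd (hier columns ignored)
    hier_col_mask: np.ndarray    # columns whose prior comes from a hierarchy
    scalar_hierarchies: list[ScalarHierarchy] = field(default_factory=list)
    rte: RTEBlock | None = None
    imputation: ImputationBlock | None = None
    trial_means: dict[str, float] = field(default_factory=dict)
    omega_cols: dict[tuple[str, ...], int] = field(default_factory=dict)
    phi_cols: list[int] = field(default_factory=list)
    closing_edge_of: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)

    # -- dimensions --------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.x)

    @property
    def n_cols(self) -> int:
        return len(self.colnames)

    @property
    def n_latent(self) -> int:
        return 0 if self.imputation is None else len(self.imputation.missing_idx)

    def col(self, name: str) -> int:
        return self.colnames.index(name)

    # -- likelihood --------------------------------------------------------

    def z_filled(self, z_latent: np.ndarray | None = None) -> np.ndarray:
        """Record-level covariate vector with latents substituted for NaNs."""
        z = np.where(np.isnan(self.z_obs), 0.0, self.z_obs)
        if self.imputation is not None and z_latent is not None:
            z[self.imputation.missing_idx] = z_latent
        return z

    def eta(self, theta: np.ndarray, z_latent: np.ndarray | None = None) -> np.ndarray:
        z = self.z_filled(z_latent)
        return self.X0 @ theta + z * (self.M @ theta)

    def log_likelihood(self, theta: np.ndarray,
                       z_latent: np.ndarray | None = None) -> LogLikelihoodResult:
        eta = self.eta(theta, z_latent)
        deta = self.Xd @ theta
        return log_likelihood_arrays(self.d, eta, deta, self.x)

    def deviance(self, theta: np.ndarray,
                 z_latent: np.ndarray | None = None) -> float:
        return -2.0 * self.log_likelihood(theta, z_latent).value

    def loglik_pointwise_parts(self, theta: np.ndarray):
        """(base eta, z coefficient, d eta/dx) per record — used for fast
        latent-covariate Metropolis updates, where only z changes."""
        base = self.X0 @ theta
        coef = self.M @ theta
        deta = self.Xd @ theta
        return base, coef, deta

    def audit_table(self) -> pd.DataFrame:
        """Design audit dump: realised column values per record (observed z;
        latents at their prior midpoint)."""
        z = self.z_filled(
            None if self.imputation is None
            else np.full(self.n_latent, np.mean(self.imputation.bounds))
        )
        X = self.X0 + z[:, None] * self.M
        return pd.DataFrame(X, columns=self.colnames)


# ---------------------------------------------------------------------------


def _trial_baseline(arms: set[str], network: NetworkSpec) -> str:
    """A trial's own baseline arm: the reference if randomised, else the arm
    earliest in the declared treatment order."""
    if network.reference in arms:
        return network.reference
    return min(arms, key=network.treatments.index)


def _resolve_trial_means(dataset: IPDDataset, config: ModelConfig) -> dict[str, float]:
    cov = config.covariate
    means: dict[str, float] = {}
    for trial_id, g in dataset.table.groupby("trial", sort=False):
        z = g[cov]
        if config.trial_means is not None and trial_id in config.trial_means:
            means[str(trial_id)] = float(config.trial_means[trial_id])
        elif z.notna().any():
            means[str(trial_id)] = float(z.mean())
        elif config.interaction_mode == "separated":
            raise ValueError(
                f"trial {trial_id!r} has no observed covariate values and no "
                "supplied trial mean: the separated parameterisation needs "
                "zbar_j for every trial. Fit the combined model with "
                "imputation first, harvest effective trial means "
                "(effective_trial_means) and pass them via config.trial_means "
                "(the two-pass procedure)."
            )
        else:
            means[str(trial_id)] = np.nan  # unused by the combined/raw coding
    return means


def build_design(dataset: IPDDataset, network: NetworkSpec,
                 config: ModelConfig) -> ModelDesign:
    """Assemble the design matrices and parameter layout for one model fit."""
    cov = config.covariate
    if config.complete_case and cov is not None:
        keep = dataset.table[cov].notna().to_numpy()
        dataset = dataset.subset(keep)

    table = dataset.table
    n = len(table)
    x = np.log(table["time"].to_numpy(float))
    d = table["event"].to_numpy(float)
    trial_ids = dataset.trial_ids
    trial_index = {t: i for i, t in enumerate(trial_ids)}
    trial_of_record = table["trial"].map(trial_index).to_numpy(int)
    trials = dataset.trials
    q = network.n_basic

    use_covariate = config.covariate_mode != "none"
    if use_covariate:
        z_obs = table[cov].to_numpy(float)
        spec = dataset.covariate_spec(cov)
        any_missing = bool(np.isnan(z_obs).any())
        if any_missing and config.imputation == "off":
            raise ValueError(
                "missing covariate values present but imputation is off; "
                "enable truncated_normal imputation or set complete_case"
            )
        trial_means = _resolve_trial_means(dataset, config)
    else:
        z_obs = np.full(n, np.nan)
        spec = None
        any_missing = False
        trial_means = {}

    centered = config.interaction_mode == "separated"

    # consistency-mapped treatment pattern per record: sparse {k: coef}
    baseline = {t: _trial_baseline(arms, network) for t, arms in trials.items()}
    pattern: list[dict[int, float]] = []
    for row in table.itertuples(index=False):
        pattern.append(network.contrast_coefficients(baseline[row.trial], row.treatment))

    colnames: list[str] = []
    cols_X0: list[np.ndarray] = []
    cols_M: list[np.ndarray] = []
    cols_Xd: list[np.ndarray] = []
    prior_sd: list[float] = []
    hier_mask: list[bool] = []
    vague_sd = float(np.sqrt(config.priors.normal_variance))

    def add_col(name: str, X0c, Mc=None, Xdc=None, sd=vague_sd, hier=False) -> int:
        colnames.append(name)
        cols_X0.append(np.asarray(X0c, float))
        cols_M.append(np.zeros(n) if Mc is None else np.asarray(Mc, float))
        cols_Xd.append(np.zeros(n) if Xdc is None else np.asarray(Xdc, float))
        prior_sd.append(sd)
        hier_mask.append(hier)
        return len(colnames) - 1

    # 1. per-trial spline baselines
    knots: dict[str, KnotSet] = {}
    for t in trial_ids:
        in_trial = trial_of_record == trial_index[t]
        ev = in_trial & (d > 0)
        xe = x[ev]
        n_int = config.knots_override.get(t, config.n_knots)
        distinct = np.unique(xe).size
        if distinct < 2:
            # sparse-event fallback: boundary knots from all observed times
            # (the spline slope is then only weakly identified and the prior
            # keeps it finite; relevant for near-zero-event trials)
            xe = x[in_trial]
            distinct = np.unique(xe).size
            if distinct < 2:
                raise ValueError(
                    f"trial {t!r} has fewer than 2 distinct observation times; "
                    "cannot fit a baseline spline"
                )
            n_int = 0
        if distinct < 4:  # small-trial fallback: Weibull baseline
            n_int = 0
        n_int = min(n_int, distinct - 2)
        ks = select_knots(xe, n_int)
        knots[t] = ks
        b = basis(x, ks) * in_trial[:, None]
        db = basis_derivative(x, ks) * in_trial[:, None]
        add_col(f"gamma[{t},0]", in_trial.astype(float))
        for m in range(ks.n_basis):
            add_col(f"gamma[{t},{m + 1}]", b[:, m], Xdc=db[:, m])

    # 2. basic treatment contrasts via the consistency map
    beta_cols = []
    pat_mat = np.zeros((n, q))
    for i, pat in enumerate(pattern):
        for k, c in pat.items():
            pat_mat[i, k] = c
    for k, (_, treat) in enumerate(network.basic_parameters):
        beta_cols.append(add_col(f"beta[{treat}]", pat_mat[:, k]))

    # 3. random treatment effects: per-trial deviations u_{j,k}
    rte = None
    if config.treatment_effects == "random":
        u_cols = np.zeros((len(trial_ids), q), dtype=int)
        for j, t in enumerate(trial_ids):
            in_trial = (trial_of_record == j).astype(float)
            for k, (_, treat) in enumerate(network.basic_parameters):
                u_cols[j, k] = add_col(
                    f"u[{t},{treat}]", pat_mat[:, k] * in_trial, hier=True
                )
        rte = RTEBlock(u_cols=u_cols)

    # 4. covariate main effect
    scalar_hierarchies: list[ScalarHierarchy] = []
    if use_covariate:
        zbar = np.array([trial_means[t] for t in trial_ids])[trial_of_record]
        offset = -zbar if centered else np.zeros(n)
        if config.covariate_mode == "common":
            add_col("alpha", offset, Mc=np.ones(n))
        else:
            acols = []
            for j, t in enumerate(trial_ids):
                in_trial = (trial_of_record == j).astype(float)
                acols.append(
                    add_col(
                        f"alpha[{t}]", offset * in_trial, Mc=in_trial,
                        hier=(config.covariate_mode == "random_trial"),
                    )
                )
            if config.covariate_mode == "random_trial":
                scalar_hierarchies.append(
                    ScalarHierarchy("alpha", ["alpha"], [acols])
                )

    # 5. treatment-covariate interactions
    if config.interaction_mode != "none":
        # interaction patterns: one per basic contrast (independent effects)
        # or a single shared pattern (common effects: equal TCI coefficients,
        # so head-to-head contrasts of non-reference arms carry none)
        if config.interaction_effects == "common":
            patterns = [("", pat_mat.sum(axis=1))]
        else:
            patterns = [
                (f"[{treat}]", pat_mat[:, k])
                for k, (_, treat) in enumerate(network.basic_parameters)
            ]
        hier = config.interaction_structure == "random_trial"
        within_name = "deltaA" if config.interaction_mode == "separated" else "delta"
        within_offset = (lambda w: -w * zbar) if centered else (lambda w: np.zeros(n))
        group_names, group_cols = [], []
        for suffix, pat in patterns:
            if hier:
                cols_k = []
                for j, t in enumerate(trial_ids):
                    in_trial = (trial_of_record == j).astype(float)
                    w = pat * in_trial
                    if not np.any(w):
                        continue
                    label = f"{within_name}[{t}{',' if suffix else ''}{suffix.strip('[]')}]"
                    cols_k.append(add_col(label, within_offset(w), Mc=w, hier=True))
                group_names.append(f"{within_name}{suffix}")
                group_cols.append(cols_k)
            else:
                add_col(f"{within_name}{suffix}", within_offset(pat), Mc=pat)
        if hier:
            scalar_hierarchies.append(
                ScalarHierarchy(within_name, group_names, group_cols)
            )
        if config.interaction_mode == "separated":
            for suffix, pat in patterns:
                add_col(f"deltaB{suffix}", pat * zbar)

    # 6. inconsistency parameters, one per declared loop
    omega_cols: dict[tuple[str, ...], int] = {}
    closing_edge_of: dict[tuple[str, ...], tuple[str, str]] = {}
    order = {t: i for i, t in enumerate(network.treatments)}
    for loop in config.inconsistency:
        loop = tuple(loop)
        if loop not in network.loops:
            raise ValueError(f"declared loop {loop} is not a loop of the network")
        loop_edges = []
        cyc = list(loop)
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            e = tuple(sorted((a, b), key=order.get))
            if e in network.edges:
                loop_edges.append(e)
        if loop in config.closing_edges:
            edge = tuple(config.closing_edges[loop])
        else:
            # default: the loop edge with the fewest dedicated two-arm trials
            # (an edge seen only inside multi-arm trials cannot carry omega:
            # multi-arm trials are internally consistent)
            def n_twoarm(e):
                return sum(1 for arms in trials.values() if arms == set(e))
            candidates = [e for e in loop_edges if n_twoarm(e) > 0]
            if not candidates:
                raise ValueError(
                    f"loop {loop} has no edge with a dedicated two-arm trial; "
                    "its inconsistency cannot be assessed by the loop-omega "
                    "route"
                )
            edge = min(candidates, key=lambda e: (n_twoarm(e), e))
        closing_edge_of[loop] = edge
        u, v = edge
        col = np.zeros(n)
        for t, arms in trials.items():
            if arms == set(edge):
                in_trial = trial_of_record == trial_index[t]
                on_v = table["treatment"].to_numpy() == (v if baseline[t] == u else u)
                sign = 1.0 if baseline[t] == u else -1.0
                col[in_trial & on_v] = sign
        if not np.any(col):
            raise ValueError(
                f"no two-arm trial with design {edge} to carry the "
                f"inconsistency parameter of loop {loop}"
            )
        omega_cols[loop] = add_col(f"omega[{'-'.join(loop)}]", col)

    # 7. treatment-ln(time) interactions (proportional-hazards testing)
    phi_cols = []
    if config.ph_interactions:
        for k, (_, treat) in enumerate(network.basic_parameters):
            if not np.any(pat_mat[:, k]):
                continue
            phi_cols.append(
                add_col(f"phi[{treat}]", pat_mat[:, k] * x, Xdc=pat_mat[:, k])
            )

    design = ModelDesign(
        config=config,
        network=network,
        colnames=colnames,
        X0=np.column_stack(cols_X0),
        M=np.column_stack(cols_M),
        Xd=np.column_stack(cols_Xd),
        x=x,
        d=d,
        trial_of_record=trial_of_record,
        trial_ids=trial_ids,
        knots=knots,
        z_obs=z_obs,
        beta_cols=beta_cols,
        prior_sd=np.asarray(prior_sd),
        hier_col_mask=np.asarray(hier_mask, bool),
        scalar_hierarchies=scalar_hierarchies,
        rte=rte,
        trial_means={k: v for k, v in trial_means.items()},
        omega_cols=omega_cols,
        phi_cols=phi_cols,
        closing_edge_of=closing_edge_of,
    )

    if use_covariate and any_missing and config.imputation == "truncated_normal":
        if spec.bounds is None:
            raise ValueError(
                f"imputation requires declared bounds for covariate {cov!r}"
            )
        design = attach_imputation(design, dataset, spec.bounds)
    return design


def attach_imputation(design: ModelDesign, dataset: IPDDataset,
                      bounds: tuple[float, float]) -> ModelDesign:
    """Add latent truncated-normal variables for missing covariate values.

    Each missing z_ij becomes a latent variable with prior
    Normal(mu_j, sigma_j^2) truncated to ``bounds``; mu_j and sigma_j are
    trial-level hyper-parameters informed by that trial's observed values
    (weakly-informative hyper-priors).  A design with no missing values is
    returned unchanged.
    """
    cov = design.config.covariate
    z = design.z_obs
    missing = np.flatnonzero(np.isnan(z))
    if missing.size == 0:
        return design
    if bounds is None or not bounds[0] < bounds[1]:
        raise ValueError("imputation requires ordered covariate bounds")
    trial_with_missing = sorted(
        set(design.trial_of_record[missing]),
    )
    trial_list = [design.trial_ids[j] for j in trial_with_missing]
    local = {j: i for i, j in enumerate(trial_with_missing)}
    missing_trial = np.array([local[j] for j in design.trial_of_record[missing]])
    trial_obs = []
    for j in trial_with_missing:
        mask = (design.trial_of_record == j) & ~np.isnan(z)
        trial_obs.append(z[mask])
    imp = ImputationBlock(
        missing_idx=missing,
        missing_trial=missing_trial,
        trial_list=trial_list,
        trial_obs=trial_obs,
        bounds=(float(bounds[0]), float(bounds[1])),
    )
    return dataclasses.replace(design, imputation=imp)


def effective_trial_means(dataset: IPDDataset, covariate: str,
                          imputed: Mapping[int, float]) -> dict[str, float]:
    """Trial covariate means combining observed and imputed values.

    ``imputed`` maps a table row index (a record with missing covariate) to
    the posterior mean of its latent value.  A fully observed trial keeps its
    observed mean; a partially missing trial gets the count-weighted average
    of the observed mean and the mean of the imputed posterior means; a fully
    missing trial uses the imputed values alone.
    """
    out: dict[str, float] = {}
    table = dataset.table
    for trial_id, g in table.groupby("trial", sort=False):
        z = g[covariate]
        obs = z.dropna()
        miss_rows = z.index[z.isna()]
        imp_vals = [imputed[i] for i in miss_rows if i in imputed]
        if len(miss_rows) and len(imp_vals) != len(miss_rows):
            raise KeyError(
                f"trial {trial_id!r}: posterior means missing for some latent values"
            )
        n_obs, n_imp = len(obs), len(imp_vals)
        if n_imp == 0:
            out[str(trial_id)] = float(obs.mean())
        elif n_obs == 0:
            out[str(trial_id)] = float(np.mean(imp_vals))
        else:
            out[str(trial_id)] = float(
                (obs.sum() + np.sum(imp_vals)) / (n_obs + n_imp)
            )
    return out
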