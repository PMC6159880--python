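"""Synthetic IPD networks with known generating truth.

Emulates the structure of a connected multi-treatment survival network of
two- and three-arm randomised trials — trial-specific Weibull baseline
hazards, a bounded (optionally ordinal) patient covariate whose distribution
varies by trial, independently controllable within- and across-trial
treatment-covariate interactions, loop inconsistency, proportional-hazards
violations, administrative plus dropout censoring, and per-trial covariate
missingness (including a fully missing trial).  Event times are produced by
inverse transform on the Weibull cumulative hazard scaled by the linear
predictor — exactly the model class the package fits, so misspecification
has to be introduced deliberately (phi, non-linear covariate effects).

The default configuration is a scaled-down analogue of a four-treatment
chemoradiation network: reference radiotherapy-like arm, three active
contrasts, ~15 trials of 60 per arm, an ordinal severity covariate coded
0/1/2 whose trial means spread over the support, and ~40-50% event fraction
under administrative censoring at 5 time units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CovariateSpec, IPDDataset

__all__ = ["GeneratorConfig", "TruthRecord", "generate_network", "apply_missingness"]

DEFAULT_DESIGNS = (
    (("RT", "CTRT"), 6),
    (("RT", "CT+RT"), 4),
    (("RT", "CT+S"), 3),
    (("CT+RT", "CT+S"), 1),
    (("RT", "CTRT", "CT+RT"), 1),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating truth for one synthetic network."""

    treatments: tuple[str, ...] = ("RT", "CTRT", "CT+RT", "CT+S")
    reference: str = "RT"
    designs: tuple[tuple[tuple[str, ...], int], ...] = DEFAULT_DESIGNS
    n_per_arm: int = 60
    baseline_shape_range: tuple[float, float] = (0.8, 1.3)
    baseline_scale_range: tuple[float, float] = (4.0, 9.0)
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"CTRT": -0.2, "CT+RT": 0.0, "CT+S": -0.4}
    )
    covariate: str = "stage"
    z_bounds: tuple[float, float] = (0.0, 2.0)
    trial_mean_range: tuple[float, float] = (0.3, 1.7)
    z_sd: float = 0.7
    ordinal: bool = True
    alpha: float = 0.55
    delta_within: Mapping[str, float] = field(default_factory=dict)
    delta_across: Mapping[str, float] = field(default_factory=dict)
    nonlinear_mid_offset: float = 0.0  # departure from linearity at the middle level
    omega: Mapping[tuple[str, str], float] = field(default_factory=dict)
    phi: Mapping[str, float] = field(default_factory=dict)
    admin_censor_time: float = 5.0
    dropout_rate: float = 0.2
    trial_mean_spacing: str = "uniform"  # or "even": deterministic grid
    interaction_parameterisation: str = "separated"  # or "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.treatments:
            raise ValueError("reference must be one of the treatments")
        if self.interaction_parameterisation not in ("separated", "combined"):
            raise ValueError("interaction_parameterisation: separated|combined")
        if self.trial_mean_spacing not in ("uniform", "even"):
            raise ValueError("trial_mean_spacing: uniform|even")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        for mapping, what in (
            (self.beta, "beta"),
            (self.delta_within, "delta_within"),
            (self.delta_across, "delta_across"),
            (self.phi, "phi"),
        ):
            bad = set(mapping) - set(self.treatments)
            if bad:
                raise ValueError(f"{what} refers to unknown treatment(s) {sorted(bad)}")
        design_sets = [frozenset(arms) for arms, _ in self.designs]
        for edge in self.omega:
            if frozenset(edge) not in design_sets:
                raise ValueError(
                    f"omega declared for edge {edge} with no trial of that design"
                )
        arms_used = set().union(*design_sets)
        if not arms_used <= set(self.treatments):
            raise ValueError("designs use undeclared treatments")


@dataclass(frozen=True)
class TruthRecord:
    """Frozen generating parameters, including realised per-trial quantities."""

    config: GeneratorConfig
    trial_designs: tuple[tuple[str, tuple[str, ...]], ...]
    baseline_shape: Mapping[str, float]
    baseline_scale: Mapping[str, float]
    trial_mean_target: Mapping[str, float]
    trial_mean_realised: Mapping[str, float]

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {"|".join(k) if isinstance(k, tuple) else k: enc(v)
                        for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        return json.dumps(enc(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        raw = json.loads(text)
        cfg = raw["config"]
        cfg["treatments"] = tuple(cfg["treatments"])
        cfg["designs"] = tuple((tuple(arms), n) for arms, n in cfg["designs"])
        cfg["z_bounds"] = tuple(cfg["z_bounds"])
        cfg["baseline_shape_range"] = tuple(cfg["baseline_shape_range"])
        cfg["baseline_scale_range"] = tuple(cfg["baseline_scale_range"])
        cfg["trial_mean_range"] = tuple(cfg["trial_mean_range"])
        cfg["omega"] = {tuple(k.split("|")): v for k, v in cfg["omega"].items()}
        config = GeneratorConfig(**cfg)
        return cls(
            config=config,
            trial_designs=tuple((t, tuple(a)) for t, a in raw["trial_designs"]),
            baseline_shape=raw["baseline_shape"],
            baseline_scale=raw["baseline_scale"],
            trial_mean_target=raw["trial_mean_target"],
            trial_mean_realised=raw["trial_mean_realised"],
        )


def generate_network(config: GeneratorConfig) -> tuple[IPDDataset, TruthRecord]:
    """Generate one synthetic network; identical config (incl. seed) gives an
    identical dataset."""
    rng = np.random.default_rng(config.seed)
    a_z, b_z = config.z_bounds
    rows = []
    trial_designs = []
    shapes: dict[str, float] = {}
    scales: dict[str, float] = {}
    mean_target: dict[str, float] = {}
    mean_real: dict[str, float] = {}

    lo_m, hi_m = config.trial_mean_range

    trial_no = 0
    for arms, count in config.designs:
        if config.trial_mean_spacing == "even" and count > 1:
            # designed spread: each comparison's trials place their covariate
            # means on a deterministic full-range grid, maximising across-trial
            # identification of the aggregate interaction without confounding
            # mean level with trial design
            grid = iter(np.linspace(lo_m, hi_m, count))
        else:
            grid = None
        for _ in range(count):
            trial_no += 1
            tid = f"T{trial_no:02d}"
            trial_designs.append((tid, tuple(arms)))
            shape = rng.uniform(*config.baseline_shape_range)
            scale = rng.uniform(*config.baseline_scale_range)
            shapes[tid], scales[tid] = shape, scale
            zbar_t = (next(grid) if grid is not None
                      else rng.uniform(lo_m, hi_m))
            mean_target[tid] = zbar_t

            n_tot = config.n_per_arm * len(arms)
            # truncated-normal covariate, optionally rounded to the ordinal grid
            z = np.empty(n_tot)
            left = np.arange(n_tot)
            while left.size:
                draw = rng.normal(zbar_t, config.z_sd, size=left.size)
                ok = (draw >= a_z) & (draw <= b_z)
                z[left[ok]] = draw[ok]
                left = left[~ok]
            if config.ordinal:
                z = np.round(z)
            zbar = float(z.mean())
            mean_real[tid] = zbar

            arm_of = np.repeat(np.arange(len(arms)), config.n_per_arm)
            beta = np.array([config.beta.get(a, 0.0) for a in arms])[arm_of]
            phi = np.array([config.phi.get(a, 0.0) for a in arms])[arm_of]
            # inconsistency applies to two-arm trials of the declared design
            omega = 0.0
            for edge, w in config.omega.items():
                if set(arms) == set(edge):
                    omega = w
            non_base = (arm_of != 0).astype(float)

            dA = np.array([config.delta_within.get(a, 0.0) for a in arms])[arm_of]
            dB = np.array([config.delta_across.get(a, 0.0) for a in arms])[arm_of]
            if config.interaction_parameterisation == "separated":
                # algebraically dA*(z - zbar) + dB*zbar, written so that
                # dA == dB reduces bit-exactly to the combined form
                inter = dA * z + (dB - dA) * zbar
            else:
                inter = dA * z  # combined: delta = delta_within by convention
            eta = beta + config.alpha * z + inter + omega * non_base
            if config.nonlinear_mid_offset:
                eta = eta + config.nonlinear_mid_offset * (np.round(z) == 1.0)

            # inverse transform: ln H = (shape + phi) ln t - shape ln scale + eta
            e = rng.exponential(size=n_tot)
            k_eff = shape + phi
            if np.any(k_eff <= 0):
                raise ValueError("phi makes the cumulative hazard non-monotone")
            log_t = (np.log(e) + shape * np.log(scale) - eta) / k_eff
            t_event = np.exp(log_t)

            cens = np.full(n_tot, config.admin_censor_time)
            drop = rng.uniform(size=n_tot) < config.dropout_rate
            cens[drop] = rng.uniform(0, config.admin_censor_time, size=drop.sum())
            t_obs = np.minimum(t_event, cens)
            event = (t_event <= cens).astype(int)
            t_obs = np.maximum(t_obs, 1e-8)

            for i in range(n_tot):
                rows.append(
                    {
                        "trial": tid,
                        "treatment": arms[arm_of[i]],
                        "time": t_obs[i],
                        "event": event[i],
                        config.covariate: z[i],
                    }
                )

    table = pd.DataFrame(rows)
    dataset = IPDDataset(
        table,
        covariates=[CovariateSpec(config.covariate, bounds=config.z_bounds,
                                  ordinal=config.ordinal)],
        treatments=[t for t in config.treatments
                    if t in set(table["treatment"])],
    )
    truth = TruthRecord(
        config=config,
        trial_designs=tuple(trial_designs),
        baseline_shape=shapes,
        baseline_scale=scales,
        trial_mean_target=mean_target,
        trial_mean_realised=mean_real,
    )
    return dataset, truth


def apply_missingness(
    dataset: IPDDataset,
    mechanism: str = "MCAR",
    rates: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    covariate: str | None = None,
    fully_missing_trial: str | None = None,
    arm_factor: float = 2.0,
) -> IPDDataset:
    """Mask covariate values; everything else is untouched.

    ``MCAR`` masks each value with its trial's rate uniformly; ``MAR-on-arm``
    multiplies the rate by ``arm_factor`` on non-baseline arms (capped at 1).
    ``fully_missing_trial`` names one trial whose covariate is masked
    entirely, emulating a trial that never recorded it.
    """
    if mechanism not in ("MCAR", "MAR-on-arm"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR-on-arm'")
    if covariate is None:
        if not dataset.covariates:
            raise ValueError("dataset has no covariates")
        covariate = dataset.covariates[0].name
    rng = np.random.default_rng(seed)
    table = dataset.table.copy()

    def rate_of(trial: str) -> float:
        r = rates.get(trial, 0.0) if isinstance(rates, Mapping) else float(rates)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate for trial {trial!r} outside [0,1]: {r}")
        return r

    for trial_id, g in table.groupby("trial", sort=False):
        if trial_id == fully_missing_trial:
            table.loc[g.index, covariate] = np.nan
            continue
        r = rate_of(str(trial_id))
        if r == 0.0:
            continue
        p = np.full(len(g), r)
        if mechanism == "MAR-on-arm":
            base_arm = g["treatment"].iloc[0]
            p = np.where(g["treatment"] == base_arm, r, np.minimum(1.0, r * arm_factor))
        mask = rng.uniform(size=len(g)) < p
        table.loc[g.index[mask], covariate] = np.nan
    return IPDDataset(table, dataset.covariates, treatments=dataset.treatments)
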