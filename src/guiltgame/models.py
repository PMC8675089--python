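"""Utility-model family for player B's Cooperate/Defect choice.

The utility of player B integrates guilt aversion and Fehr–Schmidt-style
inequity aversion:

    u_B(Cooperate) = x_B - alpha * |x_A - x_B|
    u_B(Defect)    = y_B - gamma * tau * (x_A - y_A) - alpha * |y_A - y_B|

where ``gamma`` scales the guilt of falling short of A's expectation and
``alpha`` scales disutility from unequal payoffs.  Choice is stochastic with
the softmax/logistic rule at inverse temperature 1:

    P(Cooperate) = logistic(u_B(Cooperate) - u_B(Defect))

which is algebraically identical to a logistic regression on the per-trial
regressors:  logit P = beta0 + beta1*Reward + beta2*Guilt + beta3*Inequity,
with beta2 = gamma and beta3 = alpha.  The candidate model space consists of
the 10 specifications with Reward always present, optionally Guilt, and one
of {nothing, combined Inequity, Inequity-positive, Inequity-negative, both
split terms}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_design import Design, RegressorRow, TrialSpec, compute_regressors, regressor_frame

__all__ = [
    "AgentParams",
    "ModelSpec",
    "COMPONENTS",
    "utility",
    "choice_prob",
    "linear_index",
    "enumerate_model_space",
    "design_matrix",
    "get_model_spec",
]

#: component label -> regressor column
COMPONENTS = {
    "Rw": "reward",
    "Gu": "guilt",
    "Iq": "inequity",
    "Ip": "inequity_pos",
    "In": "inequity_neg",
}


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth generative parameters for one simulated participant.

    gamma and alpha are on a per-yen scale (the regressors are in yen), so
    realistic values are of order 1e-3.  A narrowly self-interested agent is
    ``gamma = alpha = 0``.
    """

    gamma: float
    alpha: float
    reward_weight: float = 1.0
    intercept: float = 0.0

    def __post_init__(self):
        for name in ("gamma", "alpha", "reward_weight", "intercept"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def utility(trial: TrialSpec, action: str, params: AgentParams) -> float:
    """Player B's utility (yen scale) of Cooperate or Defect on one trial."""
    if action == "Cooperate":
        return trial.x_B - params.alpha * abs(trial.x_A - trial.x_B)
    if action == "Defect":
        return (
            trial.y_B
            - params.gamma * trial.tau * (trial.x_A - trial.y_A)
            - params.alpha * abs(trial.y_A - trial.y_B)
        )
    raise ValueError(f"action must be 'Cooperate' or 'Defect', got {action!r}")


def _logistic(x):
    # numerically stable for large |x|
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def choice_prob(trial: TrialSpec, params: AgentParams) -> float:
    """Probability that B cooperates under the softmax rule (inverse temp 1).

    The logit is ``intercept + reward_weight*reward + gamma*guilt +
    alpha*inequity``; with reward_weight 1 and intercept 0 this is exactly
    the utility difference u_B(Cooperate) - u_B(Defect).
    """
    r = compute_regressors(trial)
    z = (
        params.intercept
        + params.reward_weight * r.reward
        + params.gamma * r.guilt
        + params.alpha * r.inequity
    )
    p = float(_logistic(z))
    # strictly interior: saturation only at floating-point resolution
    return min(max(p, np.finfo(float).tiny), 1.0 - np.finfo(float).epsneg)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate specification: a named subset of regressor components."""

    name: str
    components: tuple[str, ...]
    is_best: bool = False      # winner of the CV/BIC comparison
    is_runner_up: bool = False  # Fehr–Schmidt-type second best

    def __post_init__(self):
        unknown = set(self.components) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if "Iq" in self.components and ({"Ip", "In"} & set(self.components)):
            raise ValueError("combined inequity Iq cannot co-occur with split terms Ip/In")

    @property
    def n_params(self) -> int:
        """Number of free coefficients including the intercept."""
        return len(self.components) + 1

    @property
    def columns(self) -> list[str]:
        return [COMPONENTS[c] for c in self.components]


def enumerate_model_space() -> list[ModelSpec]:
    """The 10 candidate models: Rw always present, plus subsets of
    {Gu} x {nothing, Iq, Ip, In, IpIn}."""
    specs = []
    inequity_variants = [(), ("Iq",), ("Ip",), ("In",), ("Ip", "In")]
    for gu in [(), ("Gu",)]:
        for iq in inequity_variants:
            comps = ("Rw",) + gu + iq
            name = "".join(comps)
            specs.append(
                ModelSpec(
                    name=name,
                    components=comps,
                    is_best=(name == "RwGuIq"),
                    is_runner_up=(name == "RwGuIpIn"),
                )
            )
    assert len(specs) == 10
    return specs


def get_model_spec(name: str) -> ModelSpec:
    """Look up a model by its report label (e.g. 'RwGuIq')."""
    for spec in enumerate_model_space():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model {name!r}; valid: {[s.name for s in enumerate_model_space()]}")


def linear_index(regressors: RegressorRow, betas, spec: ModelSpec) -> float:
    """Logit value beta0 + sum_k beta_k * component_k for one trial."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} betas for {spec.name}, got {betas.shape}")
    vals = np.array([getattr(regressors, col) for col in spec.columns])
    return float(betas[0] + betas[1:] @ vals)


def design_matrix(design: Design, spec: ModelSpec) -> np.ndarray:
    """(n_trials, n_params) matrix with a leading column of ones."""
    frame = regressor_frame(design)
    X = np.column_stack([np.ones(len(design))] + [frame[col].to_numpy(float) for col in spec.columns])
    return X
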