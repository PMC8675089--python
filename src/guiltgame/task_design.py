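"""Trust-game trial designs and model regressors.

A trial of the binary trust game gives player B a choice between Cooperate
(payoffs ``x_A``, ``x_B``) and Defect (payoffs ``y_A``, ``y_B``), after
player A has forgone an outside option (``z_A``, ``z_B``) and revealed a
belief ``tau`` — the probability A assigns to B cooperating.  Two payoff
orderings make the game meaningful:

* ``y_A < z_A < x_A`` — entering is an act of trust by A;
* ``z_B < x_B < y_B`` — B is tempted to defect, so cooperating is costly.

From each trial three behavioural regressors are derived:

* ``reward  = x_B - y_B``                (monetary gain from cooperating, <= 0 is allowed)
* ``guilt   = tau * (x_A - y_A)``        (A's expected payoff shortfall if B defects)
* ``inequity = |y_A - y_B| - |x_A - x_B|`` (how much more unequal Defect is)

plus a Fehr–Schmidt split of inequity into disadvantageous (``inequity_neg``,
B behind A) and advantageous (``inequity_pos``, B ahead of A) components,
oriented so that ``inequity == inequity_pos + inequity_neg`` always holds and
positive values mean Defect produces more of that inequity type.

The canonical design has 45 trials with tau frequencies
{0.60: 7, 0.70: 5, 0.80: 13, 0.90: 11, 1.00: 9} and near-orthogonal
regressor columns (max absolute pairwise Pearson r < 0.30), obtained here by
rejection sampling over integer payoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialSpec",
    "RegressorRow",
    "Design",
    "DesignValidationError",
    "CANONICAL_TAU_TABLE",
    "DEFAULT_PAYOFF_RANGE",
    "compute_regressors",
    "regressor_frame",
    "max_abs_regressor_correlation",
    "generate_design",
    "validate_design",
    "read_design",
    "write_design",
]

#: tau -> number of trials in the canonical 45-trial design.
CANONICAL_TAU_TABLE: dict[float, int] = {0.60: 7, 0.70: 5, 0.80: 13, 0.90: 11, 1.00: 9}

#: inclusive payoff bounds (yen); payoffs are drawn as multiples of PAYOFF_STEP.
DEFAULT_PAYOFF_RANGE: tuple[int, int] = (100, 1000)
PAYOFF_STEP: int = 10


class DesignValidationError(ValueError):
    """A trial or design violates the trust-game payoff constraints."""


@dataclass(frozen=True)
class TrialSpec:
    """One trust-game trial: six payoffs (yen) and A's revealed belief tau."""

    x_A: int
    x_B: int
    y_A: int
    y_B: int
    z_A: int
    z_B: int
    tau: float

    def violations(self) -> list[str]:
        """Return human-readable descriptions of violated invariants."""
        out = []
        if not (self.y_A < self.z_A < self.x_A):
            out.append(f"trust ordering violated: require y_A < z_A < x_A, got {self.y_A}, {self.z_A}, {self.x_A}")
        if not (self.z_B < self.x_B < self.y_B):
            out.append(f"temptation ordering violated: require z_B < x_B < y_B, got {self.z_B}, {self.x_B}, {self.y_B}")
        if not (0.0 <= self.tau <= 1.0):
            out.append(f"tau must lie in [0, 1], got {self.tau}")
        for name in ("x_A", "x_B", "y_A", "y_B", "z_A", "z_B"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                out.append(f"payoff {name} must be a strictly positive integer, got {v!r}")
        return out

    def validate(self) -> "TrialSpec":
        v = self.violations()
        if v:
            raise DesignValidationError("; ".join(v))
        return self


@dataclass(frozen=True)
class RegressorRow:
    """Per-trial behavioural regressors derived from payoffs and belief."""

    reward: float
    guilt: float
    inequity: float
    inequity_pos: float
    inequity_neg: float


def compute_regressors(trial: TrialSpec) -> RegressorRow:
    """Derive the Reward/Guilt/Inequity regressors for one trial.

    Raises :class:`DesignValidationError` if the trial violates the payoff
    orderings (guilt is only guaranteed non-negative under them).
    """
    trial.validate()
    reward = trial.x_B - trial.y_B
    guilt = trial.tau * (trial.x_A - trial.y_A)
    inequity = abs(trial.y_A - trial.y_B) - abs(trial.x_A - trial.x_B)
    inequity_neg = max(trial.y_A - trial.y_B, 0) - max(trial.x_A - trial.x_B, 0)
    inequity_pos = max(trial.y_B - trial.y_A, 0) - max(trial.x_B - trial.x_A, 0)
    return RegressorRow(reward, guilt, inequity, inequity_pos, inequity_neg)


@dataclass
class Design:
    """An ordered collection of trials (canonically 45)."""

    trials: list[TrialSpec]
    seed: int | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Payoff/belief table, one row per trial."""
        return pd.DataFrame(
            {
                "trial_id": np.arange(len(self.trials)),
                "x_A": [t.x_A for t in self.trials],
                "x_B": [t.x_B for t in self.trials],
                "y_A": [t.y_A for t in self.trials],
                "y_B": [t.y_B for t in self.trials],
                "z_A": [t.z_A for t in self.trials],
                "z_B": [t.z_B for t in self.trials],
                "tau": [t.tau for t in self.trials],
            }
        )

    def tau_counts(self) -> dict[float, int]:
        out: dict[float, int] = {}
        for t in self.trials:
            out[t.tau] = out.get(t.tau, 0) + 1
        return out


def regressor_frame(design: Design) -> pd.DataFrame:
    """Regressor table (reward, guilt, inequity, inequity_pos, inequity_neg)."""
    rows = [compute_regressors(t) for t in design.trials]
    return pd.DataFrame(
        {
            "reward": [r.reward for r in rows],
            "guilt": [r.guilt for r in rows],
            "inequity": [r.inequity for r in rows],
            "inequity_pos": [r.inequity_pos for r in rows],
            "inequity_neg": [r.inequity_neg for r in rows],
        }
    )


def max_abs_regressor_correlation(design: Design) -> float:
    """Max absolute pairwise Pearson r among reward, guilt, inequity columns."""
    cols = regressor_frame(design)[["reward", "guilt", "inequity"]]
    corr = cols.corr().to_numpy()
    return float(np.max(np.abs(corr[np.triu_indices(3, k=1)])))


def _random_trial(tau: float, lo: int, hi: int, rng: np.random.Generator) -> TrialSpec:
    """Draw one trial satisfying both payoff orderings, payoffs on a 10-yen grid."""
    grid = np.arange(lo, hi + 1, PAYOFF_STEP)
    while True:
        y_A, z_A, x_A = np.sort(rng.choice(grid, size=3, replace=False))
        z_B, x_B, y_B = np.sort(rng.choice(grid, size=3, replace=False))
        return TrialSpec(int(x_A), int(x_B), int(y_A), int(y_B), int(z_A), int(z_B), tau)


def _design_correlation_metrics(design: Design) -> tuple[float, float, float]:
    """(main, cross, split) correlation summaries of a design.

    main  — max |r| among reward/guilt/inequity (the headline constraint);
    cross — max |r| of reward/guilt against the split inequity terms;
    split — r between the two split terms (high values make the combined
            and split inequity models nearly indistinguishable).
    """
    C = regressor_frame(design).corr().to_numpy()
    main = max(abs(C[0, 1]), abs(C[0, 2]), abs(C[1, 2]))
    cross = max(abs(C[0, 3]), abs(C[0, 4]), abs(C[1, 3]), abs(C[1, 4]))
    return float(main), float(cross), float(C[3, 4])


def generate_design(
    tau_table: dict[float, int] | None = None,
    payoff_range: tuple[int, int] = DEFAULT_PAYOFF_RANGE,
    max_abs_corr: float = 0.30,
    seed: int = 0,
    max_attempts: int = 2000,
    method: str = "reject",
    split_max_corr: float = 0.35,
    reference_effects: tuple[float, float, float] = (0.030, 0.015, 0.005),
) -> Design:
    """Sample a design whose regressors are nearly orthogonal.

    Parameters
    ----------
    tau_table
        Mapping tau -> trial count; defaults to the canonical table
        ``{0.60: 7, 0.70: 5, 0.80: 13, 0.90: 11, 1.00: 9}`` (45 trials).
    payoff_range
        Inclusive yen bounds for all six payoffs (drawn on a 10-yen grid).
    max_abs_corr
        Acceptance threshold on the maximum absolute pairwise Pearson
        correlation among the reward, guilt and inequity columns.
    seed
        Seeds the sampler; equal seeds yield identical designs.
    max_attempts
        Rejection budget (whole designs for "reject", single-trial
        exchanges for "exchange").
    method
        "reject" (default) redraws whole designs until the headline
        constraint holds.  "exchange" runs a single-trial exchange
        annealer that additionally keeps reward/guilt decorrelated from
        the split inequity terms (below ``split_max_corr``) and maximizes
        a local model-discriminability criterion at ``reference_effects``
        — use it when the combined-vs-split inequity models must be
        distinguishable from 45 choices.

    Raises
    ------
    RuntimeError
        If the budget is exhausted; the message reports the best (smallest)
        maximum correlation achieved.
    """
    if tau_table is None:
        tau_table = dict(CANONICAL_TAU_TABLE)
    lo, hi = payoff_range
    if hi - lo < 2 * PAYOFF_STEP:
        raise ValueError("payoff_range too narrow to admit the orderings")
    taus = [tau for tau, n in sorted(tau_table.items()) for _ in range(n)]
    rng = np.random.default_rng(seed)
    if method == "reject":
        best = np.inf
        for _ in range(max_attempts):
            trials = [_random_trial(tau, lo, hi, rng) for tau in taus]
            design = Design(trials=trials, seed=seed,
                            provenance="generate_design rejection sampling")
            m = max_abs_regressor_correlation(design)
            if m < max_abs_corr:
                return design
            best = min(best, m)
        raise RuntimeError(
            f"rejection sampling budget ({max_attempts}) exhausted; "
            f"best max |r| achieved was {best:.3f} (threshold {max_abs_corr})"
        )
    if method != "exchange":
        raise ValueError("method must be 'reject' or 'exchange'")
    return _exchange_design(taus, lo, hi, max_abs_corr, split_max_corr,
                            reference_effects, seed, max(max_attempts, 30000))


#: reference (gamma, alpha, reward_weight) at which exchange-optimized
#: designs maximize model discriminability (matches the strong-effects
#: simulation conditions used for selection validation)
DEFAULT_REFERENCE_EFFECTS: tuple[float, float, float] = (0.030, 0.015, 0.005)


def _min_discriminability(rfv: np.ndarray,
                          effects: tuple[float, float, float]) -> float:
    """Smallest expected log-likelihood gap separating the generating model
    (reward + guilt + combined inequity) from its closest rivals.

    For each rival (dropping guilt, or replacing combined inequity with one
    split term) the gap is approximated by the squared weighted-residual
    norm of the omitted regressor after projecting it onto the rival's
    columns, with logistic weights pi*(1-pi) evaluated at the reference
    effect sizes and a centering intercept — a local T-optimality measure.
    """
    gamma, alpha, rw = effects
    rwd, gu, iq, ip, iN = rfv.T
    icpt = -(gamma * gu.mean() + alpha * iq.mean() + rw * rwd.mean())
    z = icpt + rw * rwd + gamma * gu + alpha * iq
    p = 1.0 / (1.0 + np.exp(-z))
    w = p * (1 - p)

    def wres(target, others):
        X = np.column_stack([np.ones(len(target))] + others)
        Xw = X * w[:, None]
        beta = np.linalg.solve(X.T @ Xw, Xw.T @ target)
        r = target - X @ beta
        return float(r @ (w * r))

    return min(
        alpha**2 * wres(iq, [rwd, gu, ip]),   # rival: split Ip for Iq
        alpha**2 * wres(iq, [rwd, gu, iN]),   # rival: split In for Iq
        gamma**2 * wres(gu, [rwd, iq]),       # rival: guilt omitted
    )


def _exchange_design(taus, lo, hi, max_abs_corr, split_max_corr,
                     reference_effects, seed, budget) -> Design:
    """Simulated-annealing single-trial exchange: satisfy the correlation
    constraints, then maximize model discriminability at the reference
    effect sizes."""
    rng = np.random.default_rng(seed)

    def feasibility(design: Design) -> float:
        main, cross, _ = _design_correlation_metrics(design)
        return max(main / max_abs_corr, cross / split_max_corr)

    def energy(design: Design) -> float:
        rfv = regressor_frame(design).to_numpy(float)
        return (max(feasibility(design), 1.0) - 1.0
                - 0.2 * _min_discriminability(rfv, reference_effects))

    trials = [_random_trial(tau, lo, hi, rng) for tau in taus]
    design = Design(trials=trials, seed=seed,
                    provenance="generate_design single-trial exchange annealing")
    current = energy(design)
    best_trials: list[TrialSpec] | None = None
    best_energy = np.inf
    for it in range(budget):
        temp = 0.3 * (1 - it / budget) + 0.005
        i = int(rng.integers(len(trials)))
        old = trials[i]
        trials[i] = _random_trial(old.tau, lo, hi, rng)
        new = energy(design)
        if new < current or rng.random() < np.exp(-(new - current) / temp):
            current = new
            if new < best_energy and feasibility(design) <= 1.0:
                best_energy = new
                best_trials = list(trials)
        else:
            trials[i] = old
    if best_trials is None:
        raise RuntimeError(
            f"exchange budget ({budget}) exhausted without satisfying the "
            f"correlation constraints (last objective {current:.3f})"
        )
    return Design(trials=best_trials, seed=seed,
                  provenance="generate_design single-trial exchange annealing")


def validate_design(
    design: Design,
    tau_table: dict[float, int] | None = None,
    max_abs_corr: float = 0.30,
) -> list[str]:
    """Report every violated design invariant (empty list means valid).

    Checks per-trial payoff orderings, the tau frequency table (when one is
    supplied or the design has the canonical 45 trials) and the regressor
    orthogonality constraint.
    """
    report: list[str] = []
    for i, trial in enumerate(design.trials):
        for v in trial.violations():
            report.append(f"trial {i}: {v}")
    if report:
        return report  # regressors undefined on invalid trials
    if tau_table is None and len(design) == 45:
        tau_table = CANONICAL_TAU_TABLE
    if tau_table is not None:
        observed = design.tau_counts()
        expected = {round(k, 2): v for k, v in tau_table.items()}
        if {round(k, 2): v for k, v in observed.items()} != expected:
            report.append(f"tau frequency table mismatch: expected {expected}, got {observed}")
    m = max_abs_regressor_correlation(design)
    if not m < max_abs_corr:
        report.append(f"orthogonality failure: max |pairwise r| = {m:.3f} >= {max_abs_corr}")
    return report


DESIGN_COLUMNS = ["trial_id", "x_A", "x_B", "y_A", "y_B", "z_A", "z_B", "tau"]


def write_design(design: Design, path) -> None:
    """Serialize a design to CSV (columns: trial_id, payoffs, tau)."""
    design.to_frame().to_csv(path, index=False)


def read_design(path) -> Design:
    """Read a design CSV written by :func:`write_design`.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    df = pd.read_csv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing columns: {missing}")
    trials = []
    for idx, row in df.sort_values("trial_id").iterrows():
        try:
            trials.append(
                TrialSpec(
                    x_A=int(row["x_A"]), x_B=int(row["x_B"]),
                    y_A=int(row["y_A"]), y_B=int(row["y_B"]),
                    z_A=int(row["z_A"]), z_B=int(row["z_B"]),
                    tau=float(row["tau"]),
                )
            )
        except (TypeError, ValueError) as exc:
            # +2: header line plus 1-based numbering
            raise ValueError(f"malformed design row at line {idx + 2}: {exc}") from exc
    return Design(trials=trials, provenance=f"read from {path}")
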