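"""Aggregate stock-and-flow model of readmission-score adoption.

Three stocks evolve in continuous time (months):

* ``trained`` — staff trained on the score, raised by training and drained
  by turnover (headcount is constant: departures are replaced by untrained
  hires);
* ``perceived_evidence`` — first-order exponential smoothing of the
  readmission avoidance rate, representing the delay before staff perceive
  the tool working;
* ``individual_interest`` — first-order adjustment toward a weighted blend
  of institutional interest (external) and perceived success (internal).

The central auxiliary is the readmission avoidance rate

    V = L * min(f_flag, f_readmit) * D * e

with ``L`` the likelihood of red-alert use (trained fraction x attention),
``f_flag`` the fraction of discharges flagged red, ``f_readmit`` the normal
readmission fraction, ``D`` the discharge rate and ``e`` the effectiveness
of acting on the score. Only true-positive alerts can avert a readmission,
so the avoidance rate can never exceed the normal readmission rate; in the
best case (L = 1, perfect flagging, e = 1) residual readmissions are
exactly zero.

Institutional interest follows a simplified CMS excess-readmission penalty
(fractional excess of the readmission rate over the CMS goal), normalized
by its initial value and diluted by attention to conflicting priorities.
Integration is fixed-step forward Euler, the convention of desktop
system-dynamics tools, with state clamped to its physical range each step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelParameters",
    "StateVector",
    "AuxiliarySnapshot",
    "Trajectory",
    "default_params",
    "likelihood_of_red_alert_use",
    "readmission_avoidance_rate",
    "cms_penalty",
    "institutional_interest",
    "perceived_success",
    "derivatives",
    "integrate",
    "steady_state",
]

#: column order of the trajectory table and its CSV export
TRAJECTORY_COLUMNS = [
    "time",
    "trained",
    "perceived_evidence",
    "individual_interest",
    "readmission_rate",
    "readmission_fraction",
    "penalty",
    "institutional_interest",
    "likelihood_of_use",
    "avoidance_rate",
    "perceived_success",
    "training_rate",
    "departure_rate",
]


@dataclass(frozen=True)
class ModelParameters:
    """All exogenous constants of the adoption model.

    Parameters
    ----------
    n_staff
        Number of people involved in discharges (persons).
    discharge_rate
        Normal discharge rate (persons/month).
    normal_readmission_fraction
        Fraction of discharges normally readmitted; the normal readmission
        rate is this fraction times the discharge rate.
    cms_goal_fraction
        CMS goal for the readmission fraction. Must lie below the normal
        fraction so the run starts with a nonzero penalty.
    turnover_fraction
        Monthly fraction of trained staff departing (1/month).
    training_time
        Time to train the untrained pool at full drive (months).
    attention_conflicting_priorities
        Dimensionless divisor >= 1 diluting institutional interest
        (competing demands such as a pandemic or length-of-stay pressure).
    required_evidence
        Avoided readmissions per month staff must observe to fully
        perceive tool success (persons/month).
    fraction_flagged
        Fraction of discharges receiving a red alert.
    effectiveness
        Probability that attention to a true-positive alert averts the
        readmission.
    evidence_smoothing_time, interest_adjustment_time
        First-order time constants (months) of the perception delay and
        the individual-interest adjustment.
    team_pressure_weight
        Weight of the use-on-rounds term (likelihood x perceived success)
        added to the training drive.
    external_interest_weight, internal_interest_weight
        Weights of institutional interest and perceived success in the
        indicated individual interest.
    dt, horizon
        Euler step and run length (months).
    """

    n_staff: float = 100.0
    discharge_rate: float = 300.0
    normal_readmission_fraction: float = 0.15
    cms_goal_fraction: float = 0.10
    turnover_fraction: float = 0.01
    training_time: float = 1.0
    attention_conflicting_priorities: float = 1.0
    required_evidence: float = 100.0
    fraction_flagged: float = 0.15
    effectiveness: float = 1.0
    evidence_smoothing_time: float = 3.0
    interest_adjustment_time: float = 3.0
    team_pressure_weight: float = 0.5
    external_interest_weight: float = 1.0
    internal_interest_weight: float = 1.0
    dt: float = 0.0078125
    horizon: float = 60.0

    def __post_init__(self) -> None:
        def require(cond: bool, msg: str) -> None:
            if not cond:
                raise ValueError(f"ModelParameters: {msg}")

        require(self.n_staff > 0, f"n_staff must be > 0, got {self.n_staff}")
        require(
            self.discharge_rate > 0,
            f"discharge_rate must be > 0, got {self.discharge_rate}",
        )
        for name in ("normal_readmission_fraction", "cms_goal_fraction",
                     "fraction_flagged", "effectiveness"):
            v = getattr(self, name)
            require(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        require(
            self.normal_readmission_fraction > self.cms_goal_fraction,
            "normal_readmission_fraction must exceed cms_goal_fraction "
            f"({self.normal_readmission_fraction} <= {self.cms_goal_fraction}); "
            "a nonzero initial penalty is required",
        )
        require(self.cms_goal_fraction > 0, "cms_goal_fraction must be > 0")
        require(
            self.turnover_fraction >= 0,
            f"turnover_fraction must be >= 0, got {self.turnover_fraction}",
        )
        for name in ("training_time", "required_evidence",
                     "evidence_smoothing_time", "interest_adjustment_time",
                     "dt", "horizon"):
            v = getattr(self, name)
            require(v > 0, f"{name} must be > 0, got {v}")
        require(
            self.attention_conflicting_priorities >= 1,
            "attention_conflicting_priorities must be >= 1, got "
            f"{self.attention_conflicting_priorities}",
        )
        for name in ("team_pressure_weight", "external_interest_weight",
                     "internal_interest_weight"):
            require(getattr(self, name) >= 0, f"{name} must be >= 0")
        require(
            self.dt <= self.training_time / 4,
            f"dt ({self.dt}) must be <= training_time/4 "
            f"({self.training_time / 4}) for a stable Euler step",
        )

    @property
    def normal_readmission_rate(self) -> float:
        """Readmissions per month absent any score use (persons/month)."""
        return self.normal_readmission_fraction * self.discharge_rate

    @property
    def initial_penalty(self) -> float:
        """CMS penalty at the cold start, before any avoidance."""
        return cms_penalty(self.normal_readmission_fraction, self.cms_goal_fraction)

    def replace(self, **overrides: float) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)


def default_params() -> ModelParameters:
    """Baseline parameterization: strong balancing loops, weak reinforcing loops.

    Training is quick (1 month), turnover low (1%/month), red alerts match
    the normal readmission rate with no false positives, score use is fully
    effective, conflicting priorities are absent (attention divisor 1) and
    the evidence bar is high (100 persons/month).
    """
    return ModelParameters()


@dataclass(frozen=True)
class StateVector:
    """The three stocks at one instant."""

    trained: float
    perceived_evidence: float
    individual_interest: float


@dataclass(frozen=True)
class AuxiliarySnapshot:
    """Instantaneous algebraic quantities implied by a state."""

    readmission_rate: float
    readmission_fraction: float
    penalty: float
    institutional_interest: float
    likelihood_of_use: float
    avoidance_rate: float
    perceived_success: float
    training_rate: float
    departure_rate: float


def likelihood_of_red_alert_use(
    trained: float, n_staff: float, attention_fraction: float
) -> float:
    """Fraction of discharges at which the score is actually consulted.

    The product of the trained fraction of staff and the fraction of
    discharges during which trained individuals pay attention to the score.
    """
    if n_staff <= 0:
        raise ValueError(f"n_staff must be > 0, got {n_staff}")
    if not 0.0 <= trained <= n_staff:
        raise ValueError(f"trained must be in [0, {n_staff}], got {trained}")
    if not 0.0 <= attention_fraction <= 1.0:
        raise ValueError(f"attention_fraction must be in [0, 1], got {attention_fraction}")
    return (trained / n_staff) * attention_fraction


def readmission_avoidance_rate(likelihood: float, params: ModelParameters) -> float:
    """Readmissions averted per month (persons/month).

    Product of the likelihood of red-alert use, the true-positive flagged
    discharge rate and the effectiveness of score use. Only flags that
    coincide with would-be readmissions count, so the result never exceeds
    the normal readmission rate.
    """
    true_positive_fraction = min(
        params.fraction_flagged, params.normal_readmission_fraction
    )
    return (
        likelihood
        * true_positive_fraction
        * params.discharge_rate
        * params.effectiveness
    )


def cms_penalty(readmission_fraction: float, cms_goal_fraction: float) -> float:
    """Simplified CMS excess-readmission penalty.

    The fractional amount by which the readmission fraction exceeds the CMS
    goal, floored at zero. (The statutory HRRP formula is DRG-based and
    risk-adjusted; this is the model's deliberate simplification.)
    """
    if cms_goal_fraction <= 0:
        raise ValueError(f"cms_goal_fraction must be > 0, got {cms_goal_fraction}")
    return max(0.0, (readmission_fraction - cms_goal_fraction) / cms_goal_fraction)


def institutional_interest(
    penalty: float, initial_penalty: float, attention_conflicting_priorities: float
) -> float:
    """Institutional interest in the score, in [0, 1].

    The penalty normalized by its initial value (so baseline runs start at
    full interest) and diluted by the attention-to-conflicting-priorities
    divisor.
    """
    if initial_penalty <= 0:
        raise ValueError(f"initial_penalty must be > 0, got {initial_penalty}")
    return min(1.0, penalty / initial_penalty) / attention_conflicting_priorities


def perceived_success(perceived_evidence: float, required_evidence: float) -> float:
    """Perceived tool success, in [0, 1]: evidence seen over evidence required."""
    if required_evidence <= 0:
        raise ValueError(f"required_evidence must be > 0, got {required_evidence}")
    return min(1.0, perceived_evidence / required_evidence)


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def derivatives(
    state: StateVector, params: ModelParameters, initial_penalty: float
) -> tuple[tuple[float, float, float], AuxiliarySnapshot]:
    """Time derivatives of the three stocks plus the auxiliary snapshot.

    The training drive is institutional interest buoyed by internal
    pressure from use on rounds (``team_pressure_weight * likelihood *
    perceived_success``), clamped to [0, 1]; the indicated individual
    interest is the clamped weighted sum of institutional interest and
    perceived success.
    """
    p = params
    L = likelihood_of_red_alert_use(state.trained, p.n_staff, state.individual_interest)
    V = readmission_avoidance_rate(L, p)
    R = p.normal_readmission_rate - V
    penalty = cms_penalty(R / p.discharge_rate, p.cms_goal_fraction)
    I = institutional_interest(
        penalty, initial_penalty, p.attention_conflicting_priorities
    )
    S = perceived_success(state.perceived_evidence, p.required_evidence)
    training_drive = _clamp01(I + p.team_pressure_weight * L * S)
    training_rate = training_drive * (p.n_staff - state.trained) / p.training_time
    departure_rate = p.turnover_fraction * state.trained
    indicated_interest = _clamp01(
        p.external_interest_weight * I + p.internal_interest_weight * S
    )

    d_trained = training_rate - departure_rate
    d_evidence = (V - state.perceived_evidence) / p.evidence_smoothing_time
    d_interest = (indicated_interest - state.individual_interest) / p.interest_adjustment_time

    aux = AuxiliarySnapshot(
        readmission_rate=R,
        readmission_fraction=R / p.discharge_rate,
        penalty=penalty,
        institutional_interest=I,
        likelihood_of_use=L,
        avoidance_rate=V,
        perceived_success=S,
        training_rate=training_rate,
        departure_rate=departure_rate,
    )
    return (d_trained, d_evidence, d_interest), aux


@dataclass(frozen=True)
class Trajectory:
    """A simulated run: uniform time grid, stocks and auxiliaries per step."""

    data: pd.DataFrame
    params: ModelParameters
    initial_penalty: float

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def series(self, variable: str) -> np.ndarray:
        """Values of one recorded state or auxiliary over the grid."""
        if variable not in TRAJECTORY_COLUMNS or variable == "time":
            raise KeyError(f"unknown trajectory variable {variable!r}")
        return self.data[variable].to_numpy()

    def terminal_state(self) -> StateVector:
        last = self.data.iloc[-1]
        return StateVector(
            trained=float(last["trained"]),
            perceived_evidence=float(last["perceived_evidence"]),
            individual_interest=float(last["individual_interest"]),
        )

    def terminal(self) -> dict[str, float]:
        """All recorded variables at the final grid point."""
        last = self.data.iloc[-1]
        return {c: float(last[c]) for c in TRAJECTORY_COLUMNS if c != "time"}

    def to_csv(self, path) -> None:
        """Write the trajectory table; floats at 10 significant digits."""
        self.data.to_csv(path, index=False, float_format="%.10g")


def initial_state(params: ModelParameters) -> StateVector:
    """Cold start: no one trained, no perceived evidence, interest at the
    initial institutional level ``1 / attention_conflicting_priorities``."""
    return StateVector(
        trained=0.0,
        perceived_evidence=0.0,
        individual_interest=1.0 / params.attention_conflicting_priorities,
    )


def integrate(
    params: ModelParameters, init: StateVector | None = None
) -> Trajectory:
    """Forward-Euler integration over the uniform grid ``0..horizon`` step ``dt``.

    Stocks are clamped to their physical ranges after each step; a
    violation beyond floating-point tolerance (1e-9 of the variable's
    scale) raises rather than being silently clamped.
    """
    p = params
    p0 = p.initial_penalty
    state = init if init is not None else initial_state(p)
    n_steps = int(round(p.horizon / p.dt))
    rows = np.empty((n_steps + 1, len(TRAJECTORY_COLUMNS)))

    tol_trained = 1e-9 * p.n_staff
    tol_unit = 1e-9

    for i in range(n_steps + 1):
        (dT, dE, dI), aux = derivatives(state, p, p0)
        rows[i] = (
            i * p.dt,
            state.trained,
            state.perceived_evidence,
            state.individual_interest,
            aux.readmission_rate,
            aux.readmission_fraction,
            aux.penalty,
            aux.institutional_interest,
            aux.likelihood_of_use,
            aux.avoidance_rate,
            aux.perceived_success,
            aux.training_rate,
            aux.departure_rate,
        )
        if aux.readmission_rate < -1e-9 * p.normal_readmission_rate:
            raise RuntimeError(
                f"negative readmission rate {aux.readmission_rate} at t={i * p.dt}"
            )
        if i == n_steps:
            break
        T = state.trained + p.dt * dT
        E = state.perceived_evidence + p.dt * dE
        interest = state.individual_interest + p.dt * dI
        if not (-tol_trained <= T <= p.n_staff + tol_trained):
            raise RuntimeError(f"trained stock {T} out of [0, {p.n_staff}] at t={i * p.dt}")
        if E < -tol_unit * p.normal_readmission_rate:
            raise RuntimeError(f"perceived evidence {E} negative at t={i * p.dt}")
        if not (-tol_unit <= interest <= 1.0 + tol_unit):
            raise RuntimeError(f"individual interest {interest} out of [0, 1] at t={i * p.dt}")
        state = StateVector(
            trained=min(p.n_staff, max(0.0, T)),
            perceived_evidence=max(0.0, E),
            individual_interest=_clamp01(interest),
        )

    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(data=df, params=p, initial_penalty=p0)


def steady_state(
    trajectory: Trajectory, window: float, tol: float = 1e-3
) -> StateVector | None:
    """Terminal state if the run has settled, else ``None``.

    Settled means every recorded state and auxiliary varies by less than
    ``tol`` relative to its own scale (max absolute value over the run)
    within the final ``window`` months.
    """
    p = trajectory.params
    if window >= p.horizon:
        raise ValueError(f"window ({window}) must be < horizon ({p.horizon})")
    t = trajectory.times
    mask = t >= t[-1] - window
    for col in TRAJECTORY_COLUMNS:
        if col == "time":
            continue
        y = trajectory.data[col].to_numpy()
        scale = max(float(np.max(np.abs(y))), 1e-12)
        seg = y[mask]
        if float(seg.max() - seg.min()) >= tol * scale:
            return None
    return trajectory.terminal_state()
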