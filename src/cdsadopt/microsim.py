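"""Stochastic monthly event-level simulator for cross-validation.

The aggregate model treats discharges, flagging, attention and avoidance as
continuous rates. This module realizes the same assumptions as discrete
monthly events: discharges are Poisson, would-be readmissions / flags /
attention / avoidance are Binomial thinnings, and staff training and
turnover are Binomial with per-month probabilities ``1 - exp(-rate)`` so
the per-month expectations are exact for non-infinitesimal steps. The
interest and evidence states are updated monthly from the realized counts
with the same formulas as the aggregate model.

Cross-validation compares replicate means against :func:`expected_cohort`,
the deterministic month-grid expectation path obtained by running the
identical monthly update on expected counts. That isolates Monte-Carlo
error from time discretization: agreement of the month grid with the
continuous model is checked separately by the integrator convergence tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from cdsadopt.model import (
    ModelParameters,
    cms_penalty,
    institutional_interest,
    perceived_success,
)

__all__ = [
    "MonthRecord",
    "EventLog",
    "AggregateSeries",
    "simulate_cohort",
    "expected_cohort",
    "aggregate_eventlog",
    "crossvalidate",
    "CrossValidationReport",
]

MONTH_COLUMNS = [
    "month",
    "discharges",
    "flagged",
    "would_be_readmissions",
    "flagged_true_positives",
    "attended",
    "avoided",
    "readmissions",
    "trained_start",
    "newly_trained",
    "departures_trained",
]


@dataclass(frozen=True)
class MonthRecord:
    """Event counts for one simulated month."""

    month: int
    discharges: int
    flagged: int
    would_be_readmissions: int
    flagged_true_positives: int
    attended: int
    avoided: int
    readmissions: int
    trained_start: int
    newly_trained: int
    departures_trained: int


@dataclass(frozen=True)
class EventLog:
    """A seeded monthly event stream plus the parameters that produced it."""

    seed: int
    params: ModelParameters
    months: tuple[MonthRecord, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.months], columns=MONTH_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self) -> str:
        import dataclasses as _dc
        import json

        return json.dumps(
            {
                "seed": self.seed,
                "params": _dc.asdict(self.params),
                "months": [asdict(m) for m in self.months],
            },
            indent=2,
        )


@dataclass(frozen=True)
class AggregateSeries:
    """Monthly observed rates derived deterministically from an event log."""

    data: pd.DataFrame  # month, readmission_rate, readmission_fraction, avoidance_rate, trained


def _validate_record(rec: MonthRecord, n_staff: float) -> None:
    ok = (
        0 <= rec.avoided <= rec.attended <= rec.flagged_true_positives
        <= min(rec.flagged, rec.would_be_readmissions)
        and rec.readmissions == rec.would_be_readmissions - rec.avoided
        and rec.readmissions >= 0
        and 0 <= rec.trained_start + rec.newly_trained - rec.departures_trained <= n_staff
    )
    if not ok:
        raise ValueError(f"event-log invariant violated in month {rec.month}: {rec}")


def _monthly_drives(
    params: ModelParameters,
    trained: float,
    interest: float,
    evidence: float,
    readmission_fraction: float,
) -> tuple[float, float, float, float, float]:
    """(likelihood, inst_interest, success, training_drive, indicated_interest)."""
    p = params
    L = (trained / p.n_staff) * interest
    penalty = cms_penalty(readmission_fraction, p.cms_goal_fraction)
    I = institutional_interest(
        penalty, p.initial_penalty, p.attention_conflicting_priorities
    )
    S = perceived_success(evidence, p.required_evidence)
    drive = min(1.0, max(0.0, I + p.team_pressure_weight * L * S))
    indicated = min(
        1.0, max(0.0, p.external_interest_weight * I + p.internal_interest_weight * S)
    )
    return L, I, S, drive, indicated


def simulate_cohort(params: ModelParameters, seed: int) -> EventLog:
    """One seeded stochastic cohort over ``round(horizon)`` months.

    Per month, with the trained count and interest state at month start:
    discharges ~ Poisson(discharge_rate); would-be readmissions ~
    Binomial(discharges, normal_readmission_fraction); true-positive flags
    are a Binomial thinning of would-be readmissions (all of them under
    perfect flagging), false-positive flags a thinning of the remaining
    discharges when over-flagged; attended ~ Binomial(true positives,
    likelihood of use); avoided ~ Binomial(attended, effectiveness).
    Departures and trainings are Binomial over the trained/untrained pools
    with probabilities ``1 - exp(-turnover)`` and ``1 -
    exp(-drive/training_time)``. Evidence and interest update monthly from
    the realized counts.
    """
    p = params
    rng = np.random.default_rng(seed)
    n = int(round(p.n_staff))
    n_months = int(round(p.horizon))
    nrf = p.normal_readmission_fraction
    p_tp = min(p.fraction_flagged, nrf) / nrf if nrf > 0 else 0.0
    p_fp = (
        max(0.0, p.fraction_flagged - nrf) / (1.0 - nrf) if nrf < 1.0 else 0.0
    )
    p_depart = 1.0 - math.exp(-p.turnover_fraction)

    trained = 0
    evidence = 0.0
    interest = 1.0 / p.attention_conflicting_priorities
    records: list[MonthRecord] = []

    for m in range(n_months):
        likelihood = (trained / n) * interest

        discharges = int(rng.poisson(p.discharge_rate))
        would_be = int(rng.binomial(discharges, nrf)) if discharges else 0
        tp = would_be if p_tp >= 1.0 else int(rng.binomial(would_be, p_tp))
        fp = (
            int(rng.binomial(discharges - would_be, p_fp)) if p_fp > 0.0 else 0
        )
        flagged = tp + fp
        attended = int(rng.binomial(tp, likelihood)) if tp else 0
        avoided = int(rng.binomial(attended, p.effectiveness)) if attended else 0
        readmissions = would_be - avoided

        # institutional response follows the systematic (state-implied)
        # readmission fraction: CMS penalties average over long windows, so
        # single-month sampling noise does not move institutional interest
        frac = nrf * (1.0 - p_tp * likelihood * p.effectiveness)
        L, I, S, drive, indicated = _monthly_drives(
            p, trained, interest, evidence, frac
        )
        p_train = 1.0 - math.exp(-drive / p.training_time)
        newly = int(rng.binomial(n - trained, p_train)) if trained < n else 0
        departures = int(rng.binomial(trained, p_depart)) if trained else 0

        rec = MonthRecord(
            month=m,
            discharges=discharges,
            flagged=flagged,
            would_be_readmissions=would_be,
            flagged_true_positives=tp,
            attended=attended,
            avoided=avoided,
            readmissions=readmissions,
            trained_start=trained,
            newly_trained=newly,
            departures_trained=departures,
        )
        _validate_record(rec, n)
        records.append(rec)

        trained = trained + newly - departures
        evidence = max(0.0, evidence + (avoided - evidence) / p.evidence_smoothing_time)
        interest = min(
            1.0,
            max(0.0, interest + (indicated - interest) / p.interest_adjustment_time),
        )

    return EventLog(seed=int(seed), params=p, months=tuple(records))


def expected_cohort(params: ModelParameters) -> pd.DataFrame:
    """Deterministic month-grid expectation path of :func:`simulate_cohort`.

    Applies the identical monthly update to expected counts (continuous
    trained headcount, expected discharges), i.e. the aggregate model
    evaluated on the monthly grid with the same ``1 - exp(-rate)``
    transition probabilities.
    """
    p = params
    n = p.n_staff
    n_months = int(round(p.horizon))
    nrf = p.normal_readmission_fraction
    p_tp = min(p.fraction_flagged, nrf) / nrf if nrf > 0 else 0.0
    p_depart = 1.0 - math.exp(-p.turnover_fraction)

    trained = 0.0
    evidence = 0.0
    interest = 1.0 / p.attention_conflicting_priorities
    rows = []
    for m in range(n_months):
        likelihood = (trained / n) * interest
        discharges = p.discharge_rate
        would_be = discharges * nrf
        tp = would_be * p_tp
        attended = tp * likelihood
        avoided = attended * p.effectiveness
        readmissions = would_be - avoided
        frac = nrf * (1.0 - p_tp * likelihood * p.effectiveness)

        L, I, S, drive, indicated = _monthly_drives(
            p, trained, interest, evidence, frac
        )
        p_train = 1.0 - math.exp(-drive / p.training_time)
        newly = (n - trained) * p_train
        departures = trained * p_depart

        rows.append(
            {
                "month": m,
                "discharges": discharges,
                "would_be_readmissions": would_be,
                "avoided": avoided,
                "readmissions": readmissions,
                "trained_start": trained,
            }
        )
        trained = trained + newly - departures
        evidence = max(0.0, evidence + (avoided - evidence) / p.evidence_smoothing_time)
        interest = min(
            1.0,
            max(0.0, interest + (indicated - interest) / p.interest_adjustment_time),
        )
    return pd.DataFrame(rows)


def aggregate_eventlog(log: EventLog) -> AggregateSeries:
    """Monthly observed rates from an event log; validates conservation.

    ``readmission_rate`` and ``avoidance_rate`` are persons/month;
    ``trained`` is the month-start headcount.
    """
    n = log.params.n_staff
    for rec in log.months:
        _validate_record(rec, n)
    df = log.to_dataframe()
    # stock-flow accounting must reconstruct the recorded trained series
    recon = df["trained_start"] + df["newly_trained"] - df["departures_trained"]
    if not (recon.iloc[:-1].to_numpy() == df["trained_start"].iloc[1:].to_numpy()).all():
        raise ValueError("trained_start series inconsistent with recorded flows")
    out = pd.DataFrame(
        {
            "month": df["month"],
            "readmission_rate": df["readmissions"].astype(float),
            "readmission_fraction": np.where(
                df["discharges"] > 0,
                df["readmissions"] / df["discharges"].replace(0, np.nan),
                0.0,
            ),
            "avoidance_rate": df["avoided"].astype(float),
            "trained": df["trained_start"].astype(float),
        }
    )
    return AggregateSeries(data=out)


@dataclass(frozen=True)
class CrossValidationReport:
    """Agreement between replicate micro-simulation means and the
    month-grid aggregate expectation, per tracked variable."""

    n_reps: int
    n_months: int
    max_discrepancy: dict[str, float]  # max over months of |mean-expected|/SE
    means: pd.DataFrame
    expected: pd.DataFrame

    @property
    def max_overall(self) -> float:
        return max(self.max_discrepancy.values())

    def as_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "n_months": self.n_months,
            "max_standardized_discrepancy": dict(self.max_discrepancy),
        }


_TRACKED = ["readmissions", "avoided", "trained_start"]


def crossvalidate(
    params: ModelParameters, n_reps: int, seed: int
) -> CrossValidationReport:
    """Monte-Carlo check that the micro-model's means track the aggregate model.

    Runs ``n_reps`` independently seeded cohorts, averages the monthly
    readmission, avoidance and trained-headcount series, and reports the
    maximum standardized discrepancy ``|mean - expected| / SE`` per
    variable against :func:`expected_cohort`. Months where the replicate
    standard error is zero count as zero discrepancy when the difference
    is also zero.
    """
    if n_reps < 30:
        raise ValueError(f"n_reps must be >= 30 for a stable standard error, got {n_reps}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    stacks = {v: [] for v in _TRACKED}
    for s in child_seeds:
        log = simulate_cohort(params, int(s))
        df = log.to_dataframe()
        for v in _TRACKED:
            stacks[v].append(df[v].to_numpy(dtype=float))

    expected = expected_cohort(params)
    n_months = len(expected)
    means = {}
    discrepancy = {}
    for v in _TRACKED:
        arr = np.vstack(stacks[v])
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / math.sqrt(n_reps)
        diff = np.abs(mean - expected[v].to_numpy())
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff > 0, np.inf, 0.0))
        means[v] = mean
        discrepancy[v] = float(np.max(z))
    means_df = pd.DataFrame({"month": expected["month"], **means})
    return CrossValidationReport(
        n_reps=n_reps,
        n_months=n_months,
        max_discrepancy=discrepancy,
        means=means_df,
        expected=expected,
    )
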