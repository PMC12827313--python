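"""Non-parametric estimation for the multi-state model.

Per-transition Nelson-Aalen cumulative hazards are the building blocks of
the Aalen-Johansen (AJ) estimator, the product-integral generalisation of
Kaplan-Meier that yields the matrix of transition probabilities of a
time-inhomogeneous Markov process,

    P(s, t) = prod_{u in (s, t]} (I + dA(u)),

where dA(u) has off-diagonal entries dA_{gh}(u) = dN_{gh}(u) / Y_g(u) and
diagonal entries minus the row sums.  The covariance of the occupation
probabilities is propagated through the product integral by the standard
delta-method recursion using Aalen (Poisson-type) increment variances
dN / Y^2, which is what combined-state confidence intervals are built on.

Kaplan-Meier overall survival, reverse Kaplan-Meier follow-up and
competing-risks cumulative incidence functions are provided as thin,
consistent front-ends (KM via lifelines; the CIF as a star-shaped
reduction of the package's own AJ machinery, so that the identity
sum_k CIF_k + KM = 1 holds by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .msdata import TransitionStructure, default_structure

__all__ = [
    "CumulativeHazard",
    "OccupationTrajectory",
    "SurvivalCurve",
    "nelson_aalen",
    "aalen_johansen",
    "kaplan_meier",
    "reverse_kaplan_meier",
    "cumulative_incidence",
    "cif_transfusion_independence_first_line",
    "cif_transfusion_independence_any_line",
]


@dataclass
class CumulativeHazard:
    """Step-function cumulative hazard of one transition.

    ``times`` are the event times (strictly increasing), ``dA`` the
    increments.  ``d`` (event counts) and ``Y`` (risk-set sizes) are kept
    when the hazard was estimated from data; model-based hazards (e.g. Cox
    profile predictions) carry only increments.
    """

    trans: int
    from_state: int
    to_state: int
    times: np.ndarray
    dA: np.ndarray
    d: Optional[np.ndarray] = None
    Y: Optional[np.ndarray] = None

    @property
    def var(self) -> Optional[np.ndarray]:
        """Aalen-type increment variances d / Y^2 (None if model-based)."""
        if self.d is None or self.Y is None:
            return None
        return self.d / self.Y**2

    def cumulative(self, t: float) -> float:
        return float(self.dA[self.times <= t].sum())


@dataclass
class SurvivalCurve:
    """A survival-type step curve with pointwise 95% confidence limits."""

    label: str
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    median: float = math.nan        # nan = not reached

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.estimate[i]) if i >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "estimate": self.estimate,
            "lower": self.lower, "upper": self.upper, "label": self.label,
        })


def _sojourns(data: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, visit) sojourn, deduplicating the arrow rows."""
    return data.drop_duplicates(subset=["patient_id", "visit", "from_state"])[
        ["patient_id", "visit", "from_state", "Tstart", "Tstop"]
    ]


def _risk_set(starts: np.ndarray, stops: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Y(t) = #{Tstart < t <= Tstop} for each t, via sorted searches."""
    ss = np.sort(starts)
    tt = np.sort(stops)
    n_stop_ge = len(tt) - np.searchsorted(tt, times, side="left")
    n_start_ge = len(ss) - np.searchsorted(ss, times, side="left")
    return n_stop_ge - n_start_ge


def nelson_aalen(
    data: pd.DataFrame,
    structure: TransitionStructure | None = None,
) -> list[CumulativeHazard]:
    """Per-transition Nelson-Aalen hazards from long-format data.

    Returns one :class:`CumulativeHazard` per transition of the structure
    (identically zero, with a zero-length grid, for transitions without
    observed events).
    """
    structure = structure if structure is not None else default_structure()
    soj = _sojourns(data)
    by_state = {
        g: (grp["Tstart"].to_numpy(float), grp["Tstop"].to_numpy(float))
        for g, grp in soj.groupby("from_state")
    }
    out = []
    for q, (g, h) in sorted(structure.transitions.items()):
        ev = data.loc[(data["trans"] == q) & (data["status"] == 1), "Tstop"]
        if len(ev) == 0:
            out.append(CumulativeHazard(
                q, g, h, np.empty(0), np.empty(0), np.empty(0), np.empty(0),
            ))
            continue
        times, d = np.unique(ev.to_numpy(float), return_counts=True)
        starts, stops = by_state[g]
        Y = _risk_set(starts, stops, times)
        assert np.all(Y >= d), f"transition {q}: more events than at risk"
        out.append(CumulativeHazard(q, g, h, times, d / Y, d.astype(float), Y.astype(float)))
    return out


@dataclass
class OccupationTrajectory:
    """State-occupation probabilities over time from a starting distribution.

    ``times`` includes the starting time ``s`` (row of the starting
    distribution); ``probs[i]`` is the occupation vector at ``times[i]``
    and ``cov[i]``, when present, its delta-method variance-covariance
    matrix.  ``matrices[i]``, when kept, is the full transition-probability
    matrix P(s, times[i]).
    """

    structure: TransitionStructure
    s: float
    start: np.ndarray
    times: np.ndarray
    probs: np.ndarray
    cov: Optional[np.ndarray] = None
    matrices: Optional[np.ndarray] = None

    def state_index(self, state: int) -> int:
        return self.structure.state_ids.index(state)

    def occupation(self, state: int) -> np.ndarray:
        return self.probs[:, self.state_index(state)]

    def at(self, t: float) -> np.ndarray:
        """Occupation vector at time ``t`` (step evaluation, P(s,s)=start)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return self.probs[max(i, 0)]

    def cov_at(self, t: float) -> np.ndarray:
        i = np.searchsorted(self.times, t, side="right") - 1
        return self.cov[max(i, 0)]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            self.structure.state_name(s): self.probs[:, i]
            for i, s in enumerate(self.structure.state_ids)
        }
        return pd.DataFrame({"time": self.times, **cols})


def aalen_johansen(
    hazards: Sequence[CumulativeHazard],
    s: float = 0.0,
    structure: TransitionStructure | None = None,
    start_state: int = 1,
    start_dist: Optional[np.ndarray] = None,
    compute_var: bool = True,
    keep_matrices: bool = False,
    clip_increments: bool = False,
) -> OccupationTrajectory:
    """Aalen-Johansen product-integral estimator of occupation probabilities.

    Parameters
    ----------
    hazards
        One cumulative hazard per transition (from :func:`nelson_aalen` or
        model-based).  Tied increments of different transitions at the same
        time enter the same ``(I + dA(u))`` factor.
    s
        Starting time; only event times in ``(s, inf)`` contribute.
    start_state, start_dist
        Either a single starting state or an explicit distribution over
        states (in ``structure.state_ids`` order).
    compute_var
        Propagate the variance-covariance of the occupation vector by the
        product-integral delta-method recursion (requires data-based
        hazards carrying event counts and risk sets).
    """
    structure = structure if structure is not None else default_structure()
    ids = structure.state_ids
    K = len(ids)
    idx = {state: i for i, state in enumerate(ids)}

    # group increments by event time
    grid = np.unique(np.concatenate(
        [h.times[h.times > s] for h in hazards] or [np.empty(0)]
    ))
    by_time: dict[float, list] = {t: [] for t in grid}
    can_var = all(h.var is not None for h in hazards if len(h.times))
    for h in hazards:
        v = h.var
        for k, t in enumerate(h.times):
            if t > s:
                by_time[t].append(
                    (idx[h.from_state], idx[h.to_state], h.dA[k],
                     v[k] if v is not None else None)
                )

    if start_dist is not None:
        p = np.asarray(start_dist, float).copy()
    else:
        p = np.zeros(K)
        p[idx[start_state]] = 1.0
    compute_var = compute_var and can_var

    times = [s]
    probs = [p.copy()]
    covs = [np.zeros((K, K))] if compute_var else None
    mats = [np.eye(K)] if keep_matrices else None
    Sig = np.zeros((K, K))
    P = np.eye(K)

    for t in grid:
        F = np.eye(K)  # I + dA(t)
        incs = by_time[t]
        for g, h, da, _ in incs:
            F[g, h] += da
            F[g, g] -= da
        if np.any(np.diag(F) < -1e-12):
            if not clip_increments:
                raise ValueError(
                    f"invalid product-integral factor at t={t}: an increment "
                    "implies more events than patients at risk"
                )
            # model-based hazards (baseline x HR) can overshoot in sparse
            # tails; rescale the offending row to a total exit mass of 1
            for g in np.where(np.diag(F) < 0)[0]:
                row_mass = 1.0 - F[g, g]
                F[g, :] /= row_mass
                F[g, g] = 1.0 - (F[g, :].sum() - F[g, g])
        if compute_var:
            # D = sum_g p_g^2 * cov of row g of dA(t)
            D = np.zeros((K, K))
            for g, h, _, vr in incs:
                w = p[g] ** 2 * vr
                D[h, h] += w
                D[g, h] -= w
                D[h, g] -= w
                D[g, g] += w
            Sig = F.T @ Sig @ F + D
            covs.append(Sig.copy())
        p = p @ F
        if keep_matrices:
            P = P @ F
            mats.append(P.copy())
        times.append(t)
        probs.append(p.copy())

    return OccupationTrajectory(
        structure=structure,
        s=s,
        start=probs[0],
        times=np.asarray(times, float),
        probs=np.asarray(probs),
        cov=np.asarray(covs) if compute_var else None,
        matrices=np.asarray(mats) if keep_matrices else None,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier front-ends (lifelines; log(-log) confidence intervals)


def kaplan_meier(times, status, label: str = "OS") -> SurvivalCurve:
    """Product-limit survival estimate with 95% CI on the log(-log) scale."""
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    if len(times) == 0 or (np.all(status == 0) and np.all(times == 0)):
        raise ValueError("no usable follow-up: all subjects censored at time 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, status, label=label)
    ci = kmf.confidence_interval_
    return SurvivalCurve(
        label=label,
        times=kmf.survival_function_.index.to_numpy(float),
        estimate=kmf.survival_function_[label].to_numpy(float),
        lower=ci.iloc[:, 0].to_numpy(float),
        upper=ci.iloc[:, 1].to_numpy(float),
        median=float(kmf.median_survival_time_),
    )


def reverse_kaplan_meier(times, status, label: str = "follow-up") -> SurvivalCurve:
    """Follow-up distribution: Kaplan-Meier censoring patients when they die.

    ``status`` is the death indicator of the original analysis; the roles
    of event and censoring are swapped.  The curve's ``median`` is the
    median follow-up (nan / inf means not reached).
    """
    status = np.asarray(status, int)
    return kaplan_meier(times, 1 - status, label=label)


# ---------------------------------------------------------------------------
# competing risks


def _star_structure(cause_labels: Sequence[str]) -> TransitionStructure:
    states = {1: "EventFree"}
    states.update({k + 2: str(lab) for k, lab in enumerate(cause_labels)})
    return TransitionStructure(
        states=states,
        transitions={k + 1: (1, k + 2) for k in range(len(cause_labels))},
        absorbing=frozenset(range(2, len(cause_labels) + 2)),
    )


def cumulative_incidence(
    times,
    events,
    cause_labels: Optional[Sequence[str]] = None,
) -> dict[str, SurvivalCurve]:
    """Cause-specific cumulative incidence functions with 95% CIs.

    ``events`` is coded 0 for censoring and 1..K for the competing causes.
    The CIFs are the absorbing-state occupation probabilities of a
    star-shaped multi-state model, so CIF_k(t) = sum_{u<=t} S(u-) d_k(u)/Y(u)
    with S the all-cause Kaplan-Meier, and sum_k CIF_k + S = 1 identically.
    CIs are Wald intervals on the probability scale truncated to [0, 1].
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    causes = sorted(c for c in np.unique(events) if c != 0)
    K = max(causes, default=0)
    if cause_labels is None:
        cause_labels = [f"cause {k}" for k in range(1, K + 1)]
    if len(cause_labels) < K:
        raise ValueError("fewer cause labels than observed causes")
    struct = _star_structure(cause_labels)
    rows = pd.DataFrame({
        "patient_id": np.arange(len(times)),
        "visit": 1,
        "from_state": 1,
        "to_state": 2,
        "trans": 1,
        "Tstart": 0.0,
        "Tstop": times,
        "status": 0,
    })
    expanded = []
    for k in range(1, len(cause_labels) + 1):
        rk = rows.copy()
        rk["trans"] = k
        rk["to_state"] = k + 1
        rk["status"] = (events == k).astype(int)
        expanded.append(rk)
    data = pd.concat(expanded, ignore_index=True)
    if (data["Tstop"] <= 0).any():
        raise ValueError("non-positive event/censoring times")
    haz = nelson_aalen(data, struct)
    traj = aalen_johansen(haz, s=0.0, structure=struct, start_state=1)
    out: dict[str, SurvivalCurve] = {}
    for k, lab in enumerate(cause_labels, start=1):
        est = traj.probs[:, k]
        se = np.sqrt(traj.cov[:, k, k])
        out[str(lab)] = SurvivalCurve(
            label=str(lab),
            times=traj.times,
            estimate=est,
            lower=np.clip(est - 1.96 * se, 0.0, 1.0),
            upper=np.clip(est + 1.96 * se, 0.0, 1.0),
        )
    return out


def _first_entry(path, states: set[int]) -> float:
    for st, t in path.visits:
        if st in states:
            return t
    return math.inf


def cif_transfusion_independence_first_line(records, paths) -> dict[str, SurvivalCurve]:
    """Cumulative incidence of transfusion independence under first-line IST.

    Event: first entry into the transfusion-independent-with-therapy state
    with no prior second-line treatment.  Competing events: death, start of
    second-line treatment (a non-transplant therapy started after day 0, or
    alloSCT) and AML/MDS treatment.
    """
    t_ev, code = [], []
    for rec, path in zip(records, paths):
        ti = _first_entry(path, {2})
        failure = _first_entry(path, {4, 6, 7, 8})
        second_line = min(
            (s for s, _ in rec.therapy_intervals if 0 < s < ti), default=math.inf
        )
        compete = min(failure, second_line)
        t = min(ti, compete, path.censoring_day)
        t_ev.append(t)
        code.append(1 if ti <= min(compete, path.censoring_day) else
                    (2 if compete <= path.censoring_day else 0))
    return cumulative_incidence(
        t_ev, code, ["transfusion independence (first line)", "competing event"]
    )


def cif_transfusion_independence_any_line(records, paths) -> dict[str, SurvivalCurve]:
    """Cumulative incidence of transfusion independence regardless of line.

    Event: first entry into a transfusion-independent state (with therapy
    or after alloSCT).  Competing events: death and AML/MDS treatment.
    """
    t_ev, code = [], []
    for rec, path in zip(records, paths):
        ti = _first_entry(path, {2, 5})
        compete = _first_entry(path, {6, 7, 8})
        t = min(ti, compete, path.censoring_day)
        t_ev.append(t)
        code.append(1 if ti <= min(compete, path.censoring_day) else
                    (2 if compete <= path.censoring_day else 0))
    return cumulative_incidence(
        t_ev, code, ["transfusion independence (any line)", "competing event"]
    )
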