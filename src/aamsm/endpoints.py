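"""Composite dynamic endpoints as functionals of the occupation trajectory.

The treatment-success endpoints are sums of state-occupation
probabilities, not time-to-first-event quantities: a patient who loses
and later regains transfusion independence counts as a success again.

* TT-DFS - transplantation- and treatment-free disease-free survival:
  occupying "free of transfusion and therapy" (state 3);
* T-DFS  - transplantation-free DFS: states {2, 3};
* DFS    - alive and transfusion-independent without AML/MDS treatment:
  states {2, 3, 5} (state 5 is transfusion independence after alloSCT);
* OS     - overall survival.  The headline OS is the Kaplan-Meier estimate
  on all-cause death; the model-internal "alive" curve 1 - P(death
  states) is reported separately because the AML/MDS state is absorbing
  and deaths after it are outside the model.

Variances of combined states use the full variance-covariance matrix of
the occupation vector (1' Sigma 1 over the state subset); confidence
intervals are Wald on the probability scale, truncated to [0, 1].
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nonparam import OccupationTrajectory, SurvivalCurve
from .registry import DAYS_PER_MONTH

__all__ = [
    "ENDPOINT_STATE_SETS",
    "combine_states",
    "endpoint_curves",
    "model_alive_curve",
    "summarize_at",
    "stacked_curves",
]

logger = logging.getLogger(__name__)

#: Default state sets of the composite endpoints (default structure ids).
ENDPOINT_STATE_SETS: dict[str, frozenset[int]] = {
    "TT-DFS": frozenset({3}),
    "T-DFS": frozenset({2, 3}),
    "DFS": frozenset({2, 3, 5}),
}

#: Stacking order used for the occupation-probability band plot: success
#: states from the bottom, then transfusion-dependent, transplant states,
#: failure states on top.
STACK_ORDER = [3, 2, 1, 5, 4, 7, 6, 8]


def combine_states(
    traj: OccupationTrajectory,
    state_set: Iterable[int],
    label: str,
) -> SurvivalCurve:
    """Probability of occupying any state in ``state_set`` over time.

    The variance is the sum of the corresponding block of the trajectory
    covariance; with a singleton set it reduces to the state's own
    variance.  Raises on states unknown to the trajectory's structure.
    """
    states = sorted(set(state_set))
    ids = traj.structure.state_ids
    unknown = [s for s in states if s not in ids]
    if unknown:
        raise ValueError(f"unknown state(s) {unknown} in endpoint {label!r}")
    cols = [ids.index(s) for s in states]
    est = traj.probs[:, cols].sum(axis=1) if cols else np.zeros(len(traj.times))
    if traj.cov is not None and cols:
        block = traj.cov[:, cols][:, :, cols]
        var = block.sum(axis=(1, 2))
        se = np.sqrt(np.clip(var, 0.0, None))
    else:
        se = np.zeros_like(est)
    return SurvivalCurve(
        label=label,
        times=traj.times,
        estimate=est,
        lower=np.clip(est - 1.96 * se, 0.0, 1.0),
        upper=np.clip(est + 1.96 * se, 0.0, 1.0),
    )


def endpoint_curves(
    traj: OccupationTrajectory,
    state_sets: Mapping[str, Iterable[int]] | None = None,
) -> dict[str, SurvivalCurve]:
    """The composite endpoint curves (default: TT-DFS, T-DFS, DFS)."""
    state_sets = state_sets if state_sets is not None else ENDPOINT_STATE_SETS
    return {lab: combine_states(traj, ss, lab) for lab, ss in state_sets.items()}


def model_alive_curve(traj: OccupationTrajectory) -> SurvivalCurve:
    """1 minus the death-state occupation of the multi-state model.

    Distinct from Kaplan-Meier OS: deaths occurring after entry into the
    absorbing AML/MDS-treatment state are outside the model, so this curve
    sits at or above the KM estimate whenever such deaths occur.
    """
    death_states = [
        s for s in traj.structure.absorbing
        if "death" in traj.structure.state_name(s).lower()
    ]
    dead = combine_states(traj, death_states, "model death")
    return SurvivalCurve(
        label="alive within model",
        times=dead.times,
        estimate=1.0 - dead.estimate,
        lower=np.clip(1.0 - dead.upper, 0.0, 1.0),
        upper=np.clip(1.0 - dead.lower, 0.0, 1.0),
    )


def summarize_at(
    curves: Mapping[str, SurvivalCurve] | Sequence[SurvivalCurve],
    horizons_months: Sequence[float] = (60.0,),
) -> pd.DataFrame:
    """Step-curve values at reporting horizons (months since IST start).

    A horizon beyond the last observed time returns the last available
    value and is flagged in the ``beyond_followup`` column.
    """
    if isinstance(curves, Mapping):
        curves = list(curves.values())
    rows = []
    for curve in curves:
        if len(curve.times) == 0:
            raise ValueError(f"empty curve {curve.label!r}")
        for hm in horizons_months:
            t = hm * DAYS_PER_MONTH
            i = np.searchsorted(curve.times, t, side="right") - 1
            i = max(i, 0)
            beyond = t > curve.times[-1]
            if beyond:
                logger.warning(
                    "%s: horizon %g months is beyond last follow-up; "
                    "reporting value at %.1f days", curve.label, hm, curve.times[-1],
                )
            rows.append({
                "endpoint": curve.label,
                "horizon_months": hm,
                "estimate": float(curve.estimate[i]),
                "lower": float(curve.lower[i]),
                "upper": float(curve.upper[i]),
                "beyond_followup": bool(beyond),
            })
    return pd.DataFrame(rows)


def stacked_curves(
    traj: OccupationTrajectory,
    order: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Cumulative band boundaries for a stacked occupation plot.

    Returns one boundary column per state in stacking order; the band for
    a state is the area between its boundary and the previous one, and the
    top boundary is identically 1.
    """
    ids = traj.structure.state_ids
    order = [s for s in (order if order is not None else STACK_ORDER) if s in ids]
    if sorted(order) != sorted(ids):
        raise ValueError("stacking order must list every state exactly once")
    out = pd.DataFrame({"time": traj.times})
    running = np.zeros(len(traj.times))
    for s in order:
        running = running + traj.probs[:, ids.index(s)]
        out[traj.structure.state_name(s)] = running
    return out
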