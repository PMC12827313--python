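"""Synthetic aplastic anaemia registry generator and exact oracles.

The generator emulates the statistical structure the estimators assume: a
clock-forward Markov multi-state process on the eight-state structure with
piecewise-constant baseline transition intensities, multiplicative
covariate effects on the log-hazard scale, and independent administrative
censoring from uniform accrual.  Default covariate marginals follow the
registry cohort (age bands 28/30/42%, severity NSAA/SAA/VSAA 33/43/24%,
PNH clone >=1% in 45% with ~12% missing at random, 64% male) and the
default covariate effects are the registry-estimated hazard ratios (PNH
2.19, age 0.41/0.43, severity 0.42/0.46 on the response transition; 7.28
for age 60+ on the death transitions).

One deliberate deviation from a pure Markov process: the promotion
transitions carry a short refractory window after state entry (28 days
for transfusion independence, 14 days for therapy freedom) during which
their intensity is zero.  This is the registry's own logical constraint -
transfusion independence is defined by 28 transfusion-free days, so it
cannot be declared earlier - and it is what makes the back-filled raw
event logs exactly consistent with the latent paths
(:func:`aamsm.registry.derive_state_path` reproduces them).

For oracle computations, :func:`true_occupation_probabilities` gives the
exact occupation probabilities of the (ungated) Markov process by chained
matrix exponentials over the constant pieces of the intensity matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .coxph import CovariateProfile
from .msdata import TransitionStructure, default_structure
from .registry import PatientRecord, StatePath

__all__ = [
    "SimulatorConfig",
    "SimulatedCohort",
    "default_baselines",
    "registry_default_config",
    "simulate_paths",
    "simulate_cohort",
    "true_occupation_probabilities",
]

_YEAR = 365.25


def default_baselines() -> dict[int, tuple[tuple[float, ...], tuple[float, ...]]]:
    """Piecewise-constant baseline intensities per transition (per day).

    Keys are transition ids of the default structure; values are
    ``(knots, rates)`` with the last piece extending to infinity.  The
    rates are chosen to give registry-like dynamics: most responses within
    the first year, therapy stops mainly from the second year on,
    non-negligible relapse and restart flows, and low but age-sensitive
    mortality.  They are configuration defaults, not estimates.
    """
    y = _YEAR
    return {
        1:  ((0.0, y), (1.80 / y, 0.25 / y)),    # 1->2 response
        2:  ((0.0,), (0.10 / y,)),               # 2->1 relapse
        3:  ((0.0, y), (0.05 / y, 0.35 / y)),    # 2->3 therapy stop
        4:  ((0.0,), (0.05 / y,)),               # 3->2 therapy restart
        5:  ((0.0,), (0.04 / y,)),               # 3->1 relapse off therapy
        6:  ((0.0,), (0.035 / y,)),              # 1->4 alloSCT
        7:  ((0.0,), (0.004 / y,)),              # 2->4
        8:  ((0.0,), (0.002 / y,)),              # 3->4
        9:  ((0.0,), (0.006 / y,)),              # 1->7 AML/MDS treatment
        10: ((0.0,), (0.004 / y,)),              # 2->7
        11: ((0.0,), (0.004 / y,)),              # 3->7
        12: ((0.0,), (0.004 / y,)),              # 1->8 death w/o SCT or AML/MDS
        13: ((0.0,), (0.004 / y,)),              # 2->8
        14: ((0.0,), (0.004 / y,)),              # 3->8
        15: ((0.0,), (2.00 / y,)),               # 4->5 post-SCT independence
        16: ((0.0,), (0.05 / y,)),               # 5->4 post-SCT relapse
        17: ((0.0,), (0.25 / y,)),               # 4->6 death after SCT
        18: ((0.0,), (0.02 / y,)),               # 5->6
    }


def _default_betas() -> dict[int, dict[str, float]]:
    ln = math.log
    response = {
        "pnh_ge1": ln(2.19),
        "age_40_59": ln(0.41),
        "age_60plus": ln(0.43),
        "sev_SAA": ln(0.42),
        "sev_VSAA": ln(0.46),
    }
    death = {"age_60plus": ln(7.28)}
    return {1: dict(response), 12: dict(death), 13: dict(death), 14: dict(death)}


#: Refractory windows (days) after state entry during which the promotion
#: transition cannot fire; keyed by transition id of the default structure.
_DEFAULT_GATES = {1: 28.0, 3: 14.0, 15: 28.0}


@dataclass
class SimulatorConfig:
    """Study conditions of the synthetic registry.

    Times are days since IST start.  ``baselines`` maps transition id to
    ``(knots, rates)``; ``betas`` maps transition id to ``{dummy: log HR}``.
    ``accrual_window_days`` spreads entry uniformly before the
    administrative cutoff, so censoring times are uniform on
    ``[cutoff - accrual, cutoff]``.
    """

    n_patients: int = 144
    n_eltrombopag: int = 17
    age_probs: tuple[float, float, float] = (0.28, 0.30, 0.42)
    severity_probs: tuple[float, float, float] = (0.33, 0.43, 0.24)
    p_pnh_ge1: float = 0.45
    p_pnh_missing: float = 15 / 127
    p_male: float = 0.64
    baselines: Mapping[int, tuple] = field(default_factory=default_baselines)
    betas: Mapping[int, Mapping[str, float]] = field(default_factory=_default_betas)
    accrual_window_days: float = 9.0 * _YEAR
    admin_cutoff_day: float = 10.0 * _YEAR
    gates: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_GATES))
    clock_reset: bool = False   # semi-Markov switch: baselines on sojourn clock

    def validate(self, structure: TransitionStructure) -> None:
        if self.n_eltrombopag > self.n_patients:
            raise ValueError("n_eltrombopag exceeds n_patients")
        for probs in (self.age_probs, self.severity_probs):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"marginals must be probabilities summing to 1: {probs}")
        start = min(structure.state_ids)
        out = structure.out_transitions(start)
        total = 0.0
        for q in out:
            knots, rates = self.baselines.get(q, ((0.0,), (0.0,)))
            if any(r < 0 for r in rates) or any(not math.isfinite(r) for r in rates):
                raise ValueError(f"invalid rates for transition {q}: {rates}")
            total += sum(rates)
        if total <= 0:
            raise ValueError("all intensities out of the start state are zero")


def registry_default_config() -> SimulatorConfig:
    """The shipped registry-default configuration (144 patients, 17 of whom
    received Eltrombopag-containing first-line treatment)."""
    return SimulatorConfig()


@dataclass
class SimulatedCohort:
    records: list[PatientRecord]
    paths: list[StatePath]
    covariates: pd.DataFrame


# ---------------------------------------------------------------------------
# sampling machinery


def _invert_piecewise(knots, rates, scale, lo, target, offset=0.0):
    """Time T >= lo with integral of scale*rate(u - offset) over (lo, T] = target."""
    n = len(knots)
    for i in range(n):
        a = knots[i] + offset
        b = (knots[i + 1] + offset) if i + 1 < n else math.inf
        a = max(a, lo)
        if b <= a:
            continue
        r = rates[i] * scale
        if r <= 0.0:
            continue
        span = (b - a) * r
        if target <= span:
            return a + target / r
        target -= span
    return math.inf


def _draw_covariates(cfg: SimulatorConfig, rng: np.random.Generator, n: int):
    age_cat = rng.choice(len(cfg.age_probs), size=n, p=cfg.age_probs)
    age_lo = np.array([18.0, 40.0, 60.0])
    age_hi = np.array([40.0, 60.0, 80.0])
    age = age_lo[age_cat] + rng.random(n) * (age_hi[age_cat] - age_lo[age_cat])
    severity = rng.choice(len(cfg.severity_probs), size=n, p=cfg.severity_probs)
    pnh_true = rng.random(n) < cfg.p_pnh_ge1
    pnh_missing = rng.random(n) < cfg.p_pnh_missing
    sex = rng.random(n) < cfg.p_male
    return age, age_cat, severity, pnh_true, pnh_missing, sex


def _dummy_values(age_cat: int, severity: int, pnh_ge1: bool) -> dict[str, float]:
    return {
        "pnh_ge1": float(pnh_ge1),
        "age_40_59": float(age_cat == 1),
        "age_60plus": float(age_cat == 2),
        "sev_SAA": float(severity == 1),
        "sev_VSAA": float(severity == 2),
    }


def simulate_paths(
    config: SimulatorConfig,
    seed: int | np.random.Generator = 0,
    structure: TransitionStructure | None = None,
    apply_gates: bool = True,
) -> SimulatedCohort:
    """Simulate latent state paths (no raw event logs).

    With ``apply_gates=False`` the process is exactly Markov (matching the
    chained matrix-exponential oracle) but its paths cannot be back-filled
    into consistent event logs; :func:`simulate_cohort` keeps gates on.
    """
    structure = structure if structure is not None else default_structure()
    config.validate(structure)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_patients
    age, age_cat, severity, pnh_true, pnh_missing, sex = _draw_covariates(
        config, rng, n
    )
    censor = config.admin_cutoff_day - rng.random(n) * config.accrual_window_days
    if np.any(censor <= 0):
        raise ValueError("accrual window produces non-positive follow-up")
    elt = np.zeros(n, bool)
    if config.n_eltrombopag:
        elt[rng.choice(n, size=config.n_eltrombopag, replace=False)] = True

    out_by_state = {g: structure.out_transitions(g) for g in structure.state_ids}
    targets = {q: gh[1] for q, gh in structure.transitions.items()}
    gates = dict(config.gates) if apply_gates else {}
    start = min(structure.state_ids)

    sev_lab = np.array(["NSAA", "SAA", "VSAA"])
    age_lab = np.array(["18-39", "40-59", "60+"])

    paths: list[StatePath] = []
    cov_rows = {}
    width = len(str(n))
    for i in range(n):
        z = _dummy_values(age_cat[i], severity[i], pnh_true[i])
        scales = {}
        for q in structure.transitions:
            b = config.betas.get(q)
            scales[q] = math.exp(sum(c * z[k] for k, c in b.items())) if b else 1.0
        pid = f"P{i:0{width}d}"
        visits = [(start, 0.0)]
        state, t = start, 0.0
        absorbed = False
        c = float(censor[i])
        while t < c and not structure.is_absorbing(state):
            best_t, best_q = math.inf, None
            entry = t
            for q in out_by_state[state]:
                knots, rates = config.baselines.get(q, ((0.0,), (0.0,)))
                lo = entry + gates.get(q, 0.0) if q in gates else entry
                offset = entry if config.clock_reset else 0.0
                cand = _invert_piecewise(
                    knots, rates, scales[q], max(lo, entry),
                    rng.exponential(), offset,
                )
                if cand < best_t:
                    best_t, best_q = cand, q
            if best_t >= c:
                break
            state = targets[best_q]
            t = best_t
            visits.append((state, t))
            absorbed = structure.is_absorbing(state)
        paths.append(StatePath(
            patient_id=pid,
            visits=visits,
            terminal_status="absorbed" if absorbed else "censored",
            censoring_day=c,
        ))
        cov_rows[pid] = {
            "age": float(age[i]),
            "age_cat": age_lab[age_cat[i]],
            "severity": sev_lab[severity[i]],
            "pnh": None if pnh_missing[i] else (">=1%" if pnh_true[i] else "<1%"),
            "pnh_true": ">=1%" if pnh_true[i] else "<1%",
            "sex": "M" if sex[i] else "F",
            "eltrombopag": bool(elt[i]),
        }
    cov = pd.DataFrame.from_dict(cov_rows, orient="index")
    cov.index.name = "patient_id"
    return SimulatedCohort(records=[], paths=paths, covariates=cov)


def _backfill_record(path: StatePath, cov: pd.Series, end: float) -> PatientRecord:
    """Raw event log exactly consistent with the latent path."""
    transfusions = [0.0]
    therapy_events: list[tuple[float, str]] = [(0.0, "start")]
    allosct = aml = death = None
    visits = path.visits

    def _fill_transfusions(t0: float, t_hi: float) -> None:
        # routine transfusions during a transfusion-dependent sojourn
        day = t0 + 10.0
        while day < t_hi - 1e-9:
            transfusions.append(day)
            day += 10.0

    for (g, t0), (h, t1) in zip(visits, visits[1:]):
        if g in (1, 4) and (g, h) not in ((1, 2), (4, 5)):
            # transfusion-dependent sojourn ending in a failure event
            _fill_transfusions(t0, t1)
        if (g, h) in ((1, 2), (4, 5)):
            _fill_transfusions(t0, t1 - 28.0)
            if t1 - 28.0 > t0 + 1e-12:
                transfusions.append(t1 - 28.0)
        elif (g, h) in ((2, 1), (3, 1), (5, 4)):
            transfusions.append(t1)
            if (g, h) == (3, 1):
                therapy_events.append((t1, "start"))
        elif (g, h) == (2, 3):
            therapy_events.append((t1 - 14.0, "stop"))
        elif (g, h) == (3, 2):
            therapy_events.append((t1, "start"))
        elif h == 4:
            allosct = t1
        elif h == 7:
            aml = t1
        elif h in (6, 8):
            death = t1
        else:  # pragma: no cover - unreachable with the default structure
            raise ValueError(f"cannot back-fill transition {g}->{h}")

    # censored while transfusion-dependent: keep routine transfusions going
    last_state, last_t = visits[-1]
    if last_state in (1, 4):
        _fill_transfusions(last_t, end)

    starts = [t for t, kind in therapy_events if kind == "start"]
    stops = [t for t, kind in therapy_events if kind == "stop"]
    intervals: list[tuple[float, Optional[float]]] = []
    for k, s in enumerate(starts):
        intervals.append((s, stops[k] if k < len(stops) else None))

    return PatientRecord(
        patient_id=path.patient_id,
        age_at_ist=float(cov["age"]),
        severity=str(cov["severity"]),
        pnh_clone=cov["pnh"],
        sex=str(cov["sex"]),
        first_line_regimen=(
            "ATGAM+CsA+Eltrombopag" if cov.get("eltrombopag", False) else "ATGAM+CsA"
        ),
        last_followup_day=end,
        transfusion_dates=sorted(transfusions),
        therapy_intervals=intervals,
        allosct_day=allosct,
        aml_mds_treatment_day=aml,
        death_day=death,
    )


def simulate_cohort(
    config: SimulatorConfig | None = None,
    seed: int = 0,
    structure: TransitionStructure | None = None,
) -> SimulatedCohort:
    """Simulate a full registry: latent paths plus consistent raw event logs.

    Identical seeds give identical cohorts.  Deriving the state path from
    each back-filled event log reproduces the latent path exactly.
    """
    config = config if config is not None else registry_default_config()
    structure = structure if structure is not None else default_structure()
    cohort = simulate_paths(config, seed, structure, apply_gates=True)
    records = []
    for path in cohort.paths:
        cov = cohort.covariates.loc[path.patient_id]
        end = (
            path.visits[-1][1]
            if path.terminal_status == "absorbed"
            and path.visits[-1][0] in (6, 8)
            else path.censoring_day
        )
        records.append(_backfill_record(path, cov, float(end)))
    cohort.records = records
    return cohort


# ---------------------------------------------------------------------------
# exact oracle


def true_occupation_probabilities(
    config: SimulatorConfig,
    profile: CovariateProfile | Mapping[str, float] | None,
    times: Sequence[float],
    structure: TransitionStructure | None = None,
    start_state: int = 1,
) -> np.ndarray:
    """Exact P(0, t) rows of the ungated Markov process for a profile.

    Piecewise-constant intensities are chained through matrix exponentials
    over the constant pieces: P(0, t) = prod_j expm(Lambda_j * dt_j).
    ``profile`` may be None (reference levels / no covariate effect), a
    :class:`CovariateProfile`, or a mapping of dummy values.
    Returns an array of shape (len(times), n_states).
    """
    structure = structure if structure is not None else default_structure()
    ids = structure.state_ids
    K = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    if profile is None:
        z = {}
    elif isinstance(profile, CovariateProfile):
        z = dict(zip(
            ("pnh_ge1", "age_40_59", "age_60plus", "sev_SAA", "sev_VSAA"),
            profile.vector(("pnh_ge1", "age_40_59", "age_60plus", "sev_SAA", "sev_VSAA")),
        ))
    else:
        z = dict(profile)

    knot_set = {0.0}
    for q in structure.transitions:
        knots, _ = config.baselines.get(q, ((0.0,), (0.0,)))
        knot_set.update(knots)
    times = np.asarray(times, float)
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise ValueError("times must be finite and non-negative")
    grid = np.unique(np.concatenate([sorted(knot_set), times]))

    def _lam(q: int, t: float) -> float:
        knots, rates = config.baselines.get(q, ((0.0,), (0.0,)))
        i = int(np.searchsorted(knots, t, side="right") - 1)
        rate = rates[i] if i >= 0 else 0.0
        b = config.betas.get(q)
        scale = math.exp(sum(c * z.get(k, 0.0) for k, c in b.items())) if b else 1.0
        if not math.isfinite(rate * scale):
            raise ValueError(f"non-finite intensity for transition {q}")
        return rate * scale

    P = np.eye(K)
    out = np.empty((len(times), K))
    want = {t: j for j, t in enumerate(times)}
    if 0.0 in want:
        out[want[0.0]] = P[idx[start_state]]
    for a, b in zip(grid, grid[1:]):
        L = np.zeros((K, K))
        for q, (g, h) in structure.transitions.items():
            lam = _lam(q, a)
            L[idx[g], idx[h]] += lam
            L[idx[g], idx[g]] -= lam
        P = P @ expm(L * (b - a))
        if b in want:
            out[want[b]] = P[idx[start_state]]
    return out
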