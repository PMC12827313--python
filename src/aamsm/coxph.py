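"""Transition-specific Cox proportional hazards models.

Each model acts on one transition of the multi-state structure (or on a
pooled set of transitions sharing a common baseline) and is fitted by
maximising the Breslow partial likelihood on the counting-process rows of
that transition, with the since-IST clock and left truncation handled
through the (Tstart, Tstop] risk sets.  The Breslow baseline cumulative
hazard A_0(t) = sum d(t) / sum_{at risk} exp(beta'Z) reduces exactly to the
Nelson-Aalen estimate when no covariates are modelled.

Three model presets mirror the registry analysis: M1 (transfusion-dependent
-> transfusion-independent-with-therapy; PNH clone, age category, disease
severity), M2 (-> free of transfusion and therapy; same covariates) and M3
(pooled transitions from the three alive non-transplant states to death,
common baseline; age 60+ vs 18-59).  All other transitions carry no
covariate model and enter predictions non-parametrically.

Model-based outcomes for a reference covariate profile are obtained by
scaling each modelled baseline by exp(beta'Z) and running the profile
hazards through the Aalen-Johansen product integral; confidence bands come
from a nonparametric bootstrap over patients.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .msdata import TransitionStructure, default_structure
from .nonparam import (
    CumulativeHazard,
    OccupationTrajectory,
    aalen_johansen,
    nelson_aalen,
)

__all__ = [
    "CovariateProfile",
    "ModelSpec",
    "CoxFit",
    "ConvergenceError",
    "encode_covariates",
    "fit_transition_cox",
    "preset_m1",
    "preset_m2",
    "preset_m3",
    "default_model_specs",
    "predict_profile_hazards",
    "predict_profile_probabilities",
    "bootstrap_profile_ci",
    "reference_profiles",
]

logger = logging.getLogger(__name__)

AGE_LEVELS = ("18-39", "40-59", "60+")
SEVERITY_LEVELS = ("NSAA", "SAA", "VSAA")
PNH_LEVELS = ("<1%", ">=1%")

#: Dummy columns derived from the baseline factors (reference levels:
#: age 18-39, NSAA, PNH <1%).  ``age_60plus`` doubles as the collapsed
#: 60+ vs 18-59 indicator used by the death model.
DUMMY_COLUMNS = ["pnh_ge1", "age_40_59", "age_60plus", "sev_SAA", "sev_VSAA"]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximisation failed (or likelihood is monotone)."""


def encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode age category, severity and PNH-clone status.

    Missing PNH status propagates as NaN so that models using it drop the
    record (complete-case analysis).
    """
    out = pd.DataFrame(index=cov.index)
    pnh = cov["pnh"]
    out["pnh_ge1"] = np.where(
        pnh.isna(), np.nan, (pnh == ">=1%").astype(float)
    )
    out["age_40_59"] = (cov["age_cat"] == "40-59").astype(float)
    out["age_60plus"] = (cov["age_cat"] == "60+").astype(float)
    out["sev_SAA"] = (cov["severity"] == "SAA").astype(float)
    out["sev_VSAA"] = (cov["severity"] == "VSAA").astype(float)
    return out


@dataclass(frozen=True)
class CovariateProfile:
    """A reference patient: one level per baseline factor."""

    age_cat: str = "18-39"
    severity: str = "NSAA"
    pnh: str = "<1%"

    def __post_init__(self):
        if self.age_cat not in AGE_LEVELS:
            raise ValueError(f"unknown age category {self.age_cat!r}")
        if self.severity not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.pnh not in PNH_LEVELS:
            raise ValueError(f"unknown PNH level {self.pnh!r}")

    def vector(self, columns: Sequence[str]) -> np.ndarray:
        values = {
            "pnh_ge1": float(self.pnh == ">=1%"),
            "age_40_59": float(self.age_cat == "40-59"),
            "age_60plus": float(self.age_cat == "60+"),
            "sev_SAA": float(self.severity == "SAA"),
            "sev_VSAA": float(self.severity == "VSAA"),
        }
        return np.array([values[c] for c in columns])

    @property
    def label(self) -> str:
        return f"{self.age_cat}/{self.severity}/PNH{self.pnh}"


def reference_profiles() -> list[CovariateProfile]:
    """All 18 reference patients (3 ages x 3 severities x 2 PNH levels)."""
    return [
        CovariateProfile(a, s, p)
        for a in AGE_LEVELS for s in SEVERITY_LEVELS for p in PNH_LEVELS
    ]


@dataclass(frozen=True)
class ModelSpec:
    """Which transitions a Cox model covers and with which covariates.

    Pooled transitions share a common baseline hazard and common
    coefficients (no from-state effect).
    """

    name: str
    transitions: tuple[int, ...]
    covariates: tuple[str, ...]


def preset_m1() -> ModelSpec:
    return ModelSpec(
        "M1", (1,), ("pnh_ge1", "age_40_59", "age_60plus", "sev_SAA", "sev_VSAA")
    )


def preset_m2() -> ModelSpec:
    return ModelSpec(
        "M2", (3,), ("pnh_ge1", "age_40_59", "age_60plus", "sev_SAA", "sev_VSAA")
    )


def preset_m3() -> ModelSpec:
    # pooled transitions 1->8, 2->8, 3->8 of the default structure
    return ModelSpec("M3", (12, 13, 14), ("age_60plus",))


def default_model_specs() -> list[ModelSpec]:
    return [preset_m1(), preset_m2(), preset_m3()]


@dataclass
class CoxFit:
    """A fitted transition-specific Cox model."""

    spec: ModelSpec
    beta: np.ndarray
    cov: np.ndarray
    baseline_times: np.ndarray
    baseline_dA: np.ndarray
    n: int                      # complete-case patients
    n_events: int
    loglik: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def hazard_ratios(self) -> pd.DataFrame:
        """HRs with 95% Wald CIs exp(beta +- 1.96 se) and p-values."""
        se = self.se
        z = self.beta / se
        return pd.DataFrame({
            "coef": self.beta,
            "HR": np.exp(self.beta),
            "lower95": np.exp(self.beta - 1.96 * se),
            "upper95": np.exp(self.beta + 1.96 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }, index=list(self.spec.covariates))

    def baseline_hazard(self) -> tuple[np.ndarray, np.ndarray]:
        return self.baseline_times, self.baseline_dA

    def to_json(self) -> str:
        return json.dumps({
            "name": self.spec.name,
            "transitions": list(self.spec.transitions),
            "covariates": list(self.spec.covariates),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "baseline_times": self.baseline_times.tolist(),
            "baseline_dA": self.baseline_dA.tolist(),
            "n": self.n,
            "n_events": self.n_events,
            "loglik": self.loglik,
        })

    @classmethod
    def from_json(cls, text: str) -> "CoxFit":
        d = json.loads(text)
        return cls(
            spec=ModelSpec(d["name"], tuple(d["transitions"]), tuple(d["covariates"])),
            beta=np.asarray(d["beta"], float),
            cov=np.asarray(d["cov"], float),
            baseline_times=np.asarray(d["baseline_times"], float),
            baseline_dA=np.asarray(d["baseline_dA"], float),
            n=int(d["n"]),
            n_events=int(d["n_events"]),
            loglik=float(d["loglik"]),
        )


# ---------------------------------------------------------------------------
# Breslow partial likelihood on (Tstart, Tstop] rows


def _suffix_sums(keys: np.ndarray, values: np.ndarray, at: np.ndarray) -> np.ndarray:
    """sum of values[j] over keys[j] >= t, for each t in ``at``.

    ``keys`` need not be sorted; ``values`` may be 2-d (rows aligned with
    keys).
    """
    order = np.argsort(keys, kind="stable")
    k = keys[order]
    v = values[order]
    suffix = np.cumsum(v[::-1], axis=0)[::-1]
    pos = np.searchsorted(k, at, side="left")
    out = np.zeros((len(at),) + v.shape[1:])
    inside = pos < len(k)
    out[inside] = suffix[pos[inside]]
    return out


def _risk_sums(Tstart, Tstop, V, at):
    """sum of V over rows at risk (Tstart < t <= Tstop) at each t in ``at``."""
    return _suffix_sums(Tstop, V, at) - _suffix_sums(Tstart, V, at)


def _breslow_quantities(beta, Tstart, Tstop, X, ev_times):
    """S0 (m,), S1 (m,p), S2 (m,p,p) at the distinct event times."""
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    p = X.shape[1]
    wX = w[:, None] * X
    iu, ju = np.triu_indices(p)
    wXX = wX[:, iu] * X[:, ju]
    V = np.column_stack([w, wX, wXX])
    R = _risk_sums(Tstart, Tstop, V, ev_times)
    S0 = R[:, 0]
    S1 = R[:, 1:1 + p]
    S2 = np.zeros((len(ev_times), p, p))
    S2[:, iu, ju] = R[:, 1 + p:]
    S2[:, ju, iu] = R[:, 1 + p:]
    return S0, S1, S2


def _fit_breslow(Tstart, Tstop, status, X, tol=1e-8, maxiter=50):
    """Newton-Raphson maximiser of the Breslow partial likelihood."""
    ev = status == 1
    n_events = int(ev.sum())
    if n_events == 0:
        raise ConvergenceError("no events on the modelled transition(s)")
    p = X.shape[1]
    ev_stop = Tstop[ev]
    ev_times, inverse = np.unique(ev_stop, return_inverse=True)
    d = np.bincount(inverse).astype(float)
    sumZ = X[ev].sum(axis=0)

    if p == 0:   # null model: Breslow baseline reduces to Nelson-Aalen
        S0 = _risk_sums(Tstart, Tstop, np.ones((len(Tstart), 1)), ev_times)[:, 0]
        assert np.all(S0 > 0), "event with empty risk set"
        ll = -float(d @ np.log(S0))
        return (np.zeros(0), np.zeros((0, 0)), ev_times, d / S0, n_events, ll)

    beta = np.zeros(p)
    # gradient is a sum over events; scale the tolerance accordingly so the
    # criterion is meaningful from 20-row fixtures to 10^5-row cohorts
    gtol = tol * max(1.0, n_events)
    ll_prev = -np.inf
    for it in range(maxiter):
        S0, S1, S2 = _breslow_quantities(beta, Tstart, Tstop, X, ev_times)
        assert np.all(S0 > 0), "event with empty risk set"
        ll = float((X[ev] @ beta).sum() - d @ np.log(S0))
        grad = sumZ - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
        Ebar = S1 / S0[:, None]
        H = -(d[:, None, None] * (S2 / S0[:, None, None]
                                  - Ebar[:, :, None] * Ebar[:, None, :])).sum(axis=0)
        if np.max(np.abs(grad)) < gtol:
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving safeguard
        new = beta + step
        for _ in range(30):
            S0n, _, _ = _breslow_quantities(new, Tstart, Tstop, X, ev_times)
            lln = float((X[ev] @ new).sum() - d @ np.log(S0n))
            if lln >= ll - 1e-12:
                break
            new = (beta + new) / 2
        beta = new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging: monotone likelihood / perfect separation"
            )
        ll_prev = ll
    else:
        raise ConvergenceError(
            f"no convergence in {maxiter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.3g}, beta={beta})"
        )
    S0, S1, S2 = _breslow_quantities(beta, Tstart, Tstop, X, ev_times)
    ll = float((X[ev] @ beta).sum() - d @ np.log(S0))
    Ebar = S1 / S0[:, None]
    H = -(d[:, None, None] * (S2 / S0[:, None, None]
                              - Ebar[:, :, None] * Ebar[:, None, :])).sum(axis=0)
    cov = np.linalg.inv(-H) if p else np.zeros((0, 0))
    dA0 = d / S0
    return beta, cov, ev_times, dA0, n_events, ll


def fit_transition_cox(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> CoxFit:
    """Fit a transition-specific Cox model on long-format data.

    Rows with a missing value in any model covariate are dropped
    (complete-case analysis, per model); ``n`` reports the number of
    distinct patients retained.  With an empty covariate list the Breslow
    baseline equals the Nelson-Aalen estimate of the (pooled) transition.
    """
    sub = data[data["trans"].isin(spec.transitions)]
    if len(sub) == 0:
        raise ValueError(f"{spec.name}: no rows for transitions {spec.transitions}")
    cols = list(spec.covariates)
    if cols:
        complete = sub[cols].notna().all(axis=1)
        sub = sub[complete]
    X = sub[cols].to_numpy(float) if cols else np.empty((len(sub), 0))
    beta, cov, times, dA0, n_events, ll = _fit_breslow(
        sub["Tstart"].to_numpy(float),
        sub["Tstop"].to_numpy(float),
        sub["status"].to_numpy(int),
        X, tol=tol, maxiter=maxiter,
    )
    return CoxFit(
        spec=spec, beta=beta, cov=cov,
        baseline_times=times, baseline_dA=dA0,
        n=int(sub["patient_id"].nunique()), n_events=n_events, loglik=ll,
    )


# ---------------------------------------------------------------------------
# model-based prediction for reference profiles


def predict_profile_hazards(
    fits: Sequence[CoxFit],
    null_hazards: Sequence[CumulativeHazard],
    profile: CovariateProfile,
    structure: TransitionStructure | None = None,
) -> list[CumulativeHazard]:
    """Per-transition cumulative hazards for a reference patient.

    Modelled transitions get A_0(t) * exp(beta'Z); every other transition
    keeps its Nelson-Aalen hazard, shared across profiles.  Every
    transition of the structure must be covered by exactly one source.
    """
    structure = structure if structure is not None else default_structure()
    covered: dict[int, CumulativeHazard] = {}

    def _claim(q: int, hz: CumulativeHazard, src: str) -> None:
        if q in covered:
            raise ValueError(f"transition {q} covered twice ({src})")
        covered[q] = hz

    for fit in fits:
        z = profile.vector(fit.spec.covariates)
        scale = float(np.exp(fit.beta @ z)) if len(z) else 1.0
        for q in fit.spec.transitions:
            g, h = structure.transitions[q]
            _claim(q, CumulativeHazard(
                q, g, h, fit.baseline_times.copy(), fit.baseline_dA * scale
            ), f"model {fit.spec.name}")
    for hz in null_hazards:
        if hz.trans in covered:
            continue  # modelled transitions take precedence only if absent
        _claim(hz.trans, hz, "null hazard")
    missing = set(structure.transitions) - set(covered)
    if missing:
        raise ValueError(f"transitions not covered by any hazard source: {sorted(missing)}")
    return [covered[q] for q in sorted(covered)]


def predict_profile_probabilities(
    profile_hazards: Sequence[CumulativeHazard],
    structure: TransitionStructure | None = None,
    s: float = 0.0,
) -> OccupationTrajectory:
    """Aalen-Johansen trajectory under profile-specific hazards."""
    structure = structure if structure is not None else default_structure()
    return aalen_johansen(
        profile_hazards, s=s, structure=structure,
        start_state=min(structure.state_ids), compute_var=False,
        clip_increments=True,
    )


def _resample_long(data: pd.DataFrame, blocks: list[np.ndarray], rng) -> pd.DataFrame:
    ids = rng.integers(0, len(blocks), size=len(blocks))
    take = np.concatenate([blocks[i] for i in ids])
    out = data.iloc[take].copy()
    out["patient_id"] = np.repeat(
        np.arange(len(ids)), [len(blocks[i]) for i in ids]
    )
    return out


def bootstrap_profile_ci(
    data: pd.DataFrame,
    model_specs: Sequence[ModelSpec],
    profile: CovariateProfile,
    horizon: float,
    B: int = 500,
    seed: int = 0,
    structure: TransitionStructure | None = None,
    state_sets: Optional[dict] = None,
) -> dict:
    """Nonparametric bootstrap bands for model-based occupation probabilities.

    Patients are resampled with replacement from the long-format data; all
    models are refitted and the profile trajectory recomputed per
    resample.  Returns percentile 2.5/97.5 bands at ``horizon`` for each
    state (and for each combined state set in ``state_sets``), plus the
    point estimate and the number of redrawn non-convergent resamples.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    structure = structure if structure is not None else default_structure()
    rng = np.random.default_rng(seed)
    ids = data["patient_id"].to_numpy()
    _, codes = np.unique(ids, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    cuts = np.searchsorted(sorted_codes, np.arange(sorted_codes[-1] + 2))
    blocks = [order[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]

    def _estimate(df: pd.DataFrame) -> np.ndarray:
        haz = nelson_aalen(df, structure)
        fits = [fit_transition_cox(df, spec) for spec in model_specs]
        ph = predict_profile_hazards(fits, haz, profile, structure)
        traj = predict_profile_probabilities(ph, structure)
        return traj.at(horizon)

    point = _estimate(data)
    samples = np.empty((B, len(point)))
    redrawn = 0
    b = 0
    while b < B:
        try:
            samples[b] = _estimate(_resample_long(data, blocks, rng))
            b += 1
        except ConvergenceError:
            redrawn += 1
            if redrawn > 0.2 * B + 5:
                raise ConvergenceError(
                    ">20% of bootstrap resamples failed to converge; "
                    "the dataset is too small for stable model-based bands"
                )
    if redrawn:
        logger.info("bootstrap: %d non-convergent resamples redrawn", redrawn)
    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    out = {
        "profile": profile.label,
        "horizon": horizon,
        "point": point,
        "lower": lo,
        "upper": hi,
        "samples": samples,
        "n_redrawn": redrawn,
    }
    if state_sets:
        sid = structure.state_ids
        for label, states in state_sets.items():
            cols = [sid.index(s) for s in states]
            vals = samples[:, cols].sum(axis=1)
            lo_s, hi_s = np.percentile(vals, [2.5, 97.5])
            out[label] = {
                "point": float(point[cols].sum()),
                "lower": float(lo_s),
                "upper": float(hi_s),
            }
    return out
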