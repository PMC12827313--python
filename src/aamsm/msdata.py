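"""Multi-state model structure and long-format transition data.

A :class:`TransitionStructure` describes the states of the model, the
allowed transitions (numbered 1..Q) and which states are absorbing.  The
default structure is the eight-state model used for aplastic anaemia
registries: patients start transfusion-dependent at the start of
immunosuppressive therapy (IST) and move between transfusion/therapy
states, with allogeneic stem-cell transplantation (alloSCT), start of
AML/MDS treatment and death as failure pathways.

:func:`expand_long_format` turns a collection of state paths into
counting-process ("long format") data: one row per transition at risk per
sojourn, with entry/exit times on the single time-since-IST clock
(clock-forward) and a 0/1 status.  This is the representation consumed by
the non-parametric and Cox estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionStructure",
    "StructuralViolationError",
    "build_transition_structure",
    "default_structure",
    "expand_long_format",
    "DEFAULT_STATES",
    "LONG_COLUMNS",
]


class StructuralViolationError(ValueError):
    """An event log or path implies a transition absent from the structure."""


#: State ids and names of the default aplastic anaemia model.
DEFAULT_STATES: dict[int, str] = {
    1: "TransfusionDependent",
    2: "TransfusionIndependentWithTherapy",
    3: "FreeOfTransfusionAndTherapy",
    4: "AlloSCT-TransfusionDependent",
    5: "AlloSCT-TransfusionIndependent",
    6: "DeathAfterAlloSCT",
    7: "AML/MDS-Treatment",
    8: "Death",
}

_DEFAULT_ARROWS: list[tuple[int, int]] = [
    (1, 2), (2, 1), (2, 3), (3, 2), (3, 1),
    (1, 4), (2, 4), (3, 4),
    (1, 7), (2, 7), (3, 7),
    (1, 8), (2, 8), (3, 8),
    (4, 5), (5, 4), (4, 6), (5, 6),
]

_DEFAULT_ABSORBING = frozenset({6, 7, 8})


@dataclass(frozen=True)
class TransitionStructure:
    """States, allowed transitions and absorbing flags of a multi-state model.

    Parameters
    ----------
    states
        Mapping from integer state id to state name.
    transitions
        Mapping from transition id (1..Q) to ``(from_state, to_state)``.
    absorbing
        Set of absorbing state ids (out-degree zero).
    """

    states: Mapping[int, str]
    transitions: Mapping[int, tuple[int, int]]
    absorbing: frozenset[int]
    _arrow_index: Mapping[tuple[int, int], int] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        pairs = list(self.transitions.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate arrow in transition structure")
        ids = sorted(self.transitions)
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("transition ids must be 1..Q without gaps")
        for q, (g, h) in self.transitions.items():
            if g == h:
                raise ValueError(f"self-loop {g}->{h} (transition {q})")
            for s in (g, h):
                if s not in self.states:
                    raise ValueError(f"unknown state {s} in transition {q}")
            if g in self.absorbing:
                raise ValueError(
                    f"arrow out of absorbing state: {self.state_name(g)}->{self.state_name(h)}"
                )
        for s in self.absorbing:
            if s not in self.states:
                raise ValueError(f"unknown absorbing state {s}")
        object.__setattr__(
            self, "_arrow_index", {gh: q for q, gh in self.transitions.items()}
        )

    # -- helpers -------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def state_ids(self) -> list[int]:
        return sorted(self.states)

    def state_name(self, s: int) -> str:
        return self.states[s]

    def transition_id(self, g: int, h: int) -> int:
        """Transition id for arrow ``g -> h``; raises if the arrow is absent."""
        try:
            return self._arrow_index[(g, h)]
        except KeyError:
            raise StructuralViolationError(
                f"transition {self.states.get(g, g)} -> {self.states.get(h, h)} "
                "is not in the structure"
            ) from None

    def has_arrow(self, g: int, h: int) -> bool:
        return (g, h) in self._arrow_index

    def out_transitions(self, g: int) -> list[int]:
        """Ids of transitions leaving state ``g`` (ordered by id)."""
        return sorted(q for q, (a, _) in self.transitions.items() if a == g)

    def is_absorbing(self, s: int) -> bool:
        return s in self.absorbing


def default_structure() -> TransitionStructure:
    """The eight-state aplastic anaemia structure (17 arrows, 3 absorbing)."""
    return TransitionStructure(
        states=dict(DEFAULT_STATES),
        transitions={q: gh for q, gh in enumerate(_DEFAULT_ARROWS, start=1)},
        absorbing=_DEFAULT_ABSORBING,
    )


def build_transition_structure(config: Mapping) -> TransitionStructure:
    """Build a validated structure from a plain config mapping.

    ``config`` has keys ``states`` (mapping or list of names), ``arrows``
    (list of ``[from, to]`` pairs, by id or by name) and ``absorbing``
    (list of states).  Transition ids are assigned in arrow-list order.
    """
    raw_states = config["states"]
    if isinstance(raw_states, Mapping):
        states = {int(k): str(v) for k, v in raw_states.items()}
    else:
        states = {i: str(name) for i, name in enumerate(raw_states, start=1)}
    by_name = {v: k for k, v in states.items()}

    def _resolve(s) -> int:
        if isinstance(s, str):
            if s not in by_name:
                raise ValueError(f"unknown state name {s!r}")
            return by_name[s]
        s = int(s)
        if s not in states:
            raise ValueError(f"unknown state id {s}")
        return s

    arrows = [(_resolve(a), _resolve(b)) for a, b in config["arrows"]]
    absorbing = frozenset(_resolve(s) for s in config.get("absorbing", []))
    return TransitionStructure(
        states=states,
        transitions={q: gh for q, gh in enumerate(arrows, start=1)},
        absorbing=absorbing,
    )


#: Column order of the long-format counting-process table.
LONG_COLUMNS = [
    "patient_id", "visit", "from_state", "to_state",
    "trans", "Tstart", "Tstop", "status",
]


def expand_long_format(
    paths: Sequence,
    structure: TransitionStructure,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand state paths into long-format transition data.

    For every sojourn in a non-absorbing state ``g`` on ``(t0, t1]`` one row
    is emitted per arrow ``g -> h``, with ``status = 1`` on the arrow the
    patient actually took (0 everywhere on a censored final sojourn).
    Repeated visits to a state increment ``visit``.  Times stay on the
    since-IST clock.

    Parameters
    ----------
    paths
        Objects with attributes ``patient_id``, ``visits`` (list of
        ``(state, entry_time)``) and ``censoring_day``.
    structure
        Active transition structure; every consecutive state pair must be
        one of its arrows.
    covariates
        Optional baseline covariates indexed by ``patient_id``; columns are
        merged onto every row of the patient.
    """
    recs: list[tuple] = []
    for path in paths:
        visits = list(path.visits)
        visit_no = 0
        for i, (g, t0) in enumerate(visits):
            if structure.is_absorbing(g):
                if i != len(visits) - 1:
                    raise StructuralViolationError(
                        f"visit after absorbing state {structure.state_name(g)} "
                        f"for patient {path.patient_id}"
                    )
                break
            if i + 1 < len(visits):
                h, t1 = visits[i + 1]
                target = structure.transition_id(g, h)  # validates the arrow
            else:
                h, t1 = None, float(path.censoring_day)
                target = None
            if not (t1 > t0):
                raise ValueError(
                    f"zero-length or negative sojourn in state "
                    f"{structure.state_name(g)} for patient {path.patient_id} "
                    f"({t0!r} -> {t1!r})"
                )
            visit_no += 1
            for q in structure.out_transitions(g):
                recs.append((
                    path.patient_id, visit_no, g, structure.transitions[q][1],
                    q, float(t0), float(t1), int(q == target),
                ))
    df = pd.DataFrame.from_records(recs, columns=LONG_COLUMNS)
    if covariates is not None:
        df = df.merge(
            covariates, left_on="patient_id", right_index=True, how="left"
        )
    return df


def write_long_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_long_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format CSV is missing columns: {missing}")
    return df
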