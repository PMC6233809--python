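"""Conditioning-task trial sequences and Rescorla-Wagner prediction errors.

The taste reward task pairs three visual conditioned stimuli (CS) with three
taste unconditioned stimuli (US): 1-molar sucrose, no solution, and artificial
saliva. Sucrose and no-solution CS trials are probabilistically violated (the
other taste is delivered) on a fixed fraction of trials; the saliva CS is
always followed by saliva. Trial-wise reward prediction errors delta = R - V
are computed with a delta-rule model whose expected value V is carried
separately per CS type, and the absolute PE |delta| serves as the parametric
modulator for the first-level GLM.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

CS_TYPES = ("sucrose", "no_solution", "saliva")

#: reward coding: what each delivered taste is worth on the 0-1 value scale
REWARD_VALUE = {"sucrose": 1.0, "no_solution": 0.0, "saliva": 0.0}

DEFAULT_TRIAL_DURATION_S = 6.0


@dataclass(frozen=True)
class Trial:
    """One conditioning trial: a visual CS followed by a taste US."""

    index: int
    cs_type: str
    us_type: str
    onset_s: float
    duration_s: float = DEFAULT_TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.cs_type not in CS_TYPES or self.us_type not in CS_TYPES:
            raise ValueError(f"unknown stimulus type in trial {self.index}")

    @property
    def is_violation(self) -> bool:
        return self.cs_type != self.us_type


@dataclass(frozen=True)
class TrialSequence:
    """Ordered conditioning trials with the violation probability that built them."""

    trials: tuple[Trial, ...]
    p_violation: float
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials])

    def n_expected_receipts(self, cs_type: str = "sucrose") -> int:
        """Trials where the CS's own taste was delivered (no violation)."""
        return sum(1 for t in self.trials if t.cs_type == cs_type and not t.is_violation)


@dataclass
class RWModel:
    """Trial-level Rescorla-Wagner delta-rule model.

    One expected value V per CS type, updated at US delivery:
    delta = R - V, V <- V + alpha * delta. With rewards in {0, 1} and
    alpha in (0, 1], V remains in [0, 1].
    """

    alpha: float = 0.7
    v0: float = 0.0
    V: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError(f"v0 must be in [0, 1], got {self.v0}")
        for cs in CS_TYPES:
            self.V.setdefault(cs, self.v0)


@dataclass(frozen=True)
class PETrace:
    """Per-trial signed prediction errors and their absolute values."""

    delta: np.ndarray
    abs_delta: np.ndarray
    trial_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.delta)


def rw_update(V: float, reward: float, alpha: float) -> tuple[float, float]:
    """One delta-rule update: returns (delta, V_new).

    delta = reward - V; V_new = V + alpha * delta.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not 0.0 <= V <= 1.0:
        raise ValueError(f"V must be in [0, 1], got {V}")
    delta = reward - V
    return delta, V + alpha * delta


def generate_trial_sequence(
    n_sucrose_cs: int,
    n_neutral_cs: int,
    n_saliva_cs: int,
    p_violation: float = 0.2,
    iti_range_s: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
    duration_s: float = DEFAULT_TRIAL_DURATION_S,
) -> TrialSequence:
    """Generate a seeded probabilistic conditioning sequence.

    Exactly round(p_violation * n) sucrose-CS trials receive no solution and
    round(p_violation * n) no-solution-CS trials receive sucrose, at uniformly
    random positions; the saliva CS is never violated. Trial order is a seeded
    random interleaving; onsets accumulate trial durations plus ITIs drawn
    uniformly from ``iti_range_s``.
    """
    counts = (n_sucrose_cs, n_neutral_cs, n_saliva_cs)
    if any(c < 0 for c in counts):
        raise ValueError("trial counts must be nonnegative")
    if not 0.0 <= p_violation <= 0.5:
        raise ValueError(f"p_violation must be in [0, 0.5], got {p_violation}")
    lo, hi = iti_range_s
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid iti_range_s {iti_range_s}")

    rng = np.random.default_rng(seed)
    cs_us: list[tuple[str, str]] = []
    for cs, other, n in (
        ("sucrose", "no_solution", n_sucrose_cs),
        ("no_solution", "sucrose", n_neutral_cs),
    ):
        n_viol = int(round(p_violation * n))
        us = np.array([cs] * n, dtype=object)
        if n_viol:
            us[rng.choice(n, size=n_viol, replace=False)] = other
        cs_us.extend((cs, u) for u in us)
    cs_us.extend(("saliva", "saliva") for _ in range(n_saliva_cs))

    order = rng.permutation(len(cs_us))
    itis = rng.uniform(lo, hi, size=len(cs_us))

    trials = []
    onset = 0.0
    for i, j in enumerate(order):
        cs, us = cs_us[j]
        trials.append(Trial(index=i, cs_type=cs, us_type=us,
                            onset_s=round(onset, 4), duration_s=duration_s))
        onset += duration_s + itis[i]
    return TrialSequence(trials=tuple(trials), p_violation=p_violation, seed=seed)


def compute_pe_trace(seq: TrialSequence, model: RWModel | None = None) -> PETrace:
    """Run the delta rule over a sequence, carrying V per CS type.

    Pure function of (sequence, alpha, v0); the model's V map is updated
    in place so a fresh model should be passed per sequence.
    """
    if len(seq) == 0:
        raise ValueError("trial sequence is empty")
    if model is None:
        model = RWModel()
    deltas = np.empty(len(seq))
    for i, trial in enumerate(seq):
        reward = REWARD_VALUE[trial.us_type]
        delta, v_new = rw_update(model.V[trial.cs_type], reward, model.alpha)
        model.V[trial.cs_type] = v_new
        deltas[i] = delta
    return PETrace(delta=deltas, abs_delta=np.abs(deltas),
                   trial_indices=np.arange(len(seq)))


# ---------------------------------------------------------------------------
# events-table I/O (BIDS events TSV dialect)

EVENTS_COLUMNS = ("onset", "duration", "trial_type", "outcome", "modulation")


def write_events_tsv(path: str | Path, seq: TrialSequence, trace: PETrace) -> None:
    """Write an events table: onset, duration, trial_type, outcome, modulation.

    ``modulation`` holds the absolute prediction error |delta| per trial.
    """
    if len(trace) != len(seq):
        raise ValueError("trace length does not match sequence length")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENTS_COLUMNS)
        for trial, mod in zip(seq, trace.abs_delta):
            w.writerow([f"{trial.onset_s:.4f}", f"{trial.duration_s:.4f}",
                        trial.cs_type, trial.us_type, f"{mod:.6f}"])


def read_events_tsv(path: str | Path) -> tuple[TrialSequence, PETrace]:
    """Read an events table back into a sequence and modulation trace."""
    trials: list[Trial] = []
    mods: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(EVENTS_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader):
            trials.append(Trial(index=i, cs_type=row["trial_type"],
                                us_type=row["outcome"],
                                onset_s=float(row["onset"]),
                                duration_s=float(row["duration"])))
            mods.append(float(row["modulation"]))
    mods_arr = np.array(mods)
    seq = TrialSequence(trials=tuple(trials), p_violation=float("nan"), seed=-1)
    trace = PETrace(delta=mods_arr.copy(), abs_delta=mods_arr,
                    trial_indices=np.arange(len(trials)))
    return seq, trace
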