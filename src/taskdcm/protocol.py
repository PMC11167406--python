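"""Spatial stimulus–response compatibility (SRC) task protocols.

The SRC paradigm presents brief lateralized visual stimuli and requires a
button press with either the ipsilateral hand (compatible, "Pro") or the
contralateral hand (incompatible, "Anti").  The experiment is organised as a
mixed block/event design: condition blocks, announced by a short instruction
cue, each contain a jittered train of 0.2-s stimuli and are separated by rest
periods.  This module generates such protocols, simulates behavioural
responses, and converts both into the boxcar stimulus functions that drive
the general linear model and the dynamic causal model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Condition = Literal["Anti", "Pro"]
Side = Literal["L", "R"]

DESIGN_TYPES = ("AllTrials", "STrials", "Blocks")
MODULATORY_CONTRASTS = ("Anti", "AntiPlusPro")

#: reaction-time validity window (ms): faster or slower responses are errors
RT_MIN_MS = 150.0
RT_MAX_MS = 1500.0


class ProtocolConfigError(ValueError):
    """Raised when protocol parameters are infeasible or out of range."""


@dataclass(frozen=True)
class ProtocolParams:
    """Timing parameters of the SRC experiment.

    Defaults reproduce the acquisition protocol this pipeline emulates:
    TR 2.03 s, 24 blocks (12 per condition), 13-16 trials per block, 0.2-s
    stimuli, inter-onset intervals jittered uniformly in [2, 4.5] s, rests
    of 15-19 s between blocks and a 2-s instruction cue before each block.
    """

    tr_seconds: float = 2.03
    n_blocks: int = 24
    trials_per_block: tuple[int, int] = (13, 16)
    stimulus_duration_s: float = 0.2
    iti_range_s: tuple[float, float] = (2.0, 4.5)
    rest_range_s: tuple[float, float] = (15.0, 19.0)
    instruction_duration_s: float = 2.0
    #: gap between instruction offset and first stimulus (not stated by the
    #: protocol description; configurable)
    instruction_gap_s: float = 2.0
    #: constrained pseudo-randomization: at most this many consecutive
    #: blocks of the same condition
    max_consecutive_blocks: int = 3
    #: extra scan time appended after the final rest
    tail_s: float = 4.0

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise ProtocolConfigError("tr_seconds must be positive")
        if self.n_blocks < 2 or self.n_blocks % 2:
            raise ProtocolConfigError("n_blocks must be even and >= 2")
        lo, hi = self.trials_per_block
        if not (1 <= lo <= hi):
            raise ProtocolConfigError("invalid trials_per_block range")
        if not (0 < self.stimulus_duration_s <= self.iti_range_s[0]):
            raise ProtocolConfigError(
                "stimulus_duration_s must be positive and no longer than "
                "the minimum inter-onset interval"
            )
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ProtocolConfigError("iti_range_s must be ordered")
        if self.rest_range_s[0] > self.rest_range_s[1]:
            raise ProtocolConfigError("rest_range_s must be ordered")
        if self.max_consecutive_blocks < 1:
            raise ProtocolConfigError("max_consecutive_blocks must be >= 1")


@dataclass(frozen=True)
class Block:
    condition: Condition
    instruction_onset_s: float
    instruction_duration_s: float
    trial_onsets_s: tuple[float, ...]
    trial_sides: tuple[Side, ...]
    trial_duration_s: float = 0.2

    @property
    def onset_s(self) -> float:
        """Block onset = first trial onset (block-design regressor onset)."""
        return self.trial_onsets_s[0]

    @property
    def end_s(self) -> float:
        return self.trial_onsets_s[-1] + self.trial_duration_s

    @property
    def duration_s(self) -> float:
        """Full block length, first trial onset to last trial offset."""
        return self.end_s - self.onset_s

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets_s)


@dataclass(frozen=True)
class TaskProtocol:
    tr_seconds: float
    n_volumes: int
    blocks: tuple[Block, ...]
    rest_durations_s: tuple[float, ...]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_seconds

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def trial_table(self) -> pd.DataFrame:
        """One row per trial: block index, condition, onset, side."""
        rows = []
        for bi, b in enumerate(self.blocks):
            for onset, side in zip(b.trial_onsets_s, b.trial_sides):
                rows.append(
                    {
                        "block": bi,
                        "condition": b.condition,
                        "onset": onset,
                        "duration": b.trial_duration_s,
                        "side": side,
                    }
                )
        return pd.DataFrame(rows)

    def condition_counts(self) -> dict[str, int]:
        out = {"Anti": 0, "Pro": 0}
        for b in self.blocks:
            out[b.condition] += 1
        return out


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-trial behavioural outcomes, aligned with the protocol's trials.

    ``rt_ms`` holds NaN for omitted responses; ``response_side`` is "none"
    for omissions.  ``correct`` follows the task rule: the response side must
    match the condition's required side and the reaction time must fall in
    the 150-1500 ms validity window.
    """

    rt_ms: np.ndarray
    response_side: np.ndarray
    correct: np.ndarray

    def __post_init__(self):
        n = len(self.rt_ms)
        if len(self.response_side) != n or len(self.correct) != n:
            raise ValueError("behavioural arrays must have equal length")

    @property
    def n_trials(self) -> int:
        return len(self.rt_ms)

    @property
    def n_errors(self) -> int:
        return int((~self.correct).sum())


@dataclass(frozen=True)
class StimulusSet:
    """Boxcar stimulus functions on the microtime grid.

    ``driving_u`` and ``modulatory_u`` are (n_bins, n_inputs) {0,1} arrays.
    Inputs are deliberately *not* mean-centred, so the intrinsic coupling
    matrix A retains its interpretation as the task-independent baseline and
    all task effects are carried by the modulatory matrices.
    """

    dt_microtime: float
    driving_u: np.ndarray
    modulatory_u: np.ndarray
    driving_labels: tuple[str, ...]
    modulatory_labels: tuple[str, ...]

    @property
    def n_bins(self) -> int:
        return self.driving_u.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.dt_microtime


def required_side(condition: str, stimulus_side: str) -> str:
    """Correct response side: ipsilateral for Pro, contralateral for Anti."""
    if condition == "Pro":
        return stimulus_side
    return "L" if stimulus_side == "R" else "R"


def _constrained_block_order(
    n_blocks: int, max_consecutive: int, rng: np.random.Generator
) -> list[Condition]:
    """Pseudo-randomized order with balanced counts and a run-length cap."""
    for _ in range(1000):
        order = ["Anti"] * (n_blocks // 2) + ["Pro"] * (n_blocks // 2)
        rng.shuffle(order)
        run, ok = 1, True
        for a, b in zip(order, order[1:]):
            run = run + 1 if a == b else 1
            if run > max_consecutive:
                ok = False
                break
        if ok:
            return order  # type: ignore[return-value]
    raise ProtocolConfigError(
        "could not satisfy the consecutive-block constraint; "
        "increase max_consecutive_blocks"
    )


def generate_protocol(
    params: ProtocolParams | None = None, seed: int = 0
) -> TaskProtocol:
    """Generate a randomized SRC protocol.

    The block order is a constrained shuffle (balanced conditions, at most
    ``max_consecutive_blocks`` identical in a row), inter-onset intervals and
    rest durations are drawn uniformly from their configured ranges and
    stimulus sides are Bernoulli(0.5).  Reproducible for a fixed seed.
    """
    params = params or ProtocolParams()
    params.validate()
    rng = np.random.default_rng(seed)

    order = _constrained_block_order(
        params.n_blocks, params.max_consecutive_blocks, rng
    )
    blocks: list[Block] = []
    rests: list[float] = []
    t = float(rng.uniform(*params.rest_range_s))  # lead-in rest
    for bi, cond in enumerate(order):
        instruction_onset = t
        n_trials = int(rng.integers(params.trials_per_block[0],
                                    params.trials_per_block[1] + 1))
        onset = instruction_onset + params.instruction_duration_s + params.instruction_gap_s
        onsets = [onset]
        for _ in range(n_trials - 1):
            onset += float(rng.uniform(*params.iti_range_s))
            onsets.append(onset)
        sides = tuple("L" if rng.random() < 0.5 else "R" for _ in range(n_trials))
        blocks.append(
            Block(
                condition=cond,
                instruction_onset_s=instruction_onset,
                instruction_duration_s=params.instruction_duration_s,
                trial_onsets_s=tuple(onsets),
                trial_sides=sides,
                trial_duration_s=params.stimulus_duration_s,
            )
        )
        rest = float(rng.uniform(*params.rest_range_s))
        rests.append(rest)
        t = onsets[-1] + params.stimulus_duration_s + rest

    total = t + params.tail_s
    n_volumes = int(np.ceil(total / params.tr_seconds))
    proto = TaskProtocol(
        tr_seconds=params.tr_seconds,
        n_volumes=n_volumes,
        blocks=tuple(blocks),
        rest_durations_s=tuple(rests),
    )
    _check_protocol(proto, params)
    return proto


def _check_protocol(proto: TaskProtocol, params: ProtocolParams) -> None:
    last_end = proto.blocks[-1].end_s
    if last_end >= proto.duration_s:
        raise ProtocolConfigError("events extend past the scan duration")
    onsets = [o for b in proto.blocks for o in b.trial_onsets_s]
    if np.any(np.diff(onsets) <= 0):
        raise ProtocolConfigError("trial onsets are not strictly increasing")


@dataclass(frozen=True)
class RTParams:
    """Lognormal reaction-time model (ms).

    The incompatible condition carries a response-selection cost, so its
    location parameter is slower.  Values are generic SRC-plausible defaults.
    """

    mu_log_ms: dict[str, float] = field(
        default_factory=lambda: {"Anti": np.log(560.0), "Pro": np.log(450.0)}
    )
    sigma_log: float = 0.22
    #: among error trials: wrong side / out-of-window RT / omission
    error_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)


def simulate_behavior(
    protocol: TaskProtocol,
    error_rate: float = 0.03,
    rt_params: RTParams | None = None,
    seed: int = 0,
) -> BehavioralRecord:
    """Simulate button presses for every trial of the protocol.

    A fraction ``error_rate`` of trials is made erroneous, split between
    wrong-side responses, out-of-window reaction times and omissions per
    ``rt_params.error_mix``.  The default 3% matches the low error rate
    typical of this paradigm.
    """
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rt_params = rt_params or RTParams()
    mix = np.asarray(rt_params.error_mix, float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("error_mix must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)

    trials = protocol.trial_table()
    n = len(trials)
    rt = np.empty(n)
    resp = np.empty(n, dtype=object)
    for i, row in enumerate(trials.itertuples()):
        req = required_side(row.condition, row.side)
        rt[i] = float(
            np.exp(rng.normal(rt_params.mu_log_ms[row.condition],
                              rt_params.sigma_log))
        )
        resp[i] = req
        if rng.random() < error_rate:
            kind = rng.choice(3, p=mix)
            if kind == 0:  # wrong side, plausible RT
                resp[i] = "L" if req == "R" else "R"
            elif kind == 1:  # correct side, invalid RT
                if rng.random() < 0.5:
                    rt[i] = float(rng.uniform(50.0, RT_MIN_MS - 1e-6))
                else:
                    rt[i] = float(rng.uniform(RT_MAX_MS + 1e-6, 2500.0))
            else:  # omission
                resp[i] = "none"
                rt[i] = np.nan

    required = np.array(
        [required_side(r.condition, r.side) for r in trials.itertuples()],
        dtype=object,
    )
    with np.errstate(invalid="ignore"):
        in_window = (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    correct = (resp == required) & np.nan_to_num(in_window, nan=False)
    return BehavioralRecord(
        rt_ms=rt, response_side=resp.astype("U4"), correct=np.asarray(correct, bool)
    )


def default_dt_microtime(tr_seconds: float, bins_per_tr: int = 16) -> float:
    """Microtime resolution: TR/16 by default (0.2-s events span >=1 bin)."""
    return tr_seconds / bins_per_tr


def _boxcar(times: np.ndarray, onsets: Sequence[float],
            durations: Sequence[float]) -> np.ndarray:
    u = np.zeros(len(times))
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    for onset, dur in zip(onsets, durations):
        i0 = int(np.floor(onset / dt))
        i1 = max(i0 + 1, int(np.ceil((onset + dur) / dt)))
        u[i0:min(i1, len(times))] = 1.0
    return u


def _selected_events(
    protocol: TaskProtocol,
    behavior: BehavioralRecord | None,
    design_type: str,
    conditions: tuple[str, ...],
) -> tuple[list[float], list[float]]:
    """Onsets/durations of the events (or blocks) of the given conditions."""
    onsets: list[float] = []
    durs: list[float] = []
    if design_type == "Blocks":
        for b in protocol.blocks:
            if b.condition in conditions:
                onsets.append(b.onset_s)
                durs.append(b.duration_s)
        return onsets, durs
    trials = protocol.trial_table()
    keep = trials["condition"].isin(conditions).to_numpy()
    if design_type == "STrials":
        if behavior is None:
            raise ValueError("STrials stimulus functions require behaviour")
        keep &= behavior.correct
    for onset, dur in zip(trials["onset"][keep], trials["duration"][keep]):
        onsets.append(float(onset))
        durs.append(float(dur))
    return onsets, durs


def stimulus_functions(
    protocol: TaskProtocol,
    behavior: BehavioralRecord | None,
    design_type: str = "AllTrials",
    modulatory_contrast: str = "Anti",
    dt_microtime: float | None = None,
    driving_equals_modulatory: bool = False,
) -> StimulusSet:
    """Build the DCM driving and modulatory inputs for one processing choice.

    The driving input covers the stimuli of *both* conditions (every trial
    presents a visual stimulus), while the modulatory input contains only the
    events or blocks selected by ``modulatory_contrast`` (Anti alone, or the
    Anti+Pro union).  Event designs emit 0.2-s boxcars per (surviving) trial;
    the block design emits full-length block boxcars.  Set
    ``driving_equals_modulatory`` to use the modulatory selection as the
    driving input for sensitivity checks.
    """
    if design_type not in DESIGN_TYPES:
        raise ValueError(f"unknown design_type {design_type!r}")
    if modulatory_contrast not in MODULATORY_CONTRASTS:
        raise ValueError(f"unknown modulatory_contrast {modulatory_contrast!r}")
    dt = dt_microtime or default_dt_microtime(protocol.tr_seconds)
    n_bins = int(round(protocol.duration_s / dt))
    times = np.arange(n_bins) * dt

    mod_conditions = ("Anti",) if modulatory_contrast == "Anti" else ("Anti", "Pro")
    mod_on, mod_dur = _selected_events(protocol, behavior, design_type, mod_conditions)
    if driving_equals_modulatory:
        drv_on, drv_dur = mod_on, mod_dur
    else:
        drv_on, drv_dur = _selected_events(
            protocol, behavior, design_type, ("Anti", "Pro")
        )
    driving = _boxcar(times, drv_on, drv_dur)[:, None]
    modulatory = _boxcar(times, mod_on, mod_dur)[:, None]
    return StimulusSet(
        dt_microtime=dt,
        driving_u=driving,
        modulatory_u=modulatory,
        driving_labels=("visual",),
        modulatory_labels=(modulatory_contrast,),
    )


# ---------------------------------------------------------------------------
# BIDS-style events.tsv interchange

def to_events_tsv(
    protocol: TaskProtocol,
    behavior: BehavioralRecord | None = None,
    path=None,
) -> pd.DataFrame:
    """Export protocol (+ behaviour) as a BIDS-style events table.

    Columns: onset, duration, trial_type (e.g. "Anti_L"), response_time (s),
    correct.  Missing values are written as ".".
    """
    trials = protocol.trial_table()
    df = pd.DataFrame(
        {
            "onset": trials["onset"],
            "duration": trials["duration"],
            "trial_type": trials["condition"] + "_" + trials["side"],
        }
    )
    if behavior is not None:
        df["response_time"] = behavior.rt_ms / 1000.0
        df["correct"] = behavior.correct.astype(int)
    else:
        df["response_time"] = np.nan
        df["correct"] = np.nan
    if path is not None:
        out = df.copy()
        out["response_time"] = out["response_time"].round(4)
        out.to_csv(path, sep="\t", index=False, na_rep=".")
    return df


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv ("." treated as missing)."""
    return pd.read_csv(path, sep="\t", na_values=".")
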