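"""Mining two-input-one-output Boolean gates from spike responses.

For an ordered electrode triple (i, j, k) the network is stimulated three
times — inputs (x, y) = (0,1), (1,0) and (1,1), applied as impulses on
electrodes i and j — and the potential at output electrode k is recorded.
Spikes from the three runs are pooled and aligned with the 6-iteration
coincidence rule; within each aligned window the presence/absence triple
(z01, z10, z11) identifies the gate:

    (1,1,1) OR   (0,0,1) AND     (1,1,0) XOR
    (1,0,0) NOTAND (x̄·y)         (0,1,0) ANDNOT (x·ȳ)
    (0,1,1) SELECT_X             (1,0,1) SELECT_Y

The (0,0) stimulation is never run: the automaton has no spontaneous
excitation, so the response to the empty input is identically silent,
which is why gates requiring a True output on (0,0) (NOR, NAND, XNOR, …)
cannot occur and the label set has seven members plus NONE.

Sweeps over the excitation threshold and refractory delay tabulate gate
frequencies per parameter pair, reproducing the analysis used to pick the
machine's working point (theta=7, delta=20).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .automaton import AutomatonParams
from .electrodes import Electrode, PotentialTrace, StimulusPattern, run_experiment
from .matrix import ConductiveMatrix
from .spikes import COINCIDENCE_WINDOW, SpikeTrain, detect_spikes, group_coincident

__all__ = [
    "Gate",
    "GateRecord",
    "classify_gate",
    "mine_gates",
    "sweep_params",
    "aggregate_gate_counts",
]


class Gate(str, Enum):
    OR = "OR"
    AND = "AND"
    XOR = "XOR"
    NOTAND = "NOTAND"  # x̄·y: responds only to (0,1)
    ANDNOT = "ANDNOT"  # x·ȳ: responds only to (1,0)
    SELECT_X = "SELECT_X"  # responds whenever x is True
    SELECT_Y = "SELECT_Y"  # responds whenever y is True
    NONE = "NONE"


_TRIPLE_TO_GATE: dict[tuple[bool, bool, bool], Gate] = {
    (False, False, False): Gate.NONE,
    (False, False, True): Gate.AND,
    (False, True, False): Gate.ANDNOT,
    (False, True, True): Gate.SELECT_X,
    (True, False, False): Gate.NOTAND,
    (True, False, True): Gate.SELECT_Y,
    (True, True, False): Gate.XOR,
    (True, True, True): Gate.OR,
}


def classify_gate(z01: bool, z10: bool, z11: bool) -> Gate:
    """Map an output-presence triple for inputs (0,1), (1,0), (1,1) to a gate label.

    Total on {0,1}^3; the all-false triple maps to NONE.
    """
    return _TRIPLE_TO_GATE[(bool(z01), bool(z10), bool(z11))]


@dataclass(frozen=True)
class GateRecord:
    """One mined gate: inputs (i, j), output k, coincidence-window time, label."""

    input_x: str
    input_y: str
    output: str
    time: int
    label: Gate


_RUN_KEYS = ("01", "10", "11")


def mine_gates(
    trace01: PotentialTrace,
    trace10: PotentialTrace,
    trace11: PotentialTrace,
    output: int | str,
    input_x: str = "x",
    input_y: str = "y",
    amp_threshold: float = 1.0,
    window: int = COINCIDENCE_WINDOW,
) -> list[GateRecord]:
    """Extract gate records for one output electrode from the three runs.

    The three traces must come from runs differing only in the input
    pattern.  Spikes on the output electrode are pooled across runs,
    coincidence-grouped, and each group labelled by :func:`classify_gate`.
    """
    traces = (trace01, trace10, trace11)
    if len({t.T for t in traces}) != 1:
        raise ValueError("the three traces must have equal length")
    trains = []
    for key, trace in zip(_RUN_KEYS, traces):
        times = detect_spikes(trace.column(output), amp_threshold, window)
        trains.append(SpikeTrain(key, times))
    label = (
        trace01.labels[output] if isinstance(output, int) else str(output)
    )
    records = []
    for group in group_coincident(trains, window):
        present = group.electrodes()
        gate = classify_gate("01" in present, "10" in present, "11" in present)
        if gate is Gate.NONE:
            continue
        records.append(GateRecord(input_x, input_y, label, group.time, gate))
    return records


def _input_pairs(
    electrodes: Sequence[Electrode],
    wiring: str,
    input_pair: tuple[str, str] | None,
) -> list[tuple[Electrode, Electrode]]:
    by_label = {e.label: e for e in electrodes}
    if wiring == "fixed_inputs":
        if input_pair is None:
            pair = (electrodes[0], electrodes[-1])
        else:
            pair = (by_label[input_pair[0]], by_label[input_pair[1]])
        return [pair]
    if wiring == "all_triples":
        return [(a, b) for a in electrodes for b in electrodes if a.label != b.label]
    raise ValueError("wiring must be 'fixed_inputs' or 'all_triples'")


def sweep_params(
    matrix: ConductiveMatrix,
    electrodes: Sequence[Electrode],
    theta_list: Sequence[int],
    delta_list: Sequence[int],
    steps: int,
    wiring: str = "all_triples",
    input_pair: tuple[str, str] | None = None,
    radius: int = 3,
    amp_threshold: float = 1.0,
    window: int = COINCIDENCE_WINDOW,
    stim_steps: int = 1,
) -> pd.DataFrame:
    """Mine gates for every (theta, delta) pair and admissible electrode triple.

    ``wiring='fixed_inputs'`` uses one designated input pair (default: the
    first and last electrode) with every other electrode as output;
    ``'all_triples'`` enumerates every ordered pair (i, j) with every third
    electrode as output.  Physical runs are cached by the set of stimulated
    electrodes, so each distinct stimulus is simulated once per parameter
    pair.  Returns a tidy frame with columns
    theta, delta, i, j, k, t, label.  Deterministic.
    """
    if not theta_list or not delta_list:
        raise ValueError("theta_list and delta_list must be non-empty")
    pairs = _input_pairs(electrodes, wiring, input_pair)
    rows: list[dict] = []
    for theta in theta_list:
        for delta in delta_list:
            params = AutomatonParams(theta=theta, delta=delta, radius=radius)
            cache: dict[frozenset[str], PotentialTrace] = {}

            def run_for(stimulated: Sequence[Electrode]) -> PotentialTrace:
                key = frozenset(e.label for e in stimulated)
                if key not in cache:
                    bits = tuple(
                        1 if e.label in key else 0 for e in electrodes
                    )
                    cache[key] = run_experiment(
                        matrix,
                        electrodes,
                        StimulusPattern(bits),
                        params,
                        steps,
                        stim_steps=stim_steps,
                    )
                return cache[key]

            for ei, ej in pairs:
                t01 = run_for([ej])
                t10 = run_for([ei])
                t11 = run_for([ei, ej])
                for ek in electrodes:
                    if ek.label in (ei.label, ej.label):
                        continue
                    for rec in mine_gates(
                        t01,
                        t10,
                        t11,
                        ek.label,
                        input_x=ei.label,
                        input_y=ej.label,
                        amp_threshold=amp_threshold,
                        window=window,
                    ):
                        rows.append(
                            {
                                "theta": theta,
                                "delta": delta,
                                "i": rec.input_x,
                                "j": rec.input_y,
                                "k": rec.output,
                                "t": rec.time,
                                "label": rec.label.value,
                            }
                        )
    return pd.DataFrame(
        rows, columns=["theta", "delta", "i", "j", "k", "t", "label"]
    )


def aggregate_gate_counts(
    records: pd.DataFrame, n_outputs: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a tidy gate table into totals and per-electrode means.

    Returns ``(totals, means)``: total gate counts per
    (theta, delta, label), and the average count per output electrode
    (totals divided by the number of distinct output electrodes observed,
    or by ``n_outputs`` when given — electrodes realizing no gates then
    still enter the denominator).
    """
    totals = (
        records.groupby(["theta", "delta", "label"]).size().rename("count").reset_index()
    )
    denom = n_outputs if n_outputs is not None else max(records["k"].nunique(), 1)
    means = totals.assign(mean_per_electrode=totals["count"] / denom).drop(
        columns="count"
    )
    return totals, means
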