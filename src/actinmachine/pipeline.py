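"""End-to-end experiment pipeline: network → traces → spikes → FSM → DNF.

Orchestrates a full droplet-machine characterization: build or load a
conductive matrix, place/load electrodes, stimulate with every input
string in the configured set, detect spikes, assemble state sequences,
build the global and pruned transition graphs, tabulate richness, and
reconstruct + minimize the per-electrode Boolean functions at the richest
transition step.  All outputs are plain-text artefacts (CSV/JSON/DOT/
GraphML, TIFF for the matrix) written with a manifest of SHA-256
checksums; a rerun with the same configuration reproduces the checksums
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import networkx as nx
import numpy as np

from . import __version__
from .automaton import AutomatonParams
from .boolmin import dnf_to_string, minimize_dnf, table_from_g
from .electrodes import (
    Electrode,
    StimulusPattern,
    builtin_electrodes,
    read_electrodes,
    run_experiment,
    write_electrodes,
)
from .fsm import (
    StateSequence,
    g_of_t,
    prune,
    richness,
    states_from_spikes,
    to_dot,
    weighted_global_graph,
)
from .matrix import ConductiveMatrix, SynthSpec, load_matrix, save_matrix, synth_network
from .spikes import COINCIDENCE_WINDOW, spike_trains

__all__ = ["ExperimentConfig", "auto_electrodes", "run_pipeline"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one machine characterization run."""

    matrix: str | SynthSpec  # path to a saved matrix, or a synthesis spec
    electrodes: str = "auto"  # path, builtin name ("E1"/"E2"), or "auto"
    k: int = 6
    theta: int = 7
    delta: int = 20
    radius: int = 3
    radius_e: float = 4.0
    steps: int = 1000
    window: int = COINCIDENCE_WINDOW
    amp_threshold: float = 1.0
    stim_steps: int = 1
    inputs: tuple[int, ...] | None = None  # default: all non-zero strings 1..2^k-1
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        raw = json.loads(Path(path).read_text())
        if isinstance(raw.get("matrix"), dict):
            raw["matrix"] = SynthSpec(**{
                k: tuple(v) if k in ("extent", "start") and v is not None else v
                for k, v in raw["matrix"].items()
            })
        if raw.get("inputs") is not None:
            raw["inputs"] = tuple(raw["inputs"])
        return cls(**raw)

    def params(self) -> AutomatonParams:
        return AutomatonParams(self.theta, self.delta, self.radius)

    def input_set(self) -> tuple[int, ...]:
        # input 0 is provably quiescent (no spontaneous excitation), skip it
        return self.inputs if self.inputs is not None else tuple(range(1, 2**self.k))


def auto_electrodes(
    matrix: ConductiveMatrix, k: int, radius_e: float = 4.0
) -> list[Electrode]:
    """Place k electrodes on a synthetic network, spread far apart.

    Uses the generator's node points (farthest-point sampling starting from
    the point nearest the droplet centre), so every electrode sits on
    conductive material.  Deterministic.
    """
    points = matrix.meta.get("points")
    if points is None:
        raise ValueError(
            "auto electrode placement needs a Delaunay-synthesized matrix "
            "(matrix.meta['points'])"
        )
    points = np.asarray(points)
    if len(points) < k:
        raise ValueError(f"need at least {k} network points, have {len(points)}")
    centre = np.array(matrix.shape, dtype=float) / 2
    chosen = [int(np.argmin(((points - centre) ** 2).sum(axis=1)))]
    while len(chosen) < k:
        d2 = np.min(
            ((points[:, None, :] - points[chosen][None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        d2[chosen] = -1
        chosen.append(int(np.argmax(d2)))
    out = []
    for n, idx in enumerate(chosen):
        i, j, z = (int(round(c)) for c in points[idx])
        out.append(Electrode(f"e{n}", i, j, z, radius_e))
    return out


def _resolve_matrix(config: ExperimentConfig) -> ConductiveMatrix:
    if isinstance(config.matrix, SynthSpec):
        return synth_network(config.matrix)
    return load_matrix(config.matrix)


def _resolve_electrodes(
    config: ExperimentConfig, matrix: ConductiveMatrix
) -> list[Electrode]:
    if config.electrodes == "auto":
        return auto_electrodes(matrix, config.k, config.radius_e)
    if config.electrodes.upper() in {"E1", "E2"}:
        electrodes = builtin_electrodes(config.electrodes)
    else:
        electrodes = read_electrodes(config.electrodes)
    return electrodes[: config.k]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full characterization and write all artefacts under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)

    matrix = _resolve_matrix(config)
    electrodes = _resolve_electrodes(config, matrix)
    if len(electrodes) != config.k:
        raise ValueError(
            f"configuration selects {len(electrodes)} electrodes but k={config.k}"
        )
    params = config.params()

    save_matrix(matrix, out / "matrix.tif")
    write_electrodes(electrodes, out / "electrodes.csv")

    sequences: list[StateSequence] = []
    all_spikes: dict[int, dict[str, list[int]]] = {}
    for decimal in config.input_set():
        pattern = StimulusPattern.from_decimal(decimal, config.k)
        trace = run_experiment(
            matrix, electrodes, pattern, params, config.steps, config.stim_steps
        )
        trace.to_csv(out / "traces" / f"input_{decimal:02d}.csv")
        trains = spike_trains(trace, config.amp_threshold, config.window)
        all_spikes[decimal] = {tr.electrode: list(tr.times) for tr in trains}
        sequences.append(
            states_from_spikes(trains, config.k, config.window, input=decimal)
        )

    (out / "spikes.json").write_text(
        json.dumps(all_spikes, indent=2, sort_keys=True)
    )
    (out / "sequences.json").write_text(
        json.dumps(
            {seq.input: list(seq.events) for seq in sequences},
            indent=2,
            sort_keys=True,
        )
    )

    G = weighted_global_graph(sequences)
    nx.write_graphml(G, out / "graph_global.graphml")
    (out / "graph_global.dot").write_text(to_dot(G))
    pruned = prune(G)
    nx.write_graphml(pruned.graph, out / "graph_pruned.graphml")
    (out / "graph_pruned.dot").write_text(to_dot(pruned.graph, pruned.node_class))
    with (out / "node_classes.csv").open("w") as fh:
        fh.write("state,class,indegree\n")
        for n in sorted(pruned.graph.nodes):
            fh.write(f"{n},{pruned.node_class[n]},{pruned.indegree[n]}\n")

    rich = richness(sequences)
    table = rich.table.copy()
    table["states"] = table["states"].map(lambda s: " ".join(map(str, s)))
    table.to_csv(out / "richness.csv", index=False)
    with (out / "states_per_input.csv").open("w") as fh:
        fh.write("input,distinct_states\n")
        for key in sorted(rich.per_input):
            fh.write(f"{key},{rich.per_input[key]}\n")
    with (out / "inputs_per_state.csv").open("w") as fh:
        fh.write("state,n_inputs\n")
        for key in sorted(rich.per_state):
            fh.write(f"{key},{rich.per_state[key]}\n")

    # reconstruct Boolean functions at the richest transition step
    dnf_report: dict[str, Any] = {"t": None, "functions": {}}
    if len(rich.table):
        t_star = int(rich.table.loc[rich.table["mu"].idxmax(), "t"])
        g = g_of_t(sequences, t_star)
        (out / "g_t.json").write_text(
            json.dumps({"t": t_star, "g": g}, indent=2, sort_keys=True)
        )
        dnf_report["t"] = t_star
        lines = []
        for e in range(config.k):
            dnf = minimize_dnf(table_from_g(g, e, config.k))
            text = dnf_to_string(dnf)
            dnf_report["functions"][f"f{e}"] = {
                "dnf": text,
                "terms": [list(map(list, term)) for term in dnf.terms],
            }
            lines.append(f"f{e}(x0..x{config.k - 1}) = {text}")
        (out / "dnf.txt").write_text("\n".join(lines) + "\n")
        (out / "dnf.json").write_text(json.dumps(dnf_report, indent=2, sort_keys=True))

    cfg = asdict(config)
    if isinstance(config.matrix, SynthSpec):
        cfg["matrix"] = asdict(config.matrix)
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "n_conductive_voxels": matrix.n_conductive,
        "n_inputs": len(config.input_set()),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
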