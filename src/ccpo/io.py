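"""Design-file I/O, run configuration and fixture generation.

File roles are fixed to avoid dialect drift: YAML for human-edited
inputs (graphs, module libraries, designs), JSON for machine reports,
CSV for curve data and FASTA for sequences.  Every report embeds the
run configuration (including seeds) and the package version so that
outputs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

import ccpo
from ccpo.assembly import (
    Arrangement,
    ModuleLibrary,
    SlotAssignment,
    sn_library,
    dump_library,
)
from ccpo.errors import SchemaError
from ccpo.topology import (
    PolyhedronGraph,
    TopologyClass,
    circular_permutations,
    enumerate_double_traces,
    group_topologies,
    tetrahedron_topologies,
)
from ccpo import biophys


@dataclass
class RunConfig:
    """Configuration recorded into every machine report."""

    command: str
    seed: Optional[int] = None
    steric_mode: str = "strict"
    folded_mode: str = "structural"
    node_cap: int = 10**6
    verbosity: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = ccpo.__version__
        return d


def write_report(path, payload: dict, config: Optional[RunConfig] = None) -> None:
    out = dict(payload)
    if config is not None:
        out["config"] = config.to_dict()
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_graph(source) -> PolyhedronGraph:
    """Load a polyhedron graph from a named built-in or a YAML/JSON file
    with ``vertices:`` and ``edges:`` lists."""
    if isinstance(source, str) and not Path(source).exists():
        return PolyhedronGraph.named(source)
    with open(source) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "vertices" not in data or "edges" not in data:
        raise SchemaError("graph file needs 'vertices' and 'edges' lists")
    return PolyhedronGraph(data["vertices"], [tuple(e) for e in data["edges"]])


def topologies_for_graph(graph: PolyhedronGraph, proper=True, strong=True):
    if graph == PolyhedronGraph.named("tetrahedron"):
        if proper and strong:
            return list(tetrahedron_topologies())
    traces = enumerate_double_traces(graph, require_proper=proper, require_strong=strong)
    return group_topologies(traces)


# ---------------------------------------------------------------------------
# design files


def dump_design(arrangement: Arrangement, path, graph_name: str = "tetrahedron") -> None:
    doc = {
        "graph": graph_name,
        "topology": arrangement.permutation.topology_label,
        "permutation": arrangement.permutation.start_index,
        "slots": [f"{s.module}@{s.copy}" for s in arrangement.slots],
        "linker": arrangement.linker,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_design(source, library: ModuleLibrary) -> Arrangement:
    """Load an arrangement file (topology, permutation, slots, linker).

    Slot entries are ``NAME@copy``; copy indices are recomputed in chain
    order and validated.  Every on-target pair implied by the topology's
    permutation must be complementary with matching geometry.
    """
    with open(source) as fh:
        doc = yaml.safe_load(fh)
    for key in ("topology", "permutation", "slots"):
        if key not in doc:
            raise SchemaError(f"design file missing {key!r}")
    graph = load_graph(doc.get("graph", "tetrahedron"))
    classes = topologies_for_graph(graph)
    by_label = {c.label: c for c in classes}
    if doc["topology"] not in by_label:
        raise SchemaError(
            f"unknown topology {doc['topology']!r}; available: {sorted(by_label)}"
        )
    perms = circular_permutations(by_label[doc["topology"]])
    start = int(doc["permutation"])
    if not 1 <= start <= len(perms):
        raise SchemaError(f"permutation index {start} out of 1..{len(perms)}")
    perm = perms[start - 1]
    raw_slots = doc["slots"]
    if len(raw_slots) != perm.n_slots:
        raise SchemaError(
            f"design has {len(raw_slots)} slots, topology requires {perm.n_slots}"
        )
    counts: dict = {}
    slots = []
    for entry in raw_slots:
        name = entry.split("@")[0] if isinstance(entry, str) else entry["module"]
        if name not in library:
            raise SchemaError(f"unknown module name {name!r} in design")
        counts[name] = counts.get(name, 0) + 1
        slots.append(SlotAssignment(module=name, copy=counts[name]))
    on_target = []
    for i, meta in enumerate(perm.slots):
        j = meta.partner_slot
        if i > j:
            continue
        a, b = slots[i].module, slots[j].module
        if not library.complementary(a, b):
            raise SchemaError(
                f"slots {i} and {j} share edge {meta.edge} but {a!r}/{b!r} "
                "are not a cognate pair"
            )
        if library[a].geometry != meta.orientation:
            raise SchemaError(
                f"{library[a].geometry} pair {a!r}:{b!r} on {meta.orientation} "
                f"edge {meta.edge}"
            )
        on_target.append((i, j))
    return Arrangement(
        permutation=perm,
        slots=tuple(slots),
        linker=doc.get("linker", "GSGPG"),
        on_target=tuple(sorted(on_target)),
    )


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("library", "design", "kinetics", "melt", "contacts", "denaturation")


def make_fixtures(kind: str, outdir, seed: int = 0, repeats: str = "2CC") -> list[Path]:
    """Generate example input files: the SN-style module library, designs
    with 0-3 duplicated pairs, and synthetic curves at the reference
    study conditions.  Deterministic for a given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib = sn_library()
    written: list[Path] = []

    if kind == "library":
        path = outdir / "sn_library.yaml"
        dump_library(lib, path)
        written.append(path)
    elif kind == "design":
        multisets = {
            "0CC": "P3SN:P4SN, P5SN:P6SN, P7SN:P8SN, GCNSN, APHSN, BCRSN",
            "2CC": "P3SN:P4SN, P5SN:P6SN x2, P7SN:P8SN, APHSN, BCRSN",
            "22CC": "P3SN:P4SN x2, P5SN:P6SN x2, APHSN, BCRSN",
            "222CC": "P3SN:P4SN x2, P5SN:P6SN x2, APHSN x2",
            "3CC": "P5SN:P6SN x3, P3SN:P4SN, APHSN, BCRSN",
        }
        if repeats not in multisets:
            raise SchemaError(f"unknown repeat pattern {repeats!r}")
        from ccpo.pathway import design_search

        report = design_search(
            list(tetrahedron_topologies())[:1], multisets[repeats], lib
        )
        path = outdir / f"design_{repeats}.yaml"
        dump_design(report.best["arrangement"], path)
        written.append(path)
    elif kind == "kinetics":
        p = biophys.REFERENCE_CONDITIONS["kinetics"]
        t = np.arange(0.0, p["t_max_s"], p["dt_s"])
        trace = biophys.simulate_kinetic_trace(
            p["k"], p["a"], p["b"], p["c"], t,
            noise_sd=biophys.REFERENCE_CONDITIONS["noise_fraction"] * p["a"],
            seed=seed,
            n_replicates=biophys.REFERENCE_CONDITIONS["n_replicates"],
        )
        path = outdir / "kinetics.csv"
        trace.to_csv(path)
        written.append(path)
    elif kind == "denaturation":
        p = biophys.REFERENCE_CONDITIONS["chem_denaturation"]
        g = np.arange(0.0, p["conc_max_M"] + 1e-9, p["dconc_M"])
        curve = biophys.simulate_chem_denaturation(
            p["dG_fold"], p["m"], p["B"], p["C"], p["D"], g,
            noise_sd=biophys.REFERENCE_CONDITIONS["noise_fraction"] * p["C"],
            seed=seed,
            n_replicates=biophys.REFERENCE_CONDITIONS["n_replicates"],
        )
        path = outdir / "denaturation.csv"
        curve.to_csv(path)
        written.append(path)
    elif kind == "melt":
        temp_C = np.arange(0.0, 90.5, 1.0)
        for model in ("two-state", "three-state"):
            key = "melt_two_state" if model == "two-state" else "melt_three_state"
            params = biophys.REFERENCE_CONDITIONS[key]
            clean = biophys.simulate_thermal_curve(params, temp_C, model)
            span = float(np.ptp(clean.mre222))
            curve = biophys.simulate_thermal_curve(
                params, temp_C, model,
                noise_sd=biophys.REFERENCE_CONDITIONS["noise_fraction"] * span,
                seed=seed,
                n_replicates=biophys.REFERENCE_CONDITIONS["n_replicates"],
            )
            path = outdir / f"melt_{model.replace('-', '_')}.csv"
            curve.to_csv(path)
            written.append(path)
    elif kind == "contacts":
        times = {"APH": 0.5, "GCN": 1.5, "P3:P4": 2.0, "BCR": 3.0,
                 "P7:P8": 4.0, "P5:P6": 5.0}
        traces = biophys.simulate_contact_traces(
            times, np.linspace(0.0, 8.0, 400), noise_sd=0.05, seed=seed
        )
        import pandas as pd

        path = outdir / "contacts.csv"
        pd.DataFrame({"time": traces.time, **traces.fractions}).to_csv(
            path, index=False
        )
        written.append(path)
    else:
        raise SchemaError(f"unknown fixture kind {kind!r}; one of {FIXTURE_KINDS}")
    return written
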