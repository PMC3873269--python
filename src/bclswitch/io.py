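"""Readers and writers for the analysis artifacts.

Matrices and curves are RFC-4180 CSV, reports are JSON.  Every write
returns a manifest (seed, package version, configuration hash) so a run is
reproducible byte for byte; no timestamps are embedded.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from . import __version__
from .montecarlo import MonteCarloResult
from .network import RateParams, ReactionNetwork
from .response import BistabilityReport, ResponseCurve

__all__ = [
    "config_hash",
    "manifest",
    "write_response_curves",
    "read_response_curves",
    "write_montecarlo",
    "read_stimuli",
    "write_json",
    "export_sbml",
]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def manifest(config: dict, seed: int | None = None) -> dict:
    return {
        "package": "bclswitch",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_response_curves(up: ResponseCurve, down: ResponseCurve, path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "stimulus": up.grid,
            "up_response": up.responses,
            "down_response": down.responses,
            "up_converged": up.converged.astype(int),
            "down_converged": down.converged.astype(int),
        }
    )
    df.to_csv(path, index=False, lineterminator="\r\n")
    return df


def read_response_curves(path, stimulus_param=("kp",)) -> tuple[ResponseCurve, ResponseCurve]:
    df = pd.read_csv(path)
    up = ResponseCurve(
        stimulus_param=tuple(stimulus_param),
        grid=df["stimulus"].to_numpy(),
        responses=df["up_response"].to_numpy(),
        direction="up",
        converged=df["up_converged"].to_numpy(dtype=bool),
    )
    down = ResponseCurve(
        stimulus_param=tuple(stimulus_param),
        grid=df["stimulus"].to_numpy(),
        responses=df["down_response"].to_numpy(),
        direction="down",
        converged=df["down_converged"].to_numpy(dtype=bool),
    )
    return up, down


def bistability_to_dict(report: BistabilityReport) -> dict:
    return {
        "bistable": bool(report.bistable),
        "lower_threshold": report.lower_threshold,
        "upper_threshold": report.upper_threshold,
        "width_decades": report.width_decades,
        "max_branch_gap": float(report.max_branch_gap),
        "gap_factor": float(report.gap_factor),
    }


def write_montecarlo(result: MonteCarloResult, prefix) -> dict:
    """Stimuli CSV, responses CSV and a JSON summary under a path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stimuli_path = prefix.with_suffix(".stimuli.csv")
    responses_path = prefix.with_suffix(".responses.csv")
    summary_path = prefix.with_suffix(".summary.json")
    result.stimuli.to_frame().to_csv(stimuli_path, index=False, lineterminator="\r\n")
    pd.DataFrame(
        {
            "response": result.responses,
            "label": result.labels,
            "converged": result.converged.astype(int),
        }
    ).to_csv(responses_path, index=False, lineterminator="\r\n")
    write_json(result.summary(), summary_path)
    return {
        "stimuli": str(stimuli_path),
        "responses": str(responses_path),
        "summary": str(summary_path),
    }


def read_stimuli(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# SBML Level 3 export (flat model, expanded degradation)
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def export_sbml(net: ReactionNetwork, params: RateParams, path) -> None:
    """Write the expanded reaction system as SBML L3 for cross-validation."""
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", attrib={"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", attrib={"id": "bclswitch"})
    lc = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(
        lc,
        f"{{{_SBML_NS}}}compartment",
        attrib={"id": "cell", "constant": "true", "size": "1"},
    )

    def sid(name: str) -> str:
        return name.replace("~", "_")

    ls = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in net.species:
        ET.SubElement(
            ls,
            f"{{{_SBML_NS}}}species",
            attrib={
                "id": sid(s.name),
                "compartment": "cell",
                "initialAmount": "0",
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    lp = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    for name, value in sorted(params.values.items()):
        ET.SubElement(
            lp,
            f"{{{_SBML_NS}}}parameter",
            attrib={"id": name, "value": repr(float(value)), "constant": "true"},
        )

    lr = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")

    def add_reaction(rid, reactants, products, rate_name, modifiers=()):
        r = ET.SubElement(
            lr, f"{{{_SBML_NS}}}reaction", attrib={"id": rid, "reversible": "false"}
        )
        if reactants:
            lor = ET.SubElement(r, f"{{{_SBML_NS}}}listOfReactants")
            for s in reactants:
                ET.SubElement(
                    lor,
                    f"{{{_SBML_NS}}}speciesReference",
                    attrib={"species": sid(s), "stoichiometry": "1", "constant": "true"},
                )
        if products:
            lop = ET.SubElement(r, f"{{{_SBML_NS}}}listOfProducts")
            for s in products:
                ET.SubElement(
                    lop,
                    f"{{{_SBML_NS}}}speciesReference",
                    attrib={"species": sid(s), "stoichiometry": "1", "constant": "true"},
                )
        kl = ET.SubElement(r, f"{{{_SBML_NS}}}kineticLaw")
        math = ET.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math"
        )
        terms = [rate_name] + [sid(s) for s in reactants]
        if len(terms) == 1:
            ci = ET.SubElement(math, "{http://www.w3.org/1998/Math/MathML}ci")
            ci.text = terms[0]
        else:
            apply_el = ET.SubElement(math, "{http://www.w3.org/1998/Math/MathML}apply")
            ET.SubElement(apply_el, "{http://www.w3.org/1998/Math/MathML}times")
            for t in terms:
                ci = ET.SubElement(apply_el, "{http://www.w3.org/1998/Math/MathML}ci")
                ci.text = t

    k = 0
    for rule in net.reactions:
        if rule.kind == "degradation":
            for s in net.species:
                k += 1
                add_reaction(f"r{k}_deg_{sid(s.name)}", [s.name], [], rule.forward_rate)
            continue
        k += 1
        add_reaction(f"r{k}_f", list(rule.reactants), list(rule.products), rule.forward_rate)
        if rule.is_reversible:
            add_reaction(
                f"r{k}_b", list(rule.products), list(rule.reactants), rule.reverse_rate
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")
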