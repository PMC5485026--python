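"""Report writers: JSON and plain-text renderings of fit results."""

from __future__ import annotations

import json
import math
from typing import Any

import numpy as np

from . import __version__
from .binomial import BinomialFit
from .bootstrap import BootstrapResult
from .ph import PHFit
from .simulate import ScenarioSummary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def as_dict(result: Any, seed: int | None = None) -> dict:
    """Normalise any fit/summary object into a plain dictionary."""
    doc: dict = {"software": f"crossfx {__version__}"}
    if seed is not None:
        doc["seed"] = seed
    if result is None:
        return doc
    if isinstance(result, BinomialFit):
        doc.update(result.summary())
        p = result.params
        doc["estimates_natural"] = {
            "gamma": p.gamma0 if p.common_gamma else None,
            "gamma0": p.gamma0, "gamma1": p.gamma1,
            "gamma1_star": p.gamma1_star, "omega": p.omega0,
            "pi": p.pi, "pi11": result.pi11}
    elif isinstance(result, PHFit):
        doc.update(result.summary())
    elif isinstance(result, ScenarioSummary):
        doc["scenario"] = {
            "n_per_arm": result.scenario.n_per_arm,
            "pi": result.scenario.pi,
            "exp_gamma": result.scenario.exp_gamma,
            "exp_omega": result.scenario.exp_omega,
            "censoring": result.scenario.censoring}
        doc["summary"] = result.table().to_dict(orient="records")
        doc["n_failed"] = result.n_failed
        doc["unreliable"] = result.unreliable
    elif isinstance(result, BootstrapResult):
        doc.update({"B": result.B, "seed": result.seed,
                    "failures": result.failures, "flagged": result.flagged,
                    "variance": {"gamma": result.variance("gamma"),
                                 "omega": result.variance("omega")}})
    elif isinstance(result, dict):
        doc.update(result)
    return _jsonable(doc)


def report(result: Any, format: str = "json", seed: int | None = None) -> str:
    """Render a fit or summary as a JSON document or a readable table."""
    doc = as_dict(result, seed)
    if format == "json":
        return json.dumps(doc, indent=1)
    lines = []
    for key, val in doc.items():
        if isinstance(val, dict):
            lines.append(f"{key}:")
            for k, v in val.items():
                if isinstance(v, float):
                    lines.append(f"  {k:<14} {v:.6g}")
                else:
                    lines.append(f"  {k:<14} {v}")
        elif isinstance(val, list):
            lines.append(f"{key}:")
            for item in val:
                lines.append(f"  {item}")
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines)
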