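"""Versioned JSON text serialization for structures, parameters and
trained-classifier archives.  Round trips are exact (floats via repr)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .learning import Classifier
from .models import LambdaParameters, MixtureParameters
from .priors import HyperParameters
from .structures import ModelStructure

FORMAT_VERSION = 1

__all__ = [
    "structure_to_dict", "structure_from_dict",
    "params_to_dict", "params_from_dict",
    "save_classifier", "load_classifier",
]


def structure_to_dict(st: ModelStructure) -> dict:
    return {
        "kind": st.kind, "L": st.L, "S": st.S,
        "parents": [list(p) for p in st.parents] if st.parents is not None else None,
        "pairs": [list(p) for p in st.pairs] if st.pairs is not None else None,
        "include_singletons": st.include_singletons,
        "components": st.components,
    }


def structure_from_dict(d: dict) -> ModelStructure:
    return ModelStructure(
        kind=d["kind"], L=d["L"], S=d["S"],
        parents=tuple(tuple(p) for p in d["parents"]) if d.get("parents") is not None else None,
        pairs=tuple(tuple(p) for p in d["pairs"]) if d.get("pairs") is not None else None,
        include_singletons=d.get("include_singletons", False),
        components=d.get("components", 1),
    )


def _lambda_to_dict(lam: LambdaParameters) -> dict:
    return {
        "type": "lambda",
        "structures": [structure_to_dict(st) for st in lam.structures],
        "class_values": lam.class_values.tolist(),
        "values": [v.tolist() for v in lam.values],
    }


def _lambda_from_dict(d: dict) -> LambdaParameters:
    structures = tuple(structure_from_dict(s) for s in d["structures"])
    return LambdaParameters(structures, np.asarray(d["class_values"]),
                            [np.asarray(v) for v in d["values"]])


def params_to_dict(params: LambdaParameters | MixtureParameters) -> dict:
    if isinstance(params, LambdaParameters):
        return _lambda_to_dict(params)
    return {
        "type": "mixture",
        "components": [_lambda_to_dict(c) for c in params.components],
        "weight_logits": params.weight_logits.tolist(),
        "class_logits": params.class_logits.tolist(),
    }


def params_from_dict(d: dict) -> LambdaParameters | MixtureParameters:
    if d["type"] == "lambda":
        return _lambda_from_dict(d)
    if d["type"] == "mixture":
        return MixtureParameters(
            components=[_lambda_from_dict(c) for c in d["components"]],
            weight_logits=np.asarray(d["weight_logits"]),
            class_logits=np.asarray(d["class_logits"]),
        )
    raise ValueError(f"unknown parameter type {d.get('type')!r}")


def save_classifier(clf: Classifier, path: str | Path) -> None:
    """Write a classifier archive: structures, hyper-parameters audit table,
    fitted parameters and the training log."""
    doc = {
        "format_version": FORMAT_VERSION,
        "principle": clf.principle,
        "structures": [structure_to_dict(st) for st in clf.structures],
        "hyper": {
            "ess": clf.hyper.ess.tolist(),
            "alpha": [a.tolist() for a in clf.hyper.alpha],
        },
        "params": params_to_dict(clf.params),
        "training_log": clf.training_log,
        "converged": clf.converged,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_classifier(path: str | Path) -> Classifier:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"classifier archive {path} is corrupt: {exc}") from None
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported archive version {doc.get('format_version')!r}")
    structures = tuple(structure_from_dict(s) for s in doc["structures"])
    hyper = HyperParameters(structures, np.asarray(doc["hyper"]["ess"]),
                            [np.asarray(a) for a in doc["hyper"]["alpha"]])
    return Classifier(
        structures=structures,
        params=params_from_dict(doc["params"]),
        hyper=hyper,
        principle=doc["principle"],
        training_log=doc["training_log"],
        converged=doc["converged"],
    )
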