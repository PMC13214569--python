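"""Default configuration: tissue classes, bias classes, recipes, CLI defaults."""
from __future__ import annotations

from importlib import resources as importlib_resources
from pathlib import Path

import yaml

from .atlas import LabelGrouping
from .bias import DEFAULT_BIAS_CLASSES
from .synthesis import IntensityRecipe

#: the 16 default tissue classes used for intensity modeling
DEFAULT_TISSUE_CLASSES = (
    "cerebral white matter", "cerebral gray matter", "cerebellar white matter",
    "cerebellar cortex", "caudate", "putamen", "pallidum", "lateral thalamus",
    "medial thalamus", "red nucleus", "compact brainstem white matter",
    "diffuse brainstem white matter", "hypothalamus", "mammillary bodies",
    "dentate nucleus of the cerebellum", "hippocampal white matter",
)

#: the seven coarse-protocol reference structures used by intensity recipes
RECIPE_REFERENCE_STRUCTURES = (
    "cerebral white matter", "cerebral gray matter", "cerebellar white matter",
    "cerebellar gray matter", "brainstem", "thalamus", "pallidum",
)

#: command-line defaults (kept in one place so the CLI and tests agree)
CLI_DEFAULTS = {
    "bf_mode": "dct",
    "skip": 1,
    "resolution": 0.4,
    "smoothing_steps_HRmask": 3,
    "smooth_grad_sigma": 1.0,
    "smooth_warp_sigma": 0.25,
    "optimizer_lr": 0.5,
    "cc_kernel_size": 7,
    "rel_weight_labeldiff": 2.5,
}

_YAML_NAMES = {
    "labels": "combined_atlas_labels_fireants.yaml",
    "components": "gmm_components_fireants.yaml",
    "recipe": "recipe_intensities_cheating_image_fireants.yaml",
}


def _read_yaml(name: str, yaml_path: str | Path | None):
    if yaml_path is not None:
        p = Path(yaml_path) / name
        if p.exists():
            return yaml.safe_load(p.read_text())
    ref = importlib_resources.files("histoseg") / "resources" / name
    return yaml.safe_load(ref.read_text())


def load_grouping(yaml_path: str | Path | None = None) -> LabelGrouping:
    """Tissue-class grouping + component counts from the YAML pair."""
    labels = _read_yaml(_YAML_NAMES["labels"], yaml_path) or {}
    comps = _read_yaml(_YAML_NAMES["components"], yaml_path) or {}
    roi_to_class = {int(lid): cls for cls, lids in labels.items()
                    for lid in (lids or [])}
    return LabelGrouping(classes=list(labels.keys()), roi_to_class=roi_to_class,
                         components_per_class={c: int(n) for c, n in comps.items()})


def load_recipe(yaml_path: str | Path | None = None) -> IntensityRecipe:
    rules = _read_yaml(_YAML_NAMES["recipe"], yaml_path) or {}
    return IntensityRecipe(rules={c: {s: float(a) for s, a in r.items()}
                                  for c, r in rules.items()})


def load_protocol(yaml_path: str | Path) -> dict:
    """Protocol sidecar: label names, atlas-to-protocol map, bias classes."""
    data = _read_yaml("protocol.yaml", yaml_path)
    if data is None:
        raise FileNotFoundError(f"protocol.yaml not found under {yaml_path}")
    return {
        "names": {int(k): str(v) for k, v in data["names"].items()},
        "atlas_to_protocol": {int(k): int(v)
                              for k, v in data["atlas_to_protocol"].items()},
        "brain_label_ids": [int(k) for k in data["brain_label_ids"]],
        "bias_classes": {c: [int(i) for i in ids]
                         for c, ids in data["bias_classes"].items()},
    }


__all__ = ["DEFAULT_TISSUE_CLASSES", "DEFAULT_BIAS_CLASSES",
           "RECIPE_REFERENCE_STRUCTURES", "CLI_DEFAULTS", "load_grouping",
           "load_recipe", "load_protocol"]
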