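"""Packaged default parameters and preset loaders.

All study-condition numbers (cohort structure, per-region trajectory
presets, WURS coupling, trial defaults) live in ``data/params.yaml`` so they
can be inspected and edited without touching code.
"""
from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import yaml

_CACHE: dict | None = None


def load_params(path: str | Path | None = None) -> dict:
    """Load the parameter file (packaged defaults if *path* is None)."""
    global _CACHE
    if path is None:
        if _CACHE is None:
            text = files("longimorph.data").joinpath("params.yaml").read_text()
            _CACHE = yaml.safe_load(text)
        return _CACHE
    with open(path) as fh:
        return yaml.safe_load(fh)


REGION_NAMES = (
    "brainstem",
    "ventral_pons",
    "cerebellar_white",
    "cerebellar_gray",
    "thalamus",
)
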