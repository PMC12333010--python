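"""Configuration documents, tabular output and run manifests.

One YAML document configures a run: compound constants, the PK model, PD
parameters, and the trial design.  Every CSV column is unit-suffixed
(time_h, conc_uM, vas_mm) and every output directory carries a manifest
recording the seed, the config hash and the package version, so a run is
repeatable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import AlertnessParams, CompoundParams, FeelingHighParams
from .pk import ConfigurationError, DoseEvent, PKModelSpec, Tissue, default_pk_fixture
from .population import TrialDesign, default_sampling_grid


def _build(cls, data: dict, what: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"invalid {what} section: {exc}") from None


def load_config(path: str | Path) -> dict:
    """Load and validate a run configuration document.

    Returns a dict with keys ``compounds`` (parent, metabolite),
    ``pk_spec``, ``feeling_high``, ``alertness``, ``design`` and the raw
    document under ``raw``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")

    compounds = doc.get("compounds", {})
    parent = _build(CompoundParams, compounds.get("parent", {
        "name": "THC", "molar_mass": 314.46, "f_a": 0.45, "k_a": 0.7,
        "lung_f_a": 0.6, "lung_k_a": 200.0}), "compounds.parent")
    metabolite = _build(CompoundParams, compounds.get("metabolite", {
        "name": "11-OH-THC", "molar_mass": 330.46}), "compounds.metabolite")

    pk_doc = doc.get("pk")
    if pk_doc is None:
        pk_spec = default_pk_fixture()
    else:
        pk_doc = dict(pk_doc)
        tissues = tuple(_build(Tissue, t, "pk.tissues")
                        for t in pk_doc.pop("tissues", []))
        pk_spec = _build(PKModelSpec, {**pk_doc, "tissues": tissues}, "pk")

    high = _build(FeelingHighParams, doc.get("feeling_high", {}), "feeling_high")
    alert = _build(AlertnessParams, doc.get("alertness", {}), "alertness")

    d = dict(doc.get("design", {}))
    regimen = tuple(_build(DoseEvent, ev, "design.regimen")
                    for ev in d.pop("regimen", []))
    sampling = d.pop("sampling", {"t_end": 12.0, "step": 0.05})
    if isinstance(sampling, dict):
        times = default_sampling_grid(sampling.get("t_end", 12.0),
                                      sampling.get("step", 0.05))
    else:
        times = np.asarray(sampling, dtype=float)
    design = _build(TrialDesign, {"regimen": regimen, "sampling_times": times, **d},
                    "design")
    return {
        "compounds": (parent, metabolite),
        "pk_spec": pk_spec,
        "feeling_high": high,
        "alertness": alert,
        "design": design,
        "raw": doc,
    }


def config_hash(doc: dict) -> str:
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config_doc: dict, seed: int,
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "thcpd",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config_doc),
        "config": config_doc,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def write_csv(df, path: str | Path, seed: int, cfg_hash: str) -> Path:
    """Write a CSV with a provenance header line (# seed=..., config=...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# thcpd {__version__} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")
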