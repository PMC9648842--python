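"""Configuration and file I/O: species files, trajectory/scan writers,
run configs and manifests.

All exchange formats are plain text: YAML for configuration and
metadata, comma-separated CSV (UTF-8, '.' decimal, mandatory header)
for tabular output, with units documented in a YAML sidecar rather than
in column headers.  Validation is strict — unknown keys are errors, not
warnings, because pathway and metabolite names key the stoichiometry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import PathwayParams, SpeciesModel
from .reactor import FeedProgram, Trajectory

log = logging.getLogger("cocultsim")

__all__ = [
    "load_species",
    "packaged_species_path",
    "load_run_config",
    "write_trajectory",
    "write_manifest",
    "ConfigError",
]

PACKAGED_SPECIES = ("ecoli_k12", "scerevisiae_cenpk")

_SPECIES_KEYS = {
    "name",
    "description",
    "metabolites",
    "enzyme_defaults",
    "enzyme_synthesis_scaled_by_biomass",
    "pathways",
}
_PATHWAY_KEYS = {
    "id",
    "substrate",
    "mu_max",
    "Ks",
    "q_max",
    "Yx",
    "Yp",
    "eps_c",
    "eps_i",
    "K_ind",
    "delta",
}
_ENZYME_KEYS = {"eps_c", "eps_i", "K_ind", "delta"}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def packaged_species_path(name: str) -> Path:
    """Path of a species parameter file shipped with the package."""
    if name not in PACKAGED_SPECIES:
        raise KeyError(f"unknown packaged species '{name}'; have {PACKAGED_SPECIES}")
    return Path(str(resources.files("cocultsim").joinpath("data", f"{name}.yaml")))


def _check_keys(block: Mapping, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def load_species(path: str | Path) -> SpeciesModel:
    """Load and validate a species parameter file.

    ``path`` may be a filesystem path or the name of a packaged species
    (``ecoli_k12`` / ``scerevisiae_cenpk``).  Printed
    negative consumption rates are converted to positive magnitudes.
    Invariant violations are reported with pathway identity.
    """
    p = Path(path)
    if not p.exists() and str(path) in PACKAGED_SPECIES:
        p = packaged_species_path(str(path))
    if not p.exists():
        raise FileNotFoundError(f"species file not found: {path}")
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{p}: species file must be a mapping")
    _check_keys(doc, _SPECIES_KEYS, str(p))
    for req in ("name", "pathways"):
        if req not in doc:
            raise ConfigError(f"{p}: missing required key '{req}'")
    defaults = doc.get("enzyme_defaults", {}) or {}
    _check_keys(defaults, _ENZYME_KEYS, f"{p}: enzyme_defaults")

    pathways = []
    errors = []
    for i, row in enumerate(doc["pathways"]):
        where = f"{p}: pathway #{i} ({row.get('id', '?')})"
        try:
            _check_keys(row, _PATHWAY_KEYS, where)
            kw = {**defaults, **row}
            q = float(kw["q_max"])
            if q < 0:
                log.info(
                    "%s: consumption rate %.4g converted to magnitude", where, q
                )
                kw["q_max"] = abs(q)
            pathways.append(PathwayParams(**kw))
        except (ConfigError, ValueError, KeyError, TypeError) as exc:
            errors.append(f"{where}: {exc}")
    if errors:
        raise ConfigError("species file invalid:\n" + "\n".join(errors))
    return SpeciesModel(
        name=doc["name"],
        pathways=pathways,
        metabolites=doc.get("metabolites", ["GLU", "ACE", "ETH"]),
        enzyme_synthesis_scaled_by_biomass=bool(
            doc.get("enzyme_synthesis_scaled_by_biomass", False)
        ),
    )


# ---------------------------------------------------------------------------
# run configuration

_RUN_KEYS = {
    "scenario",
    "species",
    "feed",
    "initial",
    "solver",
    "seed",
    "outdir",
    "t_end",
    "scan",
    "fit",
    "generate",
}
_FEED_KEYS = {"mode", "D_on", "w", "s", "feed", "D_is_average"}
_INITIAL_KEYS = {"X", "M", "psi_rel"}
_SOLVER_KEYS = {"report_dt", "rtol", "atol", "method"}
_SCAN_KEYS = {"D", "w", "s", "t_end", "threshold"}
_FIT_KEYS = {"dataset", "template", "free", "bounds"}
_GEN_KEYS = {"design", "cv", "replicates", "additive_sd", "t_max", "sample_every"}

SCENARIOS = ("batch", "chemostat", "pulsed", "scan", "fit", "generate-data")


def load_run_config(path: str | Path) -> dict[str, Any]:
    """Load a run configuration, validating structure strictly."""
    p = Path(path)
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{p}: run config must be a mapping")
    _check_keys(doc, _RUN_KEYS, str(p))
    if doc.get("scenario") not in SCENARIOS:
        raise ConfigError(
            f"{p}: scenario must be one of {SCENARIOS}, got {doc.get('scenario')!r}"
        )
    for block, allowed in (
        ("feed", _FEED_KEYS),
        ("initial", _INITIAL_KEYS),
        ("solver", _SOLVER_KEYS),
        ("scan", _SCAN_KEYS),
        ("fit", _FIT_KEYS),
        ("generate", _GEN_KEYS),
    ):
        if block in doc and doc[block] is not None:
            _check_keys(doc[block], allowed, f"{p}: {block}")
    return doc


def feed_from_config(block: Mapping[str, Any] | None) -> FeedProgram:
    block = dict(block or {})
    return FeedProgram(**block)


# ---------------------------------------------------------------------------
# writers

def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory CSV plus a YAML sidecar documenting units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = traj.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    meta = {
        "columns": {
            "t": "time, h",
            "D": "realized dilution rate, 1/h",
            "X_<species>": "biomass concentration, g/L",
            "GLU/ACE/ETH": "metabolite concentration, g/L",
            "psi_rel_<species>_<pathway>": "relative key-enzyme level, dimensionless",
            "u_<species>_<pathway>": "synthesis allocation weight, dimensionless",
            "v_<species>_<pathway>": "activity weight, dimensionless",
            "mu_<species>": "realized specific growth rate, 1/h",
        },
        "species": traj.species_names,
        "metabolites": traj.metabolites,
    }
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_trajectory_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    config_path: str | Path | None,
    seed: int | None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write a machine-readable run manifest (inputs hash, seed, versions)."""
    import scipy

    import cocultsim

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "cocultsim",
        "version": cocultsim.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": seed,
    }
    if config_path is not None:
        manifest["config"] = str(config_path)
        manifest["config_sha256"] = file_sha256(config_path)
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def grid_from_config(values: Sequence[float] | Mapping[str, float]) -> np.ndarray:
    """A grid axis given either as an explicit list or {start, stop, num}."""
    if isinstance(values, Mapping):
        _check_keys(values, {"start", "stop", "num"}, "grid")
        return np.linspace(values["start"], values["stop"], int(values["num"]))
    return np.asarray(list(values), dtype=float)
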