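"""Config parsing and CSV/JSON serialisation.

Complex numbers cross the config/JSON boundary as two-element
``[real, imag]`` arrays (bit-exact, no string parsing).  Config blocks
are validated strictly: unknown keys are a hard error so that a
misspelled parameter can never fall back to a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import ConfigurationError, Precisions, StateVector
from .integrate import Trajectory
from .linear import AttractorAnalysis, LinearParams
from .stimuli import Stimulus

__all__ = [
    "load_config",
    "parse_complex",
    "complex_pair",
    "linear_params_from_config",
    "stimulus_from_config",
    "state_from_config",
    "write_trajectory",
    "analysis_to_dict",
]


def load_config(path: Union[str, Path]) -> dict:
    """Read a JSON or YAML config file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def parse_complex(value, name: str = "value") -> complex:
    """Accept a real number or a two-element [real, imag] array."""
    if isinstance(value, (int, float)):
        return complex(value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return complex(float(value[0]), float(value[1]))
    raise ConfigurationError(
        f"{name}: expected a number or [real, imag] pair, got {value!r}"
    )


def complex_pair(z: complex) -> list:
    return [float(np.real(z)), float(np.imag(z))]


def _check_keys(block: dict, allowed: set, context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


_THETA_KEYS = {
    "theta_g0", "theta_g1", "theta_g2",
    "theta_f0", "theta_f1", "theta_pi0", "theta_pi2",
}


def linear_params_from_config(block: dict) -> LinearParams:
    """Build :class:`LinearParams` from a ``model`` config block."""
    allowed = {"kind", "masses"} | _THETA_KEYS
    _check_keys(block, allowed, "model block")
    kind = block.get("kind", "linear")
    if kind != "linear":
        raise ConfigurationError(f"unknown built-in model kind {kind!r} (expected 'linear')")
    masses = block.get("masses", [1.0, 1.0, 1.0])
    if len(masses) != 3:
        raise ConfigurationError("masses must be [m_z, m_w, m_eta]")
    thetas = {k: parse_complex(block.get(k, 0), k) for k in _THETA_KEYS}
    return LinearParams(
        precisions=Precisions(m_z=float(masses[0]), m_w=float(masses[1]),
                              m_eta=float(masses[2])),
        **thetas,
    )


def stimulus_from_config(block: dict) -> Stimulus:
    """Build a :class:`Stimulus` from a ``stimulus`` config block."""
    _check_keys(block, {"kind", "value", "s_inf", "k", "t_m", "series_csv"}, "stimulus block")
    kind = block.get("kind")
    if kind == "null" or kind is None:
        return Stimulus.null()
    if kind == "constant":
        return Stimulus.constant(parse_complex(block["value"], "stimulus value"))
    if kind == "sigmoid":
        return Stimulus.sigmoid(
            parse_complex(block["s_inf"], "s_inf"), float(block["k"]), float(block["t_m"])
        )
    if kind == "series":
        import pandas as pd

        df = pd.read_csv(block["series_csv"])
        if df.shape[1] < 2:
            raise ConfigurationError("series CSV needs two columns (t, value)")
        return Stimulus.series(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
    raise ConfigurationError(f"unknown stimulus kind {kind!r}")


def state_from_config(value) -> StateVector:
    """Initial state: 'zeros' or a list of four [real, imag] pairs."""
    if value in (None, "zeros"):
        return StateVector.zeros()
    if isinstance(value, (list, tuple)) and len(value) == 4:
        return StateVector(*[parse_complex(v, "psi0 component") for v in value])
    raise ConfigurationError("psi0 must be 'zeros' or four [real, imag] pairs")


def write_trajectory(
    traj: Trajectory,
    csv_path: Union[str, Path],
    sidecar: Optional[dict] = None,
) -> None:
    """Trajectory CSV plus a JSON sidecar with parameters and provenance."""
    csv_path = Path(csv_path)
    traj.to_dataframe().to_csv(csv_path, index=False, float_format="%.12g")
    meta = {"n_samples": len(traj), "dt": traj.dt, **traj.meta}
    if sidecar:
        meta.update(sidecar)
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def analysis_to_dict(analysis: AttractorAnalysis) -> dict:
    """JSON-ready attractor analysis (complex values as [re, im] pairs)."""
    out = {
        "centre": [complex_pair(z) for z in analysis.centre.to_array()],
        "eigenvalues": [complex_pair(z) for z in analysis.eigenvalues],
        "eigenvectors": [
            [complex_pair(z) for z in analysis.eigenvectors[:, i]]
            for i in range(analysis.eigenvectors.shape[1])
        ],
        "intensity": analysis.intensity,
        "trace": complex_pair(analysis.trace),
        "det": complex_pair(analysis.det),
        "det_closed_form": complex_pair(analysis.det_closed),
        "max_real_part": analysis.max_real_part,
        "centre_like": [bool(b) for b in analysis.centre_like]
        if analysis.centre_like is not None
        else None,
        "stimulus": complex_pair(analysis.stimulus_value),
    }
    if analysis.coefficients is not None:
        out["coefficients"] = [complex_pair(z) for z in analysis.coefficients]
    return out
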