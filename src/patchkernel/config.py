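"""Optional YAML configuration: radius-table override and kernel parameters.

Recognized keys::

    radii:            # element -> van der Waals radius (Å), overlaid on defaults
      C: 1.70
      SE: 1.90
    kernel:
      gamma: 72       # Gaussian width 1/(2 delta^2)
      c: 2            # Brownian-bridge cutoff (hop counts)
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import FormatError
from .features import DEFAULT_RADII
from .kernel import KernelParams


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    try:
        obj = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: invalid YAML: {exc}") from exc
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return obj


def radii_from_config(config: dict) -> dict[str, float]:
    radii = dict(DEFAULT_RADII)
    for element, value in (config.get("radii") or {}).items():
        radii[str(element).upper()] = float(value)
    return radii


def kernel_params_from_config(config: dict, *, gamma: float | None = None,
                              c: float | None = None) -> KernelParams:
    """Kernel parameters: explicit arguments win over config, config over defaults."""
    section = config.get("kernel") or {}
    defaults = KernelParams()
    return KernelParams(
        gamma=gamma if gamma is not None else float(section.get("gamma", defaults.gamma)),
        c=c if c is not None else float(section.get("c", defaults.c)),
    )
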