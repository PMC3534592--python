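"""Run configuration: one structured object for the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from dbareit.forward_sim import ElectrodeLayout, Inclusion, PhantomSpec

__all__ = ["RunConfig", "load_config", "phantom_from_dict", "phantom_to_dict"]


@dataclass
class RunConfig:
    """All tunable parameters with the experiment-scale defaults.

    Layout: 32 or 16 electrodes on a unit-radius disk (a 15 cm tank maps to
    r = 0.15 with consistent units), 1 mA trigonometric patterns.  Solver:
    truncation radius 4, 16 one-sided sinc indices (m = 33), 64x64 image.
    """

    # electrode layout
    L: int = 32
    r: float = 1.0
    A: float | None = None
    height: float = 1.0
    z_contact: float = 1e-4
    M: float = 1.0  # current amplitude (mA)

    # forward simulation
    forward_elements: int = 6400
    edges_per_electrode: int = 6

    # noise
    noise_amplitude: float = 0.0
    noise_target: str = "currents"
    seed: int = 0

    # reconstruction
    R: float = 4.0
    m_idx: int = 16          # one-sided sinc index count (m = 2*m_idx + 1)
    h: float | None = None   # sinc step; None = coverage-based default
    tol: float = 1e-5
    maxit: int = 200
    image_size: int = 64
    calibration: float = 1.0
    eig_tol: float = 1e-6   # eigendecomposition reconstitution guard

    # phantom (None means homogeneous unit background)
    phantom: dict | None = None

    def __post_init__(self) -> None:
        for name in ("r", "M", "height", "z_contact", "R", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")

    def layout(self) -> ElectrodeLayout:
        return ElectrodeLayout(
            L=self.L, r=self.r, A=self.A, height=self.height,
            z_contact=self.z_contact,
        )

    def phantom_spec(self) -> PhantomSpec:
        if self.phantom is None:
            return PhantomSpec(background_sigma=1.0, domain_radius=self.r)
        return phantom_from_dict(self.phantom, domain_radius=self.r)

    def as_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Read a YAML config file and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def phantom_from_dict(d: dict, domain_radius: float = 1.0) -> PhantomSpec:
    incs = []
    for item in d.get("inclusions", []):
        incs.append(
            Inclusion(
                shape=item["shape"],
                center=tuple(item["center"]),
                semi_axes=tuple(
                    item.get("semi_axes")
                    or (item["radius"], item["radius"])
                ),
                sigma=float(item["sigma"]),
                angle=float(np.deg2rad(item.get("angle_deg", 0.0))),
            )
        )
    return PhantomSpec(
        background_sigma=float(d["background"]),
        inclusions=incs,
        domain_radius=domain_radius,
    )


def phantom_to_dict(ph: PhantomSpec) -> dict:
    return {
        "background": ph.background_sigma,
        "inclusions": [
            {
                "shape": i.shape,
                "center": list(i.center),
                "semi_axes": list(i.semi_axes),
                "sigma": i.sigma,
                "angle_deg": float(np.rad2deg(i.angle)),
            }
            for i in ph.inclusions
        ],
    }
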