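"""Run configuration: YAML in, fully resolved YAML out beside the results.

Every CLI run serializes the resolved configuration next to its outputs
so a run is reproducible from the artefacts alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomSpec, WedgeModulation

logger = logging.getLogger("cinestrain")


@dataclass
class RunConfig:
    """Resolved parameters of one analysis run."""

    pixel_spacing: float = 1.0          # mm/px, in-plane (isotropic)
    slice_spacing: float = 1.0          # mm
    frame_window: tuple[int, int] = (1, 17)
    n_points: int = 100
    strain_convention: str = "green-lagrange"
    reference_angle: float = 0.0        # rad, sector model reference ray
    loss_alpha: float = 0.2
    loss_beta: float = 0.8
    phantom: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        if "wedge" in kw and kw["wedge"] is not None:
            kw["wedge"] = WedgeModulation(**kw["wedge"])
        if "translation" in kw:
            kw["translation"] = tuple(kw["translation"])
        kw.setdefault("seed", self.seed)
        return PhantomSpec(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "frame_window" in data:
            data["frame_window"] = tuple(data["frame_window"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["frame_window"] = list(data["frame_window"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr for CLI runs."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
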