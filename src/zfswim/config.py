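"""Run configuration.

All tunable thresholds and cutoffs of the pipeline live in a single
:class:`RunConfig` so that a run can be reproduced from its manifest.
Configuration files are flat ``key = value`` text; unknown keys are
rejected so that typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    """Pipeline parameters with their defaults.

    Attributes
    ----------
    threshold:
        Global threshold (8-bit intensity units) applied to the absolute
        frame-minus-background difference image.
    min_area:
        Smallest connected-component area (pixels) accepted as a fish.
    spatial_cutoff, temporal_cutoff:
        Normalized low-pass cutoffs in (0, 0.5] (1.0 = sampling rate) for
        smoothing the curvature matrix along the body and along time.
    cycle_target_length:
        Number of frames every body-waving cycle is normalized to.
    n_control_points:
        Number of arc-length-uniform midline control points.
    alpha:
        Significance level of the group comparisons.
    expected_rate:
        If set, overrides the container frame rate (high-speed cameras
        often store a wrong nominal rate).
    travel_mode:
        ``"path"`` sums per-frame centroid displacements; ``"net"`` uses
        start-to-end displacement only.
    equal_variance:
        Classical pooled-variance Student t when True, Welch when False.
    peak_prominence:
        Minimum prominence of tail-offset maxima for automatic cycle
        detection, in tail-offset units.
    seed:
        Seed for every stochastic step of a run.
    """

    threshold: float = 25.0
    min_area: int = 50
    spatial_cutoff: float = 0.2
    temporal_cutoff: float = 0.15
    cycle_target_length: int = 30
    n_control_points: int = 20
    alpha: float = 0.05
    expected_rate: float | None = None
    travel_mode: str = "path"
    equal_variance: bool = True
    per_fish_averaging: bool = False
    peak_prominence: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("spatial_cutoff", "temporal_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 0.5:
                raise ConfigError(f"{name} must be in (0, 0.5], got {v}")
        if self.n_control_points < 3:
            raise ConfigError("n_control_points must be >= 3")
        if self.cycle_target_length < 2:
            raise ConfigError("cycle_target_length must be >= 2")
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.travel_mode not in ("path", "net"):
            raise ConfigError("travel_mode must be 'path' or 'net'")

    # -- flat key = value round trip -------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from flat ``key = value`` text.

        Blank lines and ``#`` comments are ignored.
        """
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _parse_value(value, fields[key].type)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parse_value(text: str, annot) -> object:
    if text in ("None", ""):
        return None
    if text in ("True", "true"):
        return True
    if text in ("False", "false"):
        return False
    annot = str(annot)
    if "int" in annot and "float" not in annot:
        return int(text)
    if "float" in annot:
        return float(text)
    if "bool" in annot:
        raise ConfigError(f"expected a boolean, got {text!r}")
    return text
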