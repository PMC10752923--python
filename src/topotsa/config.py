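"""Experiment configuration: YAML-backed, validated, fully resolved.

Every command resolves its configuration (filling defaults) and writes the
resolved file back next to its outputs, so a run can be reproduced
byte-identically from the emitted file.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .ar2 import AR2Spec, ar2_from_peak, band_preset
from .graphs import (
    DependenceGraph,
    PolygonQuotientSpec,
    circular_ladder,
    dodecahedron,
    double_circular_ladder,
    sample_quotient_graph,
    torus_grid,
)
from .pipeline import HIGH_BAND, MID_BAND, SpectralOptions

__all__ = [
    "GraphConfig",
    "BandConfig",
    "MixingConfig",
    "SpectralConfig",
    "PersistenceConfig",
    "ExperimentDesign",
    "RunConfig",
    "load_config",
    "dump_config",
    "PRESETS",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GraphConfig(_Strict):
    kind: Literal[
        "circular_ladder",
        "double_circular_ladder",
        "torus_grid",
        "dodecahedron",
        "quotient",
        "edge_list",
    ] = "circular_ladder"
    n_rungs: int = 15
    n_rungs_per_lobe: int = 8
    n_bridges: int = 2
    rows: int = 9
    cols: int = 17
    wrap_rows: bool = True
    wrap_cols: bool = True
    mode: Literal["regular", "uniform_random"] = "regular"
    n_points: Optional[int] = None
    path: Optional[str] = None  # for kind=edge_list

    def build(self, seed: int = 0) -> DependenceGraph:
        if self.kind == "circular_ladder":
            return circular_ladder(self.n_rungs)
        if self.kind == "double_circular_ladder":
            return double_circular_ladder(self.n_rungs_per_lobe, self.n_bridges)
        if self.kind == "torus_grid":
            return torus_grid(self.rows, self.cols)
        if self.kind == "dodecahedron":
            return dodecahedron()
        if self.kind == "quotient":
            spec = PolygonQuotientSpec(
                rows=self.rows,
                cols=self.cols,
                wrap_rows=self.wrap_rows,
                wrap_cols=self.wrap_cols,
            )
            return sample_quotient_graph(
                spec, n_points=self.n_points, seed=seed, mode=self.mode
            )
        if self.kind == "edge_list":
            if self.path is None:
                raise ValueError("graph.kind=edge_list requires graph.path")
            from .io import read_edge_list

            return read_edge_list(self.path)
        raise ValueError(f"unknown graph kind {self.kind!r}")


class BandConfig(_Strict):
    preset: Optional[str] = "alpha"
    peak_freq_hz: Optional[float] = None
    sampling_rate_hz: float = 100.0
    root_magnitude: float = 1.05
    innovation_sd: float = 1.0

    def build(self) -> AR2Spec:
        if self.peak_freq_hz is not None:
            return ar2_from_peak(
                self.peak_freq_hz,
                self.sampling_rate_hz,
                self.root_magnitude,
                self.innovation_sd,
            )
        if self.preset is None:
            raise ValueError("band needs either a preset or a peak_freq_hz")
        return band_preset(self.preset, self.sampling_rate_hz, self.root_magnitude)


class MixingConfig(_Strict):
    K: int = 2
    decay: Literal["inv_linear", "inv_quadratic", "exponential"] = "inv_linear"
    noise_sd: Optional[float] = 0.0
    snr: Optional[float] = None

    @model_validator(mode="after")
    def _one_noise_spec(self):
        if self.snr is not None and self.noise_sd not in (None, 0.0):
            raise ValueError("give either mixing.noise_sd or mixing.snr, not both")
        if self.K < 0:
            raise ValueError("mixing.K must be >= 0")
        return self


class SpectralConfig(_Strict):
    kernel: Literal["daniell", "triangular", "identity"] = "daniell"
    half_width: Optional[int] = None
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"mid": MID_BAND, "high": HIGH_BAND}
    )
    analysis_band: str = "mid"
    transform: Literal["one_minus", "sqrt_one_minus"] = "one_minus"

    def options(self) -> SpectralOptions:
        if self.analysis_band not in self.bands:
            raise ValueError(
                f"analysis_band {self.analysis_band!r} not among bands {sorted(self.bands)}"
            )
        return SpectralOptions(
            kernel=self.kernel,
            half_width=self.half_width,
            band_hz=tuple(self.bands[self.analysis_band]),
            transform=self.transform,
        )


class PersistenceConfig(_Strict):
    max_dim: int = 1
    rel_threshold: float = 0.5
    thresh: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if self.max_dim not in (1, 2):
            raise ValueError("persistence.max_dim must be 1 or 2")
        if not 0 < self.rel_threshold <= 1:
            raise ValueError("persistence.rel_threshold must be in (0, 1]")
        return self


class ExperimentDesign(_Strict):
    n_time_samples: int = 2000
    n_samples_per_group: int = 20
    n_bootstrap: int = 200
    snr_grid: list[float] = Field(default_factory=lambda: [0.25, 0.5, 1, 2, 4, 8, 16])
    n_replicates: int = 50
    snr: float = 4.0


class RunConfig(_Strict):
    graph: GraphConfig = Field(default_factory=GraphConfig)
    band: BandConfig = Field(default_factory=BandConfig)
    mixing: MixingConfig = Field(default_factory=MixingConfig)
    spectral: SpectralConfig = Field(default_factory=SpectralConfig)
    persistence: PersistenceConfig = Field(default_factory=PersistenceConfig)
    experiment: ExperimentDesign = Field(default_factory=ExperimentDesign)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    )


#: The four canonical experiment configurations.
PRESETS: dict[str, RunConfig] = {
    "one_cycle": RunConfig(
        graph=GraphConfig(kind="circular_ladder", n_rungs=15),
        persistence=PersistenceConfig(max_dim=1),
    ),
    "two_cycle": RunConfig(
        graph=GraphConfig(kind="double_circular_ladder", n_rungs_per_lobe=8),
        persistence=PersistenceConfig(max_dim=1),
    ),
    "torus": RunConfig(
        graph=GraphConfig(kind="torus_grid", rows=9, cols=17),
        mixing=MixingConfig(K=3),
        persistence=PersistenceConfig(max_dim=2),
    ),
    "sphere": RunConfig(
        graph=GraphConfig(kind="dodecahedron"),
        persistence=PersistenceConfig(max_dim=2),
    ),
}
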