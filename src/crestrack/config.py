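"""Run configuration: simulation, imaging and analysis parameters.

All schedules are in hours post-fertilisation (hpf), space in μm, the frame
interval in seconds.  ``SimulationConfig`` defaults encode the study
conditions: the first neural-crest (NC) wave delaminates at 12–14 hpf from
the lateral stripe, the second wave appears mediodorsally at 16–17 hpf,
clusters near the dorsal eye rim during 18–22 hpf and enters the distal eye
during 22–28 hpf, with 20–30 cells entering.  Cell speeds and the division
rate are free parameters — the underlying study reports behaviour, not
kinetic rates — with defaults chosen to look like typical cranial NC
migration (order 1 μm/min, divisions every ~20 h per cell).

Configs serialise to JSON; unknown keys are rejected on load so that typos
fail loudly rather than silently running defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

GENOTYPES = ("wildtype", "pax6b_null", "pax6_double_null")


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


def _check_window(name: str, w: tuple[float, float], lo: float, hi: float) -> None:
    if not (lo <= w[0] <= w[1] <= hi):
        raise ConfigError(
            f"{name} = {w} must be ordered and within [{lo}, {hi}]"
        )


@dataclass
class SimulationConfig:
    """Ground-truth simulation parameters for one embryo."""

    dt_s: float = 20.4                 # frame interval; stride 10 = 3 min 24 s
    t_start_hpf: float = 11.0
    t_end_hpf: float = 31.0
    n_1nc: int = 30                    # founders of the early (proximal) wave
    n_2nc: int = 14                    # founders of the late (distal) wave
    delamination_window_1nc: tuple[float, float] = (12.0, 14.0)
    delamination_window_2nc: tuple[float, float] = (16.0, 17.0)
    cluster_window: tuple[float, float] = (18.0, 22.0)
    entry_window: tuple[float, float] = (22.0, 28.0)
    n_entering_2nc: int = 25           # cap on 2° cells entering the distal eye
    division_rate_per_h: float = 0.05
    speed_um_per_min: dict[str, float] = field(
        default_factory=lambda: {"1NC": 0.3, "2NC": 1.5}
    )
    noise_sigma_um: float = 0.25       # diffusive jitter, μm per sqrt(minute)
    genotype: str = "wildtype"
    mixing_fraction: float = 0.09      # P(lineage programmed mixed-destination)
    wnt_wave2_fraction: float = 0.5    # fraction of 2NC with 2nd Wnt wave
    seed: int = 0

    # geometry
    eye_radius_um: float = 40.0
    mirrored: bool = False

    # reporter dynamics
    silencing_1nc_hpf: float = 16.0    # promoter hard-off times
    silencing_2nc_hpf: float = 20.0
    k_syn_per_h: float = 1.0           # green-pool synthesis while promoter on
    green_halflife_h: float = 12.0     # pool decay half-life ("persists to ~48 hpf")
    wnt_wave1_peak_hpf: float = 14.0   # transient wave in all NC
    wnt_wave2_peak_hpf: float = 21.0   # sustained wave in a subset of 2NC

    def validate(self) -> "SimulationConfig":
        if self.dt_s <= 0:
            raise ConfigError("dt_s must be positive")
        if self.t_start_hpf >= self.t_end_hpf:
            raise ConfigError("t_start_hpf must precede t_end_hpf")
        lo, hi = self.t_start_hpf, self.t_end_hpf
        _check_window("delamination_window_1nc", self.delamination_window_1nc, lo, hi)
        _check_window("delamination_window_2nc", self.delamination_window_2nc, lo, hi)
        _check_window("cluster_window", self.cluster_window, lo, hi)
        _check_window("entry_window", self.entry_window, lo, hi)
        if self.n_1nc < 0 or self.n_2nc < 0:
            raise ConfigError("population sizes must be non-negative")
        if not 0 <= self.mixing_fraction <= 1:
            raise ConfigError("mixing_fraction must be in [0, 1]")
        if not 0 <= self.wnt_wave2_fraction <= 1:
            raise ConfigError("wnt_wave2_fraction must be in [0, 1]")
        if self.genotype not in GENOTYPES:
            raise ConfigError(f"genotype must be one of {GENOTYPES}")
        if self.division_rate_per_h < 0:
            raise ConfigError("division_rate_per_h must be non-negative")
        if self.eye_radius_um <= 0:
            raise ConfigError("eye_radius_um must be positive")
        for pop in ("1NC", "2NC"):
            if pop not in self.speed_um_per_min:
                raise ConfigError(f"speed_um_per_min missing population {pop!r}")
        return self

    @property
    def dt_h(self) -> float:
        return self.dt_s / 3600.0

    @property
    def n_frames(self) -> int:
        return int(round((self.t_end_hpf - self.t_start_hpf) / self.dt_h)) + 1

    def frame_times(self):
        import numpy as np

        return self.t_start_hpf + np.arange(self.n_frames) * self.dt_h


@dataclass
class ImagingConfig:
    """Light-sheet-like rendering parameters.

    Voxel size and PSF widths default to the DSLM values (0.4 μm lateral /
    2.0 μm axial voxels; PSF FWHM 1.5 μm lateral, 6.6 μm axial).
    """

    voxel_size_um: tuple[float, float, float] = (0.4, 0.4, 2.0)   # (x, y, z)
    psf_fwhm_um: tuple[float, float] = (1.5, 6.6)                 # (lateral, axial)
    bit_depth: int = 16
    background_level: float = 100.0    # counts
    gain: float = 2000.0               # counts per fluorophore unit at blob peak
    read_noise_sigma: float = 2.0      # Gaussian read noise, counts
    field_lo_um: tuple[float, float, float] = (-70.0, -25.0, -55.0)
    field_hi_um: tuple[float, float, float] = (60.0, 125.0, 55.0)

    def validate(self) -> "ImagingConfig":
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigError("voxel sizes must be positive")
        if self.psf_fwhm_um[0] < min(self.voxel_size_um[:2]):
            raise ConfigError("lateral PSF FWHM must be >= lateral voxel size")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")
        return self


@dataclass
class AnalysisConfig:
    """Downstream-analysis parameters shared across fate / angle stages."""

    shell_um: float = 6.0              # eye-surface band half-thickness
    margin_um: float = 0.0             # equatorial dead zone for labelling
    t_select_early_hpf: float = 17.0   # selection stages mirrored from the study
    t_select_late_hpf: float = 24.0
    t_eval_hpf: float = 30.0
    stride_frames: int = 10
    min_step_um: float = 0.5
    angle_window_start_hpf: float = 15.0   # sample angles from the migration era
    bin_width_deg: float = 10.0
    gate_um: float = 12.0              # linking gate per frame step
    max_gap_frames: int = 2
    r_match_um: float = 2.0

    def validate(self) -> "AnalysisConfig":
        if self.shell_um <= 0 or self.gate_um <= 0 or self.r_match_um <= 0:
            raise ConfigError("shell_um, gate_um, r_match_um must be positive")
        if self.stride_frames < 1:
            raise ConfigError("stride_frames must be >= 1")
        if 360.0 % self.bin_width_deg != 0:
            raise ConfigError("bin_width_deg must divide 360")
        return self


@dataclass
class RunConfig:
    """Merged configuration for the command-line pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int | None = None            # overrides simulation.seed when set
    out_dir: str = "crestrack_out"

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        self.imaging.validate()
        self.analysis.validate()
        if self.seed is not None:
            self.simulation.seed = int(self.seed)
        return self


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        elif isinstance(value, list) and "window" in key:
            value = tuple(value)
        elif isinstance(value, list) and key in (
            "voxel_size_um",
            "psf_fwhm_um",
            "field_lo_um",
            "field_hi_um",
        ):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "imaging": ImagingConfig,
    "analysis": AnalysisConfig,
}


def run_config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _from_dict(cls, data.pop(name))
    allowed = {"seed", "out_dir"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys for RunConfig: {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs).validate()


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return run_config_from_dict(json.load(fh))


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
        fh.write("\n")
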