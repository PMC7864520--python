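"""Run configuration: typed, strict, YAML round-trippable.

All study-condition defaults live here rather than in the algorithm
code: the species panel with per-species kinetic rates and aggregate
morphology, the AEF dose grid, the imaging-time grid, replicate count,
the AEF-fraction-to-seed-fraction ceiling, imaging parameters and the
morphology-classifier cutoffs.  Species differences are encoded only
through kinetic parameters; the effective seeding order (cat >= mouse >>
camel ~ cattle ~ goat) mirrors the empirical activity ranking the
pipeline is designed to recover.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .kinetics import KineticParams
from .quant import MorphologyCutoffs
from .render import ImagingParams

__all__ = ["SpeciesConfig", "RunConfig", "DEFAULT_SPECIES",
           "load_config", "save_config"]


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species kinetic and rendering defaults."""

    elongation_rate: float          # 1/(unit * hour)
    nucleation_rate: float = 0.0    # 1/hour; 0: no spontaneous aggregation
    noise_sd: float = 0.02          # observation noise on mass fraction
    morphology: str = "dotted"


# effective seeding: cat >= mouse >> camel ~ cattle ~ goat; only the
# mouse-like aggregate is mesh-form
DEFAULT_SPECIES: dict[str, SpeciesConfig] = {
    "cat": SpeciesConfig(elongation_rate=0.100),
    "mouse": SpeciesConfig(elongation_rate=0.085, morphology="mesh"),
    "goat": SpeciesConfig(elongation_rate=0.012),
    "cattle": SpeciesConfig(elongation_rate=0.011),
    "camel": SpeciesConfig(elongation_rate=0.010),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs, with explicit seeds."""

    seed: int = 0
    outdir: str = "seedquant_run"
    species: dict[str, SpeciesConfig] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES))
    aef_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    times_h: tuple[float, ...] = (0, 24, 48, 72, 96, 120, 144, 168)
    replicates: int = 3
    seed_ceiling: float = 0.1       # seed_fraction at aef_fraction = 1
    total_monomer: float = 1.0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    morphology_cutoffs: MorphologyCutoffs = field(
        default_factory=MorphologyCutoffs)
    gap_open: float = -12.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species panel must be non-empty")
        if not self.aef_fractions or not self.times_h:
            raise ValueError("aef_fractions and times_h must be non-empty")
        if any(not 0 <= f <= 1 for f in self.aef_fractions):
            raise ValueError("aef_fractions must lie in [0, 1]")
        if list(self.times_h) != sorted(set(self.times_h)):
            raise ValueError("times_h must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.seed_ceiling <= 1:
            raise ValueError("seed_ceiling must lie in (0, 1]")

    def kinetic_params(self, species: str, aef_fraction: float
                       ) -> KineticParams:
        sp = self.species[species]
        return KineticParams(
            total_monomer=self.total_monomer,
            nucleation_rate=sp.nucleation_rate,
            elongation_rate=sp.elongation_rate,
            seed_fraction=aef_fraction * self.seed_ceiling,
            noise_sd=sp.noise_sd,
        )

    def imaging_params(self, species: str, rng_seed: int = 0) -> ImagingParams:
        return replace(self.imaging, morphology=self.species[species].morphology,
                       rng_seed=rng_seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = {k: asdict(v) for k, v in self.species.items()}
        d["aef_fractions"] = list(self.aef_fractions)
        d["times_h"] = list(self.times_h)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(data)
        if "species" in kw:
            kw["species"] = {
                name: _strict(SpeciesConfig, sp, f"species.{name}")
                for name, sp in kw["species"].items()
            }
        if "imaging" in kw:
            kw["imaging"] = _strict(ImagingParams, kw["imaging"], "imaging")
        if "morphology_cutoffs" in kw:
            kw["morphology_cutoffs"] = _strict(
                MorphologyCutoffs, kw["morphology_cutoffs"], "morphology_cutoffs")
        for name in ("aef_fractions", "times_h"):
            if name in kw:
                kw[name] = tuple(kw[name])
        return cls(**kw)


def _strict(cls, data, where: str):
    if isinstance(data, cls):
        return data
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
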