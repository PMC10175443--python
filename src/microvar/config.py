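"""Simulation configuration: the knobs of the nested-replicate study design.

The default values encode the study design being emulated: 5 subjects sampled
on days 1, 2, 8 and 9, two DNA-extraction replicates per sample and two
library-prep/sequencing replicates per extraction, measured with two
modalities (16S-like amplicon and shallow-shotgun-like) that share the
underlying biology but carry modality-specific technical noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

READ_LENGTH = 100  # bp; shotgun reads are fixed-length and error-free


class ConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of the synthetic study.

    The sigma_* parameters are standard deviations of log-scale multiplicative
    perturbations applied at each level of the nested design (subject, week,
    day, extraction, library prep).  ``amplicon_bias_sigma`` is a per-taxon
    bias fixed across the whole study for the amplicon modality (PCR primer
    bias); ``amplicon_extra_libprep_sigma`` is additional amplicon-only noise
    drawn independently per library prep (amplification stochasticity).
    """

    n_subjects: int = 5
    days: tuple[int, ...] = (1, 2, 8, 9)
    n_extractions: int = 2
    n_libpreps: int = 2
    n_taxa: int = 50
    sigma_subject: float = 1.0
    sigma_week: float = 0.4
    sigma_day: float = 0.4
    sigma_extraction: float = 0.1
    sigma_libprep: float = 0.1
    amplicon_bias_sigma: float = 0.5
    amplicon_extra_libprep_sigma: float = 0.2
    p_species_16s: float = 0.1
    read_depth_shotgun: int = 10_000
    read_depth_amplicon: int = 10_000
    genome_length_range: tuple[int, int] = (200_000, 1_000_000)
    unique_fraction: float = 0.3
    n_kos_per_genome: int = 10
    p_tie: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", tuple(self.days))
        object.__setattr__(self, "genome_length_range", tuple(self.genome_length_range))
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.days:
            raise ConfigError("days must be nonempty")
        if list(self.days) != sorted(self.days):
            raise ConfigError("days must be sorted ascending")
        if len(set(self.days)) != len(self.days):
            raise ConfigError("days must be distinct")
        if self.n_extractions < 1 or self.n_libpreps < 1:
            raise ConfigError("replicate counts must be >= 1")
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        for name in (
            "sigma_subject", "sigma_week", "sigma_day", "sigma_extraction",
            "sigma_libprep", "amplicon_bias_sigma", "amplicon_extra_libprep_sigma",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.p_species_16s <= 1.0:
            raise ConfigError("p_species_16s must be in [0, 1]")
        if not 0.0 <= self.p_tie <= 1.0:
            raise ConfigError("p_tie must be in [0, 1]")
        if self.read_depth_shotgun <= 0 or self.read_depth_amplicon <= 0:
            raise ConfigError("read depths must be > 0")
        lo, hi = self.genome_length_range
        if lo > hi:
            raise ConfigError("genome_length_range must be (min, max) with min <= max")
        if lo < READ_LENGTH:
            raise ConfigError(
                f"minimum genome length {lo} is shorter than the read length {READ_LENGTH}"
            )
        if not 0.0 < self.unique_fraction <= 1.0:
            raise ConfigError("unique_fraction must be in (0, 1]")
        if self.n_kos_per_genome < 1:
            raise ConfigError("n_kos_per_genome must be >= 1")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        d["genome_length_range"] = list(self.genome_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        """Load from a JSON file; missing fields take the stated defaults."""
        with open(path, encoding="utf-8") as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config JSON must be an object")
        return cls.from_dict(d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
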