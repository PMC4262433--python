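"""Study-emulation configuration.

:class:`StudyConfig` collects every tunable of the synthetic-data
generators in one validated record.  The defaults emulate the oleate
feeding/withdrawal study conditions in procyclic *Trypanosoma brucei*:
a ~4.7-fold increase in lipid droplets (LDs) per cell upon oleate
feeding with a hard per-cell maximum of nine, a ~4.6-fold increase in
whole-cell BODIPY fluorescence and in the TAG band on thin-layer
chromatography, exponential growth, decay of the stored signal to a
basal plateau after oleate withdrawal governed by growth dilution, a
96-species TAG catalog dominated by the 54:2/54:3/54:4 classes, and a
two-genotype (WT vs knockout) glycosomal proteome in which exactly one
protein is ablated with a ~140-fold wild-type excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = ["StudyConfig", "DEFAULT_DOMINANT_CLASSES"]

#: Default intensity share of each dominant TAG class (fraction of the
#: summed species intensity).  54:3 dominates because oleate (18:1)
#: esterified three times gives a 54:3 triacylglycerol.
DEFAULT_DOMINANT_CLASSES: dict[str, float] = {
    "54:2": 0.16,
    "54:3": 0.30,
    "54:4": 0.14,
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic study; all generators consume this.

    Parameters
    ----------
    seed
        Base seed. A fixed seed makes every generated table
        byte-identical after serialization.
    n_cells
        Cells per simulated population (microscopy counting and flow
        cytometry).
    unfed_ld_mean
        Expected LDs per cell in unfed cells (dimensionless). Not a
        printed study value; a free calibration constant chosen so the
        fed mean stays below ``ld_max``.
    ld_fold
        Fed/unfed ratio of mean LD counts.
    ld_max
        Hard per-cell maximum LD count.
    flow_fold
        Fed/unfed ratio of mean whole-cell fluorescence. Also used as
        the fed/unfed TAG densitometry fold (the emulated experiments
        show the same fold for both).
    flow_background
        Basal whole-cell fluorescence from membrane staining, arbitrary
        units.
    growth_n0
        Initial culture density, cells/ml.
    doubling_time_h
        True population doubling time Td in hours; mu = ln2/Td.
    decay_timepoints_h
        Sampling times (hours after oleate withdrawal).
    replicates
        Independent replicates per measurement.
    noise_cv
        Coefficient of variation of multiplicative lognormal replicate
        noise.
    catabolic_rate_h
        True first-order catabolic rate k (h^-1) of the stored signal;
        0 means pure growth dilution.
    basal_level
        Basal plateau B of the stored signal, as a fraction of the fed
        (t = 0) level, maintained by lipid uptake and synthesis.
    n_tag_species
        Number of distinct TAG species in the catalog (excluding the
        spiked internal standard).
    dominant_classes
        Mapping carbon:double-bond class -> share of total intensity.
    n_proteins
        Rows in the two-genotype proteome table (including the ablated
        protein).
    ablated_ratio
        True WT/KO abundance ratio of the single ablated protein.
    """

    seed: int = 0
    n_cells: int = 10_000
    unfed_ld_mean: float = 1.2
    ld_fold: float = 4.7
    ld_max: int = 9
    flow_fold: float = 4.6
    flow_background: float = 1.0
    growth_n0: float = 2e6
    doubling_time_h: float = 12.0
    decay_timepoints_h: Sequence[float] = (0, 4, 8, 12, 16, 20, 24, 28, 32)
    replicates: int = 3
    noise_cv: float = 0.05
    catabolic_rate_h: float = 0.0
    basal_level: float = 0.2
    n_tag_species: int = 96
    dominant_classes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMINANT_CLASSES)
    )
    n_proteins: int = 80
    ablated_ratio: float = 140.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.unfed_ld_mean <= 0:
            raise ValueError("unfed_ld_mean must be > 0")
        if self.ld_fold < 1:
            raise ValueError("ld_fold must be >= 1 (feeding cannot deplete LDs)")
        if self.ld_max < 1:
            raise ValueError("ld_max must be >= 1")
        if self.unfed_ld_mean * self.ld_fold > self.ld_max:
            raise ValueError(
                f"fed mean LD count {self.unfed_ld_mean * self.ld_fold:.3g} "
                f"exceeds the per-cell maximum ld_max={self.ld_max}"
            )
        if self.flow_fold <= 0:
            raise ValueError("flow_fold must be > 0")
        if self.flow_background < 0:
            raise ValueError("flow_background must be >= 0")
        if self.flow_background > 0 and self.flow_fold > 1 and (
            self.flow_fold >= self.ld_fold
        ):
            raise ValueError(
                "with positive background the whole-cell fluorescence fold "
                "is necessarily below the LD-count fold; require "
                "flow_fold < ld_fold"
            )
        if self.growth_n0 <= 0:
            raise ValueError("growth_n0 must be > 0")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0")
        ts = list(self.decay_timepoints_h)
        if len(ts) < 2 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("decay_timepoints_h must be strictly increasing")
        if ts[0] != 0:
            raise ValueError("decay_timepoints_h must start at 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.catabolic_rate_h < 0:
            raise ValueError("catabolic_rate_h must be >= 0")
        if not 0 <= self.basal_level < 1:
            raise ValueError("basal_level must be in [0, 1)")
        if self.n_tag_species < 1:
            raise ValueError("n_tag_species must be >= 1")
        w = sum(self.dominant_classes.values())
        if self.dominant_classes and not 0 < w < 1:
            raise ValueError("dominant_classes shares must sum into (0, 1)")
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.ablated_ratio <= 1:
            raise ValueError("ablated_ratio must be > 1")

    @property
    def mu(self) -> float:
        """Specific growth rate ln2/Td in h^-1."""
        return math.log(2.0) / self.doubling_time_h

    @property
    def fed_ld_mean(self) -> float:
        return self.unfed_ld_mean * self.ld_fold

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "decay_timepoints_h" in data:
            data["decay_timepoints_h"] = tuple(data["decay_timepoints_h"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decay_timepoints_h"] = list(self.decay_timepoints_h)
        return d

    def replace(self, **kwargs) -> "StudyConfig":
        d = self.to_dict()
        d.update(kwargs)
        if "decay_timepoints_h" in d:
            d["decay_timepoints_h"] = tuple(d["decay_timepoints_h"])
        return StudyConfig(**d)
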