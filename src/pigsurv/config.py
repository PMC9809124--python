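"""Configuration objects for the simulated pig breeding study.

The defaults reproduce the study design: an 18-chromosome genome (100 cM,
3,100 markers and 50 QTLs per chromosome), 300 historical generations from
200 + 200 founders, and 8 recent non-overlapping generations bred from
30 sires x 300 dams with litter sizes {10,12,14,16,18}.  A single ``scale``
factor shrinks the design proportionally for desk-scale work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

TRAIT_PRESETS = ("T_4/4", "T_2/4", "T_2/2")
SCENARIOS = ("G_all", "G80_ran", "G_alive", "G_none")
MODELS = ("LM", "LG", "PM")

LITTER_SIZES = (10, 12, 14, 16, 18)
LITTER_PROBS = (0.02, 0.14, 0.68, 0.14, 0.02)


@dataclass(frozen=True)
class TraitArchitecture:
    """Liability-scale variance architecture of the survival trait.

    Proportions refer to a total liability variance normalised so that the
    sum of the direct genetic, maternal genetic, litter and residual
    variances equals ``total_variance`` (covariance between direct and
    maternal effects is not part of the denominator; see methods note).
    """

    h2_direct: float
    h2_maternal: float
    lit2: float
    r_am: float = 0.30
    total_variance: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h2_direct", "h2_maternal", "lit2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not -1.0 <= self.r_am <= 1.0:
            raise ValueError("r_am must be in [-1,1]")
        if self.var_residual <= 0:
            raise ValueError("residual variance must be positive")

    @property
    def var_direct(self) -> float:
        return self.h2_direct * self.total_variance

    @property
    def var_maternal(self) -> float:
        return self.h2_maternal * self.total_variance

    @property
    def var_litter(self) -> float:
        return self.lit2 * self.total_variance

    @property
    def cov_am(self) -> float:
        return self.r_am * math.sqrt(self.var_direct * self.var_maternal)

    @property
    def var_residual(self) -> float:
        return self.total_variance - (
            self.var_direct + self.var_maternal + self.var_litter
        )

    @classmethod
    def preset(cls, name: str) -> "TraitArchitecture":
        """The three study traits: direct/maternal heritability presets.

        ``T_4/4``: 0.04/0.04, ``T_2/4``: 0.02/0.04, ``T_2/2``: 0.02/0.02;
        litter variance equals the maternal variance, r_am = 0.30.
        """
        table = {
            "T_4/4": (0.04, 0.04, 0.04),
            "T_2/4": (0.02, 0.04, 0.04),
            "T_2/2": (0.02, 0.02, 0.02),
        }
        if name not in table:
            raise KeyError(f"unknown trait preset {name!r}; use one of {TRAIT_PRESETS}")
        h2a, h2m, lit2 = table[name]
        return cls(h2_direct=h2a, h2_maternal=h2m, lit2=lit2)


@dataclass(frozen=True)
class GenomeConfig:
    n_chr: int = 18
    chr_length_cm: float = 100.0
    markers_per_chr: int = 3100
    qtl_per_chr: int = 50

    def __post_init__(self) -> None:
        if self.n_chr < 1 or self.markers_per_chr < 1 or self.qtl_per_chr < 1:
            raise ValueError("genome counts must be positive")
        if self.chr_length_cm < 0:
            raise ValueError("chromosome length must be non-negative")


@dataclass(frozen=True)
class HistoryConfig:
    """Historical LD-building phase: constant-size random mating."""

    n_founder_males: int = 200
    n_founder_females: int = 200
    n_generations: int = 300
    mutation_rate: float = 2.5e-5
    founder_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.n_founder_males < 1 or self.n_founder_females < 1:
            raise ValueError("founder counts must be positive")
        if self.n_generations < 0:
            raise ValueError("number of historical generations must be >= 0")
        if not 0.0 < self.founder_freq < 1.0:
            raise ValueError("founder allele frequency must be in (0,1)")


@dataclass(frozen=True)
class BreedingConfig:
    """Recent 8-generation pedigree with litters and 20% mortality."""

    n_sires: int = 30
    n_dams: int = 300
    dams_per_sire: int = 10
    litter_sizes: tuple = LITTER_SIZES
    litter_probs: tuple = LITTER_PROBS
    n_generations: int = 8
    base_boars: int = 30
    base_sows: int = 200
    mortality: float = 0.20

    def __post_init__(self) -> None:
        if abs(sum(self.litter_probs) - 1.0) > 1e-12:
            raise ValueError("litter size probabilities must sum to 1")
        if len(self.litter_sizes) != len(self.litter_probs):
            raise ValueError("litter size support and probabilities differ in length")
        if self.n_dams != self.n_sires * self.dams_per_sire:
            raise ValueError("n_dams must equal n_sires * dams_per_sire")
        if not 0.0 <= self.mortality < 1.0:
            raise ValueError("mortality must be in [0,1)")

    @property
    def expected_litter_size(self) -> float:
        return float(
            sum(s * p for s, p in zip(self.litter_sizes, self.litter_probs))
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment: trait x genotyping scenarios x models x replicates."""

    trait: str = "T_4/4"
    scenarios: tuple = SCENARIOS
    models: tuple = MODELS
    n_replicates: int = 40
    seed: int = 1
    scale: float = 1.0
    omega: float = 0.2
    analysis_generations: tuple = (5, 6, 7, 8)
    validation_generation: int = 8
    out_dir: str = "results"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    history: HistoryConfig = field(default_factory=HistoryConfig)
    breeding: BreedingConfig = field(default_factory=BreedingConfig)
    glmm_reml_rounds: int = 2

    def __post_init__(self) -> None:
        if self.trait not in TRAIT_PRESETS:
            raise ValueError(f"unknown trait preset {self.trait!r}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0,1]")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0,1]")

    @property
    def architecture(self) -> TraitArchitecture:
        return TraitArchitecture.preset(self.trait)

    @classmethod
    def scaled(cls, factor: float, **overrides) -> "ExperimentConfig":
        """Shrink the whole design by ``factor``.

        Chromosome count, marker/QTL density, historical population size and
        duration, and the breeding design are all reduced proportionally.
        The 8-generation pedigree structure and the litter-size law are part
        of the design and are kept.  Scaling the historical phase by the same
        factor in both population size and duration preserves the drift time
        t/(2Ne), hence the expected fraction of loci still segregating.
        """

        def at_least(n: int, lo: int) -> int:
            return max(lo, int(round(n)))

        # QTL density is floored well above proportional shrinkage so the
        # trait stays polygenic even in miniature genomes; an oligogenic
        # architecture would qualitatively change the genotyping-strategy
        # comparison.
        genome = GenomeConfig(
            n_chr=at_least(18 * factor, 2),
            markers_per_chr=at_least(3100 * factor, 20),
            qtl_per_chr=at_least(50 * factor, 20),
        )
        history = HistoryConfig(
            n_founder_males=at_least(200 * factor, 20),
            n_founder_females=at_least(200 * factor, 20),
            n_generations=at_least(300 * factor, 10),
        )
        n_sires = at_least(30 * factor, 2)
        breeding = BreedingConfig(
            n_sires=n_sires,
            n_dams=n_sires * 10,
            dams_per_sire=10,
            base_boars=n_sires,
            base_sows=at_least(200 * factor, 10),
        )
        kwargs = dict(
            scale=factor, genome=genome, history=history, breeding=breeding
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (
            ("genome", GenomeConfig),
            ("history", HistoryConfig),
            ("breeding", BreedingConfig),
        ):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                for tup_key in ("litter_sizes", "litter_probs"):
                    if tup_key in dd and isinstance(dd[tup_key], list):
                        dd[tup_key] = tuple(dd[tup_key])
                d[key] = sub(**dd)
        for tup_key in ("scenarios", "models", "analysis_generations"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
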