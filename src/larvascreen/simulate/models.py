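"""Statistical models behind the synthetic screen.

The generator reproduces the structure the assay relies on:

* per-larva areas are lognormal with genotype-dependent means — mutant
  homozygotes are ~75% the size of heterozygote siblings when untreated and
  ~50% in-plate on 0.1% v/v DMSO vehicle;
* homozygotes are hypersensitive to DMSO: sizes start declining at 0.025%
  v/v, the maximum tolerated dose is 0.1% v/v, and lethality ramps to 100%
  by 0.4% v/v (heterozygotes are unaffected over this range);
* rare true-hit compounds restore a fraction of the size gap between
  vehicle-treated homozygotes and heterozygotes;
* two artifact processes: uneaten food raising the image background (which
  inflates measured areas) and failed vehicle dispensing (low/no DMSO, which
  yields larger larvae).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SizeModel:
    """Genotype, vehicle-dose and rescue effects on mean larval area.

    Areas are in pixels of the rendered plate images; only ratios matter to
    the screen statistics. ``cv`` is the per-larva coefficient of variation
    of the lognormal area distribution (a well readout is the summed area of
    ``larvae_per_well`` larvae, so well-level noise is smaller by ~1/sqrt(3)).
    """

    het_mean_area: float = 280.0
    genotype_ratio: float = 0.75       # hom/het mean-area ratio, untreated
    vehicle_genotype_ratio: float = 0.5  # hom/het ratio at the in-plate vehicle dose
    cv: float = 0.15
    dmso_onset: float = 0.025          # % v/v below which size is unaffected
    dmso_mtd: float = 0.1              # % v/v maximum tolerated dose (homozygote)
    dmso_lethal: float = 0.4           # % v/v at/above which no homozygote survives
    dmso_hill: float = 1.5
    hit_rescue: float = 0.5            # default gap restoration (hits rescue partially)

    def __post_init__(self) -> None:
        if self.het_mean_area <= 0 or self.cv <= 0:
            raise ValueError("het_mean_area and cv must be positive")
        if not (0 < self.genotype_ratio <= 1 and 0 < self.vehicle_genotype_ratio <= 1):
            raise ValueError("genotype ratios must be in (0, 1]")
        if self.vehicle_genotype_ratio > self.genotype_ratio:
            raise ValueError("vehicle dose cannot increase homozygote size")
        if not (0 <= self.hit_rescue <= 1):
            raise ValueError("hit_rescue must be in [0, 1]")
        if not (0 < self.dmso_onset < self.dmso_mtd < self.dmso_lethal):
            raise ValueError("require 0 < onset < MTD < lethal dose")

    def dmso_size_factor(self, dmso_pct: float) -> float:
        """Multiplicative homozygote size factor at a DMSO dose (% v/v).

        Hill-type decline above the onset dose, calibrated so that at the
        maximum tolerated dose the homozygote/heterozygote ratio equals
        ``vehicle_genotype_ratio``. Monotone non-increasing in dose.
        """
        d = max(0.0, dmso_pct - self.dmso_onset)
        f_mtd = self.vehicle_genotype_ratio / self.genotype_ratio
        if d == 0.0 or f_mtd == 1.0:
            return 1.0
        span = self.dmso_mtd - self.dmso_onset
        k = span * (f_mtd / (1.0 - f_mtd)) ** (1.0 / self.dmso_hill)
        return 1.0 - d ** self.dmso_hill / (k ** self.dmso_hill + d ** self.dmso_hill)

    def hom_survival(self, dmso_pct: float) -> float:
        """Homozygote survival probability under vehicle alone."""
        if dmso_pct <= self.dmso_mtd:
            return 1.0
        if dmso_pct >= self.dmso_lethal:
            return 0.0
        return 1.0 - (dmso_pct - self.dmso_mtd) / (self.dmso_lethal - self.dmso_mtd)

    def mean_area(self, genotype: str, dmso_pct: float = 0.0,
                  rescue: float = 0.0) -> float:
        """Expected per-larva area for a genotype/dose/rescue combination.

        ``rescue`` in [0, 1] moves the homozygote mean toward the
        heterozygote mean at the same dose (heterozygotes are insensitive to
        DMSO over the screened range, so 1.0 restores full sibling size).
        """
        if genotype == "het":
            return self.het_mean_area
        if genotype != "hom":
            raise ValueError(f"unknown genotype {genotype!r}")
        base = self.het_mean_area * self.genotype_ratio * self.dmso_size_factor(dmso_pct)
        return base + rescue * (self.het_mean_area - base)


@dataclass(frozen=True)
class ArtifactModel:
    """Rates and strengths of the two screen artifact processes."""

    p_high_background: float = 0.005   # per-well baseline rate of uneaten food
    food_prone_fraction: float = 0.03  # compounds whose wells retain food
    p_high_background_prone: float = 0.8  # per-replicate rate for prone compounds
    food_blob_contrast: float = 0.22   # peak darkening, fraction of background
    food_blob_extent: float = 0.45     # Gaussian sigma, fraction of well radius
    food_grain: float = 0.8            # speckle modulation depth of the blob
    food_area_inflation_px: float = 200.0  # apparent extra area in the fast path
    p_low_dmso: float = 0.01
    low_dmso_size_boost: float = 1.6   # area multiplier when vehicle is missing

    def __post_init__(self) -> None:
        for p in (self.p_high_background, self.p_low_dmso,
                  self.food_prone_fraction, self.p_high_background_prone):
            if not (0.0 <= p <= 1.0):
                raise ValueError("artifact probabilities must be in [0, 1]")
        if self.low_dmso_size_boost <= 1.0:
            raise ValueError("low_dmso_size_boost must exceed 1")

    @classmethod
    def none(cls) -> "ArtifactModel":
        """Artifact-free configuration (clean wells only)."""
        return cls(p_high_background=0.0, p_low_dmso=0.0,
                   food_prone_fraction=0.0, p_high_background_prone=0.0)


@dataclass(frozen=True)
class ScreenConfig:
    """Shape of a simulated triplicate screen.

    One master seed determines everything; per (replicate, plate) substreams
    are spawned as ``default_rng([rng_seed, replicate, plate])`` so any plate
    is reproducible in isolation.
    """

    n_plates: int = 32
    n_test_wells_per_plate: int = 80
    larvae_per_well: int = 3
    n_replicates: int = 3
    true_hit_ids: tuple[str, ...] = field(default_factory=tuple)
    #: fraction of library compounds that reproducibly stunt or kill larvae
    #: (a bioactive library dosed onto vehicle-sensitised mutants), and the
    #: range of their multiplicative size effects
    toxic_fraction: float = 0.04
    toxic_size_range: tuple[float, float] = (0.35, 0.7)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plates < 1 or self.n_replicates < 1:
            raise ValueError("need at least one plate and one replicate")
        if not (0.0 <= self.toxic_fraction <= 1.0):
            raise ValueError("toxic_fraction must be in [0, 1]")
        if not (1 <= self.n_test_wells_per_plate <= 80):
            raise ValueError("a plate has at most 80 test wells")
        if self.larvae_per_well < 1:
            raise ValueError("need at least one larva per well")
        if not (0 <= self.rng_seed < 2 ** 31):
            raise ValueError("rng_seed must be a non-negative 31-bit integer")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        payload = asdict(self)
        payload["true_hit_ids"] = list(payload["true_hit_ids"])
        payload["toxic_size_range"] = list(payload["toxic_size_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["true_hit_ids"] = tuple(payload.get("true_hit_ids", ()))
        payload["toxic_size_range"] = tuple(payload["toxic_size_range"])
        return cls(**payload)
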