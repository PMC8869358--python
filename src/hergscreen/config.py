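"""Configuration objects for the synthetic generator and the pipeline.

The synthetic generator emulates a quantitative high-throughput screen
(qHTS) of a chemical library against the hERG potassium channel in a
thallium-flux fluorescence assay: every compound is tested as a full
concentration series in triplicate, flanked by DMSO-only (0% activity)
and positive-control (astemizole, -100% activity) wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for every synthetic input the pipeline consumes.

    Defaults mirror the screening design being emulated: 15-point
    concentration series covering four orders of magnitude (top 100 uM),
    triplicate runs, and a mostly-inactive library.
    """

    n_compounds: int = 200
    frac_active: float = 0.25
    conc_points: int = 15
    conc_range_decades: float = 4.0
    top_conc: float = 1e-4          # molar
    noise_sd: float = 0.05          # fraction of the DMSO - poscon signal window
    seed: int = 0
    planted_ic50_range: tuple[float, float] = (1e-7, 1e-5)  # molar
    chemotype_count: int = 100
    n_planted_chemotypes: int = 10
    enrichment_effect: float = 5.0  # odds multiplier for planted chemotypes / SAR rule
    label_noise: float = 0.0        # probability of flipping a molecule label
    # raw-signal plate scale: arbitrary but fixed so normalization is nontrivial
    dmso_level: float = 10000.0
    poscon_level: float = 5000.0
    n_dmso_wells: int = 16
    n_poscon_wells: int = 16
    n_replicates: int = 3
    # bioactivity-record emulation
    duplicate_fraction: float = 0.3
    conflict_fraction: float = 0.1
    censored_fraction: float = 0.1

    def __post_init__(self):
        if self.n_compounds <= 0:
            raise ConfigError("n_compounds must be positive")
        if not 0.0 < self.frac_active < 1.0:
            raise ConfigError("frac_active must lie strictly inside (0, 1)")
        if self.conc_points < 4:
            raise ConfigError("conc_points must be >= 4 (needed for a 4-parameter fit)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.conc_range_decades <= 0 or self.top_conc <= 0:
            raise ConfigError("concentration series must be positive and span > 0 decades")
        lo, hi = self.planted_ic50_range
        if not (0 < lo <= hi):
            raise ConfigError("planted_ic50_range must be a positive molar interval")
        if self.chemotype_count <= 0 or self.n_planted_chemotypes < 0:
            raise ConfigError("chemotype counts must be positive")
        if self.n_planted_chemotypes > self.chemotype_count:
            raise ConfigError("cannot plant more chemotypes than exist")
        if self.enrichment_effect <= 0:
            raise ConfigError("enrichment_effect is an odds multiplier and must be > 0")
        if min(self.n_dmso_wells, self.n_poscon_wells, self.n_replicates) <= 0:
            raise ConfigError("well counts must be positive")
        if self.dmso_level == self.poscon_level:
            raise ConfigError("control levels must differ for normalization to be defined")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Every threshold defaults to the printed value of the analysis it
    re-implements: efficacy cutoff 30%, antagonist rank bin [-9, -5],
    descriptor correlation cap 0.9, 25/75 active/inactive under-sampling
    ratio, AD zone boundaries 2 and 4, external pAffinity cutoff 6.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    # qhts
    efficacy_min: float = 30.0
    fit_alpha: float = 0.05
    # curation
    rho_max: float = 0.9
    ident_frac: float = 0.9
    # clustering
    som_grid: tuple[int, int] = (15, 15)
    som_epochs: int = 10
    # enrichment
    alpha: float = 0.05
    # qsar
    test_frac: float = 0.15
    active_ratio: float = 0.25
    n_subsets: int = 5
    cv_folds: int = 10
    algorithms: tuple[str, ...] = ("RF",)
    undersample: bool = True
    # ad
    ad_var_target: float = 0.80
    ad_border: tuple[float, float] = (2.0, 4.0)
    # integration
    paffinity_min: float = 6.0
    max_log10_gap: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**d["synth"])
        for key in ("som_grid", "ad_border", "algorithms"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = self.synth.to_dict()
        return d
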