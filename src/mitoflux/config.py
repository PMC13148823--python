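"""Generator configuration: group-level ground truth for the synthetic study.

A :class:`GeneratorConfig` holds two (or more) :class:`GroupConfig` blocks —
typically ``benign`` and ``tumor`` — plus shared simulation settings
(chamber geometry, trace sampling, proteome size).  The shipped preset
(:func:`study_preset`) encodes the study conditions: a tumor/benign maximal
(PMDGS) wet-weight flux ratio of 7.0 (inside the reported 4.9–9.9x range),
oligomycin coupling fractions 0.80 (tumor) and 0.55 (benign), reduced tumor
mitochondrial protein content, and detection dropout producing unique/shared
feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import yaml

__all__ = ["GroupConfig", "GeneratorConfig", "study_preset", "load_config"]

# Composite respiratory state vocabulary accepted in true_jo2 ladders.
LADDER_STATES = ("E", "PM", "PMD", "PMDG", "PMDGS", "M", "MD", "MDPC")


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GroupConfig:
    """Ground-truth parameters for one experimental group.

    true_jo2 maps composite state labels to oxygen flux in
    pmol O2 s-1 mg-1 wet weight.  coupling_fraction is the fraction of the
    maximal flux abolished by oligomycin (ATP-synthase inhibition);
    residual_fraction is the fraction remaining after antimycin A + rotenone
    (non-mitochondrial O2 consumption).  content_scale multiplies every
    mitochondrial protein abundance; mito_log2fc is an additional log2 shift
    applied to mitochondrial features on top of content_scale.
    """

    name: str
    n_samples: int
    true_jo2: dict[str, float]
    coupling_fraction: float
    residual_fraction: float = 0.02
    cc_response_fraction: float | None = None  # relative flux change with cytochrome c
    noise_sd: float = 0.2          # Gaussian trace noise, µM
    biological_cv: float = 0.0     # per-sample multiplicative flux variability
    amount_mg: float = 5.0         # tissue per chamber, mg wet weight
    n_omics_samples: int = 6       # proteome/transcriptome/Bradford replicates
    content_scale: float = 1.0
    mito_log2fc: float = 0.0
    complex_log2fc: dict[str, float] = field(default_factory=dict)
    detection_dropout_rate: float = 0.0
    protein_ug_per_mg: float = 80.0  # Bradford: µg total protein per mg wet weight
    protein_cv: float = 0.10

    def validate(self) -> "GroupConfig":
        if self.n_samples < 2:
            raise ConfigError(f"group {self.name}: n_samples must be >= 2")
        for frac_name in ("coupling_fraction", "residual_fraction",
                          "detection_dropout_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"group {self.name}: {frac_name}={v} not in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError(f"group {self.name}: noise_sd must be >= 0")
        if self.biological_cv < 0:
            raise ConfigError(f"group {self.name}: biological_cv must be >= 0")
        if self.n_omics_samples < 2:
            raise ConfigError(f"group {self.name}: n_omics_samples must be >= 2")
        if self.amount_mg <= 0 or self.protein_ug_per_mg <= 0:
            raise ConfigError(f"group {self.name}: amounts must be positive")
        if self.content_scale <= 0:
            raise ConfigError(f"group {self.name}: content_scale must be positive")
        for state, j in self.true_jo2.items():
            if state not in LADDER_STATES:
                raise ConfigError(f"group {self.name}: unknown state '{state}'")
            if j < 0:
                raise ConfigError(f"group {self.name}: true_jo2[{state}] < 0")
        # the substrate ladder must be monotone non-decreasing
        ladder = [s for s in ("E", "PM", "PMD", "PMDG", "PMDGS") if s in self.true_jo2]
        vals = [self.true_jo2[s] for s in ladder]
        if any(a > b for a, b in zip(vals, vals[1:])):
            raise ConfigError(f"group {self.name}: state ladder not monotone: {vals}")
        return self


@dataclass
class GeneratorConfig:
    groups: dict[str, GroupConfig]
    n_features: int = 1000
    frac_mito: float = 0.15
    abundance_sigma: float = 0.25   # natural-log multiplicative noise sd
    dropout_mode: str = "uniform"   # "uniform" Bernoulli or "censor" (detection limit)
    chamber_volume_ml: float = 2.0
    o2_start_uM: float = 180.0
    dt_s: float = 2.0               # trace sampling interval
    state_duration_s: float = 240.0
    n_technical_replicates: int = 2
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_features < 10:
            raise ConfigError("n_features must be >= 10")
        if not 0.0 <= self.frac_mito <= 1.0:
            # the degenerate endpoints 0 and 1 are permitted but flagged with
            # a warning in simulate_proteome output metadata
            raise ConfigError("frac_mito must be in [0, 1]")
        if self.dropout_mode not in ("uniform", "censor"):
            raise ConfigError("dropout_mode must be 'uniform' or 'censor'")
        if self.chamber_volume_ml <= 0 or self.dt_s <= 0 or self.state_duration_s <= 0:
            raise ConfigError("chamber volume, dt and state duration must be positive")
        if self.noise_free_points_per_state() < 3:
            raise ConfigError("state_duration_s too short for the sampling interval")
        for g in self.groups.values():
            g.validate()
        return self

    def noise_free_points_per_state(self) -> int:
        return int(self.state_duration_s / self.dt_s)

    def to_dict(self) -> dict:
        return asdict(self)


def _group_from_dict(name: str, d: dict) -> GroupConfig:
    return GroupConfig(name=name, **d)


def load_config(source) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML mapping, path or file object."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    raw = dict(raw)
    raw.pop("version", None)
    groups = {name: _group_from_dict(name, d) for name, d in raw.pop("groups").items()}
    return GeneratorConfig(groups=groups, **raw).validate()


def study_preset(seed: int = 0) -> GeneratorConfig:
    """The shipped benign-vs-tumor preset (see data/presets.yaml)."""
    text = resources.files("mitoflux.data").joinpath("presets.yaml").read_text()
    cfg = load_config(yaml.safe_load(text))
    cfg.seed = seed
    return cfg
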