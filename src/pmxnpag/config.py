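"""Pipeline configuration: one YAML file with per-command sections.

Every default equals the constant documented in its owning module; the
config only overrides them.  ``PipelineConfig`` round-trips through YAML
(`from_yaml` / `to_yaml`) and builds the domain objects each command needs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .cohort import DEFAULT_LLOQ

__all__ = ["PipelineConfig"]


@dataclass
class SimSection:
    n_subjects: int = 22
    samples_per_subject: int = 3
    total_samples: int | None = 64
    sampling_mode: str = "sparse"
    seed: int = 20220901
    truth_covariates: bool = True      # generate with the final covariate model


@dataclass
class ModelSection:
    compartments: int = 2
    c0: float = 0.1
    c1: float = 0.15
    c2: float = 0.0
    c3: float = 0.0
    gamma_start: float = 5.0
    lloq: float = DEFAULT_LLOQ


@dataclass
class SpaceSection:
    # bounds as {name: [lower, upper]}; empty -> module defaults
    bounds: dict = field(default_factory=dict)


@dataclass
class NpagSection:
    n_initial: int | None = None
    max_cycles: int = 100
    tol: float = 0.01
    seed: int = 0


@dataclass
class CovariateSection:
    # candidate effects as {target, covariate, reference, exponent} dicts
    candidates: list = field(default_factory=lambda: [
        {"target": "CL", "covariate": "alb", "reference": 31.45,
         "exponent": -0.95},
        {"target": "V", "covariate": "age", "reference": 68.0,
         "exponent": 0.95},
    ])
    recenter: bool = False


@dataclass
class ValidateSection:
    bootstrap_B: int = 200
    vpc_n_sim: int = 1000
    vpc_bins: int = 6
    split_fraction: float = 0.8
    seed: int = 0


@dataclass
class PtaSection:
    n: int = 1000
    mic: float = 1.0
    seed: int = 0
    mode: str = "published"            # "published" | "fitted"


@dataclass
class PipelineConfig:
    sim: SimSection = field(default_factory=SimSection)
    model: ModelSection = field(default_factory=ModelSection)
    space: SpaceSection = field(default_factory=SpaceSection)
    npag: NpagSection = field(default_factory=NpagSection)
    covariates: CovariateSection = field(default_factory=CovariateSection)
    validate: ValidateSection = field(default_factory=ValidateSection)
    pta: PtaSection = field(default_factory=PtaSection)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {f.name: _build(f, d.get(f.name, {}))
                    for f in dataclasses.fields(cls)}
        return cls(**sections)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # ---- object builders ----------------------------------------------
    def make_error(self):
        from .error import ErrorSpec
        m = self.model
        return ErrorSpec(m.c0, m.c1, m.c2, m.c3, m.gamma_start)

    def make_model(self, covariate_model=None):
        from .covariates import CovariateModel
        from .npag import ModelSpec
        return ModelSpec(compartments=self.model.compartments,
                         covariates=covariate_model or CovariateModel(),
                         error=self.make_error())

    def make_space(self):
        from .npag import ParameterSpace, default_space
        base = default_space(self.model.compartments)
        if not self.space.bounds:
            return base
        lo = base.lower.copy()
        up = base.upper.copy()
        for i, n in enumerate(base.names):
            if n in self.space.bounds:
                lo[i], up[i] = self.space.bounds[n]
        return ParameterSpace(base.names, lo, up)

    def make_npag_config(self, seed: int | None = None):
        from .npag import NpagConfig
        s = self.npag
        return NpagConfig(n_initial=s.n_initial, max_cycles=s.max_cycles,
                          tol=s.tol, seed=s.seed if seed is None else seed)

    def make_design(self):
        from .covariates import CovariateModel
        from .synth import CohortDesign
        design = CohortDesign(n_subjects=self.sim.n_subjects,
                              samples_per_subject=self.sim.samples_per_subject,
                              total_samples=self.sim.total_samples,
                              sampling_mode=self.sim.sampling_mode,
                              lloq=self.model.lloq)
        if not self.sim.truth_covariates:
            design.truth_covariates = CovariateModel()
        return design

    def make_candidates(self):
        from .covariates import CovariateEffect
        return [CovariateEffect(**c) for c in self.covariates.candidates]


def _build(f: dataclasses.Field, sub: dict):
    cls = f.default_factory().__class__
    return cls(**(sub or {}))
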