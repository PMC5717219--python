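"""Run configuration: every user-fixed model parameter in one place.

Mirrors what the model asks its user to specify up front — number of
biopsies (implied by the site table), clone count |Z| (or automatic
selection), maximum copy number, prevalence grid size, initial log-ratio
offsets — plus numerical knobs for the fitting pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import yaml


@dataclass(frozen=True)
class RunConfig:
    #: clone count |Z|, or "auto" to select by BIC/CV
    n_clones: Union[int, str] = 2
    #: maximum tumor copy number; the genotype space holds all (n, alt) pairs up to it
    c_max: int = 5
    #: size of the discrete prevalence grid (levels 1/|P| .. 1.00)
    n_prevalence_levels: int = 20
    #: initial per-biopsy log-ratio offsets c_m; None = estimate from the data
    offsets: Optional[Sequence[float]] = None
    #: master seed for anything stochastic downstream (CV folds, simulation)
    seed: int = 0
    #: EM convergence: stop when the log likelihood improves by less than tol
    tol: float = 1e-4
    max_iter: int = 100
    #: shorter EM refresh after the prevalence levels move
    refresh_iter: int = 20
    #: prevalence search: "auto" | "exhaustive" | "icm"
    prevalence_mode: str = "auto"
    icm_sweeps: int = 10
    #: minimum separation between clone levels, in grid steps (clones closer
    #: than two steps are treated as indiscernible)
    min_level_gap: int = 2
    #: rerun the whole fit when the recalibrated offset moves by more than this
    cm_refit_threshold: float = 0.01
    #: clone-number selection strategy when n_clones == "auto"
    selection_strategy: str = "bic"
    n_clones_start: int = 2
    n_clones_max: int = 6
    cv_folds: int = 3
    #: multi-biopsy joint analysis
    merge_threshold: float = 0.8
    min_shared_events: int = 5
    joint_max_iter: int = 30
    #: identifiability guard for near-null states: (reference sigma_A,
    #: reference sigma_L, squared combined effect-size threshold)
    min_effect: tuple = (0.05, 0.2, 1.0)
    #: baseline-style ablations: tie/fix transition decay, drop the SNV sites
    estimate_transitions: bool = True
    include_somatic: bool = True

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes) if changes else self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["offsets"] is not None:
            d["offsets"] = list(map(float, d["offsets"]))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
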