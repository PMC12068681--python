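"""Run and prior configuration for the multilevel HMM pipeline."""

from __future__ import annotations

import dataclasses
from typing import Sequence

__all__ = ["PriorConfig", "RunConfig"]


@dataclasses.dataclass
class PriorConfig:
    """Weakly informative hyperpriors on the 0-100 diary scale.

    Emission group means get Normal(loc, scale^2) priors; all variance
    components get scaled-inverse-chi-square(df, scale2) priors; transition
    logit group means and covariate coefficients get Normal(0, 9), wide on
    the logit scale.
    """

    emission_mean_loc: float = 50.0
    emission_mean_scale: float = 100.0
    between_var_df: float = 1.0
    between_var_scale2: float = 100.0
    resid_var_df: float = 1.0
    resid_var_scale2: float = 100.0
    logit_mean_var: float = 9.0
    logit_var_df: float = 3.0
    logit_var_scale2: float = 1.0
    coef_var: float = 9.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"prior hyperparameter {f.name} must be > 0")


@dataclasses.dataclass
class RunConfig:
    """End-to-end run settings mirroring the study protocol defaults."""

    seed: int
    m_range: Sequence[int] = (2, 3, 4, 5, 6)
    item_subset: Sequence[str] | None = None
    iterations: int = 4000
    burn_in: int = 1000
    n_extra_chains: int = 2
    priors: PriorConfig = dataclasses.field(default_factory=PriorConfig)
    ppc_reps: int = 500
    aux_threshold: float = 4.0
    mpsrf_threshold: float = 1.05

    def validate(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if any(m < 2 for m in self.m_range):
            raise ValueError("candidate state counts must be >= 2")
        self.priors.validate()
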