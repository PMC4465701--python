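"""Analysis-wide configuration.

A single :class:`AnalysisConfig` travels through every stochastic stage so
that randomization counts, the significance rule and the RNG seed are
recorded once and echoed into every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Knobs shared by the randomization / permutation machinery.

    Parameters
    ----------
    n_randomizations_structure :
        Number of tip-label randomizations for the NRI/NTI null
        distributions (default 9999).
    n_permutations_convergence :
        Permutations for the trait-convergence matrix correlations
        rho(TE) and rho(PT) (default 9999).
    n_permutations_dsep :
        Permutations for the partial correlation rho(TE.P) used in the
        d-separation step (default 999).
    seed :
        Seed for all randomness; recorded in every result object.
    z_critical :
        Two-sided normal critical value used to flag significant NRI/NTI
        (default 1.96).
    alpha :
        Significance level for permutation p-values (default 0.05).
    """

    n_randomizations_structure: int = 9999
    n_permutations_convergence: int = 9999
    n_permutations_dsep: int = 999
    seed: int = 0
    z_critical: float = 1.96
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_randomizations_structure", "n_permutations_convergence",
                     "n_permutations_dsep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def rng(self, offset: int = 0) -> np.random.Generator:
        """A fresh generator derived from the configured seed.

        ``offset`` decouples independent stages so that, e.g., the
        structure nulls and the convergence permutations do not share a
        stream.
        """
        return np.random.default_rng(np.random.SeedSequence([self.seed, offset]))

    def as_dict(self) -> dict:
        return asdict(self)
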