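"""Entry-mean phenotype simulation at a target heritability.

Phenotypes are simulated per environment (default 3, one replication each)
by adding independent normal deviations to the true genotypic values, with
no residual covariance between traits.  The per-environment residual
variance is n_env * sigma2_G * (1 - h2) / h2, so the entry mean (the average
over environments) carries error variance sigma2_G * (1 - h2) / h2 and the
expected entry-mean heritability equals the target h2.  sigma2_G is the
realized (population) genetic variance of the current population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import GenotypicValues

__all__ = ["PhenotypeRecord", "simulate_phenotypes"]


@dataclass
class PhenotypeRecord:
    """Per-environment and entry-mean phenotypes for two traits."""

    individual_id: list
    env_values: np.ndarray  # (n, n_env, 2)
    entry_means: np.ndarray  # (n, 2)
    n_environments: int
    target_heritability: tuple

    def to_frame(self) -> pd.DataFrame:
        """Long table: line_id, trait, env, value."""
        n, e, _ = self.env_values.shape
        rows = []
        for t in (1, 2):
            for j in range(e):
                rows.append(
                    pd.DataFrame(
                        {
                            "line_id": self.individual_id,
                            "trait": t,
                            "env": j + 1,
                            "value": self.env_values[:, j, t - 1],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def simulate_phenotypes(
    gv: GenotypicValues,
    h2,
    n_env: int = 3,
    seed=None,
    ids=None,
) -> PhenotypeRecord:
    """Simulate entry-mean phenotypes for both traits at heritabilities h2.

    ``h2`` is a scalar or per-trait pair in (0, 1].  h2=1 returns the
    genotypic values exactly.  Residuals are independent across traits and
    environments.
    """
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (2,)).copy()
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("heritability must be in (0, 1]")
    if np.any((gv.variances == 0) & (h2 < 1)):
        raise ValueError("zero genetic variance with h2 < 1")
    rng = np.random.default_rng(seed)
    n = gv.n_individuals

    env_sd = np.sqrt(n_env * gv.variances * (1.0 - h2) / h2)  # per-trait
    noise = rng.standard_normal((n, n_env, 2)) * env_sd
    env_values = gv.values[:, None, :] + noise
    entry_means = env_values.mean(axis=1)
    exact = env_sd == 0  # h2=1: phenotype equals the genotypic value exactly
    entry_means[:, exact] = gv.values[:, exact]
    if ids is None:
        ids = [f"I{k + 1}" for k in range(n)]
    return PhenotypeRecord(
        individual_id=list(ids),
        env_values=env_values,
        entry_means=entry_means,
        n_environments=n_env,
        target_heritability=tuple(h2),
    )
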