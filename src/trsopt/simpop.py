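"""Synthetic structured panels with known truth for testing and benchmarking.

Emulates a diversity panel of inbred-like lines split into K subpopulations
with divergent allele frequencies.  Ancestral frequencies are uniform on
(0.05, 0.95); each subpopulation draws its frequency from a Balding-Nichols
beta distribution around the ancestral value with differentiation parameter
Fst (variance Fst * p(1-p)).  Genotypes are independent across markers given
the subpopulation frequencies: fully inbred lines carry 0/2 calls (the
default, matching selfing crops), outbred mode draws Binomial(2, p).

Traits are polygenic: ``n_qtl`` causal markers receive i.i.d. Gaussian
effects, the residual variance is set from the realized genetic variance so
the phenotype hits the target narrow-sense heritability, and with
``structure_aligned=True`` causal markers are drawn preferentially among
those with large between-subpopulation frequency differences, making the
trait covary with the structure (the regime in which stratified sampling is
expected to shine).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geno_io import MarkerMatrix, PhenotypeTable


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one synthetic panel."""

    k: int
    n_per_subpop: tuple[int, ...]
    m: int = 1000
    fst: float = 0.0
    h2: float = 0.8
    n_qtl: int = 100
    structure_aligned: bool = False
    inbred: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_subpop", tuple(int(n) for n in self.n_per_subpop))
        if self.k != len(self.n_per_subpop):
            raise ValueError("k must equal len(n_per_subpop)")
        if any(n <= 0 for n in self.n_per_subpop):
            raise ValueError("subpopulation sizes must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if not 0 < self.n_qtl <= self.m:
            raise ValueError(f"n_qtl must be in (0, m={self.m}]")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_subpop)

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


@dataclass
class SimulatedPopulation:
    """A simulated panel: genotypes, subpopulation truth, TBV and phenotypes."""

    markers: MarkerMatrix
    subpop_of: dict[str, int]
    tbv: pd.Series
    phenotype: pd.Series
    realized_h2: float
    ancestral_freq: np.ndarray
    subpop_freq: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    params: SimParams

    @property
    def ids(self) -> tuple[str, ...]:
        return self.markers.individual_ids

    def phenotype_table(self, trait: str = "trait") -> PhenotypeTable:
        df = pd.DataFrame({"id": list(self.phenotype.index), "trait": trait,
                           "value": self.phenotype.to_numpy()})
        return PhenotypeTable(df)


def simulate_panel(params: SimParams) -> SimulatedPopulation:
    """Draw one structured panel with a polygenic trait at the target heritability."""
    rng = np.random.default_rng(params.seed)
    m, K = params.m, params.k
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if params.fst > 0:
        F = params.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a, b, size=(K, m))
    else:
        p_sub = np.tile(p_anc, (K, 1))

    blocks = []
    subpops = []
    for s, n_s in enumerate(params.n_per_subpop):
        if params.inbred:
            X_s = 2.0 * (rng.random((n_s, m)) < p_sub[s])
        else:
            X_s = rng.binomial(2, p_sub[s], size=(n_s, m)).astype(float)
        blocks.append(X_s)
        subpops.extend([s + 1] * n_s)
    X = np.vstack(blocks)
    n = X.shape[0]
    ids = tuple(f"g{i:04d}" for i in range(n))

    if params.structure_aligned and K > 1:
        # bias causal markers toward those most divergent among subpopulations
        weight = p_sub.var(axis=0) + 1e-12
        weight = weight / weight.sum()
        qtl = rng.choice(m, size=params.n_qtl, replace=False, p=weight)
    else:
        qtl = rng.choice(m, size=params.n_qtl, replace=False)
    effects = rng.normal(0.0, 1.0, size=params.n_qtl)
    tbv = X[:, qtl] @ effects
    tbv = tbv - tbv.mean()
    var_g = float(tbv.var(ddof=1))
    if var_g <= 0:
        raise ValueError("degenerate trait: all causal markers monomorphic in the panel")
    if params.h2 >= 1.0:
        noise = np.zeros(n)
    else:
        var_e = var_g * (1.0 - params.h2) / params.h2
        noise = rng.normal(0.0, np.sqrt(var_e), size=n)
    pheno = tbv + noise
    realized = var_g / float(pheno.var(ddof=1))

    markers = MarkerMatrix(ids, tuple(f"m{j:05d}" for j in range(m)), X)
    return SimulatedPopulation(
        markers=markers,
        subpop_of={g: s for g, s in zip(ids, subpops)},
        tbv=pd.Series(tbv, index=list(ids)),
        phenotype=pd.Series(pheno, index=list(ids)),
        realized_h2=realized,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
        qtl_indices=qtl,
        qtl_effects=effects,
        params=params,
    )


def realized_fst(pop: SimulatedPopulation) -> float:
    """Mean over markers of var(subpopulation frequency) / p(1-p) around the ancestral p."""
    p = pop.ancestral_freq
    dev2 = np.mean((pop.subpop_freq - p) ** 2, axis=0)
    return float(np.mean(dev2 / (p * (1.0 - p))))


def make_scenarios() -> dict[str, SimParams]:
    """Named presets spanning the structure regimes of interest.

    ``mild``: four subpopulations with modest divergence (wheat-like panel,
    subpopulation shares 516:350:154:107 scaled to 300 lines).  ``strong``:
    three sharply diverged subpopulations with a structure-aligned trait
    (rice-like panel, shares 145:127:99 scaled to 230 lines).
    ``unstructured``: a single panmictic group.  Each preset carries a
    documented default seed; override with :meth:`SimParams.with_seed`.
    """
    return {
        "mild": SimParams(k=4, n_per_subpop=(137, 93, 41, 29), m=1000, fst=0.08,
                          h2=0.8, n_qtl=100, structure_aligned=False, inbred=True, seed=101),
        "strong": SimParams(k=3, n_per_subpop=(90, 79, 61), m=1000, fst=0.30,
                            h2=0.8, n_qtl=100, structure_aligned=True, inbred=True, seed=102),
        "unstructured": SimParams(k=1, n_per_subpop=(500,), m=1000, fst=0.0,
                                  h2=0.8, n_qtl=100, structure_aligned=False, inbred=True, seed=103),
    }
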