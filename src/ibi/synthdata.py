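"""Synthetic genotype/phenotype generator with subgroup-specific causal variants.

The generator emulates the statistical shape the individualized scoring model
assumes: thousands of subjects, a panel of independent dominant-coded SNPs
with MAF in [0.01, 0.5], and a binary trait produced by a penetrance model in
which a low-frequency variant can act only in its (possibly further
restricted) carrier subgroup while a common variant drives the remaining
population.  Genotypes are generated directly in dominant coding — the value
of SNP j is Bernoulli(1 - (1 - m_j)^2), the carrier probability implied by
Hardy-Weinberg at allele frequency m_j.

Causal specifications are evaluated in list order and the first matching one
wins, which makes the generative model unambiguous: a subject's trait
probability is the penetrance of the first spec whose carrier condition holds,
or the baseline prevalence if none match.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ibi.types import GenotypeMatrix, TraitVector

__all__ = [
    "CausalSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "gen_genotypes",
    "gen_phenotypes",
    "simulate",
    "ab_scenario",
    "write_dataset",
]

# distinct streams for genotype vs phenotype draws under one config seed
_GENO_STREAM = 11
_PHENO_STREAM = 13


@dataclass(frozen=True)
class CausalSpec:
    """One causal variant: carriers of ``snp_index`` develop the trait with
    probability ``carrier_penetrance``.  If ``restricted_to_subgroup`` is set,
    the effect applies only to subjects also carrying that SNP.  ``maf``
    optionally pins the allele frequency of the causal SNP instead of drawing
    it from the config's MAF range."""

    snp_index: int
    carrier_penetrance: float
    restricted_to_subgroup: int | None = None
    maf: float | None = None


@dataclass
class SimulationConfig:
    n_subjects: int = 2000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal_specs: list[CausalSpec] = field(default_factory=list)
    baseline_prevalence: float = 0.1
    seed: int = 0
    #: optional LD blocks: each odd column becomes a copy of its left
    #: neighbour with entries flipped independently with this probability
    ld_flip_prob: float | None = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if not 0 <= self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in [0, 1)")
        self.causal_specs = [
            c if isinstance(c, CausalSpec) else CausalSpec(**c)
            for c in self.causal_specs
        ]
        for c in self.causal_specs:
            for idx in (c.snp_index, c.restricted_to_subgroup):
                if idx is not None and not 0 <= idx < self.n_snps:
                    raise ValueError(f"causal SNP index {idx} out of range")
            if not 0 <= c.carrier_penetrance <= 1:
                raise ValueError("penetrance must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset, reproducible from (config, seed).

    ``subgroup`` holds, per subject, the index into ``config.causal_specs`` of
    the matching spec (-1 when the baseline applied); ``trait_prob`` the
    realized per-subject trait probability; ``carrier`` the carrier indicator
    for each causal SNP.
    """

    config: SimulationConfig
    subgroup: np.ndarray
    trait_prob: np.ndarray
    carrier: dict[int, np.ndarray]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "subgroup": self.subgroup.tolist(),
                "trait_prob": self.trait_prob.tolist(),
                "carrier": {str(k): v.tolist() for k, v in self.carrier.items()},
            }
        )


def gen_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate the dominant-coded genotype matrix for ``config``.

    Deterministic under ``config.seed``; SNPs are independent unless
    ``ld_flip_prob`` is set.
    """
    rng = np.random.default_rng([config.seed, _GENO_STREAM])
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    for c in config.causal_specs:
        if c.maf is not None:
            mafs[c.snp_index] = c.maf
    carrier_p = 1.0 - (1.0 - mafs) ** 2
    values = (rng.random((config.n_subjects, config.n_snps)) < carrier_p).astype(
        np.int8
    )
    if config.ld_flip_prob is not None:
        eps = config.ld_flip_prob
        for j in range(1, config.n_snps, 2):
            flip = rng.random(config.n_subjects) < eps
            values[:, j] = np.where(flip, 1 - values[:, j - 1], values[:, j - 1])
            mafs[j] = mafs[j - 1]
    snps = pd.DataFrame(
        {
            "rsid": [f"rs{j:06d}" for j in range(config.n_snps)],
            "chrom": ["1"] * config.n_snps,
            "pos": np.arange(config.n_snps, dtype=np.int64) * 10_000 + 1,
            "maf": mafs,
        }
    )
    subjects = np.array([f"S{i:06d}" for i in range(config.n_subjects)])
    return GenotypeMatrix(values=values, snps=snps, subjects=subjects)


def gen_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[TraitVector, SyntheticTruth]:
    """Draw the binary trait from the penetrance model; first matching causal
    spec wins, everyone else is at baseline prevalence."""
    if genotypes.n_subjects != config.n_subjects or genotypes.n_snps != config.n_snps:
        raise ValueError("genotypes are inconsistent with the simulation config")
    rng = np.random.default_rng([config.seed, _PHENO_STREAM])
    g = genotypes.values
    prob = np.full(config.n_subjects, config.baseline_prevalence)
    subgroup = np.full(config.n_subjects, -1, dtype=np.int64)
    carrier: dict[int, np.ndarray] = {}
    assigned = np.zeros(config.n_subjects, dtype=bool)
    for k, spec in enumerate(config.causal_specs):
        cond = g[:, spec.snp_index] == 1
        if spec.restricted_to_subgroup is not None:
            cond &= g[:, spec.restricted_to_subgroup] == 1
        carrier[spec.snp_index] = cond.astype(np.int8)
        match = cond & ~assigned
        prob[match] = spec.carrier_penetrance
        subgroup[match] = k
        assigned |= match
    htn = (rng.random(config.n_subjects) < prob).astype(np.int8)
    trait = TraitVector(htn=htn, subjects=genotypes.subjects)
    truth = SyntheticTruth(
        config=config, subgroup=subgroup, trait_prob=prob, carrier=carrier
    )
    return trait, truth


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, TraitVector, SyntheticTruth]:
    genotypes = gen_genotypes(config)
    trait, truth = gen_phenotypes(genotypes, config)
    return genotypes, trait, truth


def ab_scenario(
    seed: int,
    n_subjects: int = 5000,
    n_snps: int = 500,
    a_index: int = 37,
    b_index: int = 211,
) -> SimulationConfig:
    """The two-subpopulation benchmark scenario.

    A rare variant A (carrier frequency ~0.03, i.e. MAF ~0.015) causes the
    trait with penetrance 0.9 in its carriers; a common variant B (carrier
    frequency ~0.5, MAF ~0.293) acts with penetrance 0.4 in the remaining
    population; everyone else is at baseline prevalence 0.1.  This is the
    structure the partitioned score is designed to recover: A should top the
    M_s,r ranking even though B dominates the population-level M_s.
    """
    return SimulationConfig(
        n_subjects=n_subjects,
        n_snps=n_snps,
        maf_range=(0.01, 0.5),
        causal_specs=[
            CausalSpec(snp_index=a_index, carrier_penetrance=0.9, maf=0.0151),
            CausalSpec(snp_index=b_index, carrier_penetrance=0.4, maf=0.2929),
        ],
        baseline_prevalence=0.1,
        seed=seed,
    )


def write_dataset(
    outdir: str | Path,
    genotypes: GenotypeMatrix,
    trait: TraitVector,
    truth: SyntheticTruth | None = None,
) -> None:
    """Write genotypes/phenotypes in the package's tab-delimited format.

    ``genotypes.tsv``: subject_id column then one 0/1 column per rsID;
    ``snps.tsv``: per-SNP metadata; ``pheno.csv``: subject_id and HTN;
    ``truth.json``: the generative ground truth, when given.
    """
    from ibi import io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_genotypes(outdir / "genotypes.tsv", genotypes)
    io.write_phenotypes(outdir / "pheno.csv", trait)
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
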