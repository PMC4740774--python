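"""Synthetic genotype and metadata generation under an island model.

The generator emulates the sampling regime the downstream analysis assumes:
``n_demes`` geographic subpopulations whose allele frequencies diverge from a
common ancestral frequency under the Balding–Nichols model, with the
subpopulation frequency at each biallelic variant drawn from

    Beta(p (1 - F) / F,  (1 - p) (1 - F) / F)

around the ancestral frequency ``p``, where ``F`` is the differentiation
coefficient (``F = 0`` collapses to panmixia: every deme uses ``p`` exactly).
Ancestral frequencies are uniform on [0.1, 0.9] so variants are rarely
monomorphic by construction; simulated monomorphic variants are nevertheless
retained — downstream filtering must cope with them.

Each sample is one diploid unphased genotype drawn binomially from its deme
frequency; missingness is applied independently per call.  Metadata carries a
``deme`` label (tracking the true deme, or shuffled across samples for a null
dataset), a binary ``elevation`` variable derived from deme parity, and any
number of nuisance labels drawn independently of structure.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .matrix import GenotypeMatrix
from .metadata import SampleMetadata


class LabelMode(str, Enum):
    """Whether categorical labels track demes (signal) or are shuffled (null)."""

    linked = "linked"
    shuffled = "shuffled"


class SimulationConfig(BaseModel):
    """Parameters of one simulated dataset.

    ``differentiation`` is the Balding–Nichols F in [0, 1); ``missing_rate``
    is the independent per-genotype probability of an uncalled genotype.
    ``nuisance_labels`` lists ``(name, n_levels)`` metadata variables drawn
    independently of deme (emulating swabbed-object / swabbed-material style
    annotations).  Identical config + seed reproduces identical output.
    """

    n_demes: int = Field(ge=1)
    samples_per_deme: int = Field(ge=1)
    n_variants: int = Field(ge=1)
    differentiation: float = Field(ge=0.0, lt=1.0)
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    label_mode: LabelMode = LabelMode.linked
    nuisance_labels: list[tuple[str, int]] = Field(default_factory=list)
    seed: int

    @field_validator("nuisance_labels")
    @classmethod
    def _levels_positive(cls, v):
        for name, n_levels in v:
            if n_levels < 1:
                raise ValueError(f"nuisance_labels: {name!r} needs n_levels >= 1")
        return v


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Draw one dataset; deterministic given ``config`` (including seed).

    Independent random sub-streams are derived from the master seed for each
    stage (frequencies, genotypes, missingness, labels) so that, e.g.,
    changing the missing rate does not perturb the genotypes drawn.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_geno, rng_miss, rng_label = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n_samples = config.n_demes * config.samples_per_deme
    deme_of = np.repeat(np.arange(config.n_demes), config.samples_per_deme)

    p_anc = rng_freq.uniform(0.1, 0.9, size=config.n_variants)
    F = config.differentiation
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        deme_freq = rng_freq.beta(a, b, size=(config.n_demes, config.n_variants))
    else:
        deme_freq = np.broadcast_to(p_anc, (config.n_demes, config.n_variants))

    # alt-allele dosage 0/1/2 maps directly onto the unordered-pair codes
    # for a biallelic variant: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2
    calls = rng_geno.binomial(2, deme_freq[deme_of, :]).astype(np.int32)
    if config.missing_rate > 0:
        miss = rng_miss.random(calls.shape) < config.missing_rate
        calls[miss] = -1

    sample_ids = [
        f"D{d + 1}S{k + 1}"
        for d in range(config.n_demes)
        for k in range(config.samples_per_deme)
    ]
    variants = pd.DataFrame(
        {
            "chrom": ["sim1"] * config.n_variants,
            "pos": np.arange(1, config.n_variants + 1) * 10,
            "ref": ["A"] * config.n_variants,
            "alt": [("T",)] * config.n_variants,
        }
    )
    matrix = GenotypeMatrix(sample_ids, variants, calls)

    deme_labels = np.array([f"deme{d + 1}" for d in deme_of])
    if config.label_mode == LabelMode.shuffled:
        deme_labels = rng_label.permutation(deme_labels)
    label_idx = np.array([int(lbl[4:]) - 1 for lbl in deme_labels])
    elevation = np.where(label_idx % 2 == 0, "above", "below")

    cols: dict[str, object] = {"deme": deme_labels, "elevation": elevation}
    for name, n_levels in config.nuisance_labels:
        draws = rng_label.integers(n_levels, size=n_samples)
        cols[name] = [f"{name}{i + 1}" for i in draws]
    table = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample"))
    return matrix, SampleMetadata(table)
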