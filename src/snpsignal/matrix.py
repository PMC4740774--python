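"""Genotype matrices from multi-sample VCFs and the completeness filter.

The central container is :class:`GenotypeMatrix`: a samples x variants table
of *unordered* categorical genotype codes with explicit missingness.  Genotypes
are treated as nominal states (no additive dosage): downstream parsimony step
counting and Hamming distances only ask whether two calls are equal, so an
unphased diploid genotype is encoded as the unordered allele pair.

Codes
-----
For a sorted allele pair ``(i, j)`` with ``i <= j`` (0 = REF, 1.. = ALT order)
the code is ``j * (j + 1) // 2 + i``::

    0/0 -> 0    0/1 -> 1    1/1 -> 2    0/2 -> 3    1/2 -> 4    2/2 -> 5 ...

Missing calls (``./.`` or any half-call) are ``MISSING`` (-1).  The encoding
extends to any number of ALT alleles and keeps distinct heterozygotes
(e.g. 0/1 vs 1/2) as distinct categories.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .metadata import SampleMetadata

logger = logging.getLogger(__name__)

MISSING = -1

#: symbols used when exporting codes to PHYLIP/NEXUS character matrices
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def genotype_code(a: int, b: int) -> int:
    """Unordered-category code for a diploid genotype with alleles ``a``, ``b``.

    Returns ``MISSING`` if either allele is negative (uncalled).
    """
    if a < 0 or b < 0:
        return MISSING
    i, j = (a, b) if a <= b else (b, a)
    return j * (j + 1) // 2 + i


def decode_genotype(code: int) -> tuple[int, int]:
    """Inverse of :func:`genotype_code`; ``MISSING`` maps to ``(-1, -1)``."""
    if code < 0:
        return (-1, -1)
    j = int((math.isqrt(8 * code + 1) - 1) // 2)
    i = code - j * (j + 1) // 2
    return (i, j)


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of categorical genotype codes.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows).
    variants
        One row per variant with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` (tuple of ALT allele strings).
    calls
        ``(n_samples, n_variants)`` integer array of genotype codes,
        ``MISSING`` (-1) for uncalled genotypes.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        for vi, alt in enumerate(self.variants["alt"]):
            n_alleles = 1 + len(alt)
            max_code = genotype_code(n_alleles - 1, n_alleles - 1)
            col = self.calls[:, vi]
            bad = col[(col != MISSING) & ((col < 0) | (col > max_code))]
            if bad.size:
                raise ValueError(
                    f"variant {vi}: code {bad[0]} invalid for {n_alleles} alleles"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        """Human-readable ``chrom:pos`` identifiers."""
        return [
            f"{c}:{p}" for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]

    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            self.variants.reset_index(drop=True),
            self.calls[np.asarray(index, dtype=int), :],
        )

    def take_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and len(self.variants) == len(other.variants)
            and all(
                self.variants[c].tolist() == other.variants[c].tolist()
                for c in ("chrom", "pos", "ref", "alt")
            )
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FilterReport:
    """Bookkeeping for the variant completeness filter."""

    n_variants_in: int
    n_variants_kept: int
    threshold: float
    per_variant_call_fraction: list[float] = field(repr=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_variants_in": self.n_variants_in,
                    "n_variants_kept": self.n_variants_kept,
                    "threshold": self.threshold,
                    "per_variant_call_fraction": self.per_variant_call_fraction,
                },
                fh,
                indent=1,
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Half-calls and genotypes with any uncalled allele are coded ``MISSING``.
    Multiallelic records are preserved: each distinct unordered allele pair is
    its own category.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError on malformed input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no samples")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    cols: list[np.ndarray] = []
    for lineno, rec in enumerate(vcf, start=1):
        gts = rec.genotypes
        if len(gts) != len(samples):
            raise ValueError(
                f"VCF {path} record {lineno} ({rec.CHROM}:{rec.POS}): "
                f"{len(gts)} genotypes for {len(samples)} samples"
            )
        col = np.empty(len(samples), dtype=np.int32)
        for si, gt in enumerate(gts):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                col[si] = MISSING
            else:
                col[si] = genotype_code(alleles[0], alleles[1])
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(tuple(rec.ALT))
        cols.append(col)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(samples), 0), dtype=np.int32)
    )
    return GenotypeMatrix(samples, variants, calls)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF v4.2 file.

    Missing codes become ``./.``; ``read_vcf`` recovers the identical matrix.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for vi in range(matrix.n_variants):
            row = matrix.variants.iloc[vi]
            alt = ",".join(row["alt"]) if row["alt"] else "."
            gts = []
            for code in matrix.calls[:, vi]:
                a, b = decode_genotype(int(code))
                gts.append("./." if a < 0 else f"{a}/{b}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{alt}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def call_fractions(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant fraction of samples with a non-missing call."""
    if matrix.n_samples == 0:
        return np.zeros(matrix.n_variants)
    return (matrix.calls != MISSING).sum(axis=0) / matrix.n_samples


def filter_by_completeness(
    matrix: GenotypeMatrix, min_call_fraction: float = 0.9
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep variants genotyped in at least ``min_call_fraction`` of samples.

    The boundary is inclusive: a variant called in exactly the threshold
    fraction of samples is retained.  Variant order is preserved and the
    sample set is untouched.
    """
    if not 0 < min_call_fraction <= 1:
        raise ValueError("min_call_fraction must be in (0, 1]")
    frac = call_fractions(matrix)
    keep = np.flatnonzero(frac >= min_call_fraction)
    report = FilterReport(
        n_variants_in=matrix.n_variants,
        n_variants_kept=int(keep.size),
        threshold=min_call_fraction,
        per_variant_call_fraction=[float(f) for f in frac],
    )
    if keep.size == 0:
        logger.warning(
            "completeness filter at %.3g removed all %d variants",
            min_call_fraction,
            matrix.n_variants,
        )
    return matrix.take_variants(keep), report


def filter_samples_by_completeness(
    matrix: GenotypeMatrix, min_call_fraction: float
) -> GenotypeMatrix:
    """Optional second knob: drop samples genotyped at fewer than
    ``min_call_fraction`` of variants (off by default in the pipeline)."""
    if not 0 < min_call_fraction <= 1:
        raise ValueError("min_call_fraction must be in (0, 1]")
    if matrix.n_variants == 0:
        return matrix
    frac = (matrix.calls != MISSING).sum(axis=1) / matrix.n_variants
    keep = np.flatnonzero(frac >= min_call_fraction)
    dropped = [s for i, s in enumerate(matrix.sample_ids) if i not in set(keep)]
    if dropped:
        logger.warning("sample completeness filter dropped %s", dropped)
    return matrix.take_samples(keep)


def drop_uninformative(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove variants with fewer than two distinct non-missing codes.

    Monomorphic characters contribute nothing to distances or parsimony and
    make the retention index undefined, so they are pruned before tree
    building.
    """
    keep = []
    for vi in range(matrix.n_variants):
        col = matrix.calls[:, vi]
        if len(np.unique(col[col != MISSING])) >= 2:
            keep.append(vi)
    n_dropped = matrix.n_variants - len(keep)
    if n_dropped:
        logger.info("dropped %d uninformative variants", n_dropped)
    return matrix.take_variants(keep)


def subset_samples(
    matrix: GenotypeMatrix,
    metadata: SampleMetadata,
    variable: str,
    level: str,
    min_samples: int = 3,
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Restrict matrix and metadata to samples with ``variable == level``.

    For a multi-label variable (e.g. transit lines) a sample matches when
    ``level`` is a member of its label set.  Original sample order is kept.
    Stratified analyses must re-apply the completeness filter on the subset.
    """
    mask = metadata.level_mask(variable, level)
    selected = [s for s in matrix.sample_ids if mask.get(s, False)]
    if len(selected) < min_samples:
        raise ValueError(
            f"selector {variable}={level} matches {len(selected)} samples; "
            f"at least {min_samples} required"
        )
    index = [matrix.sample_ids.index(s) for s in selected]
    return matrix.take_samples(index), metadata.subset(selected)


def harmonize(
    matrix: GenotypeMatrix, metadata: SampleMetadata
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Reconcile VCF and metadata sample sets by intersection.

    Samples present in only one of the two inputs are dropped with a logged
    warning listing the ids; order follows the genotype matrix.
    """
    meta_ids = set(metadata.sample_ids)
    vcf_ids = set(matrix.sample_ids)
    common = [s for s in matrix.sample_ids if s in meta_ids]
    dropped = sorted((meta_ids | vcf_ids) - set(common))
    if dropped:
        logger.warning(
            "sample sets differ between VCF and metadata; dropping %s", dropped
        )
    if not common:
        raise ValueError("no samples shared between VCF and metadata")
    index = [matrix.sample_ids.index(s) for s in common]
    return matrix.take_samples(index), metadata.subset(common)


def _symbol_rows(matrix: GenotypeMatrix) -> list[str]:
    rows = []
    if matrix.calls.size and matrix.calls.max() >= len(_SYMBOLS):
        raise ValueError("too many genotype categories for symbol export")
    for si in range(matrix.n_samples):
        rows.append(
            "".join(
                "?" if c == MISSING else _SYMBOLS[c] for c in matrix.calls[si, :]
            )
        )
    return rows


def write_phylip(matrix: GenotypeMatrix, path) -> None:
    """Relaxed-PHYLIP export: codes as single symbols, missing as ``?``."""
    rows = _symbol_rows(matrix)
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_samples} {matrix.n_variants}\n")
        width = max((len(s) for s in matrix.sample_ids), default=0) + 2
        for name, row in zip(matrix.sample_ids, rows):
            fh.write(f"{name:<{width}}{row}\n")


def write_nexus(matrix: GenotypeMatrix, path) -> None:
    """NEXUS standard-datatype export of the genotype character matrix."""
    rows = _symbol_rows(matrix)
    used = sorted(
        {c for c in matrix.calls.flat if c != MISSING} | {0}
    )
    symbols = " ".join(_SYMBOLS[c] for c in used)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(
            f"  DIMENSIONS NTAX={matrix.n_samples} NCHAR={matrix.n_variants};\n"
        )
        fh.write(
            f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;\n'
        )
        fh.write("  MATRIX\n")
        for name, row in zip(matrix.sample_ids, rows):
            quoted = f"'{name}'" if any(ch.isspace() for ch in name) else name
            fh.write(f"    {quoted}  {row}\n")
        fh.write("  ;\nEND;\n")
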