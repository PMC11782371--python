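"""Reading, writing and synthesis of gene-expression profiles.

Expression is consumed as TPM (transcripts per million) exactly as supplied
by the user's quantification pipeline; no renormalization is applied.  A
gene that is absent from a profile is treated as TPM = 0 everywhere
downstream — absence of evidence is modelled as no expression.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "ExpressionMatrix",
    "ExpressionError",
    "read_expression",
    "write_expression",
    "generate_synthetic_expression",
]

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Malformed expression table."""


@dataclass
class ExpressionProfile:
    """One sample: gene symbol (uppercase) -> TPM (finite, >= 0)."""

    sample: str
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for gene, value in self.tpm.items():
            v = float(value)
            if not math.isfinite(v) or v < 0:
                raise ExpressionError(
                    f"TPM for gene {gene!r} in sample {self.sample!r} "
                    f"must be finite and non-negative, got {value!r}"
                )
            clean[gene.upper()] = v
        self.tpm = clean

    def get(self, gene: str) -> float:
        """TPM of ``gene``; 0.0 when the gene is not in the profile."""
        return self.tpm.get(gene.upper(), 0.0)


@dataclass
class ExpressionMatrix:
    """Ordered collection of profiles with unique sample names."""

    profiles: list[ExpressionProfile]

    def __post_init__(self) -> None:
        names = [p.sample for p in self.profiles]
        if len(set(names)) != len(names):
            raise ExpressionError(f"duplicate sample names in {names}")

    @property
    def samples(self) -> list[str]:
        return [p.sample for p in self.profiles]

    def get(self, sample: str) -> ExpressionProfile:
        for p in self.profiles:
            if p.sample == sample:
                return p
        raise KeyError(
            f"sample {sample!r} not found; available samples: {self.samples}"
        )

    def genes(self) -> list[str]:
        out: set[str] = set()
        for p in self.profiles:
            out |= p.tpm.keys()
        return sorted(out)


def read_expression(source: Union[str, io.TextIOBase]) -> ExpressionMatrix:
    """Read a TSV expression table (gene column first, one column per sample).

    Lines starting with ``#`` are skipped.  Gene symbols are uppercased;
    duplicate gene rows are collapsed to the per-sample maximum (with a
    logged warning).  Negative, non-numeric or NaN values are rejected with
    the offending gene and sample named.
    """
    try:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ExpressionError("expression table is empty") from exc
    if df.shape[1] < 2:
        raise ExpressionError(
            "expression table needs a gene column plus at least one sample column"
        )
    if df.shape[0] == 0:
        raise ExpressionError("expression table has no data rows")

    gene_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    genes = df[gene_col].astype(str).str.upper()

    values = pd.DataFrame(index=df.index)
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric) | (numeric < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ExpressionError(
                f"invalid TPM value {df[col].iloc[row]!r} for gene "
                f"{genes.iloc[row]!r} in sample {col!r} "
                "(values must be non-negative finite numbers)"
            )
        values[col] = numeric

    if genes.duplicated().any():
        dupes = sorted(genes[genes.duplicated()].unique())
        logger.warning(
            "duplicate gene rows collapsed to per-sample maximum: %s", dupes
        )
    values.index = genes
    collapsed = values.groupby(level=0, sort=False).max()

    profiles = [
        ExpressionProfile(sample=col, tpm=collapsed[col].to_dict())
        for col in sample_cols
    ]
    return ExpressionMatrix(profiles=profiles)


def write_expression(matrix: ExpressionMatrix, target: Union[str, io.TextIOBase]) -> None:
    """Write a matrix as TSV with 6 significant digits.

    Genes absent from a profile are written as 0 (their downstream value).
    """
    genes = matrix.genes()
    own = isinstance(target, str)
    handle = open(target, "w", encoding="utf-8") if own else target
    try:
        handle.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for gene in genes:
            row = "\t".join(f"{p.get(gene):.6g}" for p in matrix.profiles)
            handle.write(f"{gene}\t{row}\n")
    finally:
        if own:
            handle.close()


def generate_synthetic_expression(
    genes: Sequence[str],
    seed: int = 0,
    active_fraction: float = 0.8,
    lognormal_params: tuple[float, float] = (2.0, 1.0),
    sample: str | None = None,
) -> ExpressionProfile:
    """Seeded random profile over ``genes``.

    Each gene is "active" with probability ``active_fraction``; active genes
    draw TPM from a log-normal with natural-log parameters
    ``lognormal_params = (mu, sigma)`` (the defaults give a median of
    ``exp(2) ~ 7.4`` TPM, typical of robustly expressed enzymes), inactive
    genes draw background noise uniformly from [0, 0.1].
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must be in [0, 1]")
    mu, sigma = lognormal_params
    if sigma <= 0:
        raise ValueError("lognormal sigma must be > 0")
    rng = np.random.default_rng(seed)
    ordered = [g.upper() for g in genes]
    active = rng.random(len(ordered)) < active_fraction
    high = rng.lognormal(mean=mu, sigma=sigma, size=len(ordered))
    low = rng.uniform(0.0, 0.1, size=len(ordered))
    tpm = {
        gene: float(high[i] if active[i] else low[i])
        for i, gene in enumerate(ordered)
    }
    return ExpressionProfile(sample=sample or f"synthetic-{seed}", tpm=tpm)
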