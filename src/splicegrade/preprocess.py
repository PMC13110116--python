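"""Expression filtering and TMM between-sample normalization.

A transcript is considered expressed within a tissue when it reaches
``min_cpm`` counts per million in at least ``min_samples`` samples (all diet
groups pooled); a gene is expressed when at least one of its isoforms is.
Filtered matrices are then normalized by the trimmed mean of M-values (TMM):
per-sample scaling factors computed from trimmed, precision-weighted log
ratios of relative abundances against a reference sample, rescaled to
geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from splicegrade.annotation_io import AnnotationMap, ExpressionMatrixSet
from splicegrade.errors import ConfigError, DegenerateDataError

# Canonical TMM trimming fractions: 30% of the M (log-ratio) tails and 5% of
# the A (log-abundance) tails are removed before the weighted mean.
LOGRATIO_TRIM = 0.30
ABUNDANCE_TRIM = 0.05


@dataclass
class NormFactors:
    """Per-sample TMM factors; effective library size = library_size * factor."""

    factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DegenerateDataError("TMM factors must be strictly positive")

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors


@dataclass
class FilterResult:
    """Expression-filter outcome: kept ids plus per-feature pass flags."""

    kept_transcripts: list[str]
    kept_genes: list[str]
    transcript_pass: pd.Series  # bool per transcript
    n_samples_above: pd.Series  # support count per transcript


def compute_cpm(
    counts: pd.DataFrame | np.ndarray,
    library_sizes: pd.Series | np.ndarray,
    log: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame | np.ndarray:
    """Counts per million against (effective) library sizes.

    Linear CPM is ``count * 1e6 / libsize``; log CPM is
    ``log2((count + prior) / (libsize + 2*prior) * 1e6)``.
    """
    lib = np.asarray(library_sizes, dtype=float)
    if (lib <= 0).any():
        raise DegenerateDataError("library sizes must be positive")
    vals = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if log:
        out = np.log2((vals + prior) / (lib + 2.0 * prior) * 1e6)
    else:
        out = vals / lib * 1e6
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_expressed(
    tx: ExpressionMatrixSet,
    ann: AnnotationMap,
    min_cpm: float = 1.0,
    min_samples: int = 4,
) -> FilterResult:
    """Apply the expressed-transcript rule within one tissue.

    A transcript passes when CPM >= ``min_cpm`` in >= ``min_samples`` samples
    (raw library sizes, since filtering precedes normalization); a gene passes
    when any member transcript does.
    """
    n = tx.counts.shape[1]
    if min_samples > n:
        raise ConfigError(f"min_samples={min_samples} exceeds sample count {n}")
    cpm = compute_cpm(tx.counts, tx.library_sizes)
    support = (cpm >= min_cpm).sum(axis=1)
    tx_pass = support >= min_samples
    kept_tx = [t for t in tx.features if tx_pass[t]]
    kept_gene_set = {ann.transcript_gene[t] for t in kept_tx if t in ann.transcript_gene}
    kept_genes = [g for g in ann.genes() if g in kept_gene_set]
    return FilterResult(
        kept_transcripts=kept_tx,
        kept_genes=kept_genes,
        transcript_pass=tx_pass,
        n_samples_above=support,
    )


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    # sample whose CPM upper quartile is closest to the mean upper quartile
    uq = np.array([np.quantile(counts[:, j] / lib[j] * 1e6, 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise DegenerateDataError("no co-expressed genes with the reference sample")
    o, r = obs[pos], ref[pos]
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M; weight = inverse variance
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.allclose(np.abs(m), 0.0, atol=1e-6):
        return 1.0
    n = m.size
    lo_m = np.floor(n * LOGRATIO_TRIM) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * ABUNDANCE_TRIM) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise DegenerateDataError("trimming removed all genes; sample too divergent")
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    ref: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Genes with a zero count in either member of a pair are excluded; 30% of
    the M tails and 5% of the A tails are trimmed; remaining M values are
    averaged with inverse asymptotic-variance weights.  Factors are rescaled
    to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ConfigError("TMM needs at least 2 samples")
    lib = (
        counts.sum(axis=0).astype(float)
        if library_sizes is None
        else pd.Series(library_sizes, index=counts.columns).astype(float)
    )
    if (counts.sum(axis=0) <= 0).any():
        raise DegenerateDataError("a sample has no nonzero counts")
    vals = counts.to_numpy(dtype=float)
    libv = lib.to_numpy()
    ref_idx = list(counts.columns).index(ref) if ref is not None else _choose_reference(vals, libv)
    raw = np.array(
        [
            _tmm_pair(vals[:, j], vals[:, ref_idx], libv[j], libv[ref_idx])
            for j in range(vals.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(factors=pd.Series(factors, index=counts.columns), library_sizes=lib)
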