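"""PSI computation, isoform-level DTU testing and gene-level DAS calls.

Percent spliced-in (PSI, Ψ) is an isoform's share of its gene's total TPM in
one sample; a single-isoform gene has Ψ = 1 and two equally expressed isoforms
have Ψ = 0.5 each.  ΔΨ is the difference of group-mean Ψ (treatment minus
control), computed over samples where the gene is expressed.

The DTU p-value contrasts each isoform's log2 fold change against its gene's
precision-weighted average log2 fold change (a moderated t on the deviation,
with a leave-weight variance correction); ΔΨ acts as the effect-size filter.
Gene-level differential alternative splicing (DAS) combines the member
isoforms' p-values with the Simes method.  Calls use strict inequalities:
|ΔΨ| > delta and FDR < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from splicegrade.annotation_io import AnnotationMap
from splicegrade.diffexpr import DesignInfo, FitResult, ModerationParams, bh_adjust
from splicegrade.errors import ValidationError


@dataclass
class PsiMatrix:
    """Isoform x sample Ψ values with a validity mask.

    Entries are undefined (masked False, stored NaN) wherever the gene's total
    TPM is zero in that sample.  On every defined (gene, sample) the member
    Ψ's sum to 1.
    """

    psi: pd.DataFrame
    valid: pd.DataFrame
    gene_of: pd.Series  # isoform -> gene


def compute_psi(tpm: pd.DataFrame, ann: AnnotationMap) -> PsiMatrix:
    """Ψ[i,s] = TPM[i,s] / sum of TPM over gene(i)'s isoforms in sample s."""
    orphans = [t for t in tpm.index if t not in ann.transcript_gene]
    if orphans:
        raise ValidationError(f"transcripts absent from annotation: {orphans[:10]}")
    genes = pd.Index([ann.transcript_gene[t] for t in tpm.index])
    gene_tot = tpm.groupby(genes, sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = tpm / gene_tot
    valid = gene_tot > 0
    psi = psi.where(valid)
    return PsiMatrix(psi=psi, valid=valid, gene_of=pd.Series(genes.to_numpy(), index=tpm.index))


def delta_psi(
    psi: PsiMatrix,
    design: DesignInfo,
    contrast: tuple[str, str],
    min_valid: int = 3,
) -> pd.DataFrame:
    """Group-mean Ψ difference (treatment minus control) per isoform.

    ΔΨ is NaN (untestable) when fewer than ``min_valid`` defined Ψ values are
    available in either group; the support counts are reported alongside.
    """
    trt, ctl = contrast
    trt_samples = design.groups.index[design.groups == trt]
    ctl_samples = design.groups.index[design.groups == ctl]
    if len(trt_samples) == 0 or len(ctl_samples) == 0:
        raise ValidationError(f"contrast {contrast} names an empty group")
    mean_trt = psi.psi[trt_samples].mean(axis=1)  # pandas skips NaN
    mean_ctl = psi.psi[ctl_samples].mean(axis=1)
    n_trt = psi.valid[trt_samples].sum(axis=1)
    n_ctl = psi.valid[ctl_samples].sum(axis=1)
    dpsi = (mean_trt - mean_ctl).where((n_trt >= min_valid) & (n_ctl >= min_valid))
    return pd.DataFrame(
        {
            "isoform_id": psi.psi.index,
            "gene_id": psi.gene_of.to_numpy(),
            "delta_psi": dpsi.to_numpy(),
            "n_valid_treatment": n_trt.to_numpy(),
            "n_valid_control": n_ctl.to_numpy(),
        }
    ).set_index("isoform_id")


def dtu_test(
    fit: FitResult,
    mod: ModerationParams,
    ann: AnnotationMap,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Isoform-versus-gene log2FC deviation test for one contrast.

    For isoform j of gene g with contrast estimate b_j and moderated standard
    error SE_j: the gene average b̄_g is the precision-weighted (w = 1/SE²)
    mean over member isoforms, and t_j = (b_j − b̄_g)/SE(b_j − b̄_g) with the
    leave-weight correction SE² = SE_j²·(1 − w_j/Σw), on the moderated df.
    Single-isoform genes are untestable and omitted.
    """
    try:
        k = fit.contrasts.index(tuple(contrast))
    except ValueError:
        raise ValidationError(f"contrast {contrast} not in fit") from None
    beta = pd.Series(fit.coef[:, k], index=fit.features)
    se = pd.Series(
        fit.unscaled_se[:, k] * np.sqrt(mod.posterior_var), index=fit.features
    )
    df = pd.Series(mod.total_df, index=fit.features)
    genes = pd.Series({t: ann.transcript_gene.get(t) for t in fit.features})
    missing = genes.index[genes.isna()]
    if len(missing):
        raise ValidationError(f"transcripts absent from annotation: {list(missing[:10])}")

    rows = []
    for gene, members in genes.groupby(genes, sort=False).groups.items():
        if len(members) < 2:
            continue
        b = beta[members].to_numpy()
        s = se[members].to_numpy()
        if (s == 0).any():
            warnings.warn(f"zero SE in gene {gene}; p set to 0 for affected isoforms", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 / s**2
            wsum = w.sum()
            gene_beta = np.sum(w * b) / wsum
            var = s**2 * (1.0 - w / wsum)
            t = (b - gene_beta) / np.sqrt(var)
        d = df[members].to_numpy()
        d_eval = np.where(np.isinf(d), 1e12, d)
        p = 2.0 * t_dist.sf(np.abs(t), d_eval)
        p = np.where(s == 0, 0.0, p)
        p = np.minimum(np.where(np.isnan(t), np.nan, p), 1.0)
        for i, iso in enumerate(members):
            rows.append((iso, gene, b[i], gene_beta, t[i], p[i]))
    out = pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "log2FC", "gene_log2FC", "t", "p"]
    ).set_index("isoform_id")
    return out


def simes_combine(pvalues) -> float:
    """Simes combination: min over k of m·p_(k)/k for ascending p, capped at 1.

    NaNs are dropped first; an empty vector raises (untestable gene).
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("no finite p-values to combine (untestable gene)")
    p_sorted = np.sort(p)
    m = p.size
    return float(min(1.0, np.min(m * p_sorted / np.arange(1, m + 1))))


def classify_das(
    dtu: pd.DataFrame,
    dpsi: pd.DataFrame,
    delta: float = 0.05,
    alpha: float = 0.05,
    biotype: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge DTU statistics with ΔΨ, adjust and call at strict thresholds.

    Isoform call: DTU-up/DTU-down iff |ΔΨ| > delta and isoform BH FDR < alpha
    (direction = sign of ΔΨ).  Gene call: DAS iff max|ΔΨ| over member isoforms
    > delta and the BH-adjusted Simes p < alpha.  BH families are all tested
    isoforms (resp. genes) of the given table.  alpha >= 1 disables the FDR
    gate (an adjusted p of exactly 1 can never pass the strict inequality).
    """
    merged = dtu.join(dpsi[["delta_psi"]], how="left")
    tested = merged["p"].notna()
    fdr = np.full(len(merged), np.nan)
    if tested.any():
        # extreme statistics can underflow to p = 0; clamp into BH's domain
        p_fam = np.maximum(merged.loc[tested, "p"].to_numpy(), np.nextafter(0, 1))
        fdr[tested.to_numpy()] = bh_adjust(p_fam)
    merged["fdr"] = fdr
    eff = merged["delta_psi"].abs() > delta
    sig = merged["fdr"].notna() if alpha >= 1 else merged["fdr"] < alpha
    merged["call"] = np.where(
        eff & sig & (merged["delta_psi"] > 0),
        "DTU-up",
        np.where(eff & sig & (merged["delta_psi"] < 0), "DTU-down", "ns"),
    )
    if biotype is not None:
        merged["biotype"] = biotype.reindex(merged.index)

    gene_rows = []
    for gene, sub in merged.groupby("gene_id", sort=False):
        p_fin = sub["p"].dropna()
        if p_fin.empty:
            continue
        simes_p = simes_combine(p_fin.to_numpy())
        max_dpsi = sub["delta_psi"].abs().max()
        gene_rows.append((gene, max_dpsi, simes_p))
    das = pd.DataFrame(gene_rows, columns=["gene_id", "max_abs_delta_psi", "simes_p"]).set_index(
        "gene_id"
    )
    if len(das):
        das["fdr"] = bh_adjust(np.maximum(das["simes_p"].to_numpy(), np.nextafter(0, 1)))
        gene_sig = das["fdr"].notna() if alpha >= 1 else das["fdr"] < alpha
        das["call"] = (das["max_abs_delta_psi"] > delta) & gene_sig
    else:
        das["fdr"] = pd.Series(dtype=float)
        das["call"] = pd.Series(dtype=bool)
    return merged, das


def das_analysis(
    fit: FitResult,
    mod: ModerationParams,
    psi: PsiMatrix,
    design: DesignInfo,
    ann: AnnotationMap,
    delta: float = 0.05,
    alpha: float = 0.05,
    min_valid: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run DTU + DAS for every contrast of the design; tidy long tables."""
    biotype = pd.Series(ann.transcript_biotype)
    dtu_frames, das_frames = [], []
    for contrast in design.contrasts:
        dtu = dtu_test(fit, mod, ann, contrast)
        dpsi = delta_psi(psi, design, contrast, min_valid=min_valid)
        iso, gene = classify_das(dtu, dpsi, delta=delta, alpha=alpha, biotype=biotype)
        label = f"{contrast[0]}-{contrast[1]}"
        iso = iso.assign(contrast=label)
        gene = gene.assign(contrast=label)
        dtu_frames.append(iso.reset_index())
        das_frames.append(gene.reset_index())
    return (
        pd.concat(dtu_frames, ignore_index=True),
        pd.concat(das_frames, ignore_index=True),
    )
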