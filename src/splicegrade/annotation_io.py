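"""Quantification-table and annotation import.

The pipeline starts from transcript-level quantification tables in the Salmon
``quant.sf`` dialect (tab-separated ``Name/Length/EffectiveLength/TPM/NumReads``
per sample) plus a GENCODE-dialect GTF that supplies transcript-to-gene
membership and transcript biotypes.  Abundances are converted to
length-scaled counts (TPM times mean effective length, rescaled per sample so
column sums match the estimated fragment totals) and can be aggregated from
transcript to gene level by summation.
"""

from __future__ import annotations

import gzip
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from splicegrade.errors import DegenerateDataError, FormatError, ValidationError

QUANT_COLUMNS = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")

#: Collapse of annotation transcript types onto the four biotypes reported by
#: the pipeline plus a catch-all.  Pc = protein coding, NMD = nonsense-mediated
#: decay prone, PT = processed transcript, RI = retained intron.
BIOTYPE_MAP = {
    "protein_coding": "Pc",
    "nonsense_mediated_decay": "NMD",
    "processed_transcript": "PT",
    "retained_intron": "RI",
}
BIOTYPES = ("Pc", "NMD", "PT", "RI", "other")


@dataclass(frozen=True)
class TranscriptQuant:
    """One row of a quant.sf-dialect table."""

    transcript_id: str
    length: int
    effective_length: float
    tpm: float
    num_reads: float


@dataclass
class AnnotationMap:
    """Transcript → gene / biotype mapping plus gene symbols.

    Every transcript maps to exactly one gene; biotypes are restricted to
    :data:`BIOTYPES`.
    """

    transcript_gene: dict[str, str]
    transcript_biotype: dict[str, str]
    gene_symbol: dict[str, str]

    def __post_init__(self) -> None:
        bad = {b for b in self.transcript_biotype.values() if b not in BIOTYPES}
        if bad:
            raise ValidationError(f"unknown biotype codes: {sorted(bad)}")

    @property
    def transcripts(self) -> list[str]:
        return list(self.transcript_gene)

    def genes(self) -> list[str]:
        """Gene ids in first-appearance (transcript) order."""
        seen: dict[str, None] = {}
        for g in self.transcript_gene.values():
            seen.setdefault(g)
        return list(seen)

    def isoforms_of(self, gene_id: str) -> list[str]:
        return [t for t, g in self.transcript_gene.items() if g == gene_id]


@dataclass
class ExpressionMatrixSet:
    """Paired count/TPM matrices (features x samples) with sample metadata.

    ``counts`` and ``tpm`` share identical row and column orderings;
    ``library_sizes`` are the count column sums at import time.
    ``sample_sheet`` is indexed by sample id with at least ``tissue`` and
    ``group`` columns.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    feature_level: str  # "transcript" | "gene"
    sample_sheet: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_level not in ("transcript", "gene"):
            raise ValidationError(f"feature_level must be transcript|gene, got {self.feature_level}")
        if not self.counts.index.equals(self.tpm.index) or not self.counts.columns.equals(
            self.tpm.columns
        ):
            raise ValidationError("counts and tpm must share row and column orderings")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrixSet":
        samples = list(samples)
        return ExpressionMatrixSet(
            counts=self.counts[samples],
            tpm=self.tpm[samples],
            feature_level=self.feature_level,
            sample_sheet=self.sample_sheet.loc[samples],
            library_sizes=self.library_sizes[samples],
        )

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrixSet":
        features = list(features)
        return ExpressionMatrixSet(
            counts=self.counts.loc[features],
            tpm=self.tpm.loc[features],
            feature_level=self.feature_level,
            sample_sheet=self.sample_sheet,
            library_sizes=self.library_sizes,  # import-time sizes are kept
        )


def read_quant_table(path: str | Path) -> list[TranscriptQuant]:
    """Read one Salmon quant.sf-dialect table into records, order preserved.

    Raises :class:`FormatError` when a required column is missing and
    :class:`ValidationError` (naming the row index) on negative TPM/NumReads.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("TPM", "NumReads"):
        neg = np.flatnonzero(df[col].to_numpy() < 0)
        if neg.size:
            raise ValidationError(f"{path}: negative {col} at row index {neg[0]}")
    return [
        TranscriptQuant(
            transcript_id=str(r.Name),
            length=int(r.Length),
            effective_length=float(r.EffectiveLength),
            tpm=float(r.TPM),
            num_reads=float(r.NumReads),
        )
        for r in df.itertuples(index=False)
    ]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    # first occurrence wins (GTF tags may repeat)
    out: dict[str, str] = {}
    for key, val in _ATTR_RE.findall(attr_field):
        out.setdefault(key, val)
    return out


def read_annotation(path: str | Path) -> AnnotationMap:
    """Parse transcript features of a GENCODE-dialect GTF (plain or gzip).

    Biotypes are collapsed via :data:`BIOTYPE_MAP` with everything else mapped
    to ``other``.  Both ``transcript_type`` (GENCODE) and ``transcript_biotype``
    (Ensembl) attribute keys are accepted, first match wins.  A transcript
    appearing under two different gene ids raises :class:`ValidationError`.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    gene_symbol: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            attrs = _parse_attributes(fields[8])
            try:
                tid = attrs["transcript_id"]
                gid = attrs["gene_id"]
            except KeyError as exc:
                raise FormatError(f"{path}: transcript feature missing {exc} attribute")
            if tid in tx_gene and tx_gene[tid] != gid:
                raise ValidationError(
                    f"{path}: transcript {tid} maps to both {tx_gene[tid]} and {gid}"
                )
            ttype = attrs.get("transcript_type", attrs.get("transcript_biotype", ""))
            tx_gene[tid] = gid
            tx_biotype[tid] = BIOTYPE_MAP.get(ttype, "other")
            gene_symbol.setdefault(gid, attrs.get("gene_name", gid))
    return AnnotationMap(tx_gene, tx_biotype, gene_symbol)


def length_scaled_counts(
    quants: Mapping[str, Sequence[TranscriptQuant]],
    sample_sheet: pd.DataFrame | None = None,
) -> ExpressionMatrixSet:
    """Convert per-sample TPM to length-scaled counts at transcript level.

    For transcript *i* the raw scaled count in sample *s* is
    ``TPM[i,s] * mean_s(effective_length[i,s])``; each column is then rescaled
    by a single factor so its sum equals that sample's original NumReads total
    (column-sum preservation).  All samples must cover the same transcript set.
    Zero effective lengths are clamped to 1 bp with a warning.
    """
    if not quants:
        raise ValidationError("no samples supplied")
    samples = list(quants)
    ref_ids = [q.transcript_id for q in quants[samples[0]]]
    ref_set = set(ref_ids)
    tpm = np.empty((len(ref_ids), len(samples)))
    efflen = np.empty_like(tpm)
    reads_total = np.empty(len(samples))
    for j, s in enumerate(samples):
        recs = quants[s]
        if {q.transcript_id for q in recs} != ref_set or len(recs) != len(ref_ids):
            raise ValidationError(f"sample {s}: transcript set differs from first sample")
        by_id = {q.transcript_id: q for q in recs}
        ordered = [by_id[t] for t in ref_ids]
        tpm[:, j] = [q.tpm for q in ordered]
        efflen[:, j] = [q.effective_length for q in ordered]
        reads_total[j] = sum(q.num_reads for q in ordered)
        if tpm[:, j].sum() <= 0:
            raise DegenerateDataError(f"sample {s}: total TPM is zero (degenerate library)")
    if (efflen <= 0).any():
        warnings.warn("effective length <= 0 clamped to 1 bp", stacklevel=2)
        efflen = np.maximum(efflen, 1.0)
    mean_len = efflen.mean(axis=1)
    raw = tpm * mean_len[:, None]
    col = raw.sum(axis=0)
    scaled = raw * (reads_total / col)
    counts = pd.DataFrame(scaled, index=ref_ids, columns=samples)
    tpm_df = pd.DataFrame(tpm, index=ref_ids, columns=samples)
    if sample_sheet is None:
        sample_sheet = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    else:
        sample_sheet = sample_sheet.loc[samples]
    return ExpressionMatrixSet(
        counts=counts, tpm=tpm_df, feature_level="transcript", sample_sheet=sample_sheet
    )


def aggregate_to_gene(tx: ExpressionMatrixSet, ann: AnnotationMap) -> ExpressionMatrixSet:
    """Sum transcript counts and TPM to gene level.

    Row order is first-appearance order of genes along the transcript rows.
    Transcripts absent from ``ann`` raise :class:`ValidationError` listing the
    orphan ids.
    """
    if tx.feature_level != "transcript":
        raise ValidationError("aggregate_to_gene requires transcript-level input")
    orphans = [t for t in tx.features if t not in ann.transcript_gene]
    if orphans:
        raise ValidationError(f"transcripts absent from annotation: {orphans}")
    genes = pd.Index([ann.transcript_gene[t] for t in tx.features])
    order: dict[str, None] = {}
    for g in genes:
        order.setdefault(g)
    gene_order = list(order)
    counts = tx.counts.groupby(genes, sort=False).sum().loc[gene_order]
    tpm = tx.tpm.groupby(genes, sort=False).sum().loc[gene_order]
    return ExpressionMatrixSet(
        counts=counts,
        tpm=tpm,
        feature_level="gene",
        sample_sheet=tx.sample_sheet,
        library_sizes=tx.library_sizes,
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, tissue, group[, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")


def write_matrix_set(ems: ExpressionMatrixSet, directory: str | Path, prefix: str) -> None:
    """Serialize a matrix set as TSVs plus a sidecar JSON of sample metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ems.counts.rename_axis("feature_id").to_csv(
        directory / f"{prefix}_counts.tsv", sep="\t", float_format="%.8g"
    )
    ems.tpm.rename_axis("feature_id").to_csv(
        directory / f"{prefix}_tpm.tsv", sep="\t", float_format="%.8g"
    )
    meta = {
        "feature_level": ems.feature_level,
        "library_sizes": {s: float(v) for s, v in ems.library_sizes.items()},
        "samples": {
            s: {k: (v if pd.notna(v) else None) for k, v in row.items()}
            for s, row in ems.sample_sheet.iterrows()
        },
    }
    (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_matrix_set(directory: str | Path, prefix: str) -> ExpressionMatrixSet:
    """Inverse of :func:`write_matrix_set`."""
    directory = Path(directory)
    counts = pd.read_csv(directory / f"{prefix}_counts.tsv", sep="\t", index_col="feature_id")
    tpm = pd.read_csv(directory / f"{prefix}_tpm.tsv", sep="\t", index_col="feature_id")
    meta = json.loads((directory / f"{prefix}_meta.json").read_text())
    sheet = pd.DataFrame.from_dict(meta["samples"], orient="index")
    sheet.index.name = "sample_id"
    return ExpressionMatrixSet(
        counts=counts,
        tpm=tpm,
        feature_level=meta["feature_level"],
        sample_sheet=sheet.loc[counts.columns],
        library_sizes=pd.Series(meta["library_sizes"])[counts.columns],
    )
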