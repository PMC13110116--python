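"""Cross-layer synthesis: overlaps, combination matrices, tallies, SR tables.

Brings the per-tissue, per-dose result tables together: hypergeometric tests
for DE/DAS co-regulation, UpSet-style combination counts across doses or
tissues, DTU biotype-by-direction tallies, intersection of differentially
expressed genes with a user-supplied splicing-regulator (SR) symbol list, and
dose-trend summaries with monotonicity flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from splicegrade.annotation_io import AnnotationMap
from splicegrade.errors import ValidationError


@dataclass
class OverlapTest:
    """Exact upper-tail hypergeometric overlap test P(X >= k)."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    p_value: float


def hypergeom_overlap(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapTest:
    """Test whether two gene sets overlap more than chance within a universe.

    The universe should be the features testable in the stratum (e.g. genes
    passing the expression filter in that tissue), so the null conditions on
    testability.  Sets must be contained in the universe.
    """
    uni = set(universe)
    a = set(set_a)
    b = set(set_b)
    stray = sorted((a | b) - uni)
    if stray:
        raise ValidationError(f"ids outside the universe: {stray[:10]}")
    n_uni, n_a, n_b = len(uni), len(a), len(b)
    k = len(a & b)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(hypergeom.sf(k - 1, n_uni, n_a, n_b))
    return OverlapTest(n_uni, n_a, n_b, k, min(1.0, max(p, 0.0)))


def combination_counts(
    sets: Mapping[str, Iterable[str]], mode: str = "exclusive"
) -> pd.DataFrame:
    """UpSet-style subset counts over named sets.

    ``exclusive`` counts elements belonging to exactly that subset of sets
    (the counts over all non-empty subsets sum to the union size);
    ``inclusive`` counts elements belonging to at least that subset.
    Duplicate ids within a set are collapsed with a warning.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 named sets")
    if mode not in ("exclusive", "inclusive"):
        raise ValidationError(f"unknown mode {mode!r}")
    clean: dict[str, set[str]] = {}
    for name, ids in sets.items():
        ids = list(ids)
        uniq = set(ids)
        if len(uniq) < len(ids):
            warnings.warn(f"set {name!r}: duplicate ids collapsed", stacklevel=2)
        clean[name] = uniq
    names = list(clean)
    signature: dict[str, tuple[str, ...]] = {}
    for el in sorted(set().union(*clean.values())):
        signature[el] = tuple(n for n in names if el in clean[n])
    exclusive: dict[tuple[str, ...], int] = {}
    for sig in signature.values():
        exclusive[sig] = exclusive.get(sig, 0) + 1
    if mode == "exclusive":
        table = exclusive
    else:
        table = {}
        for sig in exclusive:
            for other, cnt in exclusive.items():
                if set(sig) <= set(other):
                    table[sig] = table.get(sig, 0) + cnt
    rows = [
        {"subset": "&".join(sig), "degree": len(sig), "count": cnt}
        for sig, cnt in sorted(table.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["subset", "degree", "count"])


def biotype_direction_tally(dtu: pd.DataFrame) -> pd.DataFrame:
    """Count DTU calls per (tissue, contrast, biotype, direction).

    Expects a classified DTU table with columns tissue, contrast, biotype and
    call in {DTU-up, DTU-down, ns}; only non-ns rows are tallied.  The
    ``other`` biotype is kept as its own stratum so it can be reported
    separately from the four named biotypes.
    """
    called = dtu[dtu["call"].isin(["DTU-up", "DTU-down"])]
    if called.empty:
        return pd.DataFrame(columns=["tissue", "contrast", "biotype", "direction", "count"])
    out = (
        called.assign(direction=called["call"].map({"DTU-up": "up", "DTU-down": "down"}))
        .groupby(["tissue", "contrast", "biotype", "direction"], sort=False, observed=True)
        .size()
        .reset_index(name="count")
    )
    return out


def sr_intersection(
    de: pd.DataFrame, sr_symbols: Iterable[str], ann: AnnotationMap
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Intersect differentially expressed genes with a splicing-regulator list.

    ``de`` is a gene-level DE table with columns tissue, contrast, feature_id,
    call.  Returns (per-stratum SR DE table, per-SR cross-tissue sharing
    counts, symbols that resolved to no annotated gene).  Unresolvable
    symbols are reported, not fatal.
    """
    symbol_to_genes: dict[str, list[str]] = {}
    for gid, sym in ann.gene_symbol.items():
        symbol_to_genes.setdefault(sym, []).append(gid)
    wanted = list(dict.fromkeys(sr_symbols))
    unresolved = [s for s in wanted if s not in symbol_to_genes]
    sr_gene_ids = {g: s for s in wanted for g in symbol_to_genes.get(s, [])}
    hits = de[(de["call"] != "ns") & de["feature_id"].isin(sr_gene_ids)].copy()
    hits["symbol"] = hits["feature_id"].map(sr_gene_ids)
    hits["direction"] = hits["call"]
    table = hits[["tissue", "contrast", "feature_id", "symbol", "direction"]].reset_index(
        drop=True
    )
    if table.empty:
        sharing = pd.DataFrame(columns=["symbol", "n_tissues"])
    else:
        sharing = (
            table.groupby("symbol", sort=False)["tissue"]
            .nunique()
            .reset_index(name="n_tissues")
        )
    return table, sharing, unresolved


def dose_trend_summary(
    calls: pd.DataFrame, dose_order: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue call counts by dose with non-decreasing monotonicity flags.

    ``calls`` has columns tissue, contrast, metric (DEG|DTU|DAS), count; the
    contrast labels must cover >= 2 of ``dose_order``.  Returns the tissue x
    dose x metric count table and a (tissue, metric, monotone) flag table.
    """
    present = [d for d in dose_order if d in set(calls["contrast"])]
    if len(present) < 2:
        raise ValidationError("need classified calls for >= 2 dose levels")
    counts = (
        calls[calls["contrast"].isin(present)]
        .groupby(["tissue", "metric", "contrast"], sort=False, observed=True)["count"]
        .sum()
        .reset_index()
    )
    flags = []
    for (tissue, metric), sub in counts.groupby(["tissue", "metric"], sort=False):
        by_dose = [int(sub.loc[sub["contrast"] == d, "count"].sum()) for d in present]
        monotone = all(b >= a for a, b in zip(by_dose, by_dose[1:]))
        flags.append({"tissue": tissue, "metric": metric, "monotone": monotone})
    return counts, pd.DataFrame(flags)
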