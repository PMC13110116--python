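"""Multi-tissue graded-dose RNA-seq simulator with planted DE and isoform switches.

Emulates the study design the pipeline targets: six tissues, one *ad libitum*
control group plus four graded restriction levels (10-40%), unequal group
sizes, genes carrying 1-10 isoforms, negative-binomial counts (variance
mu + phi*mu^2), and planted effects whose magnitude scales with dose --
either linearly (the default, matching a response broadly proportional to
restriction level) or as a step (threshold responses at the two highest
doses).  Differential expression is planted as a gene-level fold change;
differential usage redistributes TPM share between exactly one gaining and
one losing isoform, leaving the others untouched.

Structural parameters (annotation, baseline abundances, isoform usage,
transcript lengths) are drawn from a master stream; each tissue gets an
independent child stream for its sampling noise, so adding tissues never
perturbs existing ones and a fixed seed reproduces fixtures byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from splicegrade.annotation_io import (
    AnnotationMap,
    ExpressionMatrixSet,
)
from splicegrade.errors import ConfigError

DEFAULT_TISSUES = ("eWAT", "liver", "hypothalamus", "muscle", "testes", "stomach")
DEFAULT_GROUPS = ("12AL", "10CR", "20CR", "30CR", "40CR")
#: study group sizes in group order: control, 10%, 20%, 30%, 40% restriction
DEFAULT_N_PER_GROUP = (8, 8, 8, 7, 9)
#: isoforms-per-gene probabilities for counts 1..10 (majority single/few-isoform)
DEFAULT_ISOFORM_PROBS = (0.42, 0.22, 0.12, 0.08, 0.06, 0.04, 0.03, 0.015, 0.01, 0.005)
#: biotype proportions for non-canonical isoforms (canonical isoform is always Pc)
DEFAULT_BIOTYPE_PROBS = {"Pc": 0.45, "NMD": 0.20, "PT": 0.18, "RI": 0.14, "other": 0.03}


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated experiment."""

    n_tissues: int = 6
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: tuple[int, ...] = DEFAULT_N_PER_GROUP
    n_genes: int = 1000
    isoform_count_probs: tuple[float, ...] = DEFAULT_ISOFORM_PROBS
    biotype_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_PROBS))
    library_size_mean: float = 1e7
    library_size_cv: float = 0.1
    nb_dispersion: float = 0.05
    seed: int = 0
    tissue_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_tissues <= 0 or self.n_genes <= 0:
            raise ConfigError("n_tissues and n_genes must be positive")
        if len(self.n_per_group) != len(self.groups):
            raise ConfigError("n_per_group must align with groups")
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigError("group sizes must be positive")
        probs = np.asarray(self.isoform_count_probs, float)
        if probs.size == 0 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
            raise ConfigError("isoform_count_probs must be non-negative and sum to 1")
        if self.library_size_mean <= 0 or self.nb_dispersion < 0:
            raise ConfigError("library_size_mean must be positive, nb_dispersion non-negative")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.tissue_names is not None:
            return self.tissue_names[: self.n_tissues]
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.n_tissues]
        extra = tuple(f"tissue{i}" for i in range(len(DEFAULT_TISSUES), self.n_tissues))
        return DEFAULT_TISSUES + extra

    def dose_fraction(self, group: str, scaling: str = "linear") -> float:
        """Planted-effect scaling per group: 0 for control, 1 at the top dose."""
        idx = list(self.groups).index(group)
        n_dose = len(self.groups) - 1
        if idx == 0 or n_dose == 0:
            return 0.0
        if scaling == "linear":
            return idx / n_dose
        if scaling == "step":
            return 1.0 if idx >= max(1, n_dose - 1) else 0.0
        raise ConfigError(f"unknown dose_scaling {scaling!r}")


@dataclass
class PlantedEffect:
    """One gene's planted response: expression shift, usage switch, or both."""

    gene_id: str
    effect_kind: str  # DE | DTU | both
    base_log2fc_at_max_dose: float = 0.0
    delta_psi_at_max_dose: float = 0.0
    dose_scaling: str = "linear"
    switched_isoform_pair: tuple[str, str] | None = None  # (gaining, losing)

    def __post_init__(self) -> None:
        if self.effect_kind not in ("DE", "DTU", "both"):
            raise ConfigError(f"effect_kind must be DE|DTU|both, got {self.effect_kind!r}")
        if not -1.0 < self.delta_psi_at_max_dose < 1.0:
            raise ConfigError("delta_psi_at_max_dose must lie in (-1, 1)")
        if self.effect_kind in ("DTU", "both") and self.delta_psi_at_max_dose == 0.0:
            raise ConfigError(f"{self.gene_id}: DTU effect needs a nonzero delta_psi")

    @property
    def has_de(self) -> bool:
        return self.effect_kind in ("DE", "both")

    @property
    def has_dtu(self) -> bool:
        return self.effect_kind in ("DTU", "both")


@dataclass
class TruthTable:
    """Ground truth of the planted effects, per gene/isoform and dose group.

    ``genes``: gene_id, group, true_log2fc, is_de.
    ``isoforms``: isoform_id, gene_id, group, true_delta_psi, is_dtu.
    Null genes carry 0 everywhere; is_das(gene, group) = any member is_dtu.
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame

    def de_genes(self, group: str) -> list[str]:
        sub = self.genes[(self.genes["group"] == group) & self.genes["is_de"]]
        return sub["gene_id"].tolist()

    def dtu_isoforms(self, group: str) -> list[str]:
        sub = self.isoforms[(self.isoforms["group"] == group) & self.isoforms["is_dtu"]]
        return sub["isoform_id"].tolist()

    def das_genes(self, group: str) -> list[str]:
        sub = self.isoforms[(self.isoforms["group"] == group) & self.isoforms["is_dtu"]]
        return sorted(sub["gene_id"].unique().tolist())


@dataclass
class SimulationResult:
    """Per-tissue expression matrices plus ground truth and shared annotation."""

    tissues: dict[str, ExpressionMatrixSet]
    truth: TruthTable
    annotation: AnnotationMap
    lengths: pd.Series
    effective_lengths: pd.Series
    config: SimulationConfig
    effects: list[PlantedEffect]


def _master_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))


def simulate_annotation(cfg: SimulationConfig) -> AnnotationMap:
    """Draw a toy annotation: genes with 1-10 isoforms and mixed biotypes.

    The canonical (first) isoform of each gene is protein coding; further
    isoforms draw their biotype from ``cfg.biotype_probs``.  Deterministic in
    ``cfg.seed``.
    """
    rng = _master_rng(cfg)
    iso_counts = rng.choice(
        np.arange(1, len(cfg.isoform_count_probs) + 1),
        size=cfg.n_genes,
        p=np.asarray(cfg.isoform_count_probs, float),
    )
    bio_names = list(cfg.biotype_probs)
    bio_p = np.asarray([cfg.biotype_probs[b] for b in bio_names], float)
    bio_p = bio_p / bio_p.sum()
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    gene_symbol: dict[str, str] = {}
    for g in range(cfg.n_genes):
        gid = f"SGENE{g + 1:06d}"
        gene_symbol[gid] = f"Sg{g + 1:06d}"
        for k in range(int(iso_counts[g])):
            tid = f"{gid}.T{k + 1}"
            tx_gene[tid] = gid
            tx_biotype[tid] = "Pc" if k == 0 else str(rng.choice(bio_names, p=bio_p))
    return AnnotationMap(tx_gene, tx_biotype, gene_symbol)


def _structural_draws(cfg: SimulationConfig, ann: AnnotationMap, rng: np.random.Generator):
    """Baseline gene abundances, isoform usage, transcript lengths (shared)."""
    genes = ann.genes()
    gene_members = {g: ann.isoforms_of(g) for g in genes}
    # gene baseline relative abundance: heavy-tailed, as in real libraries
    theta = rng.lognormal(mean=0.0, sigma=1.5, size=len(genes))
    theta = theta / theta.sum()
    usage: dict[str, np.ndarray] = {}
    for g in genes:
        m = len(gene_members[g])
        usage[g] = np.full(1, 1.0) if m == 1 else rng.dirichlet(np.full(m, 2.0))
    transcripts = ann.transcripts
    lengths = pd.Series(
        rng.integers(500, 5001, size=len(transcripts)), index=transcripts, name="length"
    )
    efflen = (lengths - 200).clip(lower=1).astype(float)
    efflen.name = "effective_length"
    return genes, gene_members, theta, usage, lengths, efflen


def _resolve_effects(
    effects: Sequence[PlantedEffect],
    gene_members: dict[str, list[str]],
    usage: dict[str, np.ndarray],
) -> dict[str, PlantedEffect]:
    """Validate planted effects and pin down the switched isoform pairs."""
    resolved: dict[str, PlantedEffect] = {}
    for eff in effects:
        if eff.gene_id not in gene_members:
            raise ConfigError(f"effect gene {eff.gene_id} not in annotation")
        if eff.gene_id in resolved:
            raise ConfigError(f"duplicate effect for gene {eff.gene_id}")
        members = gene_members[eff.gene_id]
        if eff.has_dtu:
            if len(members) < 2:
                raise ConfigError(f"{eff.gene_id}: DTU effect needs >= 2 isoforms")
            pair = eff.switched_isoform_pair
            if pair is None:
                # auto pick: least-used isoform gains, most-used loses; the
                # losing isoform's baseline usage is topped up (mass taken
                # proportionally from the others) so the full-dose switch
                # stays within [0, 1]
                u = usage[eff.gene_id]
                gain_i, lose_i = int(np.argmin(u)), int(np.argmax(u))
                need = abs(eff.delta_psi_at_max_dose) + 0.05
                if u[lose_i] < need:
                    others = np.arange(u.size) != lose_i
                    u[others] *= (1.0 - need) / u[others].sum()
                    u[lose_i] = need
                    gain_i = int(np.argmin(u))
                pair = (members[gain_i], members[lose_i])
            gain, lose = pair
            if gain not in members or lose not in members or gain == lose:
                raise ConfigError(f"{eff.gene_id}: invalid switched_isoform_pair {pair}")
            u = usage[eff.gene_id]
            d = abs(eff.delta_psi_at_max_dose)
            if u[members.index(gain)] + d > 1.0 or u[members.index(lose)] - d < 0.0:
                raise ConfigError(
                    f"{eff.gene_id}: planted delta_psi {d} pushes a usage outside [0, 1]"
                )
            eff = PlantedEffect(
                gene_id=eff.gene_id,
                effect_kind=eff.effect_kind,
                base_log2fc_at_max_dose=eff.base_log2fc_at_max_dose,
                delta_psi_at_max_dose=eff.delta_psi_at_max_dose,
                dose_scaling=eff.dose_scaling,
                switched_isoform_pair=(gain, lose),
            )
        resolved[eff.gene_id] = eff
    return resolved


def _build_truth(
    cfg: SimulationConfig,
    genes: list[str],
    gene_members: dict[str, list[str]],
    resolved: dict[str, PlantedEffect],
) -> TruthTable:
    gene_rows, iso_rows = [], []
    for group in cfg.groups:
        for g in genes:
            eff = resolved.get(g)
            lfc = 0.0
            if eff is not None and eff.has_de:
                lfc = eff.base_log2fc_at_max_dose * cfg.dose_fraction(group, eff.dose_scaling)
            gene_rows.append((g, group, lfc, lfc != 0.0))
            for iso in gene_members[g]:
                dpsi = 0.0
                if eff is not None and eff.has_dtu:
                    f = cfg.dose_fraction(group, eff.dose_scaling)
                    gain, lose = eff.switched_isoform_pair  # type: ignore[misc]
                    if iso == gain:
                        dpsi = eff.delta_psi_at_max_dose * f
                    elif iso == lose:
                        dpsi = -eff.delta_psi_at_max_dose * f
                iso_rows.append((iso, g, group, dpsi, dpsi != 0.0))
    return TruthTable(
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "group", "true_log2fc", "is_de"]),
        isoforms=pd.DataFrame(
            iso_rows, columns=["isoform_id", "gene_id", "group", "true_delta_psi", "is_dtu"]
        ),
    )


def simulate_experiment(
    cfg: SimulationConfig,
    effects: Sequence[PlantedEffect] = (),
    ann: AnnotationMap | None = None,
) -> SimulationResult:
    """Generate per-tissue transcript count/TPM matrices with known truth.

    Expected isoform fragment count is library size x baseline gene abundance
    x gene fold-change(dose) x isoform usage(dose), weighted by effective
    length; counts are negative binomial (gamma-Poisson) with dispersion
    ``cfg.nb_dispersion``; TPM is recomputed from the sampled counts exactly
    as a quantifier would report it.
    """
    if ann is None:
        ann = simulate_annotation(cfg)
    # structural draws live on their own derived stream, independent of the
    # annotation stream, so passing a custom annotation changes nothing else
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x57A7]))
    genes, gene_members, theta, usage, lengths, efflen = _structural_draws(cfg, ann, rng)
    resolved = _resolve_effects(effects, gene_members, usage)
    truth = _build_truth(cfg, genes, gene_members, resolved)

    transcripts = ann.transcripts
    tx_index = pd.Index(transcripts)
    efflen_v = efflen.to_numpy()
    theta_by_gene = dict(zip(genes, theta))

    # per-group relative TPM profile per transcript (shared across tissues)
    group_rel = {}
    for group in cfg.groups:
        rel = np.empty(len(transcripts))
        pos = 0
        for g in genes:
            members = gene_members[g]
            eff = resolved.get(g)
            fold = 1.0
            u = usage[g].copy()
            if eff is not None:
                f = cfg.dose_fraction(group, eff.dose_scaling)
                if eff.has_de:
                    fold = 2.0 ** (eff.base_log2fc_at_max_dose * f)
                if eff.has_dtu:
                    gain, lose = eff.switched_isoform_pair  # type: ignore[misc]
                    u[members.index(gain)] += eff.delta_psi_at_max_dose * f
                    u[members.index(lose)] -= eff.delta_psi_at_max_dose * f
            rel[pos : pos + len(members)] = theta_by_gene[g] * fold * u
            pos += len(members)
        group_rel[group] = rel

    children = np.random.SeedSequence([cfg.seed, 0x5EED]).spawn(cfg.n_tissues)
    tissues: dict[str, ExpressionMatrixSet] = {}
    phi = cfg.nb_dispersion
    sigma_lib = np.sqrt(np.log(1.0 + cfg.library_size_cv**2))
    for t_idx, tissue in enumerate(cfg.tissues):
        t_rng = np.random.default_rng(children[t_idx])
        sample_ids, groups_col = [], []
        count_cols, tpm_cols = [], []
        for group, n in zip(cfg.groups, cfg.n_per_group):
            rel = group_rel[group]
            frag_w = rel * efflen_v
            frag_p = frag_w / frag_w.sum()
            for rep in range(1, n + 1):
                lib = cfg.library_size_mean * t_rng.lognormal(
                    mean=-0.5 * sigma_lib**2, sigma=sigma_lib
                )
                mu = lib * frag_p
                if phi > 0:
                    lam = t_rng.gamma(shape=1.0 / phi, scale=phi * mu)
                else:
                    lam = mu
                counts = t_rng.poisson(lam).astype(float)
                dens = counts / efflen_v
                tot = dens.sum()
                tpm = dens / tot * 1e6 if tot > 0 else np.zeros_like(dens)
                sample_ids.append(f"{tissue}_{group}_r{rep}")
                groups_col.append(group)
                count_cols.append(counts)
                tpm_cols.append(tpm)
        counts_df = pd.DataFrame(
            np.column_stack(count_cols), index=tx_index, columns=sample_ids
        )
        tpm_df = pd.DataFrame(np.column_stack(tpm_cols), index=tx_index, columns=sample_ids)
        sheet = pd.DataFrame(
            {"tissue": tissue, "group": groups_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        tissues[tissue] = ExpressionMatrixSet(
            counts=counts_df, tpm=tpm_df, feature_level="transcript", sample_sheet=sheet
        )
    return SimulationResult(
        tissues=tissues,
        truth=truth,
        annotation=ann,
        lengths=lengths,
        effective_lengths=efflen,
        config=cfg,
        effects=list(resolved.values()),
    )


def _spread(value, n: int) -> np.ndarray:
    """Scalar -> constant vector; (lo, hi) -> evenly spaced magnitudes."""
    if np.isscalar(value):
        return np.full(n, float(value))
    lo, hi = value
    if n == 1:
        return np.array([0.5 * (lo + hi)])
    return np.linspace(lo, hi, n)


def plan_effects(
    cfg: SimulationConfig,
    ann: AnnotationMap,
    n_de: int = 0,
    n_dtu: int = 0,
    n_both: int = 0,
    log2fc: float | tuple[float, float] = (0.7, 2.0),
    delta_psi: float | tuple[float, float] = (0.08, 0.30),
    dose_scaling: str = "linear",
    max_abs_delta_psi_feasible: float = 0.35,
) -> list[PlantedEffect]:
    """Pick effect genes deterministically (in annotation order) and build effects.

    Effect sizes may be scalars or (lo, hi) ranges; ranges are spread evenly
    across the effect genes, emulating the mix of weak and strong responders
    of a graded intervention (weak effects become detectable only at higher
    doses, so call counts keep growing along the dose axis instead of
    saturating).  Usage-switch effects go to multi-isoform genes only; the
    switched pair is resolved at simulation time from the baseline usage
    (gaining = least used, losing = most used isoform), which keeps planted
    shifts up to ~0.35 feasible under the Dirichlet baseline.
    """
    d_max = np.max(np.abs(np.atleast_1d(np.asarray(delta_psi, float))))
    if d_max > max_abs_delta_psi_feasible:
        raise ConfigError(
            f"delta_psi {delta_psi} may be infeasible under the baseline usage draw"
        )
    genes = ann.genes()
    multi = [g for g in genes if len(ann.isoforms_of(g)) >= 2]
    effects: list[PlantedEffect] = []
    multi_iter = iter(multi)
    dpsi_vals = _spread(delta_psi, n_dtu + n_both)
    lfc_vals = _spread(log2fc, n_both + n_de)
    for k in range(n_dtu):
        g = next(multi_iter, None)
        if g is None:
            raise ConfigError("not enough multi-isoform genes for requested DTU effects")
        effects.append(PlantedEffect(g, "DTU", 0.0, float(dpsi_vals[k]), dose_scaling))
    for k in range(n_both):
        g = next(multi_iter, None)
        if g is None:
            raise ConfigError("not enough multi-isoform genes for requested both-effects")
        effects.append(
            PlantedEffect(
                g, "both", float(lfc_vals[k]), float(dpsi_vals[n_dtu + k]), dose_scaling
            )
        )
    used = {e.gene_id for e in effects}
    de_candidates = (g for g in genes if g not in used)
    for k in range(n_de):
        g = next(de_candidates, None)
        if g is None:
            raise ConfigError("not enough genes for requested DE effects")
        effects.append(PlantedEffect(g, "DE", float(lfc_vals[n_both + k]), 0.0, dose_scaling))
    return effects


def write_fixture(sim: SimulationResult, directory: str | Path) -> Path:
    """Emit a fixture readable by the import stage without modification.

    Layout: ``quant/<sample>.quant.sf`` per sample, ``annotation.gtf``,
    ``samples.tsv`` (sample_id, tissue, group, path), ``truth_genes.tsv``,
    ``truth_isoforms.tsv`` and a ``sim_config.json`` echo.
    """
    directory = Path(directory)
    quant_dir = directory / "quant"
    quant_dir.mkdir(parents=True, exist_ok=True)
    ann = sim.annotation
    rows = []
    for tissue, ems in sim.tissues.items():
        for sample in ems.samples:
            path = quant_dir / f"{sample}.quant.sf"
            df = pd.DataFrame(
                {
                    "Name": ems.counts.index,
                    "Length": sim.lengths[ems.counts.index].to_numpy(),
                    "EffectiveLength": sim.effective_lengths[ems.counts.index].to_numpy(),
                    "TPM": ems.tpm[sample].to_numpy(),
                    "NumReads": ems.counts[sample].to_numpy(),
                }
            )
            df.to_csv(path, sep="\t", index=False, float_format="%.10g")
            rows.append(
                {
                    "sample_id": sample,
                    "tissue": tissue,
                    "group": ems.sample_sheet.loc[sample, "group"],
                    "path": str(path.relative_to(directory)),
                }
            )
    pd.DataFrame(rows).to_csv(directory / "samples.tsv", sep="\t", index=False)

    inverse_bt = {"Pc": "protein_coding", "NMD": "nonsense_mediated_decay",
                  "PT": "processed_transcript", "RI": "retained_intron", "other": "lincRNA"}
    with open(directory / "annotation.gtf", "w") as fh:
        fh.write("##description: synthetic toy annotation\n")
        for tid, gid in ann.transcript_gene.items():
            length = int(sim.lengths[tid])
            bt = inverse_bt[ann.transcript_biotype[tid]]
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'transcript_type "{bt}"; gene_name "{ann.gene_symbol[gid]}";'
            )
            fh.write(f"chrS\tsim\ttranscript\t1\t{length}\t.\t+\t.\t{attrs}\n")

    sim.truth.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    sim.truth.isoforms.to_csv(directory / "truth_isoforms.tsv", sep="\t", index=False)
    cfg = sim.config
    (directory / "sim_config.json").write_text(
        json.dumps(
            {
                "n_tissues": cfg.n_tissues,
                "groups": list(cfg.groups),
                "n_per_group": list(cfg.n_per_group),
                "n_genes": cfg.n_genes,
                "library_size_mean": cfg.library_size_mean,
                "library_size_cv": cfg.library_size_cv,
                "nb_dispersion": cfg.nb_dispersion,
                "seed": cfg.seed,
                "tissues": list(cfg.tissues),
            },
            indent=1,
        )
    )
    return directory
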