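"""Synthetic methylome, expression and region-set generator.

The generator emulates the statistical structure of methylation-array
data from regional epithelium so that every downstream stage can be
exercised and validated without external downloads:

* bimodal array-like beta distributions (a low/high Beta mixture per CpG),
* group-specific planted effects of a chosen delta beta at a fraction of
  CpGs (the first group is shifted relative to all others),
* manifest-style CpG annotation with genes, promoter/body feature groups
  and CpG-island relations,
* region sets in which planted differentially methylated CpGs are
  overrepresented by a chosen fold (plus matched decoy sets),
* promoter-methylation-coupled expression for a fraction of planted
  genes, and
* a linear admixture model mixing the pure epithelial signal with a
  shared contaminant profile at per-sample purity pi.

All randomness flows from one root seed through named substreams, so a
fixed configuration is byte-identically reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    PROMOTER_FEATURES,
    RegionSet,
    RegionSetCollection,
    SampleSheet,
    ValidationError,
)

_FEATURE_CHOICES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
_FEATURE_PROBS = (0.10, 0.10, 0.08, 0.07, 0.35, 0.10, 0.20)

# CGI relation given promoter vs non-promoter role
_CGI_PROM = (("Island", 0.70), ("N_Shore", 0.12), ("S_Shore", 0.12), ("N_Shelf", 0.03),
             ("S_Shelf", 0.03))
_CGI_BODY = (("OpenSea", 0.60), ("Island", 0.08), ("N_Shore", 0.08), ("S_Shore", 0.08),
             ("N_Shelf", 0.08), ("S_Shelf", 0.08))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Defaults reflect the design the analysis targets: 20,000 CpGs on a
    three-region design with six biological replicates per region,
    planted effects of delta beta 0.3 at 5% of CpGs, one region set with
    fivefold overrepresentation of planted CpGs among 200 sets, and
    promoter-expression coupling for half of the planted promoters.
    """

    seed: int
    n_cpgs: int = 20_000
    n_genes: int = 1_000
    groups: tuple[tuple[str, int], ...] = (("antrum", 6), ("corpus", 6), ("fundus", 6))
    planted_dm_fraction: float = 0.05
    planted_delta: float = 0.3
    beta_concentration: float = 30.0
    paired: bool = False
    pair_sd: float = 0.5
    coupling_fraction: float = 0.5
    enrichment_fold: float = 5.0
    n_region_sets: int = 200
    region_set_size: int = 500
    expression_slope: float = -4.0
    expression_noise_sd: float = 0.25

    def validate(self) -> None:
        for name in ("planted_dm_fraction", "coupling_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.planted_delta < 1:
            raise ValidationError(f"planted_delta must be in (0, 1), got {self.planted_delta}")
        if self.beta_concentration <= 2:
            raise ValidationError("beta_concentration must exceed 2")
        if self.enrichment_fold < 1:
            raise ValidationError("enrichment_fold must be >= 1")
        if self.paired and len({n for _, n in self.groups}) != 1:
            raise ValidationError("paired designs need equal group sizes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated data."""

    dm_effects: pd.Series                 # planted signed delta beta per DM CpG
    baseline_mu: pd.Series                # per-CpG baseline mean beta
    purity: pd.Series                     # per-sample epithelial fraction pi
    enriched_set_names: list[str] = field(default_factory=list)
    coupled_gene_ids: list[str] = field(default_factory=list)

    @property
    def dm_cpg_ids(self) -> list[str]:
        return list(self.dm_effects.index)


def generate_methylome(
    config: SimulationConfig,
) -> tuple[BetaMatrix, CpGAnnotation, SampleSheet, SimulationTruth]:
    """Generate beta matrix, annotation, sample sheet and ground truth.

    Baseline per-CpG mean betas are drawn from the {0.1, 0.9} bimodal
    mixture; betas are Beta-distributed around the (possibly shifted)
    group mean with the configured concentration.  Planted CpGs shift
    the first group's mean by +/- planted_delta, with the direction
    chosen among those keeping the target mean inside [0.02, 0.98]
    (hypermethylation at low-baseline CpGs, hypomethylation at high).
    """
    config.validate()
    rng = config.rng(0)
    n = config.n_cpgs

    cpg_ids = [f"cg{i:07d}" for i in range(n)]
    annotation = _generate_annotation(cpg_ids, config, rng)

    mu = rng.choice([0.1, 0.9], size=n, p=[0.5, 0.5])
    n_dm = int(round(config.planted_dm_fraction * n))
    dm_idx = np.sort(rng.choice(n, size=n_dm, replace=False))
    effects = np.empty(n_dm)
    for k, i in enumerate(dm_idx):
        can_hyper = mu[i] + config.planted_delta <= 0.98
        can_hypo = mu[i] - config.planted_delta >= 0.02
        if can_hyper and can_hypo:
            effects[k] = config.planted_delta * rng.choice([-1.0, 1.0])
        elif can_hyper:
            effects[k] = config.planted_delta
        elif can_hypo:
            effects[k] = -config.planted_delta
        else:
            effects[k] = config.planted_delta if mu[i] < 0.5 else -config.planted_delta

    sample_ids, group_labels, patient_ids = [], [], []
    for g, (label, n_samples) in enumerate(config.groups):
        for k in range(n_samples):
            sample_ids.append(f"{label}_{k + 1}")
            group_labels.append(label)
            patient_ids.append(f"P{k + 1}" if config.paired else f"P{g}_{k + 1}")
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": group_labels,
                "condition": group_labels,
                "patient_id": patient_ids,
            }
        )
    )

    first_label = config.groups[0][0]
    c = config.beta_concentration
    beta = np.empty((n, len(sample_ids)))
    target = np.tile(mu[:, None], (1, len(sample_ids)))
    affected_cols = np.array([lab == first_label for lab in group_labels])
    shifted = np.clip(mu[dm_idx] + effects, 0.02, 0.98)
    target[np.ix_(dm_idx, np.flatnonzero(affected_cols))] = shifted[:, None]
    beta = rng.beta(c * target, c * (1.0 - target))

    if config.paired:
        # shared per-patient intercept on the M scale
        eps = 1e-4
        m = np.log2(np.clip(beta, eps, 1 - eps) / (1 - np.clip(beta, eps, 1 - eps)))
        offsets = {}
        for pid in dict.fromkeys(patient_ids):
            offsets[pid] = rng.normal(0.0, config.pair_sd)
        for j, pid in enumerate(patient_ids):
            m[:, j] += offsets[pid]
        beta = 1.0 / (1.0 + np.power(2.0, -m))

    beta_matrix = BetaMatrix(pd.DataFrame(beta, index=cpg_ids, columns=sample_ids))
    realized_effects = shifted - mu[dm_idx]
    truth = SimulationTruth(
        dm_effects=pd.Series(realized_effects, index=[cpg_ids[i] for i in dm_idx]),
        baseline_mu=pd.Series(mu, index=cpg_ids),
        purity=pd.Series(1.0, index=sample_ids),
    )
    return beta_matrix, annotation, sheet, truth


def _generate_annotation(
    cpg_ids: list[str], config: SimulationConfig, rng: np.random.Generator
) -> CpGAnnotation:
    n = len(cpg_ids)
    n_chrom = 5
    gene_of = (np.arange(n) * config.n_genes) // n
    chrom_of = (gene_of * n_chrom) // config.n_genes
    positions = np.zeros(n, dtype=np.int64)
    cursor = {}
    for i in range(n):
        c = chrom_of[i]
        cursor[c] = cursor.get(c, 1000) + int(rng.integers(300, 700))
        positions[i] = cursor[c]

    roles = rng.choice(len(_FEATURE_CHOICES), size=n, p=_FEATURE_PROBS)
    extra_gene = rng.random(n) < 0.05
    genes, feats, cgi = [], [], []
    for i in range(n):
        role = _FEATURE_CHOICES[roles[i]]
        if role == "IGR":
            g: tuple[str, ...] = ()
            f: tuple[str, ...] = ()
        else:
            g = (f"G{gene_of[i]:04d}",)
            f = (role,)
            if extra_gene[i] and gene_of[i] + 1 < config.n_genes:
                g = g + (f"G{gene_of[i] + 1:04d}",)
                f = f + ("TSS1500",)
        table = _CGI_PROM if role in PROMOTER_FEATURES else _CGI_BODY
        labels, probs = zip(*table)
        cgi.append(str(rng.choice(labels, p=np.array(probs) / sum(probs))))
        genes.append(g)
        feats.append(f)
    frame = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": positions,
            "genes": genes,
            "feature_groups": feats,
            "cgi_relation": cgi,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return CpGAnnotation(frame)


def generate_expression(
    beta: BetaMatrix,
    truth: SimulationTruth,
    annotation: CpGAnnotation,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Expression matrix with promoter-methylation-coupled genes.

    Coupled genes (a fraction of genes carrying a planted promoter CpG)
    get expression affine in their mean promoter beta with the
    configured slope plus Gaussian noise; all other genes are
    independent noise around a gene-specific baseline.
    """
    rng = config.rng(1)
    gene_map = annotation.gene_map()
    prom = gene_map[gene_map["feature_group"].isin(PROMOTER_FEATURES)]
    genes_with_prom = set(prom["gene"])

    dm_set = set(truth.dm_cpg_ids)
    dm_prom_genes = sorted(set(prom.loc[prom["cpg_id"].isin(dm_set), "gene"]))
    n_coupled = int(round(config.coupling_fraction * len(dm_prom_genes)))
    coupled = list(rng.choice(dm_prom_genes, size=n_coupled, replace=False)) if n_coupled else []
    for g in coupled:
        if g not in genes_with_prom:
            raise ValidationError(f"coupling requested for gene without promoter CpGs: {g}")

    all_genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_samples = len(beta.sample_ids)
    base = rng.normal(8.0, 1.0, size=config.n_genes)
    expr = base[:, None] + rng.normal(0.0, 0.5, size=(config.n_genes, n_samples))

    prom_by_gene = prom.groupby("gene")["cpg_id"].apply(list)
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for g in coupled:
        prom_beta = beta.frame.loc[prom_by_gene[g]].mean(axis=0).to_numpy()
        centred = prom_beta - prom_beta.mean()
        expr[gene_index[g]] = (
            base[gene_index[g]]
            + config.expression_slope * centred
            + rng.normal(0.0, config.expression_noise_sd, size=n_samples)
        )
    truth.coupled_gene_ids = sorted(coupled)
    return ExpressionMatrix(
        pd.DataFrame(expr, index=all_genes, columns=beta.sample_ids)
    )


def generate_region_sets(
    annotation: CpGAnnotation,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> RegionSetCollection:
    """Region sets: one enriched for planted DM CpGs plus decoys.

    Each set is a collection of 2-bp windows centred on CpG positions.
    The enriched set samples CpGs with planted CpGs weighted
    ``enrichment_fold`` times higher than background; decoys sample
    uniformly.  With enrichment_fold == 1 every set is a null set.
    """
    config.validate()
    rng = config.rng(2)
    cpg_ids = np.array(annotation.cpg_ids)
    n = len(cpg_ids)
    size = min(config.region_set_size, n)
    planted = np.isin(cpg_ids, truth.dm_cpg_ids)

    weights = np.where(planted, config.enrichment_fold, 1.0)
    weights = weights / weights.sum()

    sets = []
    chosen = rng.choice(n, size=size, replace=False, p=weights)
    sets.append(_windows_set("enriched", annotation, cpg_ids[np.sort(chosen)]))
    for k in range(config.n_region_sets - 1):
        chosen = rng.choice(n, size=size, replace=False)
        sets.append(_windows_set(f"decoy_{k + 1:03d}", annotation, cpg_ids[np.sort(chosen)]))
    truth.enriched_set_names = ["enriched"] if config.enrichment_fold > 1 else []
    return RegionSetCollection(sets)


def _windows_set(name: str, annotation: CpGAnnotation, members: np.ndarray) -> RegionSet:
    sub = annotation.frame.loc[members]
    intervals = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": np.maximum(sub["pos"].to_numpy() - 2, 0),
            "end": sub["pos"].to_numpy(),
            "name": members,
        }
    )
    return RegionSet(name, intervals)


def mix_with_contaminant(
    pure: BetaMatrix,
    contaminant_profile: pd.Series,
    purity: pd.Series | float,
) -> BetaMatrix:
    """Linear admixture: beta_mixed = pi * beta_pure + (1 - pi) * contaminant.

    ``contaminant_profile`` is a per-CpG beta vector covering every CpG of
    the pure matrix; ``purity`` is a scalar or a per-sample series of the
    epithelial fraction pi in [0, 1].
    """
    missing = pure.frame.index.difference(contaminant_profile.index)
    if len(missing):
        raise ValidationError(
            f"contaminant profile missing {len(missing)} CpGs (e.g. {missing[0]})"
        )
    if np.isscalar(purity):
        pi = pd.Series(float(purity), index=pure.sample_ids)
    else:
        pi = purity.reindex(pure.sample_ids)
        if pi.isna().any():
            raise ValidationError("purity series does not cover all samples")
    if ((pi < 0) | (pi > 1)).any():
        raise ValidationError("purity values must lie in [0, 1]")
    cont = contaminant_profile.reindex(pure.frame.index).to_numpy()[:, None]
    mixed = pi.to_numpy()[None, :] * pure.values + (1 - pi.to_numpy()[None, :]) * cont
    return BetaMatrix(
        pd.DataFrame(mixed, index=pure.frame.index, columns=pure.sample_ids)
    )


def cgi_regions_from_annotation(annotation: CpGAnnotation, pad: int = 50) -> RegionSet:
    """Build CpG-island intervals from Island-annotated CpGs.

    Island CpGs are grouped per chromosome into runs closer than 2 kb and
    each run becomes one island interval (padded by ``pad`` bp).  Used by
    the end-to-end pipeline to derive island coordinates consistent with
    the synthetic annotation.
    """
    isl = annotation.frame[annotation.frame["cgi_relation"] == "Island"]
    rows = []
    k = 0
    for chrom, sub in isl.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size == 0:
            continue
        run_start = pos[0]
        prev = pos[0]
        for p in pos[1:]:
            if p - prev > 2000:
                rows.append((chrom, max(run_start - 1 - pad, 0), prev + pad, f"CGI_{k:05d}"))
                k += 1
                run_start = p
            prev = p
        rows.append((chrom, max(run_start - 1 - pad, 0), prev + pad, f"CGI_{k:05d}"))
        k += 1
    return RegionSet("cgi", pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_truth(truth: SimulationTruth, path) -> None:
    """Write the ground truth as a long-format TSV (kind, id, value)."""
    rows = [("dm_cpg", cpg, f"{eff:.6g}") for cpg, eff in truth.dm_effects.items()]
    rows += [("enriched_set", name, "") for name in truth.enriched_set_names]
    rows += [("coupled_gene", g, "") for g in truth.coupled_gene_ids]
    rows += [("purity", s, f"{pi:.6g}") for s, pi in truth.purity.items()]
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(path, sep="\t", index=False)
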