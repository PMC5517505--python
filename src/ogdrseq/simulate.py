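"""Synthetic five-condition OGD/R-style count matrices with planted truth.

The generator emulates the study design this pipeline targets: a single
RNA-seq library per condition over an oxygen-glucose-deprivation /
reperfusion time course (control; OGD; reperfusion at 6, 12 and 18 h), with
differential expression planted between conditions, co-expressed gene
modules planted via a shared latent condition profile, and gene sets
constructed to be enriched among the planted DE genes. Everything planted is
recorded in a :class:`SyntheticTruth` so downstream stages can be scored
against ground truth without any external data.

Noise model
-----------
Expected counts are length- and depth-scaled from a log-normal baseline
RPKM. Overdispersion (``dispersion`` = the usual negative-binomial alpha,
``Var = mu + alpha * mu^2``) is realised as a per-gene gamma random effect
with mean 1 and variance alpha that is *shared across libraries*, on top of
independent per-library Poisson shot noise. Marginally every count is
negative binomial around its scaled mean; between libraries the gene effect
cancels, which is the noise structure a replicate-free design can actually
resolve (a single library per condition carries no information about
per-library biological dispersion). ``dispersion=0`` is the pure Poisson
limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, ValidationError

#: condition names matching the five-point OGD/reperfusion design
OGDR_CONDITIONS = ("OGD0_R0h", "OGD45_R0h", "OGD45_R6h", "OGD45_R12h", "OGD45_R18h")

#: the four default treatment-vs-reference comparisons (acute OGD vs control,
#: then each reperfusion time point vs OGD)
OGDR_COMPARISONS = (
    ("OGD45_R0h", "OGD0_R0h"),
    ("OGD45_R6h", "OGD45_R0h"),
    ("OGD45_R12h", "OGD45_R0h"),
    ("OGD45_R18h", "OGD45_R0h"),
)

_GENE_LENGTH_FLOOR = 200  # bp; prevents degenerate RPKM denominators


def _condition_names(n: int) -> list[str]:
    if n == len(OGDR_CONDITIONS):
        return list(OGDR_CONDITIONS)
    return [f"cond{i:02d}" for i in range(n)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults describe the reference scenario used throughout the test suite:
    2000 genes, five conditions, one library of ~5 million mapped reads per
    condition, log-normal gene lengths (median ~1.5 kb, floored at 200 bp),
    log-normal baseline expression (median ~12 RPKM), negative-binomial
    overdispersion 0.05, 100 planted DE genes at 4-16 fold, three 30-gene
    co-expression modules at target correlation 0.95, and 50 gene sets of
    10-40 members of which 5 are enriched (80% of their members drawn from
    the planted DE genes).
    """

    n_genes: int = 2000
    n_conditions: int = 5
    n_replicates: int = 1
    mean_library_size: int = 5_000_000
    gene_length_log_mean: float = 7.3
    gene_length_log_sd: float = 0.6
    baseline_expression_log_mean: float = 2.5
    baseline_expression_log_sd: float = 1.0
    dispersion: float = 0.05
    n_de_genes: int = 100
    de_log2fc_range: tuple[float, float] = (2.0, 4.0)
    de_condition: int = 1
    n_modules: int = 3
    module_size: int = 30
    module_correlation: float = 0.95
    module_profile_sd: float = 2.0
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (10, 40)
    n_enriched_sets: int = 5
    enriched_set_de_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_conditions <= 0:
            raise ValidationError("n_conditions must be positive")
        if self.n_replicates <= 0:
            raise ValidationError("n_replicates must be positive")
        if self.mean_library_size <= 0:
            raise ValidationError("mean_library_size must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValidationError("n_de_genes must satisfy 0 <= n_de_genes <= n_genes")
        if self.de_log2fc_range[0] > self.de_log2fc_range[1]:
            raise ValidationError("de_log2fc_range must be ordered low <= high")
        if self.de_log2fc_range[0] < 0:
            raise ValidationError("de_log2fc_range bounds are absolute log2 fold changes (>= 0)")
        if not 1 <= self.de_condition < self.n_conditions:
            raise ValidationError("de_condition must index a non-reference condition")
        if self.n_modules < 0 or self.module_size <= 0:
            raise ValidationError("n_modules must be >= 0 and module_size > 0")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError("n_modules * module_size must not exceed n_genes")
        if self.n_de_genes + self.n_modules * self.module_size > self.n_genes:
            raise ValidationError(
                "planted DE genes and module genes must fit disjointly in n_genes"
            )
        if not 0 <= self.module_correlation < 1:
            raise ValidationError("module_correlation must be in [0, 1)")
        if self.n_gene_sets <= 0:
            raise ValidationError("n_gene_sets must be positive")
        lo, hi = self.gene_set_size_range
        if lo <= 0 or lo > hi:
            raise ValidationError("gene_set_size_range must be ordered positive low <= high")
        if hi > self.n_genes:
            raise ValidationError("gene_set_size_range upper bound exceeds n_genes")
        if self.n_enriched_sets < 0 or self.n_enriched_sets > self.n_gene_sets:
            raise ValidationError("n_enriched_sets must satisfy 0 <= n_enriched_sets <= n_gene_sets")
        if not 0 < self.enriched_set_de_fraction <= 1:
            raise ValidationError("enriched_set_de_fraction must be in (0, 1]")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def condition_names(self) -> list[str]:
        return _condition_names(self.n_conditions)

    def sample_ids(self) -> list[str]:
        conds = self.condition_names()
        if self.n_replicates == 1:
            return conds
        return [f"{c}_rep{r + 1}" for c in conds for r in range(self.n_replicates)]


@dataclass
class SyntheticTruth:
    """What a generated dataset planted, for scoring recovery downstream.

    ``de_genes`` maps each ordered condition pair ``(treatment, reference)``
    with at least one planted difference to ``{gene_id: signed log2 fold
    change}``. Module latent profiles induce real condition-dependence too;
    those genes are listed in ``module_assignments``, not in ``de_genes``.
    """

    de_genes: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    module_assignments: dict[str, str] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)

    def de_set(self, treatment: str, reference: str) -> frozenset[str]:
        return frozenset(self.de_genes.get((treatment, reference), {}))

    def all_de_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for d in self.de_genes.values():
            out |= d.keys()
        return frozenset(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": {
                f"{t}|{r}": dict(sorted(d.items())) for (t, r), d in sorted(self.de_genes.items())
            },
            "module_assignments": dict(sorted(self.module_assignments.items())),
            "enriched_terms": sorted(self.enriched_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        de = {}
        for key, d in payload["de_genes"].items():
            t, _, r = key.partition("|")
            de[(t, r)] = {g: float(v) for g, v in d.items()}
        return cls(
            de_genes=de,
            module_assignments=dict(payload["module_assignments"]),
            enriched_terms=set(payload["enriched_terms"]),
        )


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate a count matrix with planted DE genes and co-expression modules.

    Identical configs (including seed) yield bit-identical outputs; all draws
    flow through one seeded generator.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    g, c = config.n_genes, config.n_conditions

    lengths = np.maximum(
        _GENE_LENGTH_FLOOR,
        np.rint(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, g)),
    ).astype(np.int64)
    baseline_rpkm = rng.lognormal(
        config.baseline_expression_log_mean, config.baseline_expression_log_sd, g
    )

    gene_ids = config.gene_ids()
    conds = config.condition_names()

    # planted DE: each DE gene multiplies its expected expression by
    # 2^(signed lfc) in one perturbed condition (default: the OGD condition)
    planted = np.zeros((g, c))
    perm = rng.permutation(g)
    de_idx = perm[: config.n_de_genes]
    if config.n_de_genes:
        lfc = rng.uniform(*config.de_log2fc_range, config.n_de_genes)
        lfc *= rng.choice([-1.0, 1.0], config.n_de_genes)
        planted[de_idx, config.de_condition] = lfc

    # modules: gene log2 offset = sqrt(rho)*u_module + sqrt(1-rho)*eps_gene,
    # giving pairwise correlation ~= rho across conditions; module genes are
    # drawn disjointly from the DE genes so planted truth stays exact
    module_off = np.zeros((g, c))
    module_assignments: dict[str, str] = {}
    if config.n_modules:
        pool = perm[config.n_de_genes: config.n_de_genes + config.n_modules * config.module_size]
        rho, s = config.module_correlation, config.module_profile_sd
        for m in range(config.n_modules):
            members = pool[m * config.module_size: (m + 1) * config.module_size]
            u = rng.normal(0.0, s, c)
            eps = rng.normal(0.0, s, (len(members), c))
            module_off[members] = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps
            for i in members:
                module_assignments[gene_ids[i]] = f"M{m + 1:02d}"

    totals = np.rint(
        config.mean_library_size * rng.lognormal(0.0, 0.02, c * config.n_replicates)
    ).astype(np.int64)

    expected_rpkm = baseline_rpkm[:, None] * np.exp2(planted + module_off)
    rep = np.repeat(np.arange(c), config.n_replicates)
    mu = expected_rpkm[:, rep] * lengths[:, None] * totals[None, :] / 1e9

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        gene_effect = rng.gamma(shape, 1.0 / shape, g)  # mean 1, var = dispersion
        mu = mu * gene_effect[:, None]
    counts = rng.poisson(mu).astype(np.int64)

    sample_ids = config.sample_ids()
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        lengths=pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"), name="length_bp"),
        totals=pd.Series(totals, index=pd.Index(sample_ids), name="total_mapped_reads"),
    )

    # truth for every ordered condition pair, derived from planted offsets
    de_genes: dict[tuple[str, str], dict[str, float]] = {}
    for a in range(c):
        for b in range(c):
            if a == b:
                continue
            diff = planted[:, a] - planted[:, b]
            nz = np.nonzero(diff)[0]
            if nz.size:
                de_genes[(conds[a], conds[b])] = {gene_ids[i]: float(diff[i]) for i in nz}
    truth = SyntheticTruth(de_genes=de_genes, module_assignments=module_assignments)
    return cm, truth


def generate_gene_sets(config: SimulationConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Construct gene sets, a known subset of which is enriched in planted DE.

    ``n_enriched_sets`` sets draw ``enriched_set_de_fraction`` of their
    members from the planted DE genes (the rest uniformly from all genes);
    the remaining sets are uniform draws. Enriched term ids are recorded in
    ``truth.enriched_terms``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = np.array(config.gene_ids())
    de_pool = np.array(sorted(truth.all_de_genes()))

    lo, hi = config.gene_set_size_range
    sizes = rng.integers(lo, hi + 1, config.n_gene_sets)
    need = int(np.ceil(config.enriched_set_de_fraction * sizes[: config.n_enriched_sets].max()
                       if config.n_enriched_sets else 0))
    if config.n_enriched_sets and need > len(de_pool):
        raise ValidationError(
            f"enriched sets need up to {need} DE genes but only {len(de_pool)} were planted"
        )

    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    for i, size in enumerate(sizes):
        tid = f"T{i + 1:03d}"
        if i < config.n_enriched_sets:
            n_de = int(np.ceil(config.enriched_set_de_fraction * size))
            de_members = rng.choice(de_pool, n_de, replace=False)
            others = np.setdiff1d(gene_ids, de_members, assume_unique=False)
            fill = rng.choice(others, size - n_de, replace=False)
            members = frozenset(de_members) | frozenset(fill)
            desc = "planted enriched set"
            truth.enriched_terms.add(tid)
        else:
            members = frozenset(rng.choice(gene_ids, size, replace=False))
            desc = "background set"
        terms[tid] = (desc, "custom", members)
    return GeneSetCollection(terms=terms)


def generate_mechanism_list(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_de_members: int = 30,
    n_background: int = 20,
) -> frozenset[str]:
    """Synthetic stand-in for a curated known-mechanism gene list.

    Real screens use a literature-curated list (e.g. calcium-overload and
    oxygen-radical genes); the synthetic stand-in samples part of the planted
    DE genes plus unrelated background genes so the key-gene screen's third
    criterion has both hits and misses.
    """
    rng = np.random.default_rng([config.seed, 2])
    de_pool = np.array(sorted(truth.all_de_genes()))
    gene_ids = np.array(config.gene_ids())
    picked: set[str] = set()
    if len(de_pool):
        picked |= set(rng.choice(de_pool, min(n_de_members, len(de_pool)), replace=False))
    others = np.setdiff1d(gene_ids, np.array(sorted(picked)) if picked else np.array([], str))
    picked |= set(rng.choice(others, min(n_background, len(others)), replace=False))
    return frozenset(picked)
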