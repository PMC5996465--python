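"""Synthetic paired miR/gene expression with planted regulatory structure.

The generator emulates the situation the analysis is built to detect: two
conditions (A = baseline, B = disease-like) measured on the same features,
where some miRs regulate dedicated gene sets. Three kinds of structure are
planted:

* **Commodore miRs** — each solely regulates a large exclusive block of
  target genes (no other planted regulator touches those genes). Active in
  condition B only, so condition A should classify zero Commodores.
* **Redundant groups** — small sets of miRs that co-regulate one shared
  gene block. Group members share a latent factor (member = factor +
  jitter), so each member-target dependence carries the full coupling
  strength; the group's targets stay co-covered if any one member is
  removed, making members highly redundant. Active in both conditions.
* **Noise genes** — everything else is independent noise.

Profiles are log-normal: latent Gaussian signals are coupled linearly on
the log scale (target = sign * coupling * driver + noise, sign negative by
default to mimic miR repression) and exponentiated. Because the MI
estimator bins by rank, only the dependence structure matters, not the
marginal family.

Default dimensions (100 miRs x 3500 genes, 200 samples per condition) put
the planted pair fraction (~0.23% of the 350,000 pairs) just under the
default MI filter retention (top 0.259%), so the planted network is
recoverable at the pipeline's default quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationCatalog
from .errors import ConfigurationError
from .preprocessing import ExpressionMatrix

log = logging.getLogger("cdrenet")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark (defaults are the ones
    all packaged property checks run under)."""

    n_samples: int = 200
    n_mirs: int = 100
    n_genes: int = 3500
    n_commodores: int = 3
    commodore_target_count: int = 150
    n_redundant_groups: int = 2
    group_size: int = 3
    group_target_count: int = 60
    coupling_strength: float = 0.8
    noise_sd: float = 0.5
    member_jitter_sd: float = 0.3
    repression: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_samples", "n_mirs", "n_genes", "commodore_target_count",
                     "n_redundant_groups", "group_size", "group_target_count"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_commodores < 0:
            raise ConfigurationError("n_commodores must be nonnegative")
        if not (0.0 < self.coupling_strength <= 1.0):
            raise ConfigurationError("coupling_strength must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.member_jitter_sd < 0:
            raise ConfigurationError("member_jitter_sd must be nonnegative")
        needed_genes = (self.n_commodores * self.commodore_target_count
                        + self.n_redundant_groups * self.group_target_count)
        if needed_genes > self.n_genes:
            raise ConfigurationError(
                f"planted targets need {needed_genes} genes but n_genes="
                f"{self.n_genes} (n_commodores*commodore_target_count + "
                f"n_redundant_groups*group_target_count must be <= n_genes)"
            )
        needed_mirs = self.n_commodores + self.n_redundant_groups * self.group_size
        if needed_mirs > self.n_mirs:
            raise ConfigurationError(
                f"planted regulators need {needed_mirs} miRs but n_mirs={self.n_mirs}"
            )


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    regulon_map: dict[str, set[str]]
    commodore_ids: set[str]
    redundant_group_ids: list[set[str]]
    noise_sd: float
    # which planted structure is expressed in each condition
    active_structure: dict[str, list[str]] = field(
        default_factory=lambda: {
            "A": ["redundant_groups"],
            "B": ["redundant_groups", "commodores"],
        }
    )

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """All (regulator, target) pairs planted in condition B."""
        return {(m, g) for m, targets in self.regulon_map.items() for g in targets}

    def pairs_active_in(self, condition: str) -> set[tuple[str, str]]:
        active = self.active_structure[condition]
        pairs = set()
        if "redundant_groups" in active:
            members = set().union(*self.redundant_group_ids) if \
                self.redundant_group_ids else set()
            pairs |= {(m, g) for m, ts in self.regulon_map.items()
                      if m in members for g in ts}
        if "commodores" in active:
            pairs |= {(m, g) for m, ts in self.regulon_map.items()
                      if m in self.commodore_ids for g in ts}
        return pairs

    def to_json_dict(self) -> dict:
        return {
            "regulon_map": {m: sorted(g) for m, g in sorted(self.regulon_map.items())},
            "commodore_ids": sorted(self.commodore_ids),
            "redundant_group_ids": [sorted(g) for g in self.redundant_group_ids],
            "noise_sd": self.noise_sd,
            "active_structure": self.active_structure,
        }


@dataclass
class ConditionData:
    """The paired matrices of one condition."""

    mir: ExpressionMatrix
    gene: ExpressionMatrix


def _simulate_condition(
    config: SyntheticConfig,
    rng: np.random.Generator,
    condition: str,
    mir_ids: list[str],
    gene_ids: list[str],
    commodore_targets: dict[int, np.ndarray],
    group_members: list[list[int]],
    group_targets: list[np.ndarray],
    commodores_active: bool,
) -> ConditionData:
    c = config.coupling_strength
    sign = -1.0 if config.repression else 1.0
    n, n_mirs, n_genes = config.n_samples, config.n_mirs, config.n_genes

    mir_latent = rng.standard_normal((n_mirs, n))
    gene_latent = rng.standard_normal((n_genes, n))  # noise; overwritten for targets
    gene_noise = rng.standard_normal((n_genes, n))

    # redundant groups: members share a latent factor; targets follow it
    for members, targets in zip(group_members, group_targets):
        factor = rng.standard_normal(n)
        for m in members:
            mir_latent[m] = factor + config.member_jitter_sd * mir_latent[m]
        gene_latent[targets] = (
            sign * c * factor + config.noise_sd * gene_noise[targets]
        )

    if commodores_active:
        for m, targets in commodore_targets.items():
            gene_latent[targets] = (
                sign * c * mir_latent[m] + config.noise_sd * gene_noise[targets]
            )

    sample_ids = [f"{condition}-s{i + 1:03d}" for i in range(n)]
    mir_df = pd.DataFrame(np.exp(mir_latent), index=mir_ids, columns=sample_ids)
    gene_df = pd.DataFrame(np.exp(gene_latent), index=gene_ids, columns=sample_ids)
    return ConditionData(
        mir=ExpressionMatrix(mir_df, "mir", condition),
        gene=ExpressionMatrix(gene_df, "gene", condition),
    )


def generate_expression_pair(
    config: SyntheticConfig,
) -> tuple[ConditionData, ConditionData, GroundTruth]:
    """Generate paired miR/gene matrices for conditions A and B plus truth.

    Condition A contains only the redundant-group structure; condition B
    additionally activates the Commodore structure. Identical configs
    (including the seed) give bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    rng_struct, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    mir_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirs)]
    gene_ids = [f"gene-{i + 1:04d}" for i in range(config.n_genes)]

    # assign disjoint target blocks from a random gene permutation
    perm = rng_struct.permutation(config.n_genes)
    cursor = 0
    commodore_targets: dict[int, np.ndarray] = {}
    for i in range(config.n_commodores):
        commodore_targets[i] = perm[cursor:cursor + config.commodore_target_count]
        cursor += config.commodore_target_count
    group_targets: list[np.ndarray] = []
    for _ in range(config.n_redundant_groups):
        group_targets.append(perm[cursor:cursor + config.group_target_count])
        cursor += config.group_target_count
    group_members = []
    m_cursor = config.n_commodores
    for _ in range(config.n_redundant_groups):
        group_members.append(list(range(m_cursor, m_cursor + config.group_size)))
        m_cursor += config.group_size

    regulon: dict[str, set[str]] = {}
    for m, targets in commodore_targets.items():
        regulon[mir_ids[m]] = {gene_ids[g] for g in targets}
    for members, targets in zip(group_members, group_targets):
        tset = {gene_ids[g] for g in targets}
        for m in members:
            regulon[mir_ids[m]] = set(tset)

    truth = GroundTruth(
        regulon_map=regulon,
        commodore_ids={mir_ids[m] for m in commodore_targets},
        redundant_group_ids=[{mir_ids[m] for m in members}
                             for members in group_members],
        noise_sd=config.noise_sd,
    )

    cond_a = _simulate_condition(
        config, rng_a, "A", mir_ids, gene_ids, commodore_targets,
        group_members, group_targets, commodores_active=False,
    )
    cond_b = _simulate_condition(
        config, rng_b, "B", mir_ids, gene_ids, commodore_targets,
        group_members, group_targets, commodores_active=True,
    )
    log.info(
        "simulated %d miRs x %d genes x %d samples per condition "
        "(%d commodores, %d redundant groups)",
        config.n_mirs, config.n_genes, config.n_samples,
        config.n_commodores, config.n_redundant_groups,
    )
    return cond_a, cond_b, truth


@dataclass
class PlantedEnrichment:
    """Spec for one category planted to overlap a designated gene set."""

    target_genes: frozenset
    overlap: int
    size: int
    category_id: str = "planted-1"
    description: str = "planted enriched category"


def generate_annotation(
    gene_ids,
    n_categories: int = 150,
    size_range: tuple[int, int] = (10, 100),
    planted: PlantedEnrichment | None = None,
    rng_seed: int = 0,
) -> AnnotationCatalog:
    """Random annotation catalog over the gene universe, with optional
    planted true enrichment.

    Categories are gene subsets sampled without replacement; if ``planted``
    is given, one extra category is built from ``overlap`` genes of the
    designated target set plus random non-target genes up to ``size``.
    """
    gene_ids = list(gene_ids)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(gene_ids)):
        raise ConfigurationError(
            f"size_range {size_range} must lie within [1, {len(gene_ids)}]"
        )
    if n_categories < 0:
        raise ConfigurationError("n_categories must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    cats: dict[str, tuple[str, frozenset]] = {}
    width = max(3, len(str(max(n_categories, 1))))
    for i in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(rng.choice(gene_ids, size=size, replace=False))
        cid = f"CAT:{i + 1:0{width}d}"
        cats[cid] = (f"random category {i + 1}", genes)
    if planted is not None:
        target = sorted(planted.target_genes)
        if planted.overlap > min(planted.size, len(target)):
            raise ConfigurationError(
                "planted overlap exceeds the target set or category size"
            )
        non_target = sorted(set(gene_ids) - set(target))
        if planted.size - planted.overlap > len(non_target):
            raise ConfigurationError("planted category larger than the universe allows")
        chosen = list(rng.choice(target, size=planted.overlap, replace=False))
        chosen += list(
            rng.choice(non_target, size=planted.size - planted.overlap, replace=False)
        )
        cats[planted.category_id] = (planted.description, frozenset(chosen))
    return AnnotationCatalog(cats, universe=frozenset(gene_ids))
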