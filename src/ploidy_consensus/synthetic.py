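"""Synthetic multi-cohort ploidy study with known planted structure.

The generator emulates the layout of a five-cohort diploid-vs-polyploid
meta-analysis: independent cohorts on mixed platforms (negative-binomial
RNA-seq counts and Gaussian log-intensity microarrays), two species linked
by an ortholog table, a shared planted ploidy signal (genes shifted in the
same direction in every cohort) on top of cohort-specific noise DEGs, a
scale-free interaction network with planted hub regulators whose
neighborhoods are packed with planted DEGs, and a GMT signature collection
with a subset of sets enriched for planted genes. Every planted element is
recorded in a :class:`GroundTruth` so downstream stages have recovery
oracles.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` children, one per component, so each
component is reproducible in isolation and emitted files are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    DIPLOID,
    PLATFORM_COUNTS,
    PLATFORM_INTENSITY,
    PLATFORM_KINDS,
    POLYPLOID,
    ExpressionDataset,
    OrthologMap,
    SignatureCollection,
)
from .errors import ValidationError
from . import io_formats

#: default per-cohort platform pattern: two microarray-like, three count-based
DEFAULT_PLATFORMS = (
    PLATFORM_INTENSITY,
    PLATFORM_COUNTS,
    PLATFORM_INTENSITY,
    PLATFORM_COUNTS,
    PLATFORM_COUNTS,
)

#: default species pattern: cohorts 2 and 3 are mouse, the rest human
DEFAULT_SPECIES = ("human", "mouse", "mouse", "human", "human")


@dataclass
class NetworkParams:
    """Interaction-network generation knobs."""

    attachment_degree: int = 3
    n_planted_hubs: int = 10
    hub_neighborhood_size: int = 20
    hub_deg_fraction: float = 0.8


@dataclass
class SignatureParams:
    """Signature-collection generation knobs."""

    n_signatures: int = 100
    min_size: int = 20
    max_size: int = 60
    n_enriched: int = 10
    enrichment_fraction: float = 0.5


@dataclass
class SimulationConfig:
    """Full study-design description for one synthetic run.

    Defaults reproduce the reference layout: 5 cohorts, 2000 genes, 6
    samples per ploidy group, 50 planted up + 50 planted down genes with a
    2-fold-per-doubling (log2) effect, and 30 cohort-private noise DEGs
    per cohort.
    """

    n_cohorts: int = 5
    n_genes: int = 2000
    samples_per_group: int = 6
    n_planted_up: int = 50
    n_planted_down: int = 50
    effect_size: float = 2.0
    cohort_noise_degs: int = 30
    platform_kinds: tuple[str, ...] | None = None
    species: tuple[str, ...] | None = None
    ortholog_one_to_one_fraction: float = 0.95
    network: NetworkParams = field(default_factory=NetworkParams)
    signatures: SignatureParams = field(default_factory=SignatureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.n_genes < 1 or self.samples_per_group < 2:
            raise ValidationError(
                "need n_cohorts >= 1, n_genes >= 1, samples_per_group >= 2"
            )
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ValidationError("planted gene counts must be non-negative")
        committed = (
            self.n_planted_up
            + self.n_planted_down
            + self.cohort_noise_degs * self.n_cohorts
        )
        if committed > self.n_genes:
            raise ValidationError(
                f"planted + noise genes ({committed}) exceed n_genes ({self.n_genes})"
            )
        if self.platform_kinds is None:
            pattern = DEFAULT_PLATFORMS
            self.platform_kinds = tuple(
                pattern[i % len(pattern)] for i in range(self.n_cohorts)
            )
        self.platform_kinds = tuple(self.platform_kinds)
        if len(self.platform_kinds) != self.n_cohorts:
            raise ValidationError("platform_kinds length must equal n_cohorts")
        bad = set(self.platform_kinds) - set(PLATFORM_KINDS)
        if bad:
            raise ValidationError(f"unknown platform kind(s): {sorted(bad)}")
        if self.species is None:
            pattern = DEFAULT_SPECIES
            self.species = tuple(
                pattern[i % len(pattern)] for i in range(self.n_cohorts)
            )
        self.species = tuple(self.species)
        if len(self.species) != self.n_cohorts:
            raise ValidationError("species length must equal n_cohorts")
        if not 0.0 <= self.ortholog_one_to_one_fraction <= 1.0:
            raise ValidationError("ortholog_one_to_one_fraction must be in [0,1]")
        if self.network.hub_neighborhood_size >= self.n_genes:
            raise ValidationError("hub_neighborhood_size must be < n_genes")
        if self.network.hub_neighborhood_size <= 5:
            raise ValidationError(
                "hub_neighborhood_size must exceed 5 so hubs are testable"
            )
        if not 0.0 <= self.network.hub_deg_fraction <= 1.0:
            raise ValidationError("hub_deg_fraction must be in [0,1]")
        sig = self.signatures
        if sig.min_size < 1 or sig.max_size < sig.min_size:
            raise ValidationError("signature sizes must satisfy 1 <= min <= max")
        if sig.n_enriched > sig.n_signatures:
            raise ValidationError("n_enriched exceeds n_signatures")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic study."""

    planted_up: frozenset[str]
    planted_down: frozenset[str]
    planted_hubs: frozenset[str]
    hubs_up: frozenset[str]
    hubs_down: frozenset[str]
    enriched_signatures: frozenset[str]
    enriched_up_signatures: frozenset[str]
    enriched_down_signatures: frozenset[str]
    cohort_noise: dict[str, frozenset[str]]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValidationError("planted up/down sets overlap")


# ---------------------------------------------------------------------------
# seeding layout — fixed child indices keep components independently
# reproducible
# ---------------------------------------------------------------------------

_CHILD_ROLES = 0  # gene-role assignment
_CHILD_NETWORK = 1
_CHILD_SIGNATURES = 2
_CHILD_ORTHOLOGS = 3
_CHILD_COHORT_BASE = 10  # cohort c uses child _CHILD_COHORT_BASE + c
_CHILD_VALIDATION_BASE = 1000


def _child_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(index + 1)
    return np.random.default_rng(children[index])


def gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


def _assign_roles(config: SimulationConfig) -> GroundTruth:
    """Draw disjoint planted-up / planted-down / per-cohort noise gene sets."""
    rng = _child_rng(config, _CHILD_ROLES)
    genes = gene_ids(config.n_genes)
    shuffled = list(rng.permutation(genes))
    cursor = 0
    planted_up = shuffled[cursor : cursor + config.n_planted_up]
    cursor += config.n_planted_up
    planted_down = shuffled[cursor : cursor + config.n_planted_down]
    cursor += config.n_planted_down
    cohort_noise: dict[str, frozenset[str]] = {}
    for c in range(config.n_cohorts):
        chunk = shuffled[cursor : cursor + config.cohort_noise_degs]
        cursor += config.cohort_noise_degs
        cohort_noise[f"cohort_{c + 1}"] = frozenset(chunk)

    n_hubs = config.network.n_planted_hubs
    n_hubs_up = min((n_hubs + 1) // 2, len(planted_up))
    n_hubs_down = min(n_hubs - n_hubs_up, len(planted_down))
    hubs_up = frozenset(planted_up[:n_hubs_up])
    hubs_down = frozenset(planted_down[:n_hubs_down])

    sig = config.signatures
    enriched = [f"sig_enriched_{i + 1:03d}" for i in range(sig.n_enriched)]
    enriched_up = frozenset(enriched[0::2])
    enriched_down = frozenset(enriched[1::2])
    return GroundTruth(
        planted_up=frozenset(planted_up),
        planted_down=frozenset(planted_down),
        planted_hubs=hubs_up | hubs_down,
        hubs_up=hubs_up,
        hubs_down=hubs_down,
        enriched_signatures=frozenset(enriched),
        enriched_up_signatures=enriched_up,
        enriched_down_signatures=enriched_down,
        cohort_noise=cohort_noise,
        genes=tuple(genes),
    )


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

def _effect_vector(
    config: SimulationConfig,
    truth: GroundTruth,
    cohort_name: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene log2 shift applied to the polyploid group in this cohort."""
    delta = np.zeros(len(truth.genes))
    index = {g: i for i, g in enumerate(truth.genes)}
    for g in truth.planted_up:
        delta[index[g]] = config.effect_size
    for g in truth.planted_down:
        delta[index[g]] = -config.effect_size
    for g in sorted(truth.cohort_noise.get(cohort_name, ())):
        delta[index[g]] = config.effect_size * (1 if rng.random() < 0.5 else -1)
    return delta


def _sample_cohort(
    config: SimulationConfig,
    truth: GroundTruth,
    cohort_name: str,
    platform: str,
    species: str,
    rng: np.random.Generator,
    ortholog_map: OrthologMap | None,
) -> ExpressionDataset:
    n = config.samples_per_group
    samples = [f"{cohort_name}_dip{j + 1}" for j in range(n)] + [
        f"{cohort_name}_pol{j + 1}" for j in range(n)
    ]
    groups = {s: DIPLOID if "_dip" in s else POLYPLOID for s in samples}
    delta = _effect_vector(config, truth, cohort_name, rng)
    n_genes = len(truth.genes)

    if platform == PLATFORM_COUNTS:
        # gene-level abundance with a dispersion ~ 1/mean trend; median
        # depth ~ 256 counts per gene, typical for bulk libraries
        log2_mean = rng.normal(8.0, 1.5, size=n_genes)
        base_mean = 2.0 ** np.clip(log2_mean, 1.0, 14.0)
        dispersion = 0.05 + 2.0 / base_mean
        r = 1.0 / dispersion
        values = np.empty((n_genes, 2 * n))
        for j, sample in enumerate(samples):
            mean = base_mean * (
                2.0 ** delta if groups[sample] == POLYPLOID else 1.0
            )
            p = r / (r + mean)
            values[:, j] = rng.negative_binomial(r, p)
    else:
        base = rng.normal(7.0, 1.5, size=n_genes)
        gene_sd = 0.15 + np.abs(rng.normal(0.3, 0.1, size=n_genes))
        values = np.empty((n_genes, 2 * n))
        for j, sample in enumerate(samples):
            shift = delta if groups[sample] == POLYPLOID else 0.0
            values[:, j] = base + shift + rng.normal(0.0, gene_sd)

    matrix = pd.DataFrame(values, index=list(truth.genes), columns=samples)
    if species != "human":
        if ortholog_map is None:
            raise ValidationError(
                f"cohort {cohort_name}: non-human species needs an ortholog map"
            )
        # relabel rows into the mouse namespace; duplicated orthologs copy
        # their human gene's profile
        humans = [a for a, _ in ortholog_map.pairs]
        mice = [b for _, b in ortholog_map.pairs]
        mouse_matrix = matrix.loc[humans].copy()
        mouse_matrix.index = mice
        matrix = mouse_matrix
    return ExpressionDataset(
        name=cohort_name,
        matrix=matrix,
        sample_groups=groups,
        platform=platform,
        species=species,
    )


def simulate_orthologs(config: SimulationConfig) -> OrthologMap:
    """Human/mouse ortholog table: mostly 1:1, the rest one-to-many.

    A configurable fraction of genes get a single mouse ortholog
    (``Mxxxxx`` ids); the remaining human genes each get two mouse
    orthologs, which the 1:1 mapping rule later drops — exercising the
    conservative ortholog-restriction path.
    """
    rng = _child_rng(config, _CHILD_ORTHOLOGS)
    genes = gene_ids(config.n_genes)
    n_one_to_one = int(round(config.ortholog_one_to_one_fraction * len(genes)))
    # planted / noise genes stay 1:1 so the consensus signal survives mapping
    truth = _assign_roles(config)
    special = truth.planted_up | truth.planted_down
    for s in truth.cohort_noise.values():
        special |= s
    plain = [g for g in genes if g not in special]
    rng.shuffle(plain)
    n_multi = len(genes) - n_one_to_one
    multi = set(plain[:n_multi])
    pairs: list[tuple[str, str]] = []
    counter = 1
    for g in genes:
        pairs.append((g, f"M{counter:05d}"))
        counter += 1
        if g in multi:
            pairs.append((g, f"M{counter:05d}"))
            counter += 1
    return OrthologMap(pairs=pairs, species_a="human", species_b="mouse")


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate all consensus cohorts plus the planted ground truth."""
    truth = _assign_roles(config)
    ortholog_map = simulate_orthologs(config)
    datasets = []
    for c in range(config.n_cohorts):
        name = f"cohort_{c + 1}"
        rng = _child_rng(config, _CHILD_COHORT_BASE + c)
        datasets.append(
            _sample_cohort(
                config,
                truth,
                name,
                config.platform_kinds[c],
                config.species[c],
                rng,
                ortholog_map,
            )
        )
    return datasets, truth


def simulate_validation_cohort(
    config: SimulationConfig, truth: GroundTruth, index: int = 0
) -> ExpressionDataset:
    """An extra held-out cohort carrying the same planted ploidy signal.

    Used as the external study for signature-overlap validation; always
    human counts so it needs no ortholog mapping.
    """
    rng = _child_rng(config, _CHILD_VALIDATION_BASE + index)
    return _sample_cohort(
        config,
        truth,
        f"validation_{index + 1}",
        PLATFORM_COUNTS,
        "human",
        rng,
        None,
    )


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def simulate_network(config: SimulationConfig, truth: GroundTruth) -> nx.Graph:
    """Scale-free background graph with planted DEG-dense hubs.

    Preferential attachment supplies the background degree distribution;
    each planted hub is then rewired to a fresh neighborhood of
    ``hub_neighborhood_size`` genes of which a fraction
    ``hub_deg_fraction`` are planted DEGs of the hub's own direction.
    """
    params = config.network
    rng = _child_rng(config, _CHILD_NETWORK)
    seed_int = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(
        config.n_genes, params.attachment_degree, seed=seed_int
    )
    genes = list(truth.genes)
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))

    for hub in sorted(truth.planted_hubs):
        direction_set = (
            truth.planted_up if hub in truth.hubs_up else truth.planted_down
        )
        n_deg = int(round(params.hub_deg_fraction * params.hub_neighborhood_size))
        # other hubs are excluded from the pools: a hub's later rewiring
        # clears its own edge list and would sever a previously wired hub
        deg_pool = sorted(direction_set - truth.planted_hubs)
        n_deg = min(n_deg, len(deg_pool))
        chosen = list(rng.choice(deg_pool, size=n_deg, replace=False))
        other_pool = sorted(
            set(genes)
            - truth.planted_up
            - truth.planted_down
            - truth.planted_hubs
            - {hub}
            - set(chosen)
        )
        n_other = params.hub_neighborhood_size - n_deg
        chosen += list(rng.choice(other_pool, size=n_other, replace=False))
        graph.remove_edges_from(list(graph.edges(hub)))
        graph.add_edges_from((hub, nbr) for nbr in chosen)
    return graph


# ---------------------------------------------------------------------------
# signature collection
# ---------------------------------------------------------------------------

def simulate_signatures(
    config: SimulationConfig, truth: GroundTruth
) -> SignatureCollection:
    """GMT collection: planted-enriched signatures plus uniform null sets.

    Enriched signatures draw ``enrichment_fraction`` of their members from
    one planted direction (alternating up/down across the enriched sets);
    null signatures are uniform draws from the whole gene universe.
    """
    params = config.signatures
    rng = _child_rng(config, _CHILD_SIGNATURES)
    genes = np.array(truth.genes)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(params.n_signatures):
        size = int(rng.integers(params.min_size, params.max_size + 1))
        if i < params.n_enriched:
            name = f"sig_enriched_{i + 1:03d}"
            planted = (
                truth.planted_up
                if name in truth.enriched_up_signatures
                else truth.planted_down
            )
            planted = sorted(planted)
            n_planted = min(int(round(params.enrichment_fraction * size)), len(planted))
            members = set(rng.choice(planted, size=n_planted, replace=False))
            pool = sorted(set(genes) - set(planted))
            members |= set(rng.choice(pool, size=size - n_planted, replace=False))
            descriptions[name] = "planted-enriched"
        else:
            name = f"sig_null_{i + 1:03d}"
            members = set(rng.choice(genes, size=size, replace=False))
            descriptions[name] = "null"
        sets[name] = frozenset(members)
    return SignatureCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# full-study emission
# ---------------------------------------------------------------------------

def write_study(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate everything and write the study to ``outdir`` as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, truth = simulate_cohorts(config)
    ortholog_map = simulate_orthologs(config)
    network = simulate_network(config, truth)
    signatures = simulate_signatures(config, truth)

    for ds in datasets:
        matrix = ds.matrix
        if ds.platform == PLATFORM_COUNTS:
            ds = ExpressionDataset(
                name=ds.name,
                matrix=matrix.astype(int),
                sample_groups=ds.sample_groups,
                platform=ds.platform,
                species=ds.species,
            )
        io_formats.write_expression(ds, outdir / f"{ds.name}_expression.tsv")
        io_formats.write_sample_metadata(ds, outdir / f"{ds.name}_samples.tsv")
    io_formats.write_orthologs(ortholog_map, outdir / "orthologs.tsv")
    io_formats.write_edge_list(network, outdir / "network.tsv")
    io_formats.write_gmt(signatures, outdir / "signatures.gmt")
    io_formats.write_gene_list(truth.planted_up, outdir / "truth_planted_up.tsv")
    io_formats.write_gene_list(truth.planted_down, outdir / "truth_planted_down.tsv")
    io_formats.write_gene_list(truth.planted_hubs, outdir / "truth_hubs.tsv")
    with open(outdir / "truth_enriched_signatures.tsv", "w", encoding="utf-8") as fh:
        fh.write("signature\n")
        for name in sorted(truth.enriched_signatures):
            fh.write(name + "\n")
    return truth
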