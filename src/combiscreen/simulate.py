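"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the screen's real inputs at desk scale:

* ``gen_cohort`` — a negative-binomial RNA-seq case/control cohort with a
  recorded subset of genes carrying a planted log2 mean shift;
* ``gen_perturbation_panel`` — signed perturbation profiles per
  (compound, cell line, experiment) with latent mechanisms; designated
  "reverser" compounds oppose the disease signature on genes outside the
  reference drug's support (high DR, zero CR by construction) and "mimic"
  compounds copy the reference (high CR);
* ``gen_ppi_with_modules`` — a preferential-attachment protein-interaction
  graph with a densified two-sub-region disease module and drug target sets
  placed to realize each exposure scenario (complementary / overlapping /
  single / non);
* ``gen_dose_matrix`` — Hill-curve monotherapies combined under Bliss
  independence plus a planted synergy delta and multiplicative noise.

All generators are deterministic given (config, seed) and return the ground
truth alongside the data so downstream tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .network import CATEGORIES, COMPLEMENTARY, NON, OVERLAPPING, SINGLE, ProteinSet
from .signatures import ExpressionCohort, PerturbationPanel, SignedSignature
from .synergy import DoseResponseMatrix

__all__ = [
    "CohortConfig",
    "PanelConfig",
    "NetworkConfig",
    "DoseConfig",
    "SimulationConfig",
    "gen_cohort",
    "gen_perturbation_panel",
    "gen_ppi_with_modules",
    "gen_dose_matrix",
]


def _check_positive(**kwargs) -> None:
    for name, v in kwargs.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")


def _check_prob(**kwargs) -> None:
    for name, v in kwargs.items():
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class CohortConfig:
    """Negative-binomial case/control cohort with planted DE genes.

    Means are log-normal across genes (median ~55 counts); the planted genes
    get a log2 shift of +/- ``lfc_magnitude`` applied to the case arm, half up,
    half down.  ``nb_dispersion`` is the NB size-reciprocal: var = mu + d*mu^2.
    """

    n_genes: int = 1000
    n_case: int = 20
    n_control: int = 20
    fraction_de: float = 0.05
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    log_mean_mu: float = 4.0
    log_mean_sigma: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(
            n_genes=self.n_genes, n_case=self.n_case, n_control=self.n_control
        )
        _check_prob(fraction_de=self.fraction_de)
        if self.nb_dispersion < 0 or self.lfc_magnitude < 0:
            raise ValueError("dispersion and lfc_magnitude must be non-negative")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[ExpressionCohort, pd.DataFrame]:
    """Simulated cohort plus a per-gene truth table (is_de, true_lfc)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    base = np.exp(rng.normal(config.log_mean_mu, config.log_mean_sigma, config.n_genes))
    n_de = int(round(config.fraction_de * config.n_genes))
    if config.fraction_de > 0 and n_de < 1:
        warnings.warn("fraction_de * n_genes < 1; planting zero DE genes", stacklevel=2)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    true_lfc = np.zeros(config.n_genes)
    signs = np.ones(n_de)
    signs[n_de // 2 :] = -1.0
    true_lfc[de_idx] = signs * config.lfc_magnitude
    case_mean = base * 2.0**true_lfc
    case = _nb_draw(
        rng, np.repeat(case_mean[:, None], config.n_case, axis=1), config.nb_dispersion
    )
    ctrl = _nb_draw(
        rng, np.repeat(base[:, None], config.n_control, axis=1), config.nb_dispersion
    )
    samples = [f"case{i:03d}" for i in range(config.n_case)] + [
        f"ctrl{i:03d}" for i in range(config.n_control)
    ]
    values = pd.DataFrame(
        np.hstack([case, ctrl]), index=pd.Index(genes, name="gene"), columns=samples
    )
    conditions = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )
    truth = pd.DataFrame(
        {"is_de": true_lfc != 0, "true_lfc": true_lfc},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionCohort(values, conditions, units="counts"), truth


@dataclass
class PanelConfig:
    """Perturbation panel: compounds x cell lines x experiments.

    Latent mechanisms are sparse signed vectors of ``mechanism_size`` genes at
    magnitude ``mechanism_magnitude``; each record adds a per-cell-line offset
    and per-experiment Gaussian noise, mimicking level-4 robust z-scores.
    ``n_reversers``/``n_mimics`` compounds get planted structure relative to
    the reference mechanism and the disease signature.  ``call_threshold`` is
    the per-experiment binarization cut to use when screening these
    continuous scores (half the mechanism magnitude, a robust-z-style |z|>=1
    cut): without it every gene of every profile would call +/-1 and the
    reference signature would cover the whole universe.
    """

    n_compounds: int = 100
    n_reversers: int = 3
    n_mimics: int = 5
    n_cell_lines: int = 3
    n_experiments: int = 3
    mechanism_size: int = 150
    mechanism_magnitude: float = 2.0
    cell_line_sd: float = 0.3
    noise_sd: float = 0.5
    call_threshold: float = 1.0
    reference_id: str = "reference-0"

    def __post_init__(self) -> None:
        _check_positive(
            n_compounds=self.n_compounds,
            n_cell_lines=self.n_cell_lines,
            n_experiments=self.n_experiments,
            mechanism_size=self.mechanism_size,
        )
        if self.n_reversers + self.n_mimics > self.n_compounds:
            raise ValueError("n_reversers + n_mimics exceeds n_compounds")
        if self.cell_line_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def gen_perturbation_panel(
    config: PanelConfig,
    disease: SignedSignature,
    reference_mechanism: pd.Series | None = None,
    seed: int | None = None,
) -> tuple[PerturbationPanel, dict]:
    """Panel plus truth {roles, mechanisms, reference_id}.

    The reference compound's mechanism covers ``mechanism_size`` random genes;
    reversers take the opposite sign on the reference's support and oppose the
    disease signature on disease genes outside it, so that with no noise their
    normalized CR is 0 and DR is 1 against the reference.
    """
    rng = np.random.default_rng(seed)
    genes = disease.genes
    n_genes = len(genes)
    if config.mechanism_size > n_genes:
        raise ValueError("mechanism_size exceeds the gene universe")
    mag = config.mechanism_magnitude
    if reference_mechanism is None:
        idx = rng.choice(n_genes, size=config.mechanism_size, replace=False)
        ref = np.zeros(n_genes)
        ref[idx] = rng.choice([-mag, mag], size=config.mechanism_size)
        reference_mechanism = pd.Series(ref, index=genes)
    else:
        reference_mechanism = reference_mechanism.reindex(genes, fill_value=0.0)
        if (reference_mechanism != 0).sum() == 0:
            raise ValueError("reference mechanism is empty on the gene universe")
    ref_support = reference_mechanism.to_numpy() != 0
    d_dir = disease.direction_on(genes)
    disease_only = (d_dir != 0) & ~ref_support

    mechanisms: dict[str, np.ndarray] = {config.reference_id: reference_mechanism.to_numpy()}
    roles: dict[str, str] = {config.reference_id: "reference"}
    n_background = config.n_compounds - config.n_reversers - config.n_mimics
    names = (
        [f"reverser-{i}" for i in range(config.n_reversers)]
        + [f"mimic-{i}" for i in range(config.n_mimics)]
        + [f"compound-{i:03d}" for i in range(n_background)]
    )
    for name in names:
        mech = np.zeros(n_genes)
        if name.startswith("reverser"):
            mech[ref_support] = -reference_mechanism.to_numpy()[ref_support]
            mech[disease_only] = -mag * d_dir[disease_only]
            roles[name] = "reverser"
        elif name.startswith("mimic"):
            mech[ref_support] = reference_mechanism.to_numpy()[ref_support]
            roles[name] = "mimic"
        else:
            idx = rng.choice(n_genes, size=config.mechanism_size, replace=False)
            mech[idx] = rng.choice([-mag, mag], size=config.mechanism_size)
            roles[name] = "background"
        mechanisms[name] = mech

    rows = []
    index = []
    for name in [config.reference_id] + names:
        mech = mechanisms[name]
        for cl in range(config.n_cell_lines):
            offset = rng.normal(0.0, config.cell_line_sd, n_genes)
            for exp in range(config.n_experiments):
                noise = rng.normal(0.0, config.noise_sd, n_genes)
                rows.append(mech + offset + noise)
                index.append((name, f"CL{cl}", f"exp{exp}"))
    scores = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(
            index, names=["compound", "cell_line", "experiment"]
        ),
        columns=genes,
    )
    truth = {
        "roles": roles,
        "mechanisms": pd.DataFrame(mechanisms, index=genes),
        "reference_id": config.reference_id,
    }
    return PerturbationPanel(scores), truth


@dataclass
class NetworkConfig:
    """Preferential-attachment PPI with a planted two-sub-region disease module.

    Each sub-region of ``subregion_size`` nodes is densified with internal
    edge probability ``p_within``; the two sub-regions are linked with the
    much sparser ``p_cross`` so they stay topologically distinct.  Distant
    target communities hang off the node farthest from the disease module via
    a path of ``appendix_length`` nodes.
    """

    n_nodes: int = 400
    attachment_m: int = 3
    subregion_size: int = 20
    p_within: float = 0.35
    p_cross: float = 0.02
    target_size: int = 8
    overlap_fraction: float = 0.5
    appendix_length: int = 5

    def __post_init__(self) -> None:
        _check_positive(
            n_nodes=self.n_nodes,
            attachment_m=self.attachment_m,
            subregion_size=self.subregion_size,
            target_size=self.target_size,
            appendix_length=self.appendix_length,
        )
        _check_prob(
            p_within=self.p_within,
            p_cross=self.p_cross,
            overlap_fraction=self.overlap_fraction,
        )
        if 2 * self.subregion_size >= self.n_nodes:
            raise ValueError("disease module must be smaller than the graph")
        if self.target_size > self.subregion_size:
            raise ValueError("target_size exceeds subregion_size")
        if self.p_cross >= self.p_within:
            raise ValueError(
                "p_cross >= p_within would merge the disease sub-regions"
            )


def _densify(graph: nx.Graph, nodes: list, p: float, rng: np.random.Generator) -> None:
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if not graph.has_edge(u, v) and rng.random() < p:
                graph.add_edge(u, v)


def _grow_distant_cluster(
    graph: nx.Graph,
    disease_nodes: set,
    config: NetworkConfig,
    rng: np.random.Generator,
    exclude: set,
) -> list:
    """Attach a small target community far from the disease module."""
    dist = nx.multi_source_dijkstra_path_length(graph, disease_nodes, weight=None)
    candidates = [
        n
        for n in graph.nodes()
        if n not in exclude and isinstance(n, int)
    ]
    far = max(candidates, key=lambda n: (dist.get(n, -1), -graph.degree(n)))
    prev = far
    base = graph.number_of_nodes()
    for k in range(config.appendix_length):
        node = f"apx{base}_{k}"
        graph.add_edge(prev, node)
        prev = node
    cluster = [f"tgt{base}_{k}" for k in range(config.target_size)]
    for node in cluster:
        graph.add_edge(prev, node)
    _densify(graph, cluster, 0.3, rng)
    return cluster


def gen_ppi_with_modules(
    config: NetworkConfig,
    scenario: str = COMPLEMENTARY,
    seed: int | None = None,
) -> tuple[nx.Graph, ProteinSet, ProteinSet, ProteinSet, str]:
    """(graph, disease, drugA, drugB, planted_category) for one scenario.

    complementary: each drug's targets sit in a distinct disease sub-region;
    overlapping: both drugs sample the same sub-region with forced overlap;
    single: drug A in a sub-region, drug B in a distant appended community;
    non: both drugs in distant communities.
    """
    if scenario not in CATEGORIES:
        raise ValueError(f"scenario must be one of {CATEGORIES}, got {scenario!r}")
    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(
        config.n_nodes, config.attachment_m, seed=int(rng.integers(2**31))
    )
    module_nodes = rng.choice(
        config.n_nodes, size=2 * config.subregion_size, replace=False
    )
    region1 = [int(n) for n in module_nodes[: config.subregion_size]]
    region2 = [int(n) for n in module_nodes[config.subregion_size :]]
    _densify(graph, region1, config.p_within, rng)
    _densify(graph, region2, config.p_within, rng)
    for u in region1:
        for v in region2:
            if not graph.has_edge(u, v) and rng.random() < config.p_cross:
                graph.add_edge(u, v)
    disease_nodes = set(region1) | set(region2)
    disease = ProteinSet("disease", disease_nodes)

    def sample_targets(region: list) -> list:
        idx = rng.choice(len(region), size=config.target_size, replace=False)
        return [region[i] for i in idx]

    if scenario == COMPLEMENTARY:
        a = sample_targets(region1)
        b = sample_targets(region2)
    elif scenario == OVERLAPPING:
        a = sample_targets(region1)
        n_shared = max(1, int(round(config.overlap_fraction * config.target_size)))
        rest = [n for n in region1 if n not in a]
        idx = rng.choice(len(rest), size=config.target_size - n_shared, replace=False)
        b = a[:n_shared] + [rest[i] for i in idx]
    elif scenario == SINGLE:
        a = sample_targets(region1)
        b = _grow_distant_cluster(graph, disease_nodes, config, rng, exclude=disease_nodes)
    else:  # NON
        a = _grow_distant_cluster(graph, disease_nodes, config, rng, exclude=disease_nodes)
        b = _grow_distant_cluster(
            graph, disease_nodes, config, rng, exclude=disease_nodes | set(a)
        )
    return graph, disease, ProteinSet("drugA", a), ProteinSet("drugB", b), scenario


@dataclass
class DoseConfig:
    """Checkerboard generator: Hill monotherapies + Bliss + planted delta.

    Default curves are deliberately sub-saturating (Emax 0.8 / 0.75, top dose
    2x EC50) so a planted delta up to ~0.15 does not clip at full inhibition;
    this keeps planted-delta recovery unbiased by construction.
    """

    n_doses: int = 6
    dose_min: float = 0.0625
    dose_max: float = 2.0
    emax_a: float = 0.8
    ec50_a: float = 1.0
    slope_a: float = 1.3
    emax_b: float = 0.75
    ec50_b: float = 0.8
    slope_b: float = 1.0
    planted_delta: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        _check_positive(
            n_doses=self.n_doses,
            dose_min=self.dose_min,
            dose_max=self.dose_max,
            ec50_a=self.ec50_a,
            ec50_b=self.ec50_b,
            slope_a=self.slope_a,
            slope_b=self.slope_b,
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_doses < 4:
            raise ValueError("need >=4 non-zero doses per axis for curve fitting")
        if self.dose_min >= self.dose_max:
            raise ValueError("dose grid must be ascending")
        _check_prob(emax_a=self.emax_a, emax_b=self.emax_b)


def _hill(x: np.ndarray, emax: float, ec50: float, slope: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        return np.where(x > 0, emax / (1.0 + (ec50 / np.maximum(x, 1e-300)) ** slope), 0.0)


def gen_dose_matrix(
    config: DoseConfig,
    drug_a: str = "drugA",
    drug_b: str = "drugB",
    seed: int | None = None,
) -> tuple[DoseResponseMatrix, np.ndarray]:
    """(matrix, true_delta_surface): Bliss expectation + delta, noised, clipped."""
    rng = np.random.default_rng(seed)
    doses = np.concatenate(
        [[0.0], np.geomspace(config.dose_min, config.dose_max, config.n_doses)]
    )
    y_a = _hill(doses, config.emax_a, config.ec50_a, config.slope_a)
    y_b = _hill(doses, config.emax_b, config.ec50_b, config.slope_b)
    bliss = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    truth = np.full((config.n_doses, config.n_doses), config.planted_delta)
    expected = bliss.copy()
    expected[1:, 1:] += truth
    noise = rng.normal(0.0, config.noise_sd, expected.shape) if config.noise_sd else 0.0
    response = np.clip(expected * (1.0 + noise), 0.0, 1.0)
    response[0, 0] = 0.0
    matrix = DoseResponseMatrix(drug_a, drug_b, doses, doses.copy(), response)
    return matrix, truth


@dataclass
class SimulationConfig:
    """Bundle of per-stage generator configs plus the master seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)

    def child_seeds(self, n: int) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]

    def to_dict(self) -> dict:
        return asdict(self)
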