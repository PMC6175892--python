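"""Synthetic inputs with planted ground truth.

Every pipeline input — probe-level two-group expression studies, probe
annotations, ortholog maps, drug-signature libraries, scored PPI edge
lists, and gene-set collections — can be generated here with a known
planted signal, so each downstream stage is testable by recovery:

* studies plant a stated fraction of differentially expressed genes at a
  signed log-scale effect size on a Gaussian noise background, expand
  genes to multiple probes with probe-level jitter, and leave a fraction
  of probes unannotated;
* libraries plant reverser drugs whose signatures have an exact target
  cosine (-fidelity) with a given disease direction, mimickers at
  +fidelity, and isotropic-noise null drugs;
* PPI graphs are Erdos-Renyi backgrounds with planted hub nodes wired to
  extra random neighbours;
* gene-set collections plant one set with a stated overlap with a
  companion query list.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cdscreen.io_formats import (
    CASE,
    CONTROL,
    EdgeList,
    ExpressionStudy,
    GeneSetCollection,
    ProbeAnnotation,
    SignatureLibrary,
    edge_list_from_records,
)
from cdscreen.signature import SignatureVector


@dataclass
class GroundTruth:
    """Planted signal manifest accompanying each generated object."""

    deg_signs: dict[str, str] = field(default_factory=dict)
    reversers: list[str] = field(default_factory=list)
    mimickers: list[str] = field(default_factory=list)
    hubs: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    query_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "deg_signs": self.deg_signs,
            "reversers": self.reversers,
            "mimickers": self.mimickers,
            "hubs": self.hubs,
            "enriched_sets": self.enriched_sets,
            "query_genes": self.query_genes,
        }


@dataclass
class StudySpec:
    """Parameters of a synthetic two-group expression study.

    Defaults emulate a small RMA-normalized microarray contrast: log2
    intensities with baseline spread across genes, per-gene Gaussian noise
    of sd 0.5, 10% of genes differentially expressed at a +/-1.5 log-unit
    shift (half up, half down), most genes measured by one or two probes,
    and 5% of probes lacking a gene annotation.
    """

    n_genes: int = 1000
    n_control: int = 10
    n_case: int = 10
    deg_fraction: float = 0.10
    effect_size: float = 1.5
    noise_sd: float = 0.5
    n_probes_per_gene: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(1), P(2), P(3)
    unmapped_probe_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_case < 3:
            raise ValueError("need >= 3 samples per group")
        if not 0.0 <= self.deg_fraction < 0.5:
            raise ValueError("deg_fraction must be in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        probs = np.asarray(self.n_probes_per_gene, dtype=float)
        if probs.ndim != 1 or probs.size == 0 or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("n_probes_per_gene must be probabilities summing to 1")
        if not 0.0 <= self.unmapped_probe_fraction < 1.0:
            raise ValueError("unmapped_probe_fraction must be in [0, 1)")


@dataclass
class LibrarySpec:
    """Parameters of a synthetic drug-perturbation signature library.

    Defaults: 200 drugs over the disease gene space, one planted reverser
    with cosine fidelity 0.8 to the negated disease direction, the rest
    isotropic Gaussian nulls of unit per-gene sd.
    """

    n_drugs: int = 200
    n_reversers: int = 1
    n_mimickers: int = 0
    reverser_fidelity: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reversers + self.n_mimickers > self.n_drugs:
            raise ValueError("planted drugs exceed n_drugs")
        if not 0.0 < self.reverser_fidelity <= 1.0:
            raise ValueError("reverser_fidelity must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def planted_direction(spec: StudySpec) -> SignatureVector:
    """Unit vector of the planted effect pattern (the true disease axis)."""
    truth = _deg_assignment(spec)
    coeff = pd.Series(0.0, index=gene_names(spec.n_genes))
    for g, s in truth.items():
        coeff[g] = 1.0 if s == "up" else -1.0
    arr = coeff.to_numpy()
    if not arr.any():
        raise ValueError("spec plants no DEGs; no direction defined")
    coeff = coeff / np.linalg.norm(arr)
    return SignatureVector(coefficients=coeff, gamma=float("nan"))


def _deg_assignment(spec: StudySpec) -> dict[str, str]:
    genes = gene_names(spec.n_genes)
    n_deg = round(spec.deg_fraction * spec.n_genes)
    n_up = n_deg // 2 + n_deg % 2
    truth: dict[str, str] = {}
    for i in range(n_deg):
        truth[genes[i]] = "up" if i < n_up else "down"
    return truth


def simulate_study(
    spec: StudySpec,
) -> tuple[ExpressionStudy, ProbeAnnotation, GroundTruth]:
    """Generate a probe-level two-group study with planted DEGs.

    Gene-level values are baseline + N(0, noise_sd) per sample; case
    samples of planted DEGs are shifted by +/- effect_size.  Each gene is
    expanded to 1..k probes with per-cell jitter of sd noise_sd / 2;
    the requested fraction of probes is left unannotated, but never a
    gene's first probe, so every planted gene stays recoverable.
    """
    rng = np.random.default_rng(spec.seed)
    genes = gene_names(spec.n_genes)
    truth = _deg_assignment(spec)
    n_samples = spec.n_control + spec.n_case
    sample_ids = [f"C{i:03d}" for i in range(1, spec.n_control + 1)] + [
        f"T{i:03d}" for i in range(1, spec.n_case + 1)
    ]
    groups = pd.Series(
        [CONTROL] * spec.n_control + [CASE] * spec.n_case, index=sample_ids
    )

    baseline = rng.uniform(4.0, 12.0, size=spec.n_genes)
    shift = np.zeros(spec.n_genes)
    for i, g in enumerate(genes):
        if g in truth:
            shift[i] = spec.effect_size if truth[g] == "up" else -spec.effect_size
    gene_values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, n_samples)
    )
    gene_values[:, spec.n_control:] += shift[:, None]

    probs = np.asarray(spec.n_probes_per_gene, dtype=float)
    n_probes_each = rng.choice(np.arange(1, probs.size + 1), size=spec.n_genes, p=probs)

    probe_rows = []
    probe_ids: list[str] = []
    mapping: dict[str, str | None] = {}
    guard: list[bool] = []  # first probe of each gene is never unannotated
    for i, g in enumerate(genes):
        for k in range(int(n_probes_each[i])):
            pid = f"P{i + 1:05d}_{k + 1}"
            probe_ids.append(pid)
            mapping[pid] = g
            guard.append(k == 0)
            jitter = rng.normal(0.0, spec.noise_sd / 2.0, size=n_samples)
            probe_rows.append(gene_values[i] + jitter)
    values = pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=sample_ids)

    n_probes = len(probe_ids)
    n_unmapped = int(round(spec.unmapped_probe_fraction * n_probes))
    eligible = [i for i, is_guard in enumerate(guard) if not is_guard]
    if n_unmapped > 0 and eligible:
        chosen = rng.choice(eligible, size=min(n_unmapped, len(eligible)),
                            replace=False)
        for i in chosen:
            mapping[probe_ids[i]] = None

    study = ExpressionStudy(values=values, groups=groups)
    ann = ProbeAnnotation(mapping=mapping)
    return study, ann, GroundTruth(deg_signs=truth)


def simulate_library(
    spec: LibrarySpec, disease_direction: SignatureVector
) -> tuple[SignatureLibrary, GroundTruth]:
    """Generate a drug-signature library with planted reversers/mimickers.

    A planted drug's signature is built by projection decomposition:
    s = sign * fidelity * d + sqrt(1 - fidelity^2) * u with u a unit
    vector orthogonal to the disease direction d, so cos(s, d) equals
    -fidelity (reversers) or +fidelity (mimickers) exactly.  Remaining
    drugs are isotropic Gaussian noise.
    """
    d = disease_direction.coefficients.to_numpy(dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("disease direction is the zero vector")
    d = d / norm
    p = d.size
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"DRUG{i:04d}" for i in range(1, spec.n_drugs + 1)]
    rows = np.empty((spec.n_drugs, p))

    def planted_row(sign: float) -> np.ndarray:
        g = rng.normal(0.0, 1.0, size=p)
        g -= (g @ d) * d
        g_norm = np.linalg.norm(g)
        if g_norm == 0:  # degenerate draw; fall back to pure direction
            u = np.zeros(p)
        else:
            u = g / g_norm
        fid = spec.reverser_fidelity
        return sign * fid * d + np.sqrt(max(0.0, 1.0 - fid**2)) * u

    truth = GroundTruth()
    for i in range(spec.n_drugs):
        if i < spec.n_reversers:
            rows[i] = planted_row(-1.0)
            truth.reversers.append(drug_ids[i])
        elif i < spec.n_reversers + spec.n_mimickers:
            rows[i] = planted_row(+1.0)
            truth.mimickers.append(drug_ids[i])
        else:
            row = rng.normal(0.0, spec.noise_sd, size=p)
            while not row.any():  # pragma: no cover - probability ~0
                row = rng.normal(0.0, spec.noise_sd, size=p)
            rows[i] = row
    lib = SignatureLibrary(
        values=pd.DataFrame(
            rows, index=drug_ids, columns=list(disease_direction.gene_ids)
        )
    )
    return lib, truth


def simulate_ppi(
    n_nodes: int,
    edge_prob: float,
    n_hubs: int,
    hub_degree_boost: int,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> tuple[EdgeList, GroundTruth]:
    """Erdos-Renyi scored PPI background with planted hub nodes.

    Background edges appear independently with probability ``edge_prob``
    and carry combined scores uniform in [800, 1000]; each of the first
    ``n_hubs`` nodes is additionally wired to ``hub_degree_boost`` extra
    random non-neighbour nodes.
    """
    if not 0.0 < edge_prob < 1.0:
        raise ValueError("edge_prob must be in (0, 1)")
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be smaller than n_nodes")
    rng = np.random.default_rng(seed)
    if node_names is None:
        node_names = [f"N{i:04d}" for i in range(1, n_nodes + 1)]
    elif len(node_names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")

    pairs: set[tuple[int, int]] = set()
    for i in range(n_nodes):
        draws = rng.random(n_nodes - i - 1)
        for off in np.flatnonzero(draws < edge_prob):
            pairs.add((i, i + 1 + int(off)))
    hubs = list(range(n_hubs))
    for h in hubs:
        neighbours = {j for i, j in pairs if i == h} | {i for i, j in pairs if j == h}
        candidates = [j for j in range(n_nodes) if j != h and j not in neighbours]
        k = min(hub_degree_boost, len(candidates))
        extra = rng.choice(len(candidates), size=k, replace=False)
        for idx in extra:
            j = candidates[int(idx)]
            pairs.add((min(h, j), max(h, j)))

    records = []
    for i, j in sorted(pairs):
        score = int(rng.integers(800, 1001))
        records.append((node_names[i], node_names[j], score))
    edges = edge_list_from_records(records)
    return edges, GroundTruth(hubs=[node_names[h] for h in hubs])


def simulate_gene_sets(
    universe: list[str],
    n_sets: int,
    set_size: int,
    planted_query_overlap: int,
    seed: int = 0,
    query_size: int | None = None,
    query: list[str] | None = None,
) -> tuple[GeneSetCollection, GroundTruth]:
    """Gene-set collection with one set enriched in a companion query list.

    The query list (default size = set_size) is sampled from the universe
    unless supplied explicitly; the planted set contains
    ``planted_query_overlap`` of its genes, the rest drawn from outside
    the query.  The other n_sets - 1 sets are uniform random samples of
    the universe.
    """
    universe = list(dict.fromkeys(universe))
    if set_size >= len(universe):
        raise ValueError("set_size must be smaller than the universe")
    if planted_query_overlap > set_size:
        raise ValueError("overlap cannot exceed set_size")
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    if query is None:
        if query_size is None:
            query_size = set_size
        if planted_query_overlap > query_size:
            raise ValueError("overlap cannot exceed the query size")
        query = list(rng.choice(uni, size=query_size, replace=False))
    else:
        query = list(dict.fromkeys(query))
        if not set(query) <= set(universe):
            raise ValueError("query genes must lie in the universe")
        if planted_query_overlap > len(query):
            raise ValueError("overlap cannot exceed the query size")
    non_query = [g for g in universe if g not in set(query)]
    if set_size - planted_query_overlap > len(non_query):
        raise ValueError("universe too small for the requested set composition")

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    in_q = list(rng.choice(np.asarray(query, dtype=object),
                           size=planted_query_overlap, replace=False))
    out_q = list(rng.choice(np.asarray(non_query, dtype=object),
                            size=set_size - planted_query_overlap, replace=False))
    sets["SET_PLANTED"] = ("planted enriched set", tuple(in_q + out_q))
    for s in range(2, n_sets + 1):
        members = rng.choice(uni, size=set_size, replace=False)
        sets[f"SET{s:03d}"] = ("random set", tuple(members))
    truth = GroundTruth(enriched_sets=["SET_PLANTED"], query_genes=list(query))
    return GeneSetCollection(sets=sets), truth
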