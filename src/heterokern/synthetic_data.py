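"""Seeded synthetic datasets with the structure the classifier assumes.

The generator plants heterodimer pairs whose edge weight is drawn from a
heavier log-normal than the surrounding background edges, and whose two
proteins receive *different* noisy copies of a shared template pair of
domain compositions. Positives therefore resemble other positives across
pairs but not within a pair — the structure the metric-learning lift is
designed to exploit. Larger complexes become cliques of background-weight
edges and supply the co-complex negatives.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_model_io import (
    ComplexCatalog,
    ProfileTable,
    WeightedPPINetwork,
    canonical_pair,
    write_complex_catalog,
    write_profile_table,
    write_weighted_ppi,
)


@dataclass(frozen=True)
class SimulationParams:
    n_proteins: int = 300
    n_domains: int = 60
    n_templates: int = 8          # domain-composition template pairs shared across positives
    n_positive_pairs: int = 40
    n_large_complexes: int = 30
    complex_size_min: int = 3
    complex_size_max: int = 6
    background_edge_prob: float = 0.02
    mu_heterodimer: float = 2.0   # log-normal location of planted heterodimer weights
    mu_background: float = 0.5
    sigma_weight: float = 0.4
    domain_noise_prob: float = 0.1  # per-slot corruption of template copies
    n_genomes: int = 50
    n_localizations: int = 8
    profile_flip_prob: float = 0.1
    localization_informative: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("background_edge_prob", "domain_noise_prob", "profile_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.complex_size_min < 3 or self.complex_size_max < self.complex_size_min:
            raise ValueError("complex sizes must satisfy 3 <= min <= max")
        if 2 * self.n_positive_pairs > self.n_proteins:
            raise ValueError(
                f"protein budget exhausted: {self.n_positive_pairs} planted pairs "
                f"need {2 * self.n_positive_pairs} proteins, have {self.n_proteins}"
            )


@dataclass
class SyntheticTruth:
    """Provenance of the planted structure: pairs, complexes, params, seed."""

    positive_pairs: list[tuple[str, str]]
    large_complexes: dict[str, list[str]]
    params: SimulationParams

    def write_json(self, path: str | Path) -> None:
        payload = {
            "positive_pairs": [list(p) for p in self.positive_pairs],
            "large_complexes": {k: sorted(v) for k, v in sorted(self.large_complexes.items())},
            "params": asdict(self.params),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _protein_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _template_composition(rng: np.random.Generator, n_domains: int) -> np.ndarray:
    """A count vector over 10-20 distinct domains with multiplicities 1-3.

    Dense enough that unrelated compositions overlap by chance: template
    similarity must survive on top of that background, not on empty support.
    """
    k = int(rng.integers(10, 21))
    idx = rng.choice(n_domains, size=k, replace=False)
    v = np.zeros(n_domains, dtype=np.int64)
    v[idx] = rng.integers(1, 4, size=k)
    return v


def _noisy_copy(rng: np.random.Generator, comp: np.ndarray, noise: float) -> np.ndarray:
    """Corrupt each slot independently with probability ``noise``.

    Corrupted slots take their value from a fresh background composition, so
    noise interpolates toward the background distribution (noise=1 is an
    unrelated draw) without inflating total domain counts.
    """
    v = comp.copy()
    mask = rng.random(v.size) < noise
    fresh = _template_composition(rng, v.size)
    v[mask] = fresh[mask]
    return v


def simulate(
    params: SimulationParams,
) -> tuple[WeightedPPINetwork, tuple[ProfileTable, ProfileTable, ProfileTable], ComplexCatalog, SyntheticTruth]:
    """Generate (network, (dom, phylo, local) tables, catalog, truth), seeded."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    proteins = _protein_names(params.n_proteins)

    # planted heterodimers on a dedicated protein prefix
    positive_pairs: list[tuple[str, str]] = []
    for k in range(params.n_positive_pairs):
        positive_pairs.append(canonical_pair(proteins[2 * k], proteins[2 * k + 1]))
    pool = proteins[2 * params.n_positive_pairs:]

    # large complexes on disjoint proteins from the remaining pool
    sizes = rng.integers(
        params.complex_size_min, params.complex_size_max + 1, size=params.n_large_complexes
    )
    if int(sizes.sum()) > len(pool):
        raise ValueError(
            f"protein budget exhausted: large complexes need {int(sizes.sum())} proteins, "
            f"only {len(pool)} remain after planting positives"
        )
    shuffled = list(pool)
    rng.shuffle(shuffled)
    large_complexes: dict[str, list[str]] = {}
    cursor = 0
    for c, size in enumerate(sizes):
        members = sorted(shuffled[cursor:cursor + int(size)])
        large_complexes[f"CPX{c + 1:03d}"] = members
        cursor += int(size)

    # network: heterodimer edges, complex cliques, then background noise
    net = WeightedPPINetwork()
    for p in proteins:
        net.add_protein(p)
    for a, b in positive_pairs:
        w = float(rng.lognormal(params.mu_heterodimer, params.sigma_weight))
        net.add_edge(a, b, w)
        # shared decoy neighbors so a planted pair's local topology matches a
        # co-complex pair's (common neighbors, background-weight neighborhood);
        # only the weight contrast and domain templates carry signal
        n_decoys = int(rng.integers(params.complex_size_min, params.complex_size_max + 1)) - 2
        decoys = rng.choice(pool, size=n_decoys, replace=False)
        for d in decoys:
            for endpoint in (a, b):
                if not net.has_edge(endpoint, d):
                    w_bg = float(rng.lognormal(params.mu_background, params.sigma_weight))
                    net.add_edge(endpoint, d, w_bg)
    for members in large_complexes.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if not net.has_edge(a, b):
                    w = float(rng.lognormal(params.mu_background, params.sigma_weight))
                    net.add_edge(a, b, w)
    n = params.n_proteins
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(iu.size) < params.background_edge_prob
    bg_w = rng.lognormal(params.mu_background, params.sigma_weight, size=int(hit.sum()))
    for (i, j, w) in zip(iu[hit], ju[hit], bg_w):
        a, b = proteins[i], proteins[j]
        if not net.has_edge(a, b):
            net.add_edge(a, b, float(w))

    # catalog: one size-2 complex per planted pair + the large complexes
    complexes: dict[str, frozenset[str]] = {}
    for k, pair in enumerate(positive_pairs):
        complexes[f"HD{k + 1:03d}"] = frozenset(pair)
    for cid, members in large_complexes.items():
        complexes[cid] = frozenset(members)
    catalog = ComplexCatalog(complexes)

    # domain table: noisy template copies for positives, sparse noise elsewhere
    templates = [
        (_template_composition(rng, params.n_domains), _template_composition(rng, params.n_domains))
        for _ in range(params.n_templates)
    ]
    dom_vectors: dict[str, np.ndarray] = {}
    assignment = rng.integers(0, params.n_templates, size=params.n_positive_pairs)
    for k, (a, b) in enumerate(positive_pairs):
        comp_a, comp_b = templates[int(assignment[k])]
        dom_vectors[a] = _noisy_copy(rng, comp_a, params.domain_noise_prob)
        dom_vectors[b] = _noisy_copy(rng, comp_b, params.domain_noise_prob)
    for p in proteins:
        if p not in dom_vectors:
            dom_vectors[p] = _template_composition(rng, params.n_domains)
    dom_columns = [f"D{j + 1:03d}" for j in range(params.n_domains)]
    dom_table = ProfileTable("domain-count", dom_columns, dom_vectors)

    # phylogenetic profiles: shared complex pattern with flip noise
    phylo: dict[str, np.ndarray] = {
        p: (rng.random(params.n_genomes) < 0.5).astype(np.int64) for p in proteins
    }
    for members in complexes.values():
        pattern = (rng.random(params.n_genomes) < 0.5).astype(np.int64)
        for p in sorted(members):
            flips = rng.random(params.n_genomes) < params.profile_flip_prob
            phylo[p] = np.where(flips, 1 - pattern, pattern).astype(np.int64)
    genome_columns = [f"G{j + 1:03d}" for j in range(params.n_genomes)]
    phylo_table = ProfileTable("binary-profile", genome_columns, phylo)

    # localization: uninformative unless flagged
    local: dict[str, np.ndarray] = {
        p: (rng.random(params.n_localizations) < 0.3).astype(np.int64) for p in proteins
    }
    if params.localization_informative:
        for members in complexes.values():
            pattern = (rng.random(params.n_localizations) < 0.5).astype(np.int64)
            for p in sorted(members):
                flips = rng.random(params.n_localizations) < params.profile_flip_prob
                local[p] = np.where(flips, 1 - pattern, pattern).astype(np.int64)
    local_columns = [f"L{j + 1:02d}" for j in range(params.n_localizations)]
    local_table = ProfileTable("binary-profile", local_columns, local)

    truth = SyntheticTruth(positive_pairs, large_complexes, params)
    return net, (dom_table, phylo_table, local_table), catalog, truth


def write_bundle(
    outdir: str | Path,
    net: WeightedPPINetwork,
    tables: tuple[ProfileTable, ProfileTable, ProfileTable],
    catalog: ComplexCatalog,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Serialize the four TSV inputs plus the truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dom_table, phylo_table, local_table = tables
    paths = {
        "network": outdir / "network.tsv",
        "domains": outdir / "domains.tsv",
        "phylo": outdir / "phylo.tsv",
        "localization": outdir / "localization.tsv",
        "complexes": outdir / "complexes.tsv",
        "truth": outdir / "truth.json",
    }
    write_weighted_ppi(net, paths["network"])
    write_profile_table(dom_table, paths["domains"])
    write_profile_table(phylo_table, paths["phylo"])
    write_profile_table(local_table, paths["localization"])
    write_complex_catalog(catalog, paths["complexes"])
    truth.write_json(paths["truth"])
    return paths
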