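"""Core data types and TSV parsers for networks, complex catalogs and profiles.

All files are tab-delimited UTF-8 text; lines starting with ``#`` are ignored.
Protein identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


class ValidationError(ValueError):
    """Input violates a structural constraint (bad weight, singleton complex...)."""


class ParseError(ValueError):
    """A row of an input file could not be parsed; message names the line."""


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedPPINetwork:
    """Undirected protein interaction graph with strictly positive edge weights."""

    proteins: set[str] = field(default_factory=set)
    weights: dict[Pair, float] = field(default_factory=dict)
    # adjacency: protein -> {neighbor: weight}; kept in sync by add_edge
    _adj: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    @property
    def edges(self) -> set[Pair]:
        return set(self.weights)

    def add_protein(self, p: str) -> None:
        self.proteins.add(p)
        self._adj.setdefault(p, {})

    def add_edge(self, a: str, b: str, w: float) -> None:
        if a == b:
            raise ValidationError(f"self-edge not allowed: {a!r}")
        if not (w > 0):
            raise ValidationError(f"edge weight must be positive, got {w!r} for ({a}, {b})")
        self.add_protein(a)
        self.add_protein(b)
        self.weights[canonical_pair(a, b)] = float(w)
        self._adj[a][b] = float(w)
        self._adj[b][a] = float(w)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.weights

    def weight(self, a: str, b: str) -> float:
        return self.weights[canonical_pair(a, b)]

    def neighbors(self, p: str) -> dict[str, float]:
        """Map neighbor -> weight for protein ``p`` (empty if unknown)."""
        return self._adj.get(p, {})

    def validate(self) -> None:
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValidationError(f"self-edge present: {a!r}")
            if not (w > 0):
                raise ValidationError(f"nonpositive weight {w} on ({a}, {b})")
            if a not in self.proteins or b not in self.proteins:
                raise ValidationError(f"edge endpoint missing from protein set: ({a}, {b})")


@dataclass
class ComplexCatalog:
    """Catalog of protein complexes: complex identifier -> member set (size >= 2)."""

    complexes: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        bad = [cid for cid, members in self.complexes.items() if len(members) < 2]
        if bad:
            raise ValidationError(f"complexes with fewer than 2 members: {sorted(bad)}")

    def heterodimers(self) -> set[frozenset[str]]:
        """Member sets of all size-2 complexes."""
        return {m for m in self.complexes.values() if len(m) == 2}

    def comembership_pairs(self, min_size: int = 3) -> set[Pair]:
        """All unordered pairs co-occurring in some complex of size >= min_size."""
        out: set[Pair] = set()
        for members in self.complexes.values():
            if len(members) < min_size:
                continue
            mem = sorted(members)
            for i, a in enumerate(mem):
                for b in mem[i + 1:]:
                    out.add((a, b))
        return out


PROFILE_KINDS = ("domain-count", "binary-profile")


@dataclass
class ProfileTable:
    """Per-protein nonnegative integer vectors over an ordered column set.

    ``kind`` is ``"domain-count"`` (multiplicities of annotation labels) or
    ``"binary-profile"`` (0/1 membership, e.g. presence across genomes or
    subcellular compartments).
    """

    kind: str
    columns: list[str]
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValidationError(f"unknown profile kind {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def vector(self, protein: str) -> np.ndarray:
        """Feature vector of ``protein``; unknown proteins map to the zero vector."""
        v = self.vectors.get(protein)
        if v is None:
            return np.zeros(self.n_columns, dtype=np.int64)
        return v

    def validate(self) -> None:
        n = self.n_columns
        for p, v in self.vectors.items():
            if v.shape != (n,):
                raise ValidationError(f"vector length mismatch for {p!r}: {v.shape} != ({n},)")
            if np.any(v < 0):
                raise ValidationError(f"negative entry in profile of {p!r}")
            if self.kind == "binary-profile" and not np.all((v == 0) | (v == 1)):
                raise ValidationError(f"non-0/1 entry in binary profile of {p!r}")


@dataclass
class LabeledPairSet:
    """Ordered list of unordered protein pairs with parallel +/-1 labels."""

    pairs: list[Pair]
    labels: np.ndarray  # values in {-1, +1}, parallel to pairs

    def __post_init__(self) -> None:
        self.pairs = [canonical_pair(*p) for p in self.pairs]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.pairs) != len(self.labels):
            raise ValidationError("pairs and labels must be parallel")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate pairs in LabeledPairSet")
        if self.labels.size and not np.all(np.isin(self.labels, (-1, 1))):
            raise ValidationError("labels must be -1 or +1")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == -1))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_weighted_ppi(path: str | Path, dialect: str = "generic-3col") -> WeightedPPINetwork:
    """Parse a weighted edge list into a :class:`WeightedPPINetwork`.

    ``dialect="generic-3col"`` expects ``protein_a TAB protein_b TAB weight``.
    ``dialect="wi-phi"`` tolerates a header line and extra columns: the first
    two columns are protein names and the *last* numeric column is the weight.
    Duplicate edges keep the maximum weight (with a warning); self-edges are
    dropped (with a warning).
    """
    if dialect not in ("generic-3col", "wi-phi"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = WeightedPPINetwork()
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 fields, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if dialect == "wi-phi":
            wtoken = None
            for tok in reversed(fields[2:]):
                try:
                    w = float(tok)
                    wtoken = tok
                    break
                except ValueError:
                    continue
            if wtoken is None:
                if first:  # header line of a WI-PHI export
                    first = False
                    continue
                raise ParseError(f"{path}: line {lineno}: no numeric weight column")
        else:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: weight {fields[2]!r} is not a number") from exc
        first = False
        if not (w > 0):
            raise ValidationError(f"{path}: line {lineno}: nonpositive weight {w}")
        if a == b:
            logger.warning("%s: line %d: dropping self-edge %r", path, lineno, a)
            continue
        key = canonical_pair(a, b)
        if key in net.weights:
            logger.warning(
                "%s: line %d: duplicate edge (%s, %s); keeping max weight", path, lineno, a, b
            )
            w = max(w, net.weights[key])
        net.add_edge(a, b, w)
    return net


def write_weighted_ppi(net: WeightedPPINetwork, path: str | Path) -> None:
    """Serialize to the generic 3-column edge-list format (sorted, round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b) in sorted(net.weights):
            fh.write(f"{a}\t{b}\t{net.weights[(a, b)]!r}\n")


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Parse two-column (complex_id, protein) membership rows."""
    members: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        cid, protein = fields[0].strip(), fields[1].strip()
        members.setdefault(cid, set()).add(protein)
    singletons = sorted(cid for cid, m in members.items() if len(m) < 2)
    if singletons:
        raise ValidationError(f"complexes with a single member: {singletons}")
    return ComplexCatalog({cid: frozenset(m) for cid, m in members.items()})


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(catalog.complexes):
            for p in sorted(catalog.complexes[cid]):
                fh.write(f"{cid}\t{p}\n")


def read_profile_table(path: str | Path, kind: str) -> ProfileTable:
    """Parse a profile table.

    ``kind="domain-count"``: two-column (protein, domain) rows; repeated rows
    encode multiplicity; column order is first-seen order of domains.
    ``kind="binary-profile"``: header row ``protein TAB label1 ...`` then
    protein + 0/1 entries; header order is preserved.
    """
    if kind == "domain-count":
        columns: list[str] = []
        col_index: dict[str, int] = {}
        counts: dict[str, dict[int, int]] = {}
        for lineno, fields in _data_lines(path):
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            protein, domain = fields[0].strip(), fields[1].strip()
            if domain not in col_index:
                col_index[domain] = len(columns)
                columns.append(domain)
            row = counts.setdefault(protein, {})
            row[col_index[domain]] = row.get(col_index[domain], 0) + 1
        vectors = {}
        for protein, row in counts.items():
            v = np.zeros(len(columns), dtype=np.int64)
            for j, c in row.items():
                v[j] = c
            vectors[protein] = v
        table = ProfileTable("domain-count", columns, vectors)
    elif kind == "binary-profile":
        columns = None
        vectors = {}
        for lineno, fields in _data_lines(path):
            if columns is None:
                columns = [f.strip() for f in fields[1:]]
                continue
            if len(fields) != len(columns) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(columns) + 1} fields, got {len(fields)}"
                )
            protein = fields[0].strip()
            try:
                v = np.array([int(tok) for tok in fields[1:]], dtype=np.int64)
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: non-integer entry") from exc
            if not np.all((v == 0) | (v == 1)):
                raise ValidationError(f"{path}: line {lineno}: entries must be 0 or 1")
            vectors[protein] = v
        table = ProfileTable("binary-profile", columns or [], vectors)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    table.validate()
    return table


def write_profile_table(table: ProfileTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if table.kind == "domain-count":
            # repeated (protein, domain) rows encode multiplicity
            for protein in sorted(table.vectors):
                v = table.vectors[protein]
                for j in np.nonzero(v)[0]:
                    for _ in range(int(v[j])):
                        fh.write(f"{protein}\t{table.columns[j]}\n")
        else:
            fh.write("protein\t" + "\t".join(table.columns) + "\n")
            for protein in sorted(table.vectors):
                v = table.vectors[protein]
                fh.write(protein + "\t" + "\t".join(str(int(x)) for x in v) + "\n")


def read_labeled_pairs(path: str | Path) -> LabeledPairSet:
    pairs: list[Pair] = []
    labels: list[int] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
        y = int(fields[2])
        if y not in (-1, 1):
            raise ValidationError(f"{path}: line {lineno}: label must be -1 or 1")
        pairs.append(canonical_pair(fields[0].strip(), fields[1].strip()))
        labels.append(y)
    return LabeledPairSet(pairs, np.array(labels, dtype=np.int64))


def write_labeled_pairs(pairset: LabeledPairSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), y in zip(pairset.pairs, pairset.labels):
            fh.write(f"{a}\t{b}\t{int(y)}\n")


# ---------------------------------------------------------------------------
# Example construction
# ---------------------------------------------------------------------------

def build_examples(network: WeightedPPINetwork, catalog: ComplexCatalog) -> LabeledPairSet:
    """Label network edges as heterodimer positives / co-complex negatives.

    A pair is *positive* iff it is a network edge and equals the member set of
    some size-2 complex. A pair is *negative* iff it is a network edge, is not
    the member set of any size-2 complex, and both proteins co-occur in at
    least one complex of size >= 3. All other edges are excluded.
    """
    heterodimers = {canonical_pair(*sorted(m)) for m in catalog.heterodimers()}
    comembers = catalog.comembership_pairs(min_size=3)
    positives: list[Pair] = []
    negatives: list[Pair] = []
    for pair in sorted(network.weights):
        if pair in heterodimers:
            positives.append(pair)
        elif pair in comembers:
            negatives.append(pair)
    pairs = positives + negatives
    labels = np.concatenate(
        [np.ones(len(positives), dtype=np.int64), -np.ones(len(negatives), dtype=np.int64)]
    ) if pairs else np.zeros(0, dtype=np.int64)
    return LabeledPairSet(pairs, labels)
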