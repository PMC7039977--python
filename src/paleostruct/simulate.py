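"""Synthetic admixture-graph data generator.

Every downstream stage of the package (pseudo-haploid calling, sample QC,
f-statistics, PCA projection, rank-constrained admixture models) is tested
against data from this module, so it is first-class, seeded code rather
than a test fixture.

The truth model is frequency-level Balding-Nichols drift on a population
tree with admixture edges: a child population at drift F from its parent
(frequency p) draws allele frequencies from

    Beta( p (1 - F) / F,  (1 - p) (1 - F) / F )

which has mean p and variance F p (1 - p) — i.e. F is the expected FST
between parent and child.  An admixed node first takes the mixture
alpha * p_A + (1 - alpha) * p_B of its two parents and then applies its
own drift.  Under this model f2/f3/f4 arithmetic is exact in expectation,
so analytic recovery targets are computable without a coalescent.

Observation layers emulate capture-based ancient-DNA data: binomial true
genotypes, Poisson read depth, per-read error, pseudo-haploid sampling,
sex-dependent X/Y coverage, derived/ancestral reads along a Y-haplogroup
path, and first-degree-relative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import DIPLOID, MISSING, GenotypeMatrix


@dataclass
class DriftEdge:
    parent: str
    F: float


@dataclass
class AdmixtureNode:
    parent_a: str
    parent_b: str
    alpha: float
    #: drift applied after mixing (0 = none)
    F: float = 0.0


@dataclass
class AdmixtureGraph:
    """Population tree with drift amounts and admixture edges.

    ``edges`` maps each non-root, non-admixed node to its (parent, F) drift
    edge; ``admixtures`` maps admixed nodes to their two parents, mixing
    proportion alpha (weight on ``parent_a``), and post-admixture drift.
    Root allele frequencies are drawn uniformly on ``root_range``, bounded
    away from 0/1 because capture panels are ascertained polymorphic.
    """

    root: str
    edges: dict[str, DriftEdge] = field(default_factory=dict)
    admixtures: dict[str, AdmixtureNode] = field(default_factory=dict)
    root_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self) -> None:
        for node, e in self.edges.items():
            if not 0.0 <= e.F < 1.0:
                raise ValueError(f"drift F for {node} must be in [0, 1), got {e.F}")
        for node, a in self.admixtures.items():
            if not 0.0 <= a.F < 1.0:
                raise ValueError(f"drift F for {node} must be in [0, 1), got {a.F}")
            if not 0.0 <= a.alpha <= 1.0:
                raise ValueError(f"alpha for {node} must be in [0, 1]")
        overlap = set(self.edges) & set(self.admixtures)
        if overlap:
            raise ValueError(f"nodes with both edge kinds: {overlap}")
        self._toposort()  # raises on cycles / missing parents

    @property
    def nodes(self) -> list[str]:
        return [self.root] + list(self.edges) + list(self.admixtures)

    def _toposort(self) -> list[str]:
        parents = {n: [e.parent] for n, e in self.edges.items()}
        parents.update({n: [a.parent_a, a.parent_b]
                        for n, a in self.admixtures.items()})
        order = [self.root]
        placed = {self.root}
        pending = dict(parents)
        while pending:
            ready = [n for n, ps in pending.items() if all(p in placed for p in ps)]
            if not ready:
                missing = {p for ps in pending.values() for p in ps} - placed - set(pending)
                if missing:
                    raise ValueError(f"unknown parent node(s): {missing}")
                raise ValueError("admixture graph contains a cycle")
            for n in ready:
                order.append(n)
                placed.add(n)
                del pending[n]
        return order

    @classmethod
    def from_yaml(cls, path: str) -> "AdmixtureGraph":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        edges = {n: DriftEdge(d["parent"], float(d.get("F", 0.0)))
                 for n, d in spec.get("edges", {}).items()}
        admix = {n: AdmixtureNode(d["parent_a"], d["parent_b"],
                                  float(d["alpha"]), float(d.get("F", 0.0)))
                 for n, d in spec.get("admixtures", {}).items()}
        rr = tuple(spec.get("root_range", (0.05, 0.95)))
        return cls(root=spec["root"], edges=edges, admixtures=admix, root_range=rr)

    def to_yaml(self, path: str) -> None:
        spec = {
            "root": self.root,
            "edges": {n: {"parent": e.parent, "F": e.F}
                      for n, e in self.edges.items()},
            "admixtures": {n: {"parent_a": a.parent_a, "parent_b": a.parent_b,
                               "alpha": a.alpha, "F": a.F}
                           for n, a in self.admixtures.items()},
            "root_range": list(self.root_range),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh)


@dataclass
class TruthFrequencies:
    """Per-node true allele frequencies, nodes x SNPs."""

    freqs: dict[str, np.ndarray]

    def __getitem__(self, node: str) -> np.ndarray:
        return self.freqs[node]

    @property
    def n_snps(self) -> int:
        return len(next(iter(self.freqs.values())))


@dataclass
class AlleleDepthMatrix:
    """Per sample x SNP read counts supporting the ref and alt allele."""

    reads_ref: np.ndarray
    reads_alt: np.ndarray
    mean_coverage: float
    error: float

    def __post_init__(self) -> None:
        self.reads_ref = np.asarray(self.reads_ref, dtype=np.int32)
        self.reads_alt = np.asarray(self.reads_alt, dtype=np.int32)
        if self.reads_ref.shape != self.reads_alt.shape:
            raise ValueError("ref/alt read matrices differ in shape")

    @property
    def depth(self) -> np.ndarray:
        return self.reads_ref + self.reads_alt

    @property
    def missing_mask(self) -> np.ndarray:
        return self.depth == 0


def _drift(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    # guard exact 0/1 parent frequencies (Beta parameters must be > 0)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_frequencies(graph: AdmixtureGraph, n_snps: int,
                         seed: int) -> TruthFrequencies:
    """Draw per-node allele frequencies along the graph, Balding-Nichols drift.

    Deterministic for fixed ``seed``; admixed nodes mix their parents by
    alpha exactly before applying their own drift.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = graph.root_range
    freqs = {graph.root: rng.uniform(lo, hi, size=n_snps)}
    for node in graph._toposort()[1:]:
        if node in graph.edges:
            e = graph.edges[node]
            freqs[node] = _drift(rng, freqs[e.parent], e.F)
        else:
            a = graph.admixtures[node]
            mix = a.alpha * freqs[a.parent_a] + (1.0 - a.alpha) * freqs[a.parent_b]
            freqs[node] = _drift(rng, mix, a.F)
    return TruthFrequencies(freqs)


def _variant_frame(n_snps: int, chromosome: str = "1",
                   ancestral_ref: bool = True) -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)],
        "chromosome": chromosome,
        "position": np.arange(1, n_snps + 1, dtype=np.int64),
        "allele_ref": "A",
        "allele_alt": "G",
        "allele_ancestral": "A" if ancestral_ref else "N",
    })


def _observe_reads(rng: np.random.Generator, genotypes: np.ndarray,
                   coverage: float, error: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth, each read supports alt w.p. (g/2)(1-e) + (1-g/2)e."""
    depth = rng.poisson(coverage, size=genotypes.shape)
    p_alt = (genotypes / 2.0) * (1.0 - error) + (1.0 - genotypes / 2.0) * error
    alt = rng.binomial(depth, p_alt)
    return (depth - alt).astype(np.int32), alt.astype(np.int32)


def simulate_sample(freqs: TruthFrequencies, node: str, n_ind: int,
                    coverage: float, error: float, seed: int,
                    sample_prefix: str | None = None,
                    ) -> tuple[AlleleDepthMatrix, GenotypeMatrix]:
    """Simulate capture observations for ``n_ind`` individuals of ``node``.

    True genotypes are Binomial(2, p) per individual and SNP; read depth is
    Poisson(``coverage``) and each read reports the wrong allele with
    probability ``error``.  Returns the read counts and the true diploid
    genotypes (the latter for oracle checks).
    """
    if node not in freqs.freqs:
        raise KeyError(f"unknown node {node!r}")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0.0 <= error < 0.5:
        raise ValueError("error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    p = freqs[node]
    genotypes = rng.binomial(2, p, size=(n_ind, len(p))).astype(np.int8)
    ref, alt = _observe_reads(rng, genotypes, coverage, error)
    depths = AlleleDepthMatrix(ref, alt, coverage, error)

    prefix = sample_prefix or node
    samples = pd.DataFrame({
        "sample_id": [f"{prefix}_{i}" for i in range(n_ind)],
        "group_label": node,
        "ploidy_mode": DIPLOID,
    })
    truth = GenotypeMatrix(genotypes, samples, _variant_frame(len(p)))
    return depths, truth


def simulate_related_pair(freqs: TruthFrequencies, node: str, relation: str,
                          coverage: float, error: float, seed: int,
                          ) -> AlleleDepthMatrix:
    """Two samples with a known relationship, observed independently.

    ``duplicate``: two read layers over one true genotype (same individual
    or identical twins).  ``parent_offspring``: the child inherits one
    allele transmitted from the parent and one drawn from the population.
    ``unrelated``: independent genotypes.
    """
    if relation not in ("duplicate", "parent_offspring", "unrelated"):
        raise ValueError(f"unknown relation {relation!r}")
    rng = np.random.default_rng(seed)
    p = freqs[node]
    m = len(p)
    g1 = rng.binomial(2, p, size=m).astype(np.int8)
    if relation == "duplicate":
        g2 = g1.copy()
    elif relation == "parent_offspring":
        transmitted = rng.binomial(1, g1 / 2.0)
        other = rng.binomial(1, p, size=m)
        g2 = (transmitted + other).astype(np.int8)
    else:
        g2 = rng.binomial(2, p, size=m).astype(np.int8)
    ref, alt = _observe_reads(rng, np.stack([g1, g2]), coverage, error)
    return AlleleDepthMatrix(ref, alt, coverage, error)


def simulate_sex_reads(sex: str, coverage: float, seed: int,
                       n_autosome: int = 10000, n_x: int = 10000,
                       n_y: int = 2000, y_mismap: float = 0.005) -> dict:
    """Read-count summaries per target class for genetic sexing.

    Expected per-site depth is ``coverage`` on autosomes for both sexes;
    on X it is ``coverage`` for XX and ``coverage / 2`` for XY; on Y it is
    0 for XX (plus a small mismapping rate, default 0.5% of the autosomal
    rate) and ``coverage / 2`` for XY.  Counts are Poisson.
    """
    if sex not in ("XX", "XY"):
        raise ValueError("sex must be 'XX' or 'XY'")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    x_rate = coverage if sex == "XX" else coverage / 2.0
    y_rate = coverage * y_mismap if sex == "XX" else coverage / 2.0
    return {
        "autosome": {"n_sites": n_autosome,
                     "n_reads": int(rng.poisson(coverage * n_autosome))},
        "X": {"n_sites": n_x, "n_reads": int(rng.poisson(x_rate * n_x))},
        "Y": {"n_sites": n_y, "n_reads": int(rng.poisson(y_rate * n_y))},
    }


def simulate_y_reads(tree, haplogroup: str, error: float, coverage: float,
                     seed: int) -> pd.DataFrame:
    """Derived/ancestral read counts over a Y-haplogroup marker tree.

    Markers on the root-to-``haplogroup`` path emit derived reads, all
    other markers ancestral; each read is flipped with probability
    ``error`` and depth per marker is Poisson(``coverage``).  Returns a
    frame with columns (marker_id, node, n_derived, n_ancestral).
    """
    rng = np.random.default_rng(seed)
    path = set(tree.path_to(haplogroup))
    rows = []
    for node, markers in tree.marker_groups.items():
        derived_state = node in path
        for marker in markers:
            d = int(rng.poisson(coverage))
            p_derived = (1.0 - error) if derived_state else error
            nd = int(rng.binomial(d, p_derived))
            rows.append((marker, node, nd, d - nd))
    return pd.DataFrame(rows, columns=["marker_id", "node",
                                       "n_derived", "n_ancestral"])


def sample_group_counts(freqs: TruthFrequencies, node: str, n_ind: int,
                        seed: int, mode: str = "pseudo_haploid",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele counts (k, n) per SNP for a fully observed group.

    Shortcut for frequency-level benchmarks: a pseudo-haploid sample
    contributes one allele that is alt with probability p (a random read
    from a Binomial(2, p) genotype at zero error), so group counts are
    Binomial(n_ind, p); diploid groups give Binomial(2 * n_ind, p).
    """
    rng = np.random.default_rng(seed)
    p = freqs[node]
    n_alleles = n_ind if mode == "pseudo_haploid" else 2 * n_ind
    k = rng.binomial(n_alleles, p)
    return k, np.full(len(p), n_alleles, dtype=np.int64)


def depths_to_genotype_matrix(depths: AlleleDepthMatrix, seed: int,
                              sample_ids: list[str] | None = None,
                              group_label: str = "sim",
                              variants: pd.DataFrame | None = None,
                              ) -> GenotypeMatrix:
    """Pseudo-haploid call a depth matrix (delegates to :mod:`paleostruct.qc`)."""
    from .qc import call_pseudohaploid
    return call_pseudohaploid(depths, seed, sample_ids=sample_ids,
                              group_label=group_label, variants=variants)
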