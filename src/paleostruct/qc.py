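"""Sample-level QC: pseudo-haploid calling, genetic sex, relatedness, Y haplogroups.

Pseudo-haploid calling is the standard device for low-coverage ancient
samples: at each covered SNP one sequencing read is sampled uniformly at
random and the genotype is set homozygous for that read's allele.  The
resulting sample contributes exactly one allele to any frequency estimate,
which avoids an artificial appearance of genetic drift.

Relatedness screening uses the normalized pairwise-mismatch statistic
(READ-style): for a pair of pseudo-haploid samples the mismatch rate at
co-covered sites has expectation H/2 for the same individual, 3H/4 for
first-degree relatives and H for unrelated pairs, where H is the cohort's
expected heterozygosity.  Dividing by a cohort baseline cancels H, so the
normalized rate r clusters at 0.5 / 0.75 / 1.0 and class boundaries sit at
the midpoints 0.625 and 0.875.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, PSEUDO_HAPLOID, BlockPartition, GenotypeMatrix
from .jackknife import jackknife_ratio
from .simulate import AlleleDepthMatrix, _variant_frame


# ---------------------------------------------------------------------------
# pseudo-haploid calling
# ---------------------------------------------------------------------------

def call_pseudohaploid(depths: AlleleDepthMatrix, seed: int,
                       sample_ids: list[str] | None = None,
                       group_label: str = "NA",
                       variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Sample one read per covered site; genotype = homozygous for its allele.

    The sampled read is alt with probability d_alt / (d_ref + d_alt); zero
    depth yields missing.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    depth = depths.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(depth > 0, depths.reads_alt / np.maximum(depth, 1), 0.0)
    alt_drawn = rng.random(depth.shape) < p_alt
    calls = np.where(alt_drawn, 2, 0).astype(np.int8)
    calls[depth == 0] = MISSING

    n_ind, n_snps = depth.shape
    if sample_ids is None:
        sample_ids = [f"{group_label}_{i}" for i in range(n_ind)]
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "group_label": group_label,
                            "ploidy_mode": PSEUDO_HAPLOID})
    if variants is None:
        variants = _variant_frame(n_snps)
    return GenotypeMatrix(calls, samples, variants)


# ---------------------------------------------------------------------------
# genetic sex
# ---------------------------------------------------------------------------

@dataclass
class SexCall:
    """X/autosome and Y/autosome coverage ratios with the resulting call."""

    sample_id: str
    r_x: float
    r_y: float
    call: str
    n_sites: int
    reason: str = ""


def assign_sex(read_summary: dict, sample_id: str = "sample",
               min_sites: int = 1000,
               r_y_male_min: float = 0.3, r_y_female_max: float = 0.1,
               r_x_split: float = 0.8) -> SexCall:
    """Call genetic sex from relative X and Y coverage.

    ``read_summary`` maps each class ('autosome', 'X', 'Y') to
    ``{'n_sites': int, 'n_reads': int}``.  R_x and R_y are the per-site
    mean depths on X and Y divided by the autosomal mean depth; theoretical
    values are (1, 0) for XX and (0.5, 0.5) for XY.  The default decision
    margins are wide (XY: R_y >= 0.3 and R_x <= 0.8; XX: R_y <= 0.1 and
    R_x >= 0.8) so low-coverage noise falls into 'undetermined' rather
    than flipping the call.
    """
    auto = read_summary["autosome"]
    n_auto = auto["n_sites"]
    if n_auto < min_sites:
        return SexCall(sample_id, np.nan, np.nan, "undetermined", n_auto,
                       reason=f"only {n_auto} autosomal sites (< {min_sites})")
    auto_rate = auto["n_reads"] / n_auto
    if auto_rate == 0:
        return SexCall(sample_id, np.nan, np.nan, "undetermined", n_auto,
                       reason="zero autosomal coverage")
    r_x = (read_summary["X"]["n_reads"] / read_summary["X"]["n_sites"]) / auto_rate
    r_y = (read_summary["Y"]["n_reads"] / read_summary["Y"]["n_sites"]) / auto_rate
    if r_y >= r_y_male_min and r_x <= r_x_split:
        call = "XY"
    elif r_y <= r_y_female_max and r_x >= r_x_split:
        call = "XX"
    else:
        call = "undetermined"
    return SexCall(sample_id, float(r_x), float(r_y), call, n_auto)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

#: class boundaries on the normalized mismatch rate r — midpoints between
#: the theoretical expectations 0.5 (same individual), 0.75 (first degree)
#: and 1.0 (unrelated)
R_IDENTICAL_MAX = 0.625
R_FIRST_DEGREE_MAX = 0.875


@dataclass
class RelatednessResult:
    sample_a: str
    sample_b: str
    mismatch_rate: float
    r: float
    se: float
    n_overlap: int
    classification: str


def _classify_r(r: float, se: float, n_overlap: int, min_overlap: int) -> str:
    if n_overlap < min_overlap:
        return "indeterminate"
    lo, hi = r - 2 * se, r + 2 * se
    for bound in (R_IDENTICAL_MAX, R_FIRST_DEGREE_MAX):
        if lo < bound < hi:
            return "indeterminate"
    if r < R_IDENTICAL_MAX:
        return "identical_or_same"
    if r < R_FIRST_DEGREE_MAX:
        return "first_degree"
    return "unrelated"


def relatedness_matrix(geno: GenotypeMatrix, blocks: BlockPartition,
                       min_overlap: int = 5000) -> list[RelatednessResult]:
    """All-pairs normalized pairwise-mismatch relatedness screen.

    For each sample pair the mismatch rate over co-covered SNPs is divided
    by the cohort baseline (the median pairwise rate, dominated by
    unrelated pairs) and the ratio's SE comes from a delete-one-block
    jackknife of the pair's rate with the baseline held fixed.  A pair is
    'indeterminate' when overlap is below ``min_overlap`` or the 2-SE
    interval spans a class boundary.
    """
    if geno.n_samples < 2:
        raise ValueError("relatedness screen needs at least 2 samples")
    calls = geno.calls
    obs = calls != MISSING
    ids = geno.samples["sample_id"].tolist()

    pairs = list(itertools.combinations(range(geno.n_samples), 2))
    raw_rates = {}
    details = {}
    for i, j in pairs:
        both = obs[i] & obs[j]
        mism = both & (calls[i] != calls[j])
        num = np.where(both, mism.astype(float), np.nan)
        den = np.ones_like(num)
        est = jackknife_ratio(num, den, blocks.block_index, blocks.g)
        raw_rates[(i, j)] = est.estimate
        details[(i, j)] = (est, int(both.sum()))

    baseline = float(np.median(list(raw_rates.values())))
    if baseline == 0:
        raise ValueError("cohort baseline mismatch rate is zero; "
                         "cannot normalize (monomorphic data?)")

    results = []
    for (i, j), (est, n_overlap) in details.items():
        r = est.estimate / baseline
        se = est.se / baseline
        cls = _classify_r(r, se, n_overlap, min_overlap)
        results.append(RelatednessResult(ids[i], ids[j], est.estimate,
                                         r, se, n_overlap, cls))
    return results


# ---------------------------------------------------------------------------
# Y haplogroups
# ---------------------------------------------------------------------------

@dataclass
class YHaplotypeTree:
    """Haplogroup tree with a group of equivalent markers per node.

    ``parents`` maps each non-root node to its parent; ``marker_groups``
    maps each node to its defining markers (ids).  Marker groups must be
    disjoint across nodes.
    """

    root: str
    parents: dict[str, str]
    marker_groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for node, markers in self.marker_groups.items():
            for m in markers:
                if m in seen:
                    raise ValueError(
                        f"marker {m} assigned to both {seen[m]} and {node}")
                seen[m] = node
        for node in self.parents:
            self.path_to(node)  # raises on broken parent chains

    def children(self, node: str) -> list[str]:
        return [c for c, p in self.parents.items() if p == node]

    def path_to(self, node: str) -> list[str]:
        """Nodes from the root down to ``node`` inclusive."""
        path = [node]
        guard = 0
        while path[-1] != self.root:
            nxt = self.parents.get(path[-1])
            if nxt is None:
                raise KeyError(f"node {path[-1]!r} has no path to root")
            path.append(nxt)
            guard += 1
            if guard > len(self.parents) + 1:
                raise ValueError("cycle in haplogroup tree")
        return path[::-1]

    @classmethod
    def from_tsv(cls, path: str) -> "YHaplotypeTree":
        """Read a (node, parent, markers) TSV; parent '-' marks the root."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        root = None
        parents, groups = {}, {}
        for row in df.itertuples(index=False):
            markers = [m for m in str(row.markers).split(",") if m and m != "nan"]
            groups[row.node] = markers
            if row.parent in ("-", "", None) or pd.isna(row.parent):
                root = row.node
            else:
                parents[row.node] = row.parent
        if root is None:
            raise ValueError(f"{path}: no root row (parent '-')")
        return cls(root=root, parents=parents, marker_groups=groups)


@dataclass
class YHaplogroupCall:
    haplogroup: str
    support: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def assign_y_haplogroup(counts: pd.DataFrame, tree: YHaplotypeTree,
                        min_derived: int = 1,
                        max_conflict: float = 0.1) -> YHaplogroupCall:
    """Walk the haplogroup tree by derived-read support.

    From the root, descend into the child whose marker group carries the
    most derived reads, requiring at least ``min_derived``; stop at a tie
    between children (conservative — the ambiguity is flagged rather than
    guessed) or when no child qualifies.  Off-path nodes whose covered
    markers show a derived fraction above ``max_conflict`` raise a
    conflict flag.
    """
    per_node = counts.groupby("node")[["n_derived", "n_ancestral"]].sum()
    support = per_node.reindex(tree.marker_groups.keys(), fill_value=0)

    if int(support["n_derived"].sum()) == 0:
        return YHaplogroupCall("unassigned", support.reset_index(),
                               flags=["no_derived_calls"])

    node = tree.root
    flags: list[str] = []
    while True:
        children = tree.children(node)
        scored = [(int(support.loc[c, "n_derived"]) if c in support.index else 0, c)
                  for c in children]
        scored = [(d, c) for d, c in scored if d >= min_derived]
        if not scored:
            break
        best = max(d for d, _ in scored)
        winners = [c for d, c in scored if d == best]
        if len(winners) > 1:
            flags.append(f"ambiguous_at_{node}")
            break
        node = winners[0]

    path = set(tree.path_to(node))
    for other in tree.marker_groups:
        if other in path:
            continue
        nd = int(support.loc[other, "n_derived"])
        na = int(support.loc[other, "n_ancestral"])
        if nd + na > 0 and nd / (nd + na) > max_conflict:
            flags.append(f"conflict_{other}")
    return YHaplogroupCall(node, support.reset_index(), flags=flags)
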