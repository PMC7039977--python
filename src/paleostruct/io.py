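"""Genotype containers, standard-format I/O, panel merging, and site/sample filters.

The central container is :class:`GenotypeMatrix`: a samples x SNPs matrix of
alt-allele dosages in diploid coding ({0, 1, 2}, ``-1`` for missing) together
with a variant table and a sample table.  Pseudo-haploid samples — genotypes
formed by sampling a single sequencing read and declaring the sample
homozygous for that read's allele — carry only {0, 2, missing} and are marked
by a per-sample ploidy flag, because they contribute a single allele to any
downstream frequency estimate.

Supported on-disk formats are the EIGENSTRAT triple (.geno/.snp/.ind) and
VCF with GT fields (via pysam).  Positions are 1-based throughout; SNP
identity for merging is (chromosome, position).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING = -1

PSEUDO_HAPLOID = "pseudo_haploid"
DIPLOID = "diploid"

_VARIANT_COLUMNS = ["snp_id", "chromosome", "position",
                    "allele_ref", "allele_alt", "allele_ancestral"]
_SAMPLE_COLUMNS = ["sample_id", "group_label", "sex", "ploidy_mode"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _as_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    v = variants.copy().reset_index(drop=True)
    for col in _VARIANT_COLUMNS:
        if col not in v.columns:
            if col == "allele_ancestral":
                v[col] = "N"
            elif col == "snp_id":
                v[col] = [f"snp{i}" for i in range(len(v))]
            else:
                raise ValueError(f"variant table missing column {col!r}")
    v["position"] = v["position"].astype(np.int64)
    return v[_VARIANT_COLUMNS]


def _as_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    s = samples.copy().reset_index(drop=True)
    if "sample_id" not in s.columns:
        raise ValueError("sample table missing column 'sample_id'")
    if s["sample_id"].duplicated().any():
        dups = s.loc[s["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if "group_label" not in s.columns:
        s["group_label"] = "NA"
    if "sex" not in s.columns:
        s["sex"] = "unknown"
    if "ploidy_mode" not in s.columns:
        s["ploidy_mode"] = DIPLOID
    bad = set(s["ploidy_mode"]) - {PSEUDO_HAPLOID, DIPLOID}
    if bad:
        raise ValueError(f"unknown ploidy modes: {bad}")
    keep = _SAMPLE_COLUMNS + [c for c in s.columns if c not in _SAMPLE_COLUMNS]
    return s[keep]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix with metadata.

    Parameters
    ----------
    calls
        int8 array of shape (n_samples, n_snps); entries in {0, 1, 2} or
        ``MISSING`` (-1).  Pseudo-haploid rows use {0, 2, MISSING} only.
    samples
        Sample table with at least ``sample_id``; ``group_label``, ``sex``
        and ``ploidy_mode`` are filled with defaults if absent.
    variants
        Variant table with ``snp_id, chromosome, position, allele_ref,
        allele_alt, allele_ancestral``.
    """

    calls: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = _as_sample_table(self.samples)
        self.variants = _as_variant_table(self.variants)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants")
        ph = self.ploidy_mask
        if ph.any() and np.any(self.calls[ph] == 1):
            raise ValueError("pseudo-haploid sample carries a heterozygous call")
        self._check_positions()

    def _check_positions(self) -> None:
        for _, sub in self.variants.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def ploidy_mask(self) -> np.ndarray:
        """Boolean per-sample mask: True where pseudo-haploid."""
        return (self.samples["ploidy_mode"] == PSEUDO_HAPLOID).to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def covered_fraction(self) -> np.ndarray:
        """Per-sample fraction of non-missing sites."""
        return 1.0 - self.missing_mask.mean(axis=1)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[:, index],
                              self.samples,
                              self.variants.iloc[np.asarray(index)])

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[np.asarray(index)],
                              self.samples.iloc[np.asarray(index)],
                              self.variants)


@dataclass
class BlockPartition:
    """Contiguous SNP blocks for the block jackknife.

    ``block_index`` maps each SNP to its block; blocks never span a
    chromosome boundary.  ``sizes`` are the per-block SNP counts m_j with
    sum M over g blocks.
    """

    block_index: np.ndarray
    sizes: np.ndarray
    blen: int

    def __post_init__(self) -> None:
        self.block_index = np.asarray(self.block_index, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.sum() != self.block_index.size:
            raise ValueError("block sizes do not sum to number of SNPs")

    @property
    def g(self) -> int:
        return len(self.sizes)

    @property
    def total(self) -> int:
        return int(self.sizes.sum())


def make_blocks(variants: pd.DataFrame, blen: int = 1000) -> BlockPartition:
    """Partition SNPs into contiguous blocks of ``blen`` per chromosome.

    The final block on each chromosome may be shorter than ``blen``.  At
    least two blocks overall are required, otherwise the delete-one-block
    jackknife is undefined.
    """
    if blen < 2:
        raise ValueError("blen must be >= 2")
    variants = _as_variant_table(variants)
    block_index = np.empty(len(variants), dtype=np.int64)
    sizes: list[int] = []
    offset = 0
    for _, sub in variants.groupby("chromosome", sort=False):
        n = len(sub)
        local = np.arange(n) // blen
        block_index[sub.index.to_numpy()] = local + len(sizes)
        n_blocks = int(local[-1]) + 1 if n else 0
        for b in range(n_blocks):
            sizes.append(int(np.sum(local == b)))
        offset += n
    if len(sizes) < 2:
        raise ValueError(
            f"only {len(sizes)} jackknife block(s); need >= 2 "
            "(reduce blen or supply more SNPs)")
    return BlockPartition(block_index, np.array(sizes), blen)


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

def _eigenstrat_paths(prefix: str) -> tuple[str, str, str]:
    return prefix + ".geno", prefix + ".snp", prefix + ".ind"


def read_eigenstrat(prefix: str) -> GenotypeMatrix:
    """Read an EIGENSTRAT triple ``prefix``.geno/.snp/.ind.

    The .geno file holds one row per SNP with one character per sample in
    {0, 1, 2, 9}; 9 maps to missing.  Note the on-disk convention counts
    *reference* alleles, so the alt-allele dosage is ``2 - code``.
    """
    geno_path, snp_path, ind_path = _eigenstrat_paths(prefix)
    for p in (geno_path, snp_path, ind_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    ind = pd.read_csv(ind_path, sep=r"\s+", header=None,
                      names=["sample_id", "sex", "group_label"], dtype=str)
    snp = pd.read_csv(snp_path, sep=r"\s+", header=None,
                      names=["snp_id", "chromosome", "gpos", "position",
                             "allele_ref", "allele_alt"],
                      dtype={"snp_id": str, "chromosome": str})
    snp["position"] = snp["position"].astype(np.int64)

    n_samples, n_snps = len(ind), len(snp)
    calls = np.empty((n_samples, n_snps), dtype=np.int8)
    with open(geno_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if i >= n_snps:
                raise FormatError(f"{geno_path}: more rows than SNPs in {snp_path}")
            if len(line) != n_samples:
                raise FormatError(
                    f"{geno_path}, line {i + 1}: expected {n_samples} "
                    f"genotype characters, found {len(line)}")
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            if not np.all((row <= 2) | (row == 9)):
                raise FormatError(f"{geno_path}, line {i + 1}: invalid genotype code")
            # file counts reference alleles; convert to alt dosage
            col = (2 - row).astype(np.int8)
            col[row == 9] = MISSING
            calls[:, i] = col
    if i + 1 != n_snps:
        raise FormatError(f"{geno_path}: {i + 1} rows but {n_snps} SNPs in {snp_path}")

    variants = snp.drop(columns="gpos")
    variants["allele_ancestral"] = "N"
    samples = ind[["sample_id", "group_label", "sex"]].copy()
    het = np.any(calls == 1, axis=1)
    samples["ploidy_mode"] = np.where(het, DIPLOID, PSEUDO_HAPLOID)
    return GenotypeMatrix(calls, samples, variants)


def write_eigenstrat(geno: GenotypeMatrix, prefix: str) -> None:
    """Write ``geno`` as an EIGENSTRAT triple (ref-allele counts on disk)."""
    geno_path, snp_path, ind_path = _eigenstrat_paths(prefix)
    ref_counts = 2 - geno.calls
    ref_counts[geno.calls == MISSING] = 9
    with open(geno_path, "w") as fh:
        for j in range(geno.n_snps):
            fh.write("".join(map(str, ref_counts[:, j])) + "\n")
    v = geno.variants
    with open(snp_path, "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.snp_id}\t{row.chromosome}\t0.0\t{row.position}"
                     f"\t{row.allele_ref}\t{row.allele_alt}\n")
    with open(ind_path, "w") as fh:
        for row in geno.samples.itertuples(index=False):
            sex = row.sex if row.sex in ("M", "F") else "U"
            fh.write(f"{row.sample_id}\t{sex}\t{row.group_label}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read genotypes from a VCF with GT fields.

    Diploid GTs map to alt dosage; haploid GTs (``0`` / ``1``) are read as
    pseudo-haploid and doubled into diploid coding; ``./.`` and ``.`` map
    to missing.  A sample is flagged pseudo-haploid when every called GT
    it carries is haploid.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    rows = []
    with pysam.VariantFile(path) as vcf:
        sample_ids = list(vcf.header.samples)
        haploid_only = np.ones(len(sample_ids), dtype=bool)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise FormatError(
                    f"{path}: site {rec.chrom}:{rec.pos} is not biallelic")
            records.append((rec.id or f"{rec.chrom}_{rec.pos}", rec.chrom,
                            rec.pos, rec.ref, rec.alts[0]))
            row = np.empty(len(sample_ids), dtype=np.int8)
            for k, sid in enumerate(sample_ids):
                gt = rec.samples[sid].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    row[k] = MISSING
                elif len(alleles) == 1:
                    row[k] = 2 * alleles[0]
                else:
                    row[k] = sum(alleles)
                    haploid_only[k] = False
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no variant records")
    calls = np.stack(rows, axis=1)
    variants = pd.DataFrame(records, columns=["snp_id", "chromosome", "position",
                                              "allele_ref", "allele_alt"])
    variants["allele_ancestral"] = "N"
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "ploidy_mode": np.where(haploid_only, PSEUDO_HAPLOID, DIPLOID),
    })
    return GenotypeMatrix(calls, samples, variants)


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write ``geno`` as an uncompressed VCF 4.2 (haploid GT for PH samples)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(geno.variants["chromosome"]):
        header.contigs.add(str(chrom))
    for sid in geno.samples["sample_id"]:
        header.add_sample(sid)
    ph = geno.ploidy_mask
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, var in enumerate(geno.variants.itertuples(index=False)):
            rec = out.new_record(contig=str(var.chromosome), start=var.position - 1,
                                 stop=var.position,
                                 alleles=(var.allele_ref, var.allele_alt),
                                 id=var.snp_id)
            for k, sid in enumerate(geno.samples["sample_id"]):
                c = int(geno.calls[k, j])
                if c == MISSING:
                    rec.samples[sid]["GT"] = (None,) if ph[k] else (None, None)
                elif ph[k]:
                    rec.samples[sid]["GT"] = (c // 2,)
                else:
                    rec.samples[sid]["GT"] = (1, 1) if c == 2 else (0, c)
            out.write(rec)


def read_genotypes(path: str, format: str = "eigenstrat") -> GenotypeMatrix:
    """Dispatch to :func:`read_eigenstrat` (``path`` is a prefix) or :func:`read_vcf`."""
    if format == "eigenstrat":
        return read_eigenstrat(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path: str, format: str = "eigenstrat") -> None:
    if format == "eigenstrat":
        write_eigenstrat(geno, path)
    elif format == "vcf":
        write_vcf(geno, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# merging and filters
# ---------------------------------------------------------------------------

def merge_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge genotype panels on the intersection of (chromosome, position).

    Allele labels are harmonized against the first panel: identical ref/alt
    pairs pass through, swapped pairs are recoded (dosage ``2 - c``), and
    incompatible pairs — including strand-ambiguous mismatches — are dropped
    with a logged count.  Sample ids must be unique across panels.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    all_ids = pd.concat([p.samples["sample_id"] for p in panels])
    if all_ids.duplicated().any():
        raise ValueError(
            f"duplicate sample ids across panels: "
            f"{sorted(all_ids[all_ids.duplicated()].unique())}")

    indices = [{(c, q): i for i, (c, q) in
                enumerate(zip(p.variants["chromosome"], p.variants["position"]))}
               for p in panels]
    shared = set.intersection(*(set(ix) for ix in indices))
    if not shared:
        raise ValueError("zero overlapping SNPs between panels")

    base = panels[0].variants
    base_idx = indices[0]
    order = sorted(shared, key=lambda k: base_idx[k])

    kept_keys: list[tuple] = []
    n_dropped = 0
    for key in order:
        i0 = base_idx[key]
        ref0, alt0 = base.iloc[i0][["allele_ref", "allele_alt"]]
        ok = True
        for p, idx in zip(panels[1:], indices[1:]):
            ref, alt = p.variants.iloc[idx[key]][["allele_ref", "allele_alt"]]
            if (ref, alt) != (ref0, alt0) and (ref, alt) != (alt0, ref0):
                ok = False
                break
        if ok:
            kept_keys.append(key)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("merge_panels: dropped %d sites with incompatible alleles",
                    n_dropped)
    if not kept_keys:
        raise ValueError("zero overlapping SNPs after allele harmonization")

    variants = base.iloc[[base_idx[k] for k in kept_keys]].reset_index(drop=True)

    pieces_calls = []
    pieces_samples = []
    for p, idx in zip(panels, indices):
        cols = [idx[k] for k in kept_keys]
        sub = p.calls[:, cols].copy()
        refs = p.variants["allele_ref"].to_numpy()[cols]
        swapped = refs != variants["allele_ref"].to_numpy()
        if swapped.any():
            block = sub[:, swapped]
            flipped = np.where(block == MISSING, MISSING, 2 - block).astype(np.int8)
            sub[:, swapped] = flipped
        pieces_calls.append(sub)
        pieces_samples.append(p.samples)

    calls = np.vstack(pieces_calls)
    samples = pd.concat(pieces_samples, ignore_index=True)
    return GenotypeMatrix(calls, samples, variants)


@dataclass
class FilterReport:
    n_sites_in: int
    n_sites_removed: int
    n_census_samples: int


def filter_sites_and_samples(geno: GenotypeMatrix,
                             site_missing_max: float = 0.9,
                             sample_cover_min: float = 0.6,
                             ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove SNPs missing in too many well-covered samples.

    Samples with covered fraction below ``sample_cover_min`` are *retained*
    in the output but excluded from the missingness census: only samples at
    or above the coverage threshold vote on which SNPs are too sparse.  A
    SNP is removed when its missing fraction among census samples exceeds
    ``site_missing_max`` (strictly greater, so 1.0 removes nothing).
    """
    for name, t in (("site_missing_max", site_missing_max),
                    ("sample_cover_min", sample_cover_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    cover = geno.covered_fraction()
    census = cover >= sample_cover_min
    if not census.any():
        raise ValueError(
            "no sample meets sample_cover_min; lower the threshold")
    miss_frac = geno.missing_mask[census].mean(axis=0)
    keep = miss_frac <= site_missing_max
    report = FilterReport(n_sites_in=geno.n_snps,
                          n_sites_removed=int((~keep).sum()),
                          n_census_samples=int(census.sum()))
    logger.info("filter_sites_and_samples: removed %d/%d sites "
                "(census of %d samples)", report.n_sites_removed,
                report.n_sites_in, report.n_census_samples)
    return geno.take_sites(np.flatnonzero(keep)), report


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per site from non-missing alleles.

    Pseudo-haploid samples contribute one allele, diploid samples two.
    Sites with no observed alleles return NaN.
    """
    ph = geno.ploidy_mask
    obs = ~geno.missing_mask
    calls = np.where(obs, geno.calls, 0).astype(np.float64)
    alt = np.where(ph[:, None], calls / 2.0, calls).sum(axis=0)
    tot = np.where(ph[:, None], 1.0, 2.0) * obs
    n = tot.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, alt / np.maximum(n, 1), np.nan)


def maf_filter(geno: GenotypeMatrix, maf_min: float = 0.05) -> np.ndarray:
    """Boolean site mask keeping SNPs with minor-allele frequency >= ``maf_min``.

    The boundary is inclusive: a site with MAF exactly equal to ``maf_min``
    is kept.  Sites with no observed alleles fail.
    """
    p = allele_frequencies(geno)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    mask = np.where(np.isnan(maf), False, maf >= maf_min)
    if not mask.any():
        raise ValueError("maf_filter removed every site")
    return mask


def ld_prune(geno: GenotypeMatrix, window: int = 200, step: int = 25,
             r2_max: float = 0.4) -> np.ndarray:
    """Sliding-window LD pruning by squared genotype correlation.

    Mirrors plink's ``--indep-pairwise window step r2``: within each
    window, pairs with r^2 above ``r2_max`` lose their later member; the
    window advances by ``step``.  Returns a boolean keep mask.  All-missing
    SNPs are pruned with a warning.
    """
    if not window > step > 0:
        raise ValueError("require window > step > 0")
    n, m = geno.calls.shape
    keep = np.ones(m, dtype=bool)
    calls = geno.calls.astype(np.float64)
    obs = ~geno.missing_mask
    all_missing = ~obs.any(axis=0)
    if all_missing.any():
        logger.warning("ld_prune: %d all-missing SNPs pruned", all_missing.sum())
        keep[all_missing] = False

    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start:start + window]) + start
        for a_pos in range(len(idx)):
            a = idx[a_pos]
            if not keep[a]:
                continue
            for b in idx[a_pos + 1:]:
                if not keep[b]:
                    continue
                both = obs[:, a] & obs[:, b]
                if both.sum() < 2:
                    continue
                x, y = calls[both, a], calls[both, b]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue
                r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
                if r * r > r2_max:
                    keep[b] = False       # deterministically drop the later SNP
        if start + window >= m:
            break
        start += step
    return keep
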