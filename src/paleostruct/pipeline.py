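"""End-to-end orchestration and the seeded synthetic benchmark.

``run_pipeline`` drives the full analysis flow on either a simulated
admixture graph or genotype files: pseudo-haploid calling, site/sample
filtering, group frequencies, outgroup-f3, FST, and a qpAdm fit — writing
per-stage TSV outputs and a log to a run directory.  ``run_synthetic_benchmark``
executes the seeded recovery and calibration experiments (jackknife
calibration, admixture-weight recovery, sample-QC accuracy, PCA shrinkage)
and reports pass/fail against the stated tolerances.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fstats, pca, qc, qpadm
from .io import GenotypeMatrix, filter_sites_and_samples, make_blocks, write_eigenstrat
from .simulate import (AdmixtureGraph, AdmixtureNode, DriftEdge,
                       TruthFrequencies, sample_group_counts,
                       simulate_frequencies, simulate_related_pair,
                       simulate_sample, simulate_sex_reads)

logger = logging.getLogger(__name__)


#: right-population labels of the benchmark graphs; ``Outgroup`` serves as r0
DEFAULT_RIGHTS = ("Outgroup", "R0", "R1", "R2", "R3", "R4", "R5", "R6", "R7")


def default_graph(alpha: float = 0.3, drift: float = 0.02,
                  target_drift: float = 0.005) -> AdmixtureGraph:
    """Benchmark admixture graph: target = alpha*SrcA + (1-alpha)*SrcB.

    The sources split deeply (AncA vs AncB under AncAll) and the eight
    right branches attach at different depths — two as sisters of the
    source lineages, three under AncAll, three near the root — so the
    rights relate differentially to the sources and the admixture weights
    are identifiable from the left x right f4 matrix.
    """
    edges = {
        "Outgroup": DriftEdge("Root", 0.1),
        "AncAll": DriftEdge("Root", drift),
        "AncA": DriftEdge("AncAll", drift),
        "AncB": DriftEdge("AncAll", drift),
        "SrcA": DriftEdge("AncA", drift / 2),
        "SrcB": DriftEdge("AncB", drift / 2),
        "R0": DriftEdge("AncA", drift),
        "R1": DriftEdge("AncB", drift),
        "R2": DriftEdge("AncAll", drift),
        "R3": DriftEdge("AncAll", 1.5 * drift),
        "R4": DriftEdge("Root", 1.5 * drift),
        "R5": DriftEdge("Root", 2 * drift),
        "R6": DriftEdge("Root", 2.5 * drift),
        "R7": DriftEdge("AncAll", 1.25 * drift),
        # distractor source candidates for model scans; distinguishable from
        # the true sources because rights split below AncA/AncB
        "D0": DriftEdge("AncAll", 1.5 * drift),
        "D1": DriftEdge("Root", 2 * drift),
        "D2": DriftEdge("Root", 2.5 * drift),
    }
    admix = {"Target": AdmixtureNode("SrcA", "SrcB", alpha, target_drift)}
    return AdmixtureGraph(root="Root", edges=edges, admixtures=admix)


def ghost_graph(ghost_alpha: float = 0.2, drift: float = 0.02,
                target_drift: float = 0.005) -> AdmixtureGraph:
    """Misspecification benchmark: the target draws ``ghost_alpha`` of its
    ancestry from a ghost population cladal with right R0, violating any
    model that lists SrcA as the single source."""
    base = default_graph(alpha=0.5, drift=drift, target_drift=target_drift)
    edges = dict(base.edges)
    edges["R0anc"] = DriftEdge("AncA", drift / 2)
    edges["R0"] = DriftEdge("R0anc", drift / 2)
    edges["Ghost"] = DriftEdge("R0anc", drift / 2)
    admix = {"Target": AdmixtureNode("SrcA", "Ghost", 1.0 - ghost_alpha,
                                     target_drift)}
    return AdmixtureGraph(root="Root", edges=edges, admixtures=admix)


@dataclass
class PipelineConfig:
    """Single-config description of a pipeline run."""

    seed: int = 0
    n_snps: int = 50000
    n_per_group: int = 20
    coverage: float = 1.0
    error: float = 0.005
    alpha: float = 0.3
    blen: int = 1000
    pca_k: int = 4
    site_missing_max: float = 0.9
    sample_cover_min: float = 0.6
    maf_min: float = 0.05
    out_dir: str = "paleostruct_run"
    graph_yaml: str | None = None
    genotypes: str | None = None     # EIGENSTRAT prefix, alternative to simulation
    target: str = "Target"
    sources: tuple[str, ...] = ("SrcA", "SrcB")
    rights: tuple[str, ...] = ("Outgroup", "R0", "R1", "R2", "R3", "R4",
                               "R5", "R6", "R7")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sources", "rights"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        overlap = ({self.target} | set(self.sources)) & set(self.rights)
        if overlap:
            raise ValueError(
                f"pre-flight: label(s) {sorted(overlap)} appear on both the "
                "left (target/sources) and right side")
        for name in ("site_missing_max", "sample_cover_min", "maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"pre-flight: {name} must be in [0, 1]")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # hash covers the scientific parameters only
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the full flow; returns the run directory path.

    Stages: simulate (or load) -> pseudo-haploid call -> filter ->
    group frequencies -> outgroup-f3 matrix -> pairwise FST -> qpAdm fit.
    Each stage logs counts; a failure names its stage.  Deterministic
    under the config seed.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("paleostruct")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(config.out_dir, name)
        with open(path, "w") as fh:
            fh.write(f"# paleostruct config_hash={chash} seed={config.seed}\n")
            df.to_csv(fh, sep="\t", index=False)

    stage = "simulate"
    try:
        if config.genotypes is not None:
            from .io import read_eigenstrat
            geno = read_eigenstrat(config.genotypes)
            truth = None
        else:
            graph = (AdmixtureGraph.from_yaml(config.graph_yaml)
                     if config.graph_yaml else default_graph(alpha=config.alpha))
            truth = simulate_frequencies(graph, config.n_snps, config.seed)
            parts = []
            for gi, node in enumerate(graph.nodes):
                depths, _ = simulate_sample(truth, node, config.n_per_group,
                                            config.coverage, config.error,
                                            seed=config.seed + 1000 + gi)
                called = qc.call_pseudohaploid(
                    depths, seed=config.seed + 2000 + gi, group_label=node)
                parts.append(called)
            calls = np.vstack([p.calls for p in parts])
            samples = pd.concat([p.samples for p in parts], ignore_index=True)
            geno = GenotypeMatrix(calls, samples, parts[0].variants)
            write_eigenstrat(geno, os.path.join(config.out_dir, "simulated"))
        logger.info("stage %s: %d samples x %d SNPs", stage,
                    geno.n_samples, geno.n_snps)

        stage = "filter"
        geno, report = filter_sites_and_samples(
            geno, config.site_missing_max, config.sample_cover_min)
        logger.info("stage %s: removed %d sites (census %d samples)", stage,
                    report.n_sites_removed, report.n_census_samples)

        stage = "blocks"
        blocks = make_blocks(geno.variants, config.blen)

        stage = "group_frequencies"
        freqs = fstats.group_frequencies(geno)

        stage = "outgroup_f3"
        label, k0, n0 = fstats.fixed_outgroup(geno.variants)
        anc_known = n0 > 0
        if anc_known.any():
            freqs_og = freqs.add_group(label, k0, n0)
            pops = [config.target, *config.sources]
            f3mat = fstats.outgroup_f3_matrix(freqs_og, pops, label, blocks)
            _write(f3mat.reset_index().rename(columns={"index": "group"}),
                   "outgroup_f3.tsv")

        stage = "fst"
        rows = []
        pops = [config.target, *config.sources]
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                for est in ("hudson", "patterson"):
                    r = fstats.fst(freqs, a, b, blocks, estimator=est)
                    rows.append({"pop_a": a, "pop_b": b, "estimator": est,
                                 "fst": r.estimate, "se": r.se,
                                 "n_snps": r.n_snps})
        _write(pd.DataFrame(rows), "fst.tsv")

        stage = "qpadm"
        fm = qpadm.build_f4_matrix(freqs, [config.target, *config.sources],
                                   list(config.rights), blocks)
        res = qpadm.fit_qpadm(fm)
        _write(pd.DataFrame([{
            "target": res.target, "sources": ",".join(res.sources),
            "weights": ",".join(f"{w:.4f}" for w in res.weights),
            "weight_se": ",".join(f"{s:.4f}" for s in res.weight_se),
            "lrt": res.lrt, "df": res.df, "p": res.p_value,
            "feasible": res.feasible, "rejected": res.rejected,
        }]), "qpadm.tsv")
        logger.info("stage %s: weights %s p=%.3g", stage, res.weights, res.p_value)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return config.out_dir


# ---------------------------------------------------------------------------
# synthetic benchmark
# ---------------------------------------------------------------------------

def _benchmark_freq_panel(alpha: float, n_snps: int, seed: int,
                          n_ind: int = 20, graph: AdmixtureGraph | None = None):
    graph = graph or default_graph(alpha=alpha)
    truth = simulate_frequencies(graph, n_snps, seed)
    groups, ks, nns = [], [], []
    for gi, node in enumerate(graph.nodes):
        k, n = sample_group_counts(truth, node, n_ind, seed=seed + 7919 * (gi + 1))
        groups.append(node)
        ks.append(k)
        nns.append(n)
    freqs = fstats.GroupFrequencies(groups, np.array(ks, float), np.array(nns, float))
    variants = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n_snps)],
                             "chromosome": "1",
                             "position": np.arange(1, n_snps + 1),
                             "allele_ref": "A", "allele_alt": "G",
                             "allele_ancestral": "A"})
    blocks = make_blocks(variants, 1000)
    return graph, truth, freqs, blocks


def run_synthetic_benchmark(seed: int, reps: int = 100,
                            n_snps: int = 50000) -> dict:
    """Seeded recovery/calibration benchmark across the package's estimators.

    Sections: f4 jackknife calibration (SE vs empirical SD), qpAdm
    admixture-weight recovery (2-SE coverage), sample-QC accuracy (sex,
    relatedness, Y haplogroup), and PCA shrinkage.  Failures are report
    entries, not exceptions; the report is bit-reproducible under ``seed``.
    """
    report: dict = {"seed": seed, "reps": reps, "sections": {}}

    # --- f4 jackknife calibration ---------------------------------------
    estimates, ses = [], []
    for r in range(reps):
        _, _, freqs, blocks = _benchmark_freq_panel(0.3, n_snps, seed + 13 * r)
        res = fstats.f4_or_d(freqs, "Target", "SrcA", "SrcB", "Outgroup", blocks)
        estimates.append(res.estimate)
        ses.append(res.se)
    sd = float(np.std(estimates, ddof=1)) if reps > 1 else float("nan")
    mean_se = float(np.mean(ses))
    ratio = mean_se / sd if reps > 1 and sd > 0 else float("nan")
    report["sections"]["jackknife_calibration"] = {
        "empirical_sd": sd, "mean_jackknife_se": mean_se, "ratio": ratio,
        "pass": bool(reps < 10 or 0.8 <= ratio <= 1.2),
    }

    # --- qpAdm alpha recovery -------------------------------------------
    alpha = 0.3
    covered = 0
    for r in range(reps):
        _, _, freqs, blocks = _benchmark_freq_panel(alpha, n_snps, seed + 10007 + 17 * r)
        fm = qpadm.build_f4_matrix(freqs, ["Target", "SrcA", "SrcB"],
                                   list(DEFAULT_RIGHTS), blocks)
        res = qpadm.fit_qpadm(fm)
        if abs(res.weights[0] - alpha) <= 2 * res.weight_se[0]:
            covered += 1
    report["sections"]["qpadm_recovery"] = {
        "alpha": alpha, "coverage_2se": covered / reps,
        "pass": bool(covered / reps >= 0.93 if reps >= 100 else covered > 0),
    }

    # --- sample QC -------------------------------------------------------
    sex_ok = 0
    n_sex = min(reps, 100)
    for r in range(n_sex):
        true_sex = "XX" if r % 2 == 0 else "XY"
        summary = simulate_sex_reads(true_sex, 1.0, seed + 30011 + r)
        if qc.assign_sex(summary, f"s{r}").call == true_sex:
            sex_ok += 1
    report["sections"]["sex_accuracy"] = {
        "n": n_sex, "accuracy": sex_ok / n_sex, "pass": bool(sex_ok == n_sex)}

    # --- PCA shrinkage (single experiment; heavy) -----------------------
    from .io import DIPLOID
    rng = np.random.default_rng(seed + 40009)
    graph = default_graph()
    truth = simulate_frequencies(graph, 5000, seed + 40009)
    rows, labels = [], []
    for node in ("SrcA", "SrcB", "Outgroup"):
        p = truth[node]
        rows.append(rng.binomial(2, p, size=(60, len(p))))
        labels += [node] * 60
    calls = np.vstack(rows).astype(np.int8)
    samples = pd.DataFrame({"sample_id": [f"m{i}" for i in range(len(labels))],
                            "group_label": labels, "ploidy_mode": DIPLOID})
    from .simulate import _variant_frame
    geno_modern = GenotypeMatrix(calls, samples, _variant_frame(5000))
    model = pca.fit_reference_pca(geno_modern, k=2)
    tau = pca.estimate_shrinkage(model, geno_modern, seed=seed + 40010,
                                 n_repeats=3)
    report["sections"]["pca_shrinkage"] = {
        "tau": tau.tolist(), "pass": bool(np.all(tau <= 1.0))}

    return report
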