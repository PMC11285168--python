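"""End-to-end orchestration: simulate -> deg -> trend -> fit -> pod -> enrich.

Holds the pipeline configuration (all thresholds with their defaults), the
plain-text readers/writers for every stage artifact (counts TSV or
MatrixMarket, sample sheet CSV, DEG/trend/BMD tables TSV, report JSON), and
``run_pipeline``, which executes the stages in order, writes each table
before the next stage starts, and records a manifest with versions, seeds,
thresholds and input checksums.  Concentrations are carried in µM throughout;
log10 transforms happen at use sites and are never persisted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from . import __version__
from .synthetic_data import (CountMatrix, DoseDesign, TruthTable, make_design,
                             make_truth, simulate_counts)
from . import deg as deg_mod
from . import trend as trend_mod
from . import bmdfit
from . import pod as pod_mod
from . import enrichment as enrich_mod

log = logging.getLogger("tpod")

__all__ = ["PipelineConfig", "run_pipeline", "write_counts", "read_counts",
           "write_counts_mtx", "read_counts_mtx"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds and design parameters, YAML-serializable."""

    # design / simulation
    anchor_uM: float = 2.92
    n_dilutions: int = 3
    dilution_factor: float = 10.0
    n_replicates: int = 3
    n_genes: int = 2000
    library_size: float = 200_000.0
    responsive_fraction: float = 0.10
    seed: int = 1
    # DE thresholds
    q_cutoff: float = deg_mod.Q_CUTOFF
    lfc_cutoff: float = deg_mod.LFC_CUTOFF
    pseudocount: float = 1.0
    # trend prefilter
    trend_fc: float = trend_mod.TREND_FC_CUTOFF
    trend_alpha: float = trend_mod.TREND_ALPHA
    n_permutations: int = 10_000
    # BMD modeling
    bmr_factor: float = bmdfit.BMR_FACTOR
    confidence: float = bmdfit.CONFIDENCE
    # postfilter / tPOD
    ratio_cap: float = pod_mod.BMDU_BMDL_CAP
    tpod_fraction: float = pod_mod.TPOD_FRACTION
    kde_bandwidth: str | float = "silverman"
    # enrichment
    max_term_size: int = enrich_mod.MAX_TERM_SIZE
    ora_fdr: float = enrich_mod.ORA_FDR
    gmt_path: str | None = None

    def __post_init__(self):
        if not (0 < self.q_cutoff < 1 and 0 < self.trend_alpha < 1
                and 0 < self.confidence < 1 and 0 < self.ora_fdr < 1):
            raise ValueError("probability thresholds must lie in (0, 1)")
        if (self.lfc_cutoff < 0 or self.trend_fc < 1 or self.ratio_cap <= 1
                or not 0 <= self.tpod_fraction <= 1 or self.bmr_factor <= 0):
            raise ValueError("threshold outside its documented domain")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def design(self) -> DoseDesign:
        return make_design(self.anchor_uM, self.n_dilutions,
                           self.dilution_factor, self.n_replicates)


# ---------------------------------------------------------------------------
# Format round-tripping
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    """Genes-in-rows TSV (first column gene_id) plus sample sheet CSV."""
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samples_path, index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path)
    return CountMatrix(counts=counts, samples=samples)


def write_counts_mtx(cm: CountMatrix, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.rows, <prefix>.cols."""
    prefix = str(prefix)
    mmwrite(prefix + ".mtx", csr_matrix(cm.counts.to_numpy()))
    Path(prefix + ".rows").write_text("\n".join(cm.counts.index) + "\n")
    Path(prefix + ".cols").write_text("\n".join(cm.counts.columns) + "\n")


def read_counts_mtx(prefix, samples_path) -> CountMatrix:
    prefix = str(prefix)
    mat = np.asarray(mmread(prefix + ".mtx").todense())
    rows = Path(prefix + ".rows").read_text().splitlines()
    cols = Path(prefix + ".cols").read_text().splitlines()
    counts = pd.DataFrame(mat.astype(np.int64), index=rows, columns=cols)
    counts.index.name = "gene_id"
    return CountMatrix(counts=counts, samples=pd.read_csv(samples_path))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir,
                 counts: CountMatrix = None) -> pod_mod.TPODReport:
    """Run the full analysis and persist every stage artifact under outdir.

    When ``counts`` is None a dataset is simulated under the configured
    design (truth table written alongside for recovery scoring).  Returns the
    TPODReport; artifacts: counts.tsv, samples.csv, truth.tsv, deg.tsv,
    trend.tsv, bmd.tsv, retained_bmd.tsv, report.json, manifest.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    manifest = {
        "tpod_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stage_counts": {},
    }

    if counts is None:
        log.info("simulating %d genes under %d-sample design",
                 config.n_genes, design.n_samples)
        truth = make_truth(config.n_genes, design, seed=config.seed,
                           responsive_fraction=config.responsive_fraction)
        counts = simulate_counts(design, truth, config.library_size,
                                 seed=config.seed)
        truth.to_tsv(out / "truth.tsv")
    write_counts(counts, out / "counts.tsv", out / "samples.csv")
    manifest["inputs"]["counts_sha256"] = _sha256(out / "counts.tsv")
    manifest["stage_counts"]["input_genes"] = int(len(counts.counts))

    # --- differential expression (top concentration vs control) ---
    factors = deg_mod.size_factors(counts)
    degs = deg_mod.nb_test(counts, factors=factors)
    degs = deg_mod.call_degs(degs, config.q_cutoff, config.lfc_cutoff)
    degs.to_csv(out / "deg.tsv", sep="\t", index=False)
    manifest["stage_counts"]["degs"] = int(degs["is_deg"].sum())
    log.info("DE stage: %d DEGs of %d tested genes",
             int(degs["is_deg"].sum()), int(degs["p"].notna().sum()))

    # --- trend prefilter ---
    norm = deg_mod.normalize_log2(counts, factors, config.pseudocount)
    trend = trend_mod.williams_test_matrix(
        norm, n_permutations=config.n_permutations, seed=config.seed + 1,
        fc_cut=config.trend_fc, alpha=config.trend_alpha)
    trend.to_csv(out / "trend.tsv", sep="\t", index=False)
    passing = trend.loc[trend["passes"], "gene_id"].tolist()
    manifest["stage_counts"]["prefiltered"] = len(passing)
    log.info("trend prefilter: %d of %d genes pass", len(passing), len(trend))

    # --- BMD fitting ---
    fits = bmdfit.fit_genes(norm, passing, bmr_factor=config.bmr_factor,
                            confidence=config.confidence,
                            seed=config.seed + 2)
    fits.to_csv(out / "bmd.tsv", sep="\t", index=False)
    manifest["stage_counts"]["fitted"] = int((fits["status"] != "failed").sum()
                                             if len(fits) else 0)

    # --- postfilter + tPODs ---
    report = pod_mod.derive_tpods(fits, design, fraction=config.tpod_fraction,
                                  bandwidth=config.kde_bandwidth,
                                  ratio_cap=config.ratio_cap)
    report.retained.to_csv(out / "retained_bmd.tsv", sep="\t", index=False)
    manifest["stage_counts"]["postfiltered"] = report.n_retained
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    log.info("tPOD(10th) = %.4g uM, tPOD(mode) = %s uM",
             report.tpod_10th, report.tpod_mode)

    # --- optional enrichment of the first-mode gene set ---
    if config.gmt_path:
        coll = enrich_mod.read_gmt(config.gmt_path)
        universe = degs.loc[degs["p"].notna(), "gene_id"]
        enr = enrich_mod.ora(set(report.first_mode_gene_ids) & set(universe),
                             universe, coll, config.max_term_size,
                             config.ora_fdr)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stage_counts"]["enriched_terms"] = int(
            enr["significant"].sum()) if len(enr) else 0

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
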