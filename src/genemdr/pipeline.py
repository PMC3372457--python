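"""The Gene-MDR two-stage procedure.

Stage 1 (within-gene): for every gene, an exhaustive MDR search over its
member SNPs (combination orders 1..max_within_order) picks the best SNP
combination by cross-validation consistency and mean test balanced accuracy.
The winning combination's high/low-risk cell labeling, refit on all samples,
becomes the binary *gene predictor* — a per-sample 0/1 attribute that
summarizes the gene.

Stage 2 (between-gene): gene predictors with CVC or mean test BA below
threshold are excluded; all combinations of the retained predictors (default
pairs) are evaluated by the same cross-validated MDR machinery and ranked by
mean test balanced accuracy.

Traceback: a top-ranked gene pair is re-expressed at SNP level by fitting a
single MDR model on the pooled chosen SNPs of the two genes, so a 2-way
gene-level interaction built from 4+4 chosen SNPs corresponds to an 8th-order
SNP interaction.  Because dichotomization into a gene predictor loses
information, the traceback BA typically exceeds the gene-level BA; the delta
is reported, not hidden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GeneMap, GenotypeMatrix
from .mdr_core import (
    CellLabels,
    CVPlan,
    RiskModel,
    classify_cells,
    cross_validate,
    make_cv_plan,
    search_best,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the two-stage analysis.

    Defaults follow standard practice for this method: within-gene search up
    to 4th-order SNP combinations, 2-way between-gene search, 10-fold CV,
    predictor retention at CVC >= 5 and test BA >= 0.5, 100 kb annotation
    window, SNP-level traceback capped at 8th order, and a 500-edge network.
    """

    max_within_order: int = 4
    between_order: int = 2
    cvc_min: int = 5
    ba_min: float = 0.5
    k: int = 10
    window: int = 100_000
    seed: int = 0
    top_n_network: int = 500
    traceback_max_order: int = 8

    def __post_init__(self) -> None:
        for name in ("max_within_order", "between_order", "k", "top_n_network",
                     "traceback_max_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.cvc_min < 1 or self.cvc_min > self.k:
            raise ValueError("cvc_min must be in [1, k]")
        if self.window < 0:
            raise ValueError("window must be >= 0")


def _stage_seed(master: int, stage: int) -> int:
    """Independent per-stage RNG seed derived from the master seed (< 2^31)."""
    return int(np.random.SeedSequence([int(master), stage]).generate_state(1)[0] % (2**31))


@dataclass
class GenePredictor:
    """Binary high/low-risk gene summary from the within-gene MDR stage."""

    gene: str
    chosen_snps: tuple[str, ...]
    labels: CellLabels
    predictor_values: np.ndarray  # per-sample, high=1 / low=0
    cvc: int
    mean_test_ba: float
    n_snps_in_gene: int
    evaluated: int


@dataclass
class TracebackModel:
    """SNP-level MDR model on the pooled chosen SNPs of an interaction."""

    snps: tuple[str, ...]
    order: int
    mean_test_ba: float
    model: RiskModel


@dataclass
class InteractionResult:
    """A between-gene combination with its selection statistics."""

    genes: tuple[str, ...]
    chosen_snps: dict[str, tuple[str, ...]]
    mean_test_ba: float
    cvc: int
    snp_level: TracebackModel | None = None

    @property
    def snp_counts(self) -> tuple[int, ...]:
        return tuple(len(self.chosen_snps[g]) for g in self.genes)

    @property
    def traceback_delta(self) -> float | None:
        """SNP-level minus gene-level mean test BA (information-loss gauge)."""
        if self.snp_level is None:
            return None
        return self.snp_level.mean_test_ba - self.mean_test_ba


# ---------------------------------------------------------------------------
# stage 1: within-gene
# ---------------------------------------------------------------------------

def fit_gene_predictor(
    gene: str,
    member_snps: list[str],
    g: GenotypeMatrix,
    scores: np.ndarray,
    cfg: PipelineConfig,
    plan: CVPlan,
) -> GenePredictor:
    """Search the gene's SNP combinations and build its binary predictor.

    The search covers orders 1..min(max_within_order, #SNPs); the winning
    combination's labeling is refit on all samples to define the per-sample
    predictor values, while CVC and mean test BA are carried over from the
    cross-validated search.
    """
    if not member_snps:
        raise ValueError(f"gene {gene!r} has no member SNPs")
    candidates = {sid: g.column(sid) for sid in member_snps}
    orders = range(1, min(cfg.max_within_order, len(member_snps)) + 1)
    res = search_best(candidates, orders, scores, g.phenotype, plan)
    columns = g.columns(list(res.best.attributes))
    values = res.best.labels.predict(columns).astype(np.int8)
    return GenePredictor(
        gene=gene,
        chosen_snps=res.best.attributes,
        labels=res.best.labels,
        predictor_values=values,
        cvc=res.cvc,
        mean_test_ba=res.mean_test_ba,
        n_snps_in_gene=len(member_snps),
        evaluated=res.evaluated,
    )


def run_within_gene(
    g: GenotypeMatrix,
    gene_map: GeneMap,
    scores: np.ndarray,
    cfg: PipelineConfig,
) -> list[GenePredictor]:
    """Stage 1: one gene predictor per gene with >=1 surviving member SNP.

    Genes are processed in sorted symbol order and the CV fold plan is drawn
    once from the master seed, so results do not depend on iteration order.
    """
    g.require_complete()
    members = gene_map.members()
    if not members:
        raise ValueError("gene map has no assigned SNPs")
    plan = make_cv_plan(g.phenotype, k=cfg.k, seed=_stage_seed(cfg.seed, 1))
    preds: list[GenePredictor] = []
    present = set(g.snp_ids)
    for gene in sorted(members):
        snps = [s for s in members[gene] if s in present]
        if not snps:
            logger.info("gene %s skipped: no member SNPs survive QC", gene)
            continue
        pred = fit_gene_predictor(gene, snps, g, scores, cfg, plan)
        logger.info(
            "gene %s: %d SNPs, chose %s (CVC %d, test BA %.4f, %d fits)",
            gene, len(snps), ",".join(pred.chosen_snps), pred.cvc,
            pred.mean_test_ba, pred.evaluated,
        )
        preds.append(pred)
    return preds


def filter_predictors(
    preds: list[GenePredictor], cfg: PipelineConfig
) -> tuple[list[GenePredictor], pd.DataFrame]:
    """Exclude weak predictors: CVC < cvc_min and/or mean test BA < ba_min.

    Exclusion is strict, so boundary values (CVC == cvc_min, BA == ba_min)
    are retained.  Returns the retained predictors and an exclusion report.
    """
    if not preds:
        raise ValueError("no gene predictors to filter")
    rows = []
    retained: list[GenePredictor] = []
    for p in preds:
        why = []
        if p.cvc < cfg.cvc_min:
            why.append(f"CVC < {cfg.cvc_min}")
        if p.mean_test_ba < cfg.ba_min:
            why.append(f"test BA < {cfg.ba_min:g}")
        rows.append(
            {
                "gene": p.gene,
                "cvc": p.cvc,
                "mean_test_ba": p.mean_test_ba,
                "excluded": bool(why),
                "reasons": ";".join(why),
            }
        )
        if not why:
            retained.append(p)
    report = pd.DataFrame(rows)
    if not retained:
        raise ValueError(
            "every gene predictor was excluded; lower cvc_min/ba_min or "
            "inspect the within-gene results"
        )
    logger.info("retained %d/%d gene predictors", len(retained), len(preds))
    return retained, report


# ---------------------------------------------------------------------------
# stage 2: between-gene
# ---------------------------------------------------------------------------

def run_between_gene(
    preds: list[GenePredictor],
    scores: np.ndarray,
    phenotype: np.ndarray,
    cfg: PipelineConfig,
) -> list[InteractionResult]:
    """Stage 2: evaluate all predictor combinations, ranked by mean test BA.

    Every C(#predictors, between_order) combination of the binary gene
    predictors is cross-validated; ranking is by mean test balanced accuracy
    (descending), ties broken by the sorted gene-symbol tuple.  A
    combination's CVC is the number of folds in which it has the highest
    training BA among all combinations.
    """
    if len(preds) < cfg.between_order:
        raise ValueError(
            f"need >= {cfg.between_order} retained predictors, got {len(preds)}"
        )
    by_gene = {p.gene: p for p in preds}
    plan = make_cv_plan(phenotype, k=cfg.k, seed=_stage_seed(cfg.seed, 2))
    combos = list(combinations(sorted(by_gene), cfg.between_order))

    best_ba = np.full(cfg.k, -1.0)
    winner: list[tuple[str, ...] | None] = [None] * cfg.k
    cv_by_combo = {}
    for combo in combos:
        columns = np.column_stack([by_gene[gs].predictor_values for gs in combo])
        cvres = cross_validate(columns, scores, phenotype, plan)
        cv_by_combo[combo] = cvres
        for f in range(cfg.k):
            if cvres.train_ba[f] > best_ba[f]:
                best_ba[f] = cvres.train_ba[f]
                winner[f] = combo

    results = []
    for combo in combos:
        cvres = cv_by_combo[combo]
        results.append(
            InteractionResult(
                genes=combo,
                chosen_snps={gs: by_gene[gs].chosen_snps for gs in combo},
                mean_test_ba=cvres.mean_test_ba,
                cvc=sum(1 for w in winner if w == combo),
            )
        )
    results.sort(key=lambda r: (-r.mean_test_ba, r.genes))
    logger.info("between-gene stage: %d combinations evaluated", len(combos))
    return results


def traceback_snp_level(
    result: InteractionResult,
    g: GenotypeMatrix,
    scores: np.ndarray,
    cfg: PipelineConfig,
    plan: CVPlan | None = None,
) -> TracebackModel | None:
    """Refit one MDR model on the pooled chosen SNPs of an interaction.

    The pool is the concatenation of each gene's chosen SNPs (genes in result
    order), so its size is the SNP-level interaction order — e.g. 4+4 chosen
    SNPs give an 8th-order model.  Pools larger than ``traceback_max_order``
    are skipped with a log entry.  The fitted model is attached to
    ``result.snp_level`` and returned.
    """
    pool: list[str] = []
    for gene in result.genes:
        pool.extend(result.chosen_snps[gene])
    if len(set(pool)) != len(pool):
        raise ValueError(f"duplicate SNPs in traceback pool for {result.genes}")
    if len(pool) > cfg.traceback_max_order:
        logger.info(
            "traceback skipped for %s: pool of %d SNPs exceeds max order %d",
            result.genes, len(pool), cfg.traceback_max_order,
        )
        return None
    if plan is None:
        plan = make_cv_plan(g.phenotype, k=cfg.k, seed=_stage_seed(cfg.seed, 3))
    columns = g.columns(pool)
    cvres = cross_validate(columns, scores, g.phenotype, plan)
    labels = classify_cells(columns, scores)
    model = RiskModel(
        attributes=tuple(pool),
        labels=labels,
        train_ba=cvres.train_ba,
        test_ba=cvres.test_ba,
    )
    tb = TracebackModel(
        snps=tuple(pool),
        order=len(pool),
        mean_test_ba=cvres.mean_test_ba,
        model=model,
    )
    result.snp_level = tb
    return tb


# ---------------------------------------------------------------------------
# orchestration + serialization
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    predictors: list[GenePredictor]
    retained: list[GenePredictor]
    exclusion_report: pd.DataFrame
    interactions: list[InteractionResult]
    config: PipelineConfig


def run_pipeline(
    g: GenotypeMatrix,
    gene_map: GeneMap,
    covariates: pd.DataFrame | None,
    cfg: PipelineConfig,
    traceback: bool = True,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full two-stage analysis; optionally writes the result files.

    Output files (all deterministic given inputs + seed): ``predictors.tsv``,
    ``predictor_values.tsv``, ``exclusions.tsv``, ``interactions.tsv``,
    ``run_config.json``.
    """
    from .mdr_core import null_model_scores

    g.require_complete()
    scores = null_model_scores(g.phenotype, covariates)
    preds = run_within_gene(g, gene_map, scores, cfg)
    retained, report = filter_predictors(preds, cfg)
    interactions = run_between_gene(retained, scores, g.phenotype, cfg)
    if traceback:
        plan = make_cv_plan(g.phenotype, k=cfg.k, seed=_stage_seed(cfg.seed, 3))
        for res in interactions:
            traceback_snp_level(res, g, scores, cfg, plan=plan)
    result = PipelineResult(
        predictors=preds,
        retained=retained,
        exclusion_report=report,
        interactions=interactions,
        config=cfg,
    )
    if out_dir is not None:
        write_pipeline_outputs(result, g, out_dir)
    return result


def predictors_frame(preds: list[GenePredictor]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [p.gene for p in preds],
            "n_snps_in_gene": [p.n_snps_in_gene for p in preds],
            "chosen_snps": [",".join(p.chosen_snps) for p in preds],
            "order": [len(p.chosen_snps) for p in preds],
            "cvc": [p.cvc for p in preds],
            "mean_test_ba": [p.mean_test_ba for p in preds],
        }
    )


def interactions_frame(results: list[InteractionResult]) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(results, start=1):
        row = {
            "rank": rank,
            "genes": ",".join(r.genes),
            "n_snps": ",".join(str(c) for c in r.snp_counts),
            "mean_test_ba": r.mean_test_ba,
            "cvc": r.cvc,
            "traceback_order": r.snp_level.order if r.snp_level else "",
            "traceback_test_ba": r.snp_level.mean_test_ba if r.snp_level else "",
            "traceback_delta": r.traceback_delta if r.snp_level else "",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_pipeline_outputs(result: PipelineResult, g: GenotypeMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    predictors_frame(result.predictors).to_csv(
        out / "predictors.tsv", sep="\t", index=False, float_format="%.10g"
    )
    values = pd.DataFrame(
        {p.gene: p.predictor_values for p in result.predictors},
        index=pd.Index(g.samples, name="sample_id"),
    )
    values.to_csv(out / "predictor_values.tsv", sep="\t")
    result.exclusion_report.to_csv(
        out / "exclusions.tsv", sep="\t", index=False, float_format="%.10g"
    )
    interactions_frame(result.interactions).to_csv(
        out / "interactions.tsv", sep="\t", index=False, float_format="%.10g"
    )
    with open(out / "run_config.json", "wt", encoding="utf-8") as fh:
        json.dump(asdict(result.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
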