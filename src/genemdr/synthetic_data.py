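"""Synthetic case-control GWAS generator with controllable epistasis.

Emulates the structure of a SNP-chip case-control study: biallelic SNPs drawn
from Hardy-Weinberg proportions at configurable minor-allele frequencies,
genes of varying SNP counts with BED coordinates, sex/age covariates, and a
binary phenotype from a logistic disease model.  Multi-locus penetrance
components compose with the baseline prevalence and covariate effects on the
logit scale, so several components (and covariates) combine without leaving
[0, 1]; a single full-coverage component therefore reproduces its penetrance
table exactly.

Case/control quotas are met by sampling-until-quota: unascertained cohorts
are drawn in batches and the first ``n_cases`` cases and ``n_controls``
controls (in draw order) form the dataset.  SNPs are independent (no linkage
disequilibrium) by default.

Named presets (:func:`make_epistasis_fixture`) cover the test scenarios:
``null``, ``marginal_only``, ``pure_epistasis_2gene`` (a parity/XOR model at
MAF 0.5, marginally null at both loci by construction) and ``mixed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import data_io
from .data_io import GenotypeMatrix

_CLIP = 1e-12


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: BED-style half-open interval and SNP count."""

    symbol: str
    chrom: str
    start: int
    end: int
    n_snps: int

    def snp_ids(self) -> list[str]:
        return [f"{self.symbol}_s{i}" for i in range(1, self.n_snps + 1)]

    def snp_positions(self) -> np.ndarray:
        """1-based positions, evenly spread inside the gene interval."""
        span = self.end - self.start
        offs = (np.arange(self.n_snps) + 1) * span // (self.n_snps + 1)
        return self.start + offs + 1


@dataclass(frozen=True)
class PenetranceComponent:
    """Penetrance table over the genotype cells of a SNP tuple.

    ``table`` has shape (3,)*len(snps) with entries in [0, 1]; cell (i, j)
    is P(disease | g1 = i, g2 = j) when this is the only component and there
    are no covariate effects.
    """

    snps: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3,) * len(self.snps):
            raise ValueError("penetrance table shape must be (3,)*len(snps)")
        if t.min() < 0.0 or t.max() > 1.0:
            raise ValueError("penetrance entries must be in [0,1]")
        object.__setattr__(self, "table", t)


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    genes: list[GeneSpec]
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_mafs: dict[str, float] = field(default_factory=dict)
    baseline_prevalence: float = 0.3
    components: list[PenetranceComponent] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    age_mean: float = 45.0
    age_sd: float = 12.0
    seed: int = 0
    max_draw_factor: int = 500  # quota sampling gives up after this many x n draws

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need positive case and control quotas")
        if not self.genes:
            raise ValueError("at least one gene is required")
        if any(g.n_snps < 1 for g in self.genes):
            raise ValueError("every gene needs >= 1 SNP")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0,1)")
        all_snps = {s for g in self.genes for s in g.snp_ids()}
        for comp in self.components:
            missing = set(comp.snps) - all_snps
            if missing:
                raise ValueError(f"causal SNPs not in any declared gene: {missing}")
        bad = set(self.covariate_effects) - {"sex", "age"}
        if bad:
            raise ValueError(f"unknown covariate effects: {bad} (use 'sex'/'age')")

    def all_snp_ids(self) -> list[str]:
        return [s for g in self.genes for s in g.snp_ids()]


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    genes: pd.DataFrame  # BED frame: chrom, start, end, symbol
    covariates: pd.DataFrame
    truth: dict
    mafs: dict[str, float]

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out / "genotypes.tsv",
            "snps": out / "snps.tsv",
            "genes": out / "genes.bed",
            "covariates": out / "covariates.tsv",
            "truth": out / "truth.json",
        }
        data_io.write_genotypes(self.genotypes, paths["genotypes"])
        data_io.write_snp_positions(self.genotypes, paths["snps"])
        data_io.write_genes_bed(self.genes, paths["genes"])
        data_io.write_covariates(self.covariates, paths["covariates"])
        with open(paths["truth"], "wt", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _resolve_mafs(config: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    lo, hi = config.maf_range
    mafs = {}
    for sid in config.all_snp_ids():
        if sid in config.snp_mafs:
            mafs[sid] = float(config.snp_mafs[sid])
        else:
            mafs[sid] = float(rng.uniform(lo, hi))
    return mafs


def draw_cohort(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    mafs: dict[str, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Draw ``n`` unascertained samples: genotypes, covariates, phenotype.

    Genotypes are binomial(2, maf) per SNP (Hardy-Weinberg); the disease
    probability is expit(logit(baseline) + sex/age effects + penetrance
    offsets), where the age effect applies to standardized age.
    """
    if mafs is None:
        mafs = _resolve_mafs(config, rng)
    snp_ids = config.all_snp_ids()
    p = np.array([mafs[s] for s in snp_ids])
    calls = rng.binomial(2, p, size=(n, len(snp_ids))).astype(np.int8)

    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    cov = pd.DataFrame({"sex": sex, "age": age})

    eta = np.full(n, logit(config.baseline_prevalence))
    eta += config.covariate_effects.get("sex", 0.0) * sex
    eta += config.covariate_effects.get("age", 0.0) * (age - config.age_mean) / config.age_sd
    base_logit = logit(config.baseline_prevalence)
    col_of = {s: j for j, s in enumerate(snp_ids)}
    for comp in config.components:
        flat = logit(np.clip(comp.table, _CLIP, 1.0 - _CLIP)).ravel() - base_logit
        idx = np.zeros(n, dtype=np.int64)
        for s in comp.snps:
            idx = idx * 3 + calls[:, col_of[s]]
        eta += flat[idx]
    y = (rng.random(n) < expit(eta)).astype(np.int8)
    return calls, cov, y


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset meeting the case/control quotas.

    Fully reproducible from ``config.seed``; raises if the quotas cannot be
    met within ``max_draw_factor`` times the requested sample count (disease
    model prevalence effectively 0 or 1).
    """
    rng = np.random.default_rng(config.seed)
    mafs = _resolve_mafs(config, rng)
    need = config.n_cases + config.n_controls

    calls_parts, cov_parts, y_parts = [], [], []
    n_case = n_ctrl = drawn = 0
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if drawn >= config.max_draw_factor * need:
            raise RuntimeError(
                f"case/control quota not met after {drawn} draws "
                f"({n_case} cases, {n_ctrl} controls); disease model prevalence "
                "is too extreme for this design"
            )
        batch = max(1024, need)
        calls, cov, y = draw_cohort(config, batch, rng, mafs=mafs)
        calls_parts.append(calls)
        cov_parts.append(cov)
        y_parts.append(y)
        drawn += batch
        n_case += int((y == 1).sum())
        n_ctrl += int((y == 0).sum())

    calls = np.concatenate(calls_parts)
    cov = pd.concat(cov_parts, ignore_index=True)
    y = np.concatenate(y_parts)
    case_idx = np.flatnonzero(y == 1)[: config.n_cases]
    ctrl_idx = np.flatnonzero(y == 0)[: config.n_controls]
    keep = np.sort(np.concatenate([case_idx, ctrl_idx]))  # preserve draw order

    samples = [f"S{i + 1:06d}" for i in range(len(keep))]
    snp_ids = config.all_snp_ids()
    chrom = [g.chrom for g in config.genes for _ in range(g.n_snps)]
    pos = np.concatenate([g.snp_positions() for g in config.genes])
    genotypes = GenotypeMatrix(
        samples=samples,
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        calls=calls[keep],
        phenotype=y[keep],
    )
    covariates = cov.iloc[keep].reset_index(drop=True)
    covariates.index = pd.Index(samples, name="sample_id")
    genes = pd.DataFrame(
        {
            "chrom": [g.chrom for g in config.genes],
            "start": [g.start for g in config.genes],
            "end": [g.end for g in config.genes],
            "symbol": [g.symbol for g in config.genes],
        }
    )
    causal_snps = sorted({s for c in config.components for s in c.snps})
    snp_gene = {s: g.symbol for g in config.genes for s in g.snp_ids()}
    truth = {
        "causal_genes": sorted({snp_gene[s] for s in causal_snps}),
        "causal_snps": causal_snps,
        "components": [
            {"snps": list(c.snps), "penetrance": np.asarray(c.table).tolist()}
            for c in config.components
        ],
        "baseline_prevalence": config.baseline_prevalence,
        "covariate_effects": dict(config.covariate_effects),
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "seed": config.seed,
    }
    return SimulatedDataset(
        genotypes=genotypes, genes=genes, covariates=covariates, truth=truth, mafs=mafs
    )


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

def parity_xor_table(p_high: float, p_low: float) -> np.ndarray:
    """Two-locus penetrance: risk iff the minor-allele counts have odd parity.

    At MAF 0.5 both loci are marginally null (each genotype of one locus sees
    odd parity at the other with probability exactly 1/2) while the joint
    table carries the full signal — the canonical purely epistatic model.
    """
    g = np.arange(3)
    odd = (g[:, None] + g[None, :]) % 2 == 1
    return np.where(odd, p_high, p_low)


def additive_table(baseline: float, beta: float) -> np.ndarray:
    """Single-locus penetrance with an additive per-allele logit effect."""
    return expit(logit(baseline) + beta * np.arange(3)).astype(float)


def _null_genes(n: int, n_snps: int, prefix: str = "NULL") -> list[GeneSpec]:
    out = []
    for i in range(n):
        start = 1_000_000 + i * 400_000
        out.append(
            GeneSpec(
                symbol=f"{prefix}{i + 1:02d}",
                chrom=str(i % 4 + 1),
                start=start,
                end=start + 50_000,
                n_snps=n_snps,
            )
        )
    return out


#: scenario presets; effect sizes were calibrated once on pilot simulations
#: and are frozen — they are part of the study conditions, not tuning knobs.
_EPISTASIS_PENETRANCE = (0.80, 0.20)  # pure_epistasis_2gene, n = 2000
_MIXED_EPISTASIS_PENETRANCE = (0.75, 0.25)
_MIXED_MARGINAL_BETA = 0.40


def make_epistasis_fixture(
    scenario: str,
    seed: int = 0,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SimulatedDataset:
    """Build a named scenario preset and its machine-readable truth.

    Scenarios:

    * ``null`` — 20 genes x 5 SNPs, no genetic or covariate effects,
      500 cases / 500 controls, prevalence 0.3.
    * ``marginal_only`` — one additive-effect SNP in gene MARG1 plus null
      background genes.
    * ``pure_epistasis_2gene`` — genes EPIA and EPIB with one causal SNP
      each (MAF 0.5) under a parity/XOR penetrance with no marginal effects,
      plus 4 null genes; 1000 cases / 1000 controls.
    * ``mixed`` — a marginal gene, a purely epistatic pair, 9 null genes,
      and nonzero sex/age covariate effects.
    """
    if scenario == "null":
        cfg = SimulationConfig(
            n_cases=n_cases or 500,
            n_controls=n_controls or 500,
            genes=_null_genes(20, 5),
            maf_range=(0.1, 0.5),
            baseline_prevalence=0.3,
            seed=seed,
        )
    elif scenario == "marginal_only":
        genes = [GeneSpec("MARG1", "1", 100_000, 160_000, 3)] + _null_genes(5, 3)
        cfg = SimulationConfig(
            n_cases=n_cases or 500,
            n_controls=n_controls or 500,
            genes=genes,
            maf_range=(0.1, 0.5),
            snp_mafs={"MARG1_s1": 0.3},
            baseline_prevalence=0.3,
            components=[
                PenetranceComponent(("MARG1_s1",), additive_table(0.3, 0.5))
            ],
            seed=seed,
        )
    elif scenario == "pure_epistasis_2gene":
        p_hi, p_lo = _EPISTASIS_PENETRANCE
        genes = [
            GeneSpec("EPIA", "1", 100_000, 140_000, 1),
            GeneSpec("EPIB", "2", 100_000, 140_000, 1),
        ] + _null_genes(4, 3, prefix="BKG")
        cfg = SimulationConfig(
            n_cases=n_cases or 1000,
            n_controls=n_controls or 1000,
            genes=genes,
            maf_range=(0.1, 0.5),
            snp_mafs={"EPIA_s1": 0.5, "EPIB_s1": 0.5},
            baseline_prevalence=0.5,
            components=[
                PenetranceComponent(
                    ("EPIA_s1", "EPIB_s1"), parity_xor_table(p_hi, p_lo)
                )
            ],
            seed=seed,
        )
    elif scenario == "mixed":
        p_hi, p_lo = _MIXED_EPISTASIS_PENETRANCE
        genes = (
            [
                GeneSpec("MARG1", "1", 500_000, 560_000, 3),
                GeneSpec("EPIA", "2", 500_000, 540_000, 1),
                GeneSpec("EPIB", "3", 500_000, 540_000, 1),
            ]
            + _null_genes(9, 3)
        )
        cfg = SimulationConfig(
            n_cases=n_cases or 500,
            n_controls=n_controls or 500,
            genes=genes,
            maf_range=(0.1, 0.5),
            snp_mafs={"MARG1_s1": 0.3, "EPIA_s1": 0.5, "EPIB_s1": 0.5},
            baseline_prevalence=0.3,
            components=[
                PenetranceComponent(
                    ("MARG1_s1",), additive_table(0.3, _MIXED_MARGINAL_BETA)
                ),
                PenetranceComponent(
                    ("EPIA_s1", "EPIB_s1"), parity_xor_table(p_hi, p_lo)
                ),
            ],
            covariate_effects={"sex": 0.3, "age": 0.2},
            seed=seed,
        )
    else:
        raise ValueError(
            f"unknown scenario {scenario!r} (choose from null, marginal_only, "
            "pure_epistasis_2gene, mixed)"
        )
    ds = simulate(cfg)
    ds.truth["scenario"] = scenario
    return ds
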