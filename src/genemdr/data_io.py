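"""Genotype, annotation and covariate input/output, QC filters, and SNP-to-gene assignment.

Conventions
-----------
* Genotypes are coded as minor-allele counts in {0, 1, 2}; the minor allele is
  determined per SNP from the loaded file.  MDR treats genotypes as unordered
  categories, so only label consistency matters.
* SNP positions are 1-based base pairs; gene intervals come from BED files and
  are 0-based half-open.  All distance arithmetic converts to the 0-based
  half-open convention internally.
* Missing genotypes are tolerated only on the raw PLINK read path (coded -1
  internally) so that the missingness QC filter can be computed; every analysis
  entry point requires complete data.  The TSV dialect is strict: a missing
  symbol is a hard error pointing at the pre-imputation requirement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1  # internal missing-call code on the raw read path

#: genotype symbols that signal missing data in the strict TSV dialect
_TSV_MISSING_SYMBOLS = {"NA", "N/A", "", ".", "-9", "NAN"}


class GenotypeParseError(ValueError):
    """Malformed genotype input; message names the offending line/column."""


class EmptyMatrixError(ValueError):
    """Raised when an operation would leave no SNPs (or no samples)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele-count matrix with metadata and phenotype.

    Attributes
    ----------
    samples : list of sample identifiers (order preserved from file)
    snp_ids : list of SNP identifiers
    chrom, pos : per-SNP chromosome name and 1-based bp position
    calls : int8 array, shape (n_samples, n_snps), values in {0,1,2} (or -1
        for missing on the raw read path only)
    phenotype : int8 array, 1 = case, 0 = control
    """

    samples: list[str]
    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    calls: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, p = self.calls.shape
        if n != len(self.samples) or p != len(self.snp_ids):
            raise ValueError("calls shape does not match samples x snps")
        if len(self.chrom) != p or self.pos.shape != (p,):
            raise ValueError("SNP metadata length mismatch")
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length mismatch")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} (or -1 for missing)")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def column(self, snp_id: str) -> np.ndarray:
        """Genotype column for one SNP id."""
        return self.calls[:, self.snp_index(snp_id)]

    def columns(self, snp_ids: Sequence[str]) -> np.ndarray:
        """(n_samples, len(snp_ids)) genotype sub-matrix, in the given order."""
        idx = [self.snp_index(s) for s in snp_ids]
        return self.calls[:, idx]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snp_ids=[self.snp_ids[i] for i in keep],
            chrom=[self.chrom[i] for i in keep],
            pos=self.pos[keep],
            calls=self.calls[:, keep],
            phenotype=self.phenotype.copy(),
        )

    def require_complete(self) -> None:
        """Analysis entry points demand no missing calls and both classes."""
        if (self.calls == MISSING).any():
            raise ValueError(
                "genotype matrix contains missing calls; analysis requires "
                "complete data (impute upstream, then reload)"
            )
        if self.phenotype.min() == self.phenotype.max():
            raise ValueError("phenotype must contain both cases and controls")


@dataclass(frozen=True)
class QCThresholds:
    """SNP QC thresholds: a SNP is removed when control-HWE p < hwe_p_min,
    MAF < maf_min, or missingness > missing_max (all comparisons strict)."""

    maf_min: float = 0.05
    missing_max: float = 0.05
    hwe_p_min: float = 5.7e-7

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class GeneMap:
    """SNP -> gene assignment produced by :func:`assign_snps_to_genes`."""

    assignments: dict[str, str]
    genes: pd.DataFrame  # columns: symbol, chrom, start, end (BED half-open)
    window: int
    unassigned: list[str] = field(default_factory=list)

    def members(self) -> dict[str, list[str]]:
        """Gene symbol -> ordered list of member SNP ids."""
        out: dict[str, list[str]] = {}
        for snp, gene in self.assignments.items():
            out.setdefault(gene, []).append(snp)
        return out


class HWEResult(NamedTuple):
    p_value: float
    statistic: float
    monomorphic: bool


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "tsv", map_path=None) -> GenotypeMatrix:
    """Read a genotype file.

    Parameters
    ----------
    path : genotype file (TSV dialect, or PLINK text PED)
    format : "tsv" or "plink-text"
    map_path : PLINK MAP file; defaults to ``path`` with a .map suffix
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink-text":
        return _read_plink_text(path, map_path)
    raise ValueError(f"unknown genotype format {format!r} (use 'tsv' or 'plink-text')")


def _read_tsv(path) -> GenotypeMatrix:
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0] != "sample_id" or cols[1] != "phenotype":
            raise GenotypeParseError(
                f"{path}: header must start with 'sample_id<TAB>phenotype<TAB><snp ids>'"
            )
        snp_ids = cols[2:]
        seen: set[str] = set()
        for j, sid in enumerate(snp_ids):
            if sid in seen:
                raise GenotypeParseError(
                    f"{path}: duplicate SNP id {sid!r} at header column {j + 3}"
                )
            seen.add(sid)
        samples: list[str] = []
        phen: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            samples.append(fields[0])
            if fields[1] not in ("0", "1"):
                raise GenotypeParseError(
                    f"{path}:{lineno}: phenotype must be 0 (control) or 1 (case), "
                    f"got {fields[1]!r}"
                )
            phen.append(int(fields[1]))
            row: list[int] = []
            for j, tok in enumerate(fields[2:], start=3):
                if tok.upper() in _TSV_MISSING_SYMBOLS:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: column {j}: missing genotype symbol "
                        f"{tok!r}; the TSV dialect requires complete data — impute "
                        "missing genotypes upstream before loading"
                    )
                if tok not in ("0", "1", "2"):
                    raise GenotypeParseError(
                        f"{path}:{lineno}: column {j}: genotype must be 0/1/2, got {tok!r}"
                    )
                row.append(int(tok))
            rows.append(row)
    if not rows:
        raise GenotypeParseError(f"{path}: no sample rows")
    return GenotypeMatrix(
        samples=samples,
        snp_ids=snp_ids,
        chrom=["" for _ in snp_ids],
        pos=np.zeros(len(snp_ids), dtype=np.int64),
        calls=np.array(rows, dtype=np.int8),
        phenotype=np.array(phen, dtype=np.int8),
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect; inverse of the TSV reader for calls,
    phenotype and SNP/sample order (positions live in the MAP/BED files)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(g.snp_ids) + "\n")
        for i, sid in enumerate(g.samples):
            row = "\t".join(str(int(c)) for c in g.calls[i])
            fh.write(f"{sid}\t{int(g.phenotype[i])}\t{row}\n")


def _read_map(map_path) -> tuple[list[str], list[str], list[int]]:
    chroms: list[str] = []
    ids: list[str] = []
    pos: list[int] = []
    seen: set[str] = set()
    with open(map_path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split()
            if len(f) == 4:
                c, sid, _cm, bp = f
            elif len(f) == 3:
                c, sid, bp = f
            else:
                raise GenotypeParseError(
                    f"{map_path}:{lineno}: MAP lines need 3 or 4 fields, got {len(f)}"
                )
            if sid in seen:
                raise GenotypeParseError(f"{map_path}:{lineno}: duplicate SNP id {sid!r}")
            seen.add(sid)
            chroms.append(c)
            ids.append(sid)
            pos.append(int(bp))
    return chroms, ids, pos


def _read_plink_text(ped_path, map_path=None) -> GenotypeMatrix:
    if map_path is None:
        p = str(ped_path)
        map_path = (p[:-4] if p.endswith(".ped") else p) + ".map"
    chroms, snp_ids, pos = _read_map(map_path)
    n_snp = len(snp_ids)

    samples: list[str] = []
    phen: list[int] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split()
            if len(f) != 6 + 2 * n_snp:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snp} fields "
                    f"(6 + 2 x {n_snp} SNPs), got {len(f)}"
                )
            fam, ind = f[0], f[1]
            samples.append(f"{fam}:{ind}" if fam not in ("0", "") else ind)
            if f[5] == "2":
                phen.append(1)
            elif f[5] == "1":
                phen.append(0)
            else:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: phenotype must be 1 (control) or 2 (case), "
                    f"got {f[5]!r}"
                )
            row = []
            for j in range(n_snp):
                a, b = f[6 + 2 * j], f[7 + 2 * j]
                row.append((a, b))
            allele_rows.append(row)
    if not allele_rows:
        raise GenotypeParseError(f"{ped_path}: no sample rows")

    # per-SNP allele tally -> minor allele; ties to the lexicographically smaller
    calls = np.empty((len(samples), n_snp), dtype=np.int8)
    for j in range(n_snp):
        tally: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    tally[a] = tally.get(a, 0) + 1
        alleles = sorted(tally)
        if len(alleles) > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP {snp_ids[j]!r} has >2 alleles: {alleles}"
            )
        if not alleles:  # all missing
            minor = None
        elif len(alleles) == 1:
            minor = None  # monomorphic: count of the (absent) alternative = 0
        else:
            a1, a2 = alleles
            minor = a1 if tally[a1] <= tally[a2] else a2
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0" or b == "0":
                if (a == "0") != (b == "0"):
                    raise GenotypeParseError(
                        f"{ped_path}: sample {samples[i]} SNP {snp_ids[j]!r}: "
                        f"half-missing genotype {a} {b}"
                    )
                calls[i, j] = MISSING
            elif minor is None:
                calls[i, j] = 0
            else:
                calls[i, j] = int(a == minor) + int(b == minor)

    return GenotypeMatrix(
        samples=samples,
        snp_ids=snp_ids,
        chrom=chroms,
        pos=np.array(pos, dtype=np.int64),
        calls=calls,
        phenotype=np.array(phen, dtype=np.int8),
    )


def read_snp_positions(path) -> pd.DataFrame:
    """Read a SNP-position sidecar TSV (snp_id, chrom, pos; pos 1-based).

    The TSV genotype dialect carries calls only; positions travel in this
    sidecar (the PLINK path gets them from the MAP file instead).
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str, "pos": np.int64}
    )
    required = {"snp_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: SNP position file needs columns {sorted(required)}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"{path}: duplicate SNP id {dup!r}")
    return df


def apply_snp_positions(g: GenotypeMatrix, positions: pd.DataFrame) -> GenotypeMatrix:
    """Attach sidecar chromosome/position metadata to a loaded matrix."""
    table = positions.set_index("snp_id")
    missing = set(g.snp_ids) - set(table.index)
    if missing:
        raise ValueError(f"positions missing for SNPs {sorted(missing)[:5]}")
    g.chrom = [str(table.loc[s, "chrom"]) for s in g.snp_ids]
    g.pos = table.loc[list(g.snp_ids), "pos"].to_numpy(dtype=np.int64)
    return g


def write_snp_positions(g: GenotypeMatrix, path) -> None:
    pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos}).to_csv(
        path, sep="\t", index=False
    )


def read_genes_bed(path) -> pd.DataFrame:
    """Read a BED3+1 gene file (chrom, start, end, symbol; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "symbol": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"], "symbol"].iloc[0]
        raise ValueError(f"{path}: gene {bad!r} has end <= start")
    return df


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "symbol"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_covariates(path, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a covariate TSV (`sample_id` + numeric columns).

    If ``samples`` is given the table is re-ordered to match it; missing
    samples or missing values are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: covariate file needs a 'sample_id' column")
    df = df.set_index("sample_id")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing values in covariate column {col!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: covariate column {col!r} is not numeric")
    if samples is not None:
        missing = set(samples) - set(df.index)
        if missing:
            raise ValueError(
                f"{path}: covariates missing for samples {sorted(missing)[:5]}"
            )
        df = df.loc[list(samples)]
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts: tuple[int, int, int]) -> HWEResult:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa) = counts of calls 0, 1, 2.
    Monomorphic sites (one allele absent) return p = 1 with a flag.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("total genotype count must be positive")
    q = (n1 + 2 * n2) / (2 * n)  # minor(a)-allele frequency
    if q == 0.0 or q == 1.0:
        return HWEResult(p_value=1.0, statistic=0.0, monomorphic=True)
    p = 1.0 - q
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n0, n1, n2], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(
        p_value=float(stats.chi2.sf(statistic, df=1)),
        statistic=statistic,
        monomorphic=False,
    )


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    maf_in: str = "all",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply SNP QC filters; returns the filtered matrix and a report.

    Filters (a SNP is removed if ANY applies):

    * control-only HWE chi-square p-value < ``hwe_p_min``
    * minor allele frequency < ``maf_min`` (over ``maf_in`` samples:
      "all", "controls" or "cases"; default all)
    * missing-call proportion > ``missing_max``

    Any SNP with residual missing calls after filtering is also dropped,
    with a warning, so the surviving matrix is complete.  The report has
    one row per input SNP: snp_id, maf, missingness, hwe_p_controls,
    removed, reasons.
    """
    if g.phenotype.min() == g.phenotype.max():
        raise ValueError("apply_qc requires both cases and controls (HWE uses controls)")
    if maf_in not in ("all", "controls", "cases"):
        raise ValueError("maf_in must be 'all', 'controls' or 'cases'")

    calls = g.calls
    obs = calls != MISSING
    if maf_in == "all":
        sel = np.ones(g.n_samples, dtype=bool)
    elif maf_in == "controls":
        sel = g.phenotype == 0
    else:
        sel = g.phenotype == 1
    sub = calls[sel]
    sub_obs = sub != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            sub_obs.sum(axis=0) > 0,
            np.where(sub == MISSING, 0, sub).sum(axis=0) / (2.0 * np.maximum(sub_obs.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(freq, 1.0 - freq)
    missingness = 1.0 - obs.sum(axis=0) / g.n_samples

    ctrl = calls[g.phenotype == 0]
    hwe_p = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = ctrl[:, j]
        col = col[col != MISSING]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe_p[j] = hwe_test(counts).p_value if sum(counts) > 0 else 1.0

    reasons: list[str] = []
    removed = np.zeros(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        why = []
        if hwe_p[j] < thresholds.hwe_p_min:
            why.append(f"HWE p < {thresholds.hwe_p_min:g}")
        if np.isnan(maf[j]) or maf[j] < thresholds.maf_min:
            why.append(f"MAF < {thresholds.maf_min:g}")
        if missingness[j] > thresholds.missing_max:
            why.append(f"missingness > {thresholds.missing_max:g}")
        if not why and (calls[:, j] == MISSING).any():
            why.append("residual missing calls")
            warnings.warn(
                f"SNP {g.snp_ids[j]} passed QC thresholds but retains missing "
                "calls and was dropped (complete data required)",
                stacklevel=2,
            )
        removed[j] = bool(why)
        reasons.append(";".join(why))

    report = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "maf": maf,
            "missingness": missingness,
            "hwe_p_controls": hwe_p,
            "removed": removed,
            "reasons": reasons,
        }
    )
    if removed.all():
        raise EmptyMatrixError(
            "QC removed every SNP; relax QCThresholds or check input coding"
        )
    return g.subset_snps(~removed), report


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# SNP -> gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    g: GenotypeMatrix,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> GeneMap:
    """Assign each SNP to its nearest gene within ``window`` bp.

    Distance is 0 for a SNP inside a gene's (half-open) interval, otherwise
    the gap to the nearer interval boundary.  Only genes on the SNP's
    chromosome are considered.  SNPs with no gene in range are recorded as
    ``unassigned``; exact distance ties go to the lexicographically smallest
    gene symbol.  SNP chromosomes absent from the gene file trigger a warning
    and those SNPs are unassigned.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    gene_chroms = set(genes["chrom"])
    snp_chroms = set(g.chrom)
    orphan_chroms = {c for c in snp_chroms if c and c not in gene_chroms}
    if orphan_chroms:
        warnings.warn(
            f"SNP chromosomes {sorted(orphan_chroms)} not present in gene file; "
            "those SNPs will be unassigned",
            stacklevel=2,
        )

    by_chrom: dict[str, pd.DataFrame] = {
        c: sub.sort_values("symbol", kind="stable").reset_index(drop=True)
        for c, sub in genes.groupby("chrom")
    }
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for j, sid in enumerate(g.snp_ids):
        chrom = g.chrom[j]
        sub = by_chrom.get(chrom)
        if sub is None:
            unassigned.append(sid)
            continue
        z = int(g.pos[j]) - 1  # 0-based point
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        dist = np.maximum.reduce([starts - z, z - (ends - 1), np.zeros(len(sub), dtype=np.int64)])
        best = int(np.argmin(dist))  # ties -> first = lexicographically smallest symbol
        if dist[best] <= window:
            assignments[sid] = str(sub["symbol"].iloc[best])
        else:
            unassigned.append(sid)
    logger.info(
        "assigned %d/%d SNPs to %d genes (%d unassigned, window %d bp)",
        len(assignments), g.n_snps, len(set(assignments.values())),
        len(unassigned), window,
    )
    return GeneMap(assignments=assignments, genes=genes, window=window, unassigned=unassigned)
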