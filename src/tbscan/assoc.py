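"""Genotype-phenotype association layer.

Accessions (or cross progeny) are split at each biallelic site into the two
homozygote classes, heterozygotes and missing calls set aside, and tiller
numbers are compared with a pooled-variance Student's t-test at each
phenotyping timepoint.  Conditional association re-runs the comparison inside
one homozygote class of a second, linked site to separate the effects of two
variants travelling together.  The module also provides the chi-square
goodness-of-fit test for segregation distortion in biparental populations and
the Pearson correlation test used for expression-phenotype relationships.

Effect size is reported as the absolute difference of group means in trait
units (tillers); "mean value difference" as the percent difference relative
to the lower group mean; "variance" as the pooled within-group variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    EmptyInputError,
    InvalidParameterError,
)
from .genotypes import GenotypeMatrix

log = logging.getLogger("tbscan")

_P_FLOOR = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

@dataclass
class GroupSplit:
    """Accessions split into the two homozygote classes at one site."""

    idx_low: np.ndarray      # indices with dosage 0 (reference-like homozygote)
    idx_high: np.ndarray     # indices with dosage 2
    n_het: int
    n_missing: int
    rare: bool               # minor homozygote class below the rare cutoff
    testable: bool           # both classes have >= 2 members and not rare


def homozygote_groups(calls, rare_cutoff: float = 0.05) -> GroupSplit:
    """Split dosage calls {0,1,2,-1} into homozygote groups for testing.

    Heterozygotes and missing calls are excluded (counts recorded).  Sites
    whose minor homozygote class is rarer than ``rare_cutoff`` among the
    homozygotes are flagged rare and marked untestable, as are sites leaving
    fewer than two accessions in either group.
    """
    calls = np.asarray(calls)
    idx0 = np.flatnonzero(calls == 0)
    idx2 = np.flatnonzero(calls == 2)
    n_het = int((calls == 1).sum())
    n_missing = int((calls == -1).sum())
    n_hom = len(idx0) + len(idx2)
    rare = bool(n_hom > 0 and min(len(idx0), len(idx2)) / n_hom < rare_cutoff)
    testable = len(idx0) >= 2 and len(idx2) >= 2 and not rare
    return GroupSplit(idx0, idx2, n_het, n_missing, rare, testable)


# ---------------------------------------------------------------------------
# the two-group Student's t-test
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    site_id: str
    timepoint: int | None
    group_labels: tuple[str, str]
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    p: float
    df: int
    effect_size: float              # |mean1 - mean2| in trait units
    mean_value_difference: float    # percent, relative to the lower mean
    pooled_variance: float
    direction: str                  # which group has the larger mean
    condition: str = ""
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["group_labels"] = "/".join(self.group_labels)
        d["flags"] = ";".join(self.flags)
        return d


def t_test_association(
    group1,
    group2,
    labels: tuple[str, str] = ("group1", "group2"),
    site_id: str = "",
    timepoint: int | None = None,
    condition: str = "",
) -> AssociationResult:
    """Pooled-variance two-sample Student's t-test between homozygote groups.

    Two-sided P; the effect size is the absolute mean difference and the mean
    value difference is 100*(m_high - m_low)/m_low.  Degenerate variance:
    equal means give t = 0, P = 1; unequal means with zero variance report a
    machine-floor P with a flag.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("each group needs at least two observations")
    m1, m2 = float(x1.mean()), float(x2.mean())
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    flags: list[str] = []
    if sp2 == 0.0:
        if m1 == m2:
            t, p = 0.0, 1.0
        else:
            t = np.inf if m1 > m2 else -np.inf
            p = _P_FLOOR
            flags.append("zero_variance")
    else:
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    m_low, m_high = min(m1, m2), max(m1, m2)
    if m_low != 0:
        mvd = 100.0 * (m_high - m_low) / m_low
    else:
        mvd = float("nan")
        flags.append("zero_low_mean")
    direction = labels[0] if m1 > m2 else labels[1] if m2 > m1 else "tie"
    return AssociationResult(
        site_id=site_id, timepoint=timepoint, group_labels=labels,
        n1=n1, n2=n2, mean1=m1, mean2=m2, t=float(t), p=float(p), df=df,
        effect_size=abs(m1 - m2), mean_value_difference=mvd,
        pooled_variance=float(sp2), direction=direction,
        condition=condition, flags=flags,
    )


def conditional_association(
    calls_site,
    calls_condition,
    required_dosage: int,
    phenotype_values,
    labels: tuple[str, str] = ("group1", "group2"),
    site_id: str = "",
    timepoint: int | None = None,
    condition_label: str = "",
    rare_cutoff: float = 0.05,
) -> AssociationResult | None:
    """Association at one site within a fixed homozygote class of another.

    Subsets to individuals whose conditioning-site dosage equals
    ``required_dosage`` (0 or 2), then splits the focal site into homozygote
    groups and runs the t-test.  Returns None (with a log record) when the
    subset leaves fewer than two per group.
    """
    if required_dosage not in (0, 2):
        raise InvalidParameterError("conditioning genotype must be a homozygote dosage (0 or 2)")
    calls_site = np.asarray(calls_site)
    calls_condition = np.asarray(calls_condition)
    values = np.asarray(phenotype_values, dtype=float)
    keep = calls_condition == required_dosage
    if not keep.any():
        log.warning("conditional_association: conditioning genotype absent (%s)", condition_label)
        return None
    split = homozygote_groups(calls_site[keep], rare_cutoff=rare_cutoff)
    sub_values = values[keep]
    if not split.testable:
        log.warning("conditional_association: untestable after conditioning (%s): "
                    "n=(%d,%d)%s", condition_label, len(split.idx_low),
                    len(split.idx_high), " rare" if split.rare else "")
        return None
    log.info("conditional_association %s: subset %d -> groups (%d, %d)",
             condition_label, int(keep.sum()), len(split.idx_low), len(split.idx_high))
    return t_test_association(
        sub_values[split.idx_low], sub_values[split.idx_high],
        labels=labels, site_id=site_id, timepoint=timepoint,
        condition=condition_label,
    )


# ---------------------------------------------------------------------------
# segregation distortion
# ---------------------------------------------------------------------------

@dataclass
class SegregationResult:
    locus: str
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p: float


def segregation_test(observed, expected_ratio, locus: str = "") -> SegregationResult:
    """Pearson chi-square goodness-of-fit of genotype class counts to a ratio.

    The expectation is the ratio scaled to the observed total; df is the
    number of classes minus one.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2 or obs.size != ratio.size:
        raise InvalidParameterError("need >= 2 classes and one ratio term per class")
    if np.any(obs < 0):
        raise InvalidParameterError("counts must be non-negative")
    if np.any(ratio <= 0):
        raise InvalidParameterError("expected ratio terms must be positive")
    total = obs.sum()
    if total == 0:
        raise EmptyInputError("total count is zero")
    expected = ratio / ratio.sum() * total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    return SegregationResult(
        locus=locus,
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(float(x) for x in ratio),
        expected=tuple(float(x) for x in expected),
        chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
    )


# ---------------------------------------------------------------------------
# Pearson correlation (expression vs phenotype)
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    flags: list[str] = field(default_factory=list)


def pearson_correlation_test(x, y) -> CorrelationResult:
    """Pearson r with a two-sided P from the t transform r*sqrt((n-2)/(1-r^2)).

    Pairs with a missing member are dropped first; zero variance in either
    vector makes the correlation undefined (NaN, flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InvalidParameterError("need at least 3 complete pairs")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return CorrelationResult(float("nan"), float("nan"), n, ["zero_variance"])
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, _P_FLOOR, n, ["perfect_correlation"])
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n)


# ---------------------------------------------------------------------------
# full association table
# ---------------------------------------------------------------------------

@dataclass
class ConditionSpec:
    """One conditioning cell: test ``site`` within a homozygote of ``condition_site``."""

    site: str
    condition_site: str | None = None
    required_dosage: int | None = None

    def label(self) -> str:
        if self.condition_site is None:
            return ""
        return f"{self.condition_site}={self.required_dosage}"


def association_table(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    sites: list[str] | None = None,
    timepoints: list[int] | None = None,
    conditions: list[ConditionSpec] | None = None,
    rare_cutoff: float = 0.05,
    trait: str | None = None,
) -> pd.DataFrame:
    """One association row per (site, timepoint, conditioning cell).

    ``phenotypes`` is the long table (line_id, timepoint, trait, value);
    ``genotypes`` a lines x sites dosage table.  Identifier mismatches raise
    an error listing the orphan lines.  Untestable cells are reported with
    missing statistics and an explanatory flag.
    """
    pheno = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    if pheno.empty:
        raise EmptyInputError("no phenotype rows (after trait filter)")
    pheno_lines = set(pheno["line_id"])
    geno_lines = set(map(str, genotypes.index))
    pheno_lines = set(map(str, pheno_lines))
    orphans = sorted(pheno_lines ^ geno_lines)
    if orphans:
        common = pheno_lines & geno_lines
        if not common:
            raise DataError(f"no shared line identifiers; orphans include {orphans[:10]}")
        log.warning("association_table: %d orphan line ids dropped (e.g. %s)",
                    len(orphans), orphans[:5])
    sites = sites if sites is not None else list(genotypes.columns)
    timepoints = timepoints if timepoints is not None else sorted(pheno["timepoint"].unique())
    specs = conditions if conditions is not None else [ConditionSpec(s) for s in sites]

    geno = genotypes.copy()
    geno.index = geno.index.map(str)
    wide = pheno.assign(line_id=pheno["line_id"].astype(str)).pivot_table(
        index="line_id", columns="timepoint", values="value", aggfunc="mean")
    lines = [l for l in geno.index if l in wide.index]
    geno = geno.loc[lines]
    wide = wide.loc[lines]

    rows = []
    for spec in specs:
        if spec.site not in geno.columns:
            raise DataError(f"site {spec.site!r} absent from the genotype table")
        calls = geno[spec.site].to_numpy()
        for tp in timepoints:
            if tp not in wide.columns:
                raise DataError(f"timepoint {tp} absent from the phenotype table")
            values = wide[tp].to_numpy(dtype=float)
            ok = ~np.isnan(values)
            labels = (f"{spec.site}:low", f"{spec.site}:high")
            if spec.condition_site is None:
                split = homozygote_groups(calls[ok], rare_cutoff=rare_cutoff)
                if split.testable:
                    res = t_test_association(
                        values[ok][split.idx_low], values[ok][split.idx_high],
                        labels=labels, site_id=spec.site, timepoint=int(tp))
                else:
                    res = _untestable_row(spec, tp, labels, split)
            else:
                if spec.condition_site not in geno.columns:
                    raise DataError(f"conditioning site {spec.condition_site!r} absent")
                res = conditional_association(
                    calls[ok], geno[spec.condition_site].to_numpy()[ok],
                    spec.required_dosage, values[ok],
                    labels=labels, site_id=spec.site, timepoint=int(tp),
                    condition_label=spec.label(), rare_cutoff=rare_cutoff)
                if res is None:
                    res = _untestable_row(spec, tp, labels, None)
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def _untestable_row(spec: ConditionSpec, tp, labels, split: GroupSplit | None) -> AssociationResult:
    flags = ["untestable"]
    if split is not None and split.rare:
        flags.append("rare")
    n1 = len(split.idx_low) if split is not None else 0
    n2 = len(split.idx_high) if split is not None else 0
    return AssociationResult(
        site_id=spec.site, timepoint=int(tp), group_labels=labels,
        n1=n1, n2=n2, mean1=float("nan"), mean2=float("nan"),
        t=float("nan"), p=float("nan"), df=0,
        effect_size=float("nan"), mean_value_difference=float("nan"),
        pooled_variance=float("nan"), direction="", condition=spec.label(),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# panel ingestion (published source-data layout)
# ---------------------------------------------------------------------------

def load_panel_tables(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a panel table into (phenotypes, genotypes) for AssociationStudy.

    Expects a TSV (or .xlsx first sheet) with one row per line: a ``line_id``
    column, one dosage column per variant site (values 0/1/2, or two-letter
    genotype strings like ``TT``/``TC``/``CC``), and one ``tiller_<DAG>``
    column per phenotyping timepoint.  This is the layout used for published
    per-accession source data once exported to a flat table.
    """
    p = str(path)
    if p.endswith(".xlsx") or p.endswith(".xls"):
        df = pd.read_excel(p)
    else:
        df = pd.read_csv(p, sep="\t", comment="#")
    if "line_id" not in df.columns:
        raise DataError(f"{path}: panel table needs a line_id column")
    tiller_cols = [c for c in df.columns if str(c).startswith("tiller_")]
    if not tiller_cols:
        raise DataError(f"{path}: no tiller_<DAG> phenotype columns found")
    site_cols = [c for c in df.columns if c != "line_id" and c not in tiller_cols]

    geno = df[["line_id"] + site_cols].set_index("line_id").copy()
    for c in site_cols:
        col = geno[c]
        if col.dtype == object:
            geno[c] = _genotype_strings_to_dosage(col)
        else:
            geno[c] = col.fillna(-1).astype(int)

    long_rows = []
    for c in tiller_cols:
        tp = int(str(c).split("_", 1)[1])
        long_rows.append(pd.DataFrame({
            "line_id": df["line_id"],
            "timepoint": tp,
            "trait": "tiller_number",
            "value": pd.to_numeric(df[c], errors="coerce"),
        }))
    pheno = pd.concat(long_rows, ignore_index=True).dropna(subset=["value"])
    return pheno, geno


def _genotype_strings_to_dosage(col: pd.Series) -> pd.Series:
    """Map two-letter genotype strings in one column to dosages.

    The column's alleles are collected and sorted; dosage counts copies of the
    alphabetically later allele (so e.g. TT=2, TC=1, CC=0 for a C/T site).
    Unparsable entries become missing (-1).
    """
    cleaned = col.map(lambda g: str(g).strip().upper() if pd.notna(g) else "")
    alleles = sorted({a for s in cleaned if len(s) == 2 for a in s} - {"N", "-", "."})
    if len(alleles) > 2:
        raise DataError(f"more than two alleles in genotype column: {alleles}")

    def dosage(s: str) -> int:
        if len(s) != 2 or any(a not in alleles for a in s):
            return -1
        return sum(a == alleles[-1] for a in s)

    return cleaned.map(dosage).astype(int)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class AssociationStudy:
    """Genotype-phenotype association study over a panel or cross.

    Parameters
    ----------
    phenotypes : DataFrame
        Long table (line_id, timepoint, trait, value).
    genotypes : DataFrame or GenotypeMatrix
        Lines x sites dosage table ({0,1,2,-1}); a GenotypeMatrix is
        transposed with sites named "chrom:pos".
    """

    def __init__(self, phenotypes: pd.DataFrame, genotypes) -> None:
        if isinstance(genotypes, GenotypeMatrix):
            genotypes = genotypes.to_frame()
        self.phenotypes = phenotypes
        self.genotypes = genotypes

    @classmethod
    def from_files(cls, phenotype_path, genotype_path) -> "AssociationStudy":
        from .io import read_phenotypes

        pheno = read_phenotypes(phenotype_path)
        geno = pd.read_csv(genotype_path, sep="\t", comment="#", index_col=0)
        return cls(pheno, geno)

    def fit(
        self,
        sites: list[str] | None = None,
        timepoints: list[int] | None = None,
        conditions: list[ConditionSpec] | None = None,
        rare_cutoff: float = 0.05,
        trait: str | None = None,
    ) -> "AssociationResults":
        table = association_table(self.phenotypes, self.genotypes, sites,
                                  timepoints, conditions, rare_cutoff, trait)
        return AssociationResults(model=self, table=table)

    def segregation(self, site: str, expected_ratio=(1, 2, 1)) -> SegregationResult:
        """Distortion test of the observed genotype classes at one site."""
        calls = self.genotypes[site].to_numpy()
        counts = [(calls == 0).sum(), (calls == 1).sum(), (calls == 2).sum()]
        if len(expected_ratio) == 2:      # homozygote classes only
            counts = [counts[0], counts[2]]
        return segregation_test(counts, expected_ratio, locus=site)


@dataclass
class AssociationResults:
    model: AssociationStudy
    table: pd.DataFrame

    def summary(self) -> str:
        cols = ["site_id", "timepoint", "condition", "n1", "n2", "p",
                "effect_size", "mean_value_difference", "pooled_variance",
                "direction", "flags"]
        show = self.table[[c for c in cols if c in self.table.columns]]
        return ("Association summary\n-------------------\n"
                + show.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
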