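"""Readers and writers for the formats the pipeline touches.

No statistics live here.  Coordinate contract: in-memory, VCF and GFF use
1-based inclusive coordinates; BED-style window output is 0-based half-open.
All writers emit a '#'-prefixed header line with column names and the tool
version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError, EmptyInputError
from .genotypes import GenotypeMatrix

log = logging.getLogger("tbscan")

PHENOTYPE_COLUMNS = ["line_id", "timepoint", "trait", "value"]


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """A gene's merged coding intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if s > e:
                raise DataError(f"gene {self.gene_id}: interval start {s} > end {e}")
        self.intervals = merge_intervals(self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def site_index(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Indices of matrix sites falling in any coding interval."""
        parts = [matrix.site_index_in(s, e) for s, e in self.intervals]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


# coordinate converters (property-tested inverse bijections)

def to_bed_interval(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    return start_1based - 1, end_1based_inclusive


def from_bed_interval(start_0based: int, end_exclusive: int) -> tuple[int, int]:
    return start_0based + 1, end_exclusive


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_pop_map(path) -> dict[str, str]:
    """Sample-to-population sidecar TSV (sample <tab> population)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{ln}: expected 'sample<TAB>population'")
            out[parts[0]] = parts[1]
    if not out:
        raise EmptyInputError(f"{path}: no sample-population rows")
    return out


def read_vcf(path, sample_pop_map: dict[str, str] | str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (counts logged).  Missing GT
    becomes a missing call.  An AA INFO tag matching REF or ALT sets the
    ancestral state.  Files must contain a single chromosome.
    """
    from cyvcf2 import VCF

    if isinstance(sample_pop_map, (str, bytes)) or hasattr(sample_pop_map, "__fspath__"):
        sample_pop_map = read_pop_map(sample_pop_map)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    orphans = [s for s in samples if s not in sample_pop_map]
    if orphans:
        raise ConfigurationError(f"samples absent from population map: {orphans}")

    positions, ref, alt, ancestral, calls = [], [], [], [], []
    skipped = {"multiallelic": 0, "non_snp": 0}
    chrom = None
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ConfigurationError("multi-chromosome VCFs are not supported; split by chromosome")
        positions.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        if aa == v.REF:
            ancestral.append("ref")
        elif aa == v.ALT[0]:
            ancestral.append("alt")
        else:
            ancestral.append("unknown")
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = -1
        calls.append(gt)

    if any(skipped.values()):
        log.info("read_vcf skipped records: %s", skipped)
    if not positions:
        raise EmptyInputError(f"{path}: no parsable biallelic SNP records")

    matrix = GenotypeMatrix(
        chrom=chrom,
        positions=np.array(positions),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ancestral=np.array(ancestral, dtype=object),
        calls=np.stack(calls),
        samples=samples,
        sample_pop=np.array([sample_pop_map[s] for s in samples], dtype=object),
    )
    matrix.skipped_records = dict(skipped)  # type: ignore[attr-defined]
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only; AA in INFO where known)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=tbscan-{__version__}\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            if matrix.ancestral[i] == "ref":
                info = f"AA={matrix.ref[i]}"
            elif matrix.ancestral[i] == "alt":
                info = f"AA={matrix.alt[i]}"
            else:
                info = "."
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[i])
            fh.write(f"{matrix.chrom}\t{matrix.positions[i]}\t.\t{matrix.ref[i]}\t"
                     f"{matrix.alt[i]}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_pop_map(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample\tpopulation\ttbscan={__version__}\n")
        for s, p in zip(matrix.samples, matrix.sample_pop):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV (line_id, timepoint, trait, value).

    Duplicate (line_id, timepoint, trait) rows are averaged with a warning;
    malformed rows raise a located error.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty phenotype file") from exc
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing phenotype columns {missing}")
    df = df[PHENOTYPE_COLUMNS].copy()
    for col, kind in (("timepoint", int), ("value", float)):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"{path}: malformed {col} value {df[col].iloc[first]!r} "
                            f"in data row {first + 1}")
        df[col] = converted.astype(kind if kind is int else float)
    dup = df.duplicated(subset=["line_id", "timepoint", "trait"])
    if dup.any():
        log.warning("read_phenotypes: averaged %d duplicated (line,timepoint,trait) rows",
                    int(dup.sum()))
        df = df.groupby(["line_id", "timepoint", "trait"], as_index=False)["value"].mean()
    if df.empty:
        raise EmptyInputError(f"{path}: no phenotype rows")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#tbscan={__version__}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes (GFF3 or BED)
# ---------------------------------------------------------------------------

def read_genes(path) -> list[GeneAnnotation]:
    """Read gene coding intervals from GFF3 (CDS grouped by gene) or BED4+.

    GFF3 CDS features are grouped by their Parent attribute (falling back to
    gene_id/ID); BED rows are 0-based half-open with the gene ID in column 4.
    """
    with open(path) as fh:
        first_data = None
        for line in fh:
            if line.startswith("##gff-version"):
                return _read_genes_gff(path)
            if line.strip() and not line.startswith("#"):
                first_data = line
                break
    if first_data is None:
        raise EmptyInputError(f"{path}: no gene records")
    if len(first_data.rstrip("\n").split("\t")) >= 9:
        return _read_genes_gff(path)
    return _read_genes_bed(path)


def _read_genes_gff(path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    groups: dict[str, GeneAnnotation] = {}
    for cds in db.features_of_type("CDS"):
        attrs = cds.attributes
        if "Parent" in attrs:
            gid = attrs["Parent"][0]
        elif "gene_id" in attrs:
            gid = attrs["gene_id"][0]
        else:
            gid = attrs.get("ID", [cds.id])[0]
        if gid in groups:
            g = groups[gid]
            if g.chrom != cds.seqid:
                raise DataError(f"gene {gid}: CDS on multiple chromosomes")
            groups[gid] = GeneAnnotation(gid, g.chrom, g.intervals + [(cds.start, cds.end)], g.strand)
        else:
            groups[gid] = GeneAnnotation(gid, cds.seqid, [(cds.start, cds.end)], cds.strand or "+")
    if not groups:
        raise EmptyInputError(f"{path}: no CDS features")
    return list(groups.values())


def _read_genes_bed(path) -> list[GeneAnnotation]:
    groups: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{ln}: BED gene rows need chrom,start,end,gene_id")
            chrom, gid = parts[0], parts[3]
            try:
                start, end = from_bed_interval(int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: malformed BED coordinates") from exc
            strand = parts[5] if len(parts) > 5 else "+"
            if gid in groups:
                g = groups[gid]
                groups[gid] = GeneAnnotation(gid, g.chrom, g.intervals + [(start, end)], g.strand)
            else:
                groups[gid] = GeneAnnotation(gid, chrom, [(start, end)], strand)
    if not groups:
        raise EmptyInputError(f"{path}: no gene records")
    return list(groups.values())


def write_genes_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom\tstart\tend\tgene_id\tscore\tstrand\ttbscan={__version__}\n")
        for g in genes:
            for s, e in g.intervals:
                bs, be = to_bed_interval(s, e)
                fh.write(f"{g.chrom}\t{bs}\t{be}\t{g.gene_id}\t.\t{g.strand}\n")


# ---------------------------------------------------------------------------
# window statistics (BED-like TSV)
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "mean_fst"]


def write_window_stats(path, windows: pd.DataFrame, extra_header: str = "") -> None:
    """Write window statistics as BED-like TSV (0-based half-open coords)."""
    cols = [c for c in WINDOW_COLUMNS if c in windows.columns] + [
        c for c in windows.columns if c not in WINDOW_COLUMNS
    ]
    with open(path, "w") as fh:
        meta = f"#tbscan={__version__}"
        if extra_header:
            meta += f"\t{extra_header}"
        fh.write(meta + "\n")
        fh.write("#" + "\t".join(cols) + "\n")
        windows[cols].to_csv(fh, sep="\t", index=False, header=False, na_rep="NA")


def read_window_stats(path) -> pd.DataFrame:
    """Re-read a window TSV written by :func:`write_window_stats`."""
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") and "\t" in line and not line.startswith("#tbscan"):
                header = line[1:].rstrip("\n").split("\t")
            elif not line.startswith("#"):
                break
        if header is None:
            raise DataError(f"{path}: missing column header line")
    df = pd.read_csv(path, sep="\t", comment="#", names=header, na_values="NA")
    if df.empty:
        raise EmptyInputError(f"{path}: no window rows")
    return df
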