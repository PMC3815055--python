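"""Genotype matrices for inbred-line marker data, file I/O and marker editing.

Calls are coded 0/2 for the two homozygotes, 1 for heterozygotes and -1 for
missing, stored in an int8 matrix of lines x markers.  All marker-editing
rules used before genomic prediction live here: masking residual
heterozygotes, the missingness/MAF marker filter, and expected-value
(marker-mean) replacement of residual missing calls.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = -1

# IUPAC ambiguity codes for heterozygous single-letter diploid calls
_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
_HAPMAP_HEADER = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
    "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclasses.dataclass
class GenotypeMatrix:
    """Lines x markers biallelic calls with chromosome/position metadata.

    Parameters
    ----------
    calls : int8 array, shape (n_lines, n_markers)
        0/2 homozygotes, 1 heterozygote, -1 missing.
    line_ids, marker_ids : sequences of str
    chrom : array of str, per marker
    pos_bp : int array, per marker, 1-based physical positions
    pos_cm : optional float array, genetic positions
    """

    calls: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        n, m = self.calls.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos_bp) == m):
            raise ValueError("marker metadata length mismatch")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"{bad.sum()} calls outside {{0,1,2,missing}}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions decrease within chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.chrom))

    def chromosome_slices(self) -> dict[str, np.ndarray]:
        """Marker index array per chromosome, in stored order."""
        return {c: np.flatnonzero(self.chrom == c) for c in self.chromosomes()}

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.calls[:, idx],
            self.line_ids,
            [self.marker_ids[i] for i in idx],
            self.chrom[idx],
            self.pos_bp[idx],
            None if self.pos_cm is None else np.asarray(self.pos_cm)[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), list(self.line_ids), list(self.marker_ids),
            self.chrom.copy(), self.pos_bp.copy(),
            None if self.pos_cm is None else np.asarray(self.pos_cm).copy(),
        )


@dataclasses.dataclass
class MarkerFilterReport:
    """Per-chromosome marker-editing tallies (initial/after counts, % missing)."""

    table: pd.DataFrame  # chrom, n_initial, pct_missing_before, n_after, pct_missing_after

    def totals(self) -> pd.Series:
        t = self.table[["n_initial", "n_after"]].sum()
        t.name = "total"
        return t

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# editing operations
# ---------------------------------------------------------------------------

def set_heterozygotes_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Mask residual heterozygous calls (1 -> missing); inbred data carry no
    credible heterozygotes, so they are treated as call errors."""
    out = geno.copy()
    out.calls[out.calls == 1] = MISSING
    return out


def compute_maf(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-marker minor allele frequency on called genotypes only.

    Returns NaN for all-missing markers.  MAF = min(p, 1-p) with
    p = sum(calls)/(2 * n_called).
    """
    calls = geno.calls if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    called = calls != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    return maf


def filter_markers(
    geno: GenotypeMatrix,
    max_missing: float = 0.80,
    min_maf_exclusive: float = 0.05,
) -> tuple[GenotypeMatrix, MarkerFilterReport]:
    """Marker edit: drop markers with missing fraction > ``max_missing``, then
    drop markers with MAF <= ``min_maf_exclusive`` (MAF on called genotypes).

    The order matters — survivor counts differ if MAF is filtered first —
    and is fixed as missingness rule then MAF rule.
    """
    for t in (max_missing, min_maf_exclusive):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be in [0,1]")
    miss = geno.missing_mask.mean(axis=0)
    keep = miss <= max_missing
    maf = compute_maf(geno)
    with np.errstate(invalid="ignore"):
        keep &= ~np.isnan(maf) & (maf > min_maf_exclusive)

    rows = []
    for c in geno.chromosomes():
        on_c = geno.chrom == c
        n0 = int(on_c.sum())
        kept_c = on_c & keep
        n1 = int(kept_c.sum())
        rows.append({
            "chrom": c,
            "n_initial": n0,
            "pct_missing_before": 100.0 * geno.missing_mask[:, on_c].mean(),
            "n_after": n1,
            "pct_missing_after":
                100.0 * geno.missing_mask[:, kept_c].mean() if n1 else np.nan,
        })
    out = geno.take_markers(np.flatnonzero(keep))
    if out.n_markers == 0:
        raise ValueError("marker filter removed every marker")
    return out, MarkerFilterReport(pd.DataFrame(rows))


def expected_value_impute(geno: GenotypeMatrix) -> np.ndarray:
    """Replace residual missing calls by the marker mean among called lines
    (the expected value 2p).  Returns a complete float matrix."""
    calls = geno.calls.astype(float)
    calls[geno.missing_mask] = np.nan
    mean = np.nanmean(calls, axis=0)
    if np.isnan(mean).any():
        bad = [geno.marker_ids[i] for i in np.flatnonzero(np.isnan(mean))[:5]]
        raise ValueError(f"all-missing markers cannot be mean-imputed: {bad} ...")
    idx = np.where(np.isnan(calls))
    calls[idx] = mean[idx[1]]
    return calls


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from HapMap, VCF or matrix-CSV.

    ``format`` is one of 'hapmap', 'vcf', 'matrix-csv'; inferred from the
    file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".csv": "matrix-csv"}.get(suffix, "hapmap")
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "matrix-csv":
        return _read_matrix_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes(geno: GenotypeMatrix, path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".csv": "matrix-csv"}.get(suffix, "hapmap")
    if format == "vcf":
        _write_vcf(geno, path)
    elif format == "hapmap":
        _write_hapmap(geno, path)
    elif format == "matrix-csv":
        _write_matrix_csv(geno, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows, marker_ids, chrom, pos = [], [], [], []
        skipped_multi = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped_multi += 1
                continue
            calls = np.empty(len(samples), dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                alleles = [a for a in gt if a is not None]
                if len(alleles) < 2:  # ./., half-calls treated as missing
                    calls[j] = MISSING
                else:
                    calls[j] = alleles[0] + alleles[1]
            rows.append(calls)
            marker_ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
            chrom.append(str(rec.chrom))
            pos.append(rec.pos)
        if skipped_multi:
            import warnings
            warnings.warn(f"skipped {skipped_multi} non-biallelic sites")
    mat = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(mat, samples, marker_ids, np.array(chrom, object),
                          np.array(pos, np.int64))


def _write_vcf(geno: GenotypeMatrix, path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    for c in geno.chromosomes():
        last = int(geno.pos_bp[geno.chrom == c].max())
        header.contigs.add(str(c), length=last + 1)
    for s in geno.line_ids:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j in range(geno.n_markers):
            rec = vf.new_record(
                contig=str(geno.chrom[j]), start=int(geno.pos_bp[j]) - 1,
                stop=int(geno.pos_bp[j]), alleles=("A", "G"),
                id=geno.marker_ids[j],
            )
            for i, s in enumerate(geno.line_ids):
                rec.samples[s]["GT"] = gt_map[int(geno.calls[i, j])]
            vf.write(rec)


def _read_hapmap(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise ValueError("HapMap file needs 11 metadata columns + samples")
    meta, gts = df.iloc[:, :11], df.iloc[:, 11:]
    line_ids = list(gts.columns)
    alleles = meta.iloc[:, 1].str.split("/", expand=True)
    ref = alleles[0].to_numpy()
    alt = alleles[1].to_numpy()
    calls = np.full((len(line_ids), len(df)), MISSING, dtype=np.int8)
    bad: list[str] = []
    for j in range(len(df)):
        r, a = ref[j], alt[j]
        het_codes = {c for c, pair in _IUPAC_HET.items() if set(pair) == {r, a}}
        for i, v in enumerate(gts.iloc[j]):
            v = str(v).upper()
            if v in ("N", "NN", "NAN", "-", "--", "./."):
                calls[i, j] = MISSING
            elif v in (r, r + r):
                calls[i, j] = 0
            elif v in (a, a + a):
                calls[i, j] = 2
            elif v in het_codes or set(v) == {r, a}:
                calls[i, j] = 1
            else:
                bad.append(f"{meta.iloc[j, 0]}:{line_ids[i]}={v}")
    if bad:
        raise ValueError(f"unknown alleles in {len(bad)} records, e.g. {bad[:5]}")
    return GenotypeMatrix(calls, line_ids, list(meta.iloc[:, 0]),
                          meta.iloc[:, 2].to_numpy(object),
                          meta.iloc[:, 3].astype(np.int64).to_numpy())


def _write_hapmap(geno: GenotypeMatrix, path: Path) -> None:
    code = {0: "A", 2: "G", 1: "R", MISSING: "N"}  # R = A/G het
    cols = {
        "rs#": geno.marker_ids, "alleles": "A/G", "chrom": geno.chrom,
        "pos": geno.pos_bp, "strand": "+", "assembly#": "NA", "center": "NA",
        "protLSID": "NA", "assayLSID": "NA", "panelLSID": "NA", "QCcode": "NA",
    }
    df = pd.DataFrame(cols, columns=_HAPMAP_HEADER)
    gt = pd.DataFrame(
        np.vectorize(code.get)(geno.calls.T), columns=geno.line_ids)
    pd.concat([df, gt], axis=1).to_csv(path, sep="\t", index=False)


def _read_matrix_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    marker_ids = list(df.columns)
    # positions encoded in header as chrom:pos when available, else sequential
    chrom, pos = [], []
    for k, m in enumerate(marker_ids):
        if ":" in m:
            c, p = m.rsplit(":", 1)
            chrom.append(c)
            pos.append(int(p))
        else:
            chrom.append("1")
            pos.append(k + 1)
    return GenotypeMatrix(calls, list(df.index.astype(str)), marker_ids,
                          np.array(chrom, object), np.array(pos, np.int64))


def _write_matrix_csv(geno: GenotypeMatrix, path: Path) -> None:
    vals = geno.calls.astype(float)
    vals[geno.missing_mask] = np.nan
    cols = [f"{c}:{p}" if ":" not in m else m
            for m, c, p in zip(geno.marker_ids, geno.chrom, geno.pos_bp)]
    pd.DataFrame(vals, index=geno.line_ids, columns=cols).to_csv(path)


def concat_markers(parts: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    parts = list(parts)
    base = parts[0]
    return GenotypeMatrix(
        np.concatenate([p.calls for p in parts], axis=1),
        base.line_ids,
        sum((p.marker_ids for p in parts), []),
        np.concatenate([p.chrom for p in parts]),
        np.concatenate([p.pos_bp for p in parts]),
    )
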