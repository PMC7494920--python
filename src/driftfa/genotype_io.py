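"""Genotype matrix input/output, filtering, imputation and centering.

The in-memory container is :class:`GenotypeMatrix`, an ``n x p`` numeric
matrix (individuals by markers) with a boolean missingness mask.  Readers
are provided for unpacked EIGENSTRAT triplets (``.geno``/``.snp``/``.ind``),
VCF (genotype field only, converted to ALT-allele dosage), and plain
delimited matrices.  Filtering follows the ancient-DNA conventions used
throughout the package: samples are filtered on sequencing coverage first,
markers on their missingness fraction second, missing genotypes are then
completed with an iterative truncated-SVD low-rank algorithm, and the
matrix is finally centered by row (per individual) before model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class GenotypeIOError(ValueError):
    """Malformed or structurally inconsistent genotype input."""


class EmptyResultError(ValueError):
    """A filter removed every sample or every marker."""


@dataclass
class GenotypeMatrix:
    """Numeric genotype matrix with sample/marker identifiers.

    Attributes
    ----------
    values : ndarray of shape (n, p)
        Genotype dosages (0/1/2) or continuous values after adjustment.
        Missing cells hold ``nan`` and are flagged in ``missing_mask``.
    sample_ids, marker_ids : list of str
        Row and column identifiers.
    missing_mask : ndarray of bool, shape (n, p)
        True where the genotype is missing.
    centered : bool
        Whether rows have been centered to zero mean.
    """

    values: np.ndarray
    sample_ids: list
    marker_ids: list
    missing_mask: np.ndarray = None
    centered: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeIOError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if len(self.sample_ids) != n:
            raise GenotypeIOError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.marker_ids) != p:
            raise GenotypeIOError(
                f"{len(self.marker_ids)} marker ids for {p} matrix columns"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise GenotypeIOError("missing_mask shape does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            list(self.sample_ids),
            list(self.marker_ids),
            self.missing_mask.copy(),
            self.centered,
        )


@dataclass
class SampleMetadata:
    """Per-sample record: age (years cal BP or generations) and optional
    coverage / population / epoch annotations."""

    sample_id: str
    age: float
    coverage: Optional[float] = None
    population: Optional[str] = None
    epoch: Optional[str] = None

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"sample {self.sample_id}: age must be >= 0")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"sample {self.sample_id}: coverage must be >= 0")


def read_metadata(path) -> list:
    """Read a metadata TSV with columns sample_id, age and optionally
    coverage, population, epoch.  Returns a list of :class:`SampleMetadata`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "age" not in df.columns:
        raise GenotypeIOError(f"{path}: metadata requires sample_id and age columns")
    records = []
    for _, row in df.iterrows():
        cov = row.get("coverage")
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                coverage=None if cov is None or pd.isna(cov) else float(cov),
                population=row.get("population"),
                epoch=row.get("epoch"),
            )
        )
    return records


def join_metadata(g: GenotypeMatrix, meta: Sequence[SampleMetadata]) -> list:
    """Return metadata records aligned to ``g.sample_ids`` (exact ID match).

    Raises if any sample lacks a record or has duplicated records.
    """
    by_id = {}
    for m in meta:
        if m.sample_id in by_id:
            raise GenotypeIOError(f"duplicate metadata record for {m.sample_id}")
        by_id[m.sample_id] = m
    missing = [s for s in g.sample_ids if s not in by_id]
    if missing:
        raise GenotypeIOError(f"no metadata for samples: {missing[:5]}")
    return [by_id[s] for s in g.sample_ids]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str, missing_sentinels=("NA", "", "9")) -> GenotypeMatrix:
    """Read a genotype matrix.

    Parameters
    ----------
    path : str or Path
        For ``eigenstrat``, the path of the ``.geno`` file (the ``.snp`` and
        ``.ind`` sidecars are located by swapping the extension) or a prefix.
    format : {"eigenstrat", "vcf", "matrix"}
    missing_sentinels : tuple of str
        Tokens treated as missing in the ``matrix`` dialect.
    """
    if format == "eigenstrat":
        return _read_eigenstrat(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path, missing_sentinels)
    raise GenotypeIOError(f"unknown format {format!r}")


def _sidecar(path: Path, ext: str) -> Path:
    cand = path.with_suffix(ext)
    if cand.exists():
        return cand
    cand = Path(str(path) + ext)
    if cand.exists():
        return cand
    raise GenotypeIOError(f"cannot locate {ext} sidecar for {path}")


def _read_eigenstrat(path) -> GenotypeMatrix:
    path = Path(path)
    geno = path if path.suffix == ".geno" else _sidecar(path, ".geno")
    snp = _sidecar(path, ".snp")
    ind = _sidecar(path, ".ind")

    sample_ids = []
    for lineno, line in enumerate(ind.read_text().splitlines(), 1):
        tok = line.split()
        if not tok:
            continue
        sample_ids.append(tok[0])
    marker_ids = []
    for line in snp.read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        marker_ids.append(tok[0])

    rows = []
    for lineno, line in enumerate(geno.read_text().splitlines(), 1):
        # one line per SNP, one code per individual; tolerate separators
        codes = line.split() if (" " in line.strip() or "\t" in line) else list(line.strip())
        if not codes:
            continue
        try:
            row = [float(c) for c in codes]
        except ValueError as exc:
            raise GenotypeIOError(f"{geno}:{lineno}: invalid genotype code") from exc
        if any(c not in (0.0, 1.0, 2.0, 9.0) for c in row):
            raise GenotypeIOError(f"{geno}:{lineno}: genotype codes must be 0/1/2/9")
        rows.append(row)
    if len(rows) != len(marker_ids):
        raise GenotypeIOError(
            f"{geno}: {len(rows)} SNP lines but {len(marker_ids)} .snp records"
        )
    arr = np.array(rows, dtype=float).T  # individuals x markers
    if arr.shape[0] != len(sample_ids):
        raise GenotypeIOError(
            f"{geno}: {arr.shape[0]} individuals per line but {len(sample_ids)} .ind records"
        )
    mask = arr == 9.0
    arr[mask] = np.nan
    return GenotypeMatrix(arr, sample_ids, marker_ids, mask)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    marker_ids = []
    cols = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        cols.append(g)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multi-allelic records")
    if not cols:
        raise GenotypeIOError(f"{path}: no biallelic records found")
    arr = np.column_stack(cols)
    return GenotypeMatrix(arr, sample_ids, marker_ids, np.isnan(arr))


def _read_matrix(path, missing_sentinels) -> GenotypeMatrix:
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(missing_sentinels),
        keep_default_na=True, dtype=str,
    )
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise GenotypeIOError(f"{path}: non-numeric genotype entry") from exc
    return GenotypeMatrix(
        arr, [str(s) for s in df.index], [str(m) for m in df.columns], np.isnan(arr)
    )


def write_genotypes(g: GenotypeMatrix, path, format: str) -> None:
    """Write a genotype matrix in ``eigenstrat``, ``vcf`` or ``matrix`` format.

    EIGENSTRAT and VCF require dosage-coded (0/1/2) values; ``matrix``
    accepts any numeric content and uses NA for missing cells.
    """
    path = Path(path)
    if format == "matrix":
        df = pd.DataFrame(g.values, index=g.sample_ids, columns=g.marker_ids)
        df = df.where(~g.missing_mask)
        df.to_csv(path, sep="\t", na_rep="NA")
        return
    vals = g.values.copy()
    obs = vals[~g.missing_mask]
    if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
        raise GenotypeIOError(f"{format} output requires 0/1/2 dosages")
    if format == "eigenstrat":
        codes = vals.copy()
        codes[g.missing_mask] = 9.0
        lines = ["".join(str(int(c)) for c in col) for col in codes.T]
        path.with_suffix(".geno").write_text("\n".join(lines) + "\n")
        path.with_suffix(".snp").write_text(
            "".join(f"{m}\t1\t0.0\t{i + 1}\tA\tC\n" for i, m in enumerate(g.marker_ids))
        )
        path.with_suffix(".ind").write_text(
            "".join(f"{s}\tU\tPop\n" for s in g.sample_ids)
        )
        return
    if format == "vcf":
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(g.sample_ids) + "\n"
            )
            for j, m in enumerate(g.marker_ids):
                gts = [
                    "./." if g.missing_mask[i, j] else gt_of[vals[i, j]]
                    for i in range(g.n_samples)
                ]
                fh.write(f"1\t{j + 1}\t{m}\tA\tC\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")
        return
    raise GenotypeIOError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_samples_by_coverage(
    g: GenotypeMatrix, meta: Sequence[SampleMetadata], min_coverage: float
):
    """Retain samples with coverage >= ``min_coverage`` (order preserved).

    Returns the filtered matrix and the matching metadata subset.
    """
    aligned = join_metadata(g, meta)
    if any(m.coverage is None for m in aligned):
        raise ValueError("coverage missing for some samples")
    keep = [i for i, m in enumerate(aligned) if m.coverage >= min_coverage]
    if not keep:
        raise EmptyResultError("coverage filter removed every sample")
    out = GenotypeMatrix(
        g.values[keep],
        [g.sample_ids[i] for i in keep],
        list(g.marker_ids),
        g.missing_mask[keep],
        g.centered,
    )
    return out, [aligned[i] for i in keep]


def filter_markers_by_missingness(
    g: GenotypeMatrix, max_missing_fraction: float
) -> GenotypeMatrix:
    """Retain markers whose missing fraction is strictly below the threshold."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = g.missing_mask.mean(axis=0)
    keep = np.flatnonzero(frac < max_missing_fraction) if max_missing_fraction < 1.0 \
        else np.flatnonzero(frac < 1.0)
    if keep.size == 0:
        raise EmptyResultError("missingness filter removed every marker")
    return GenotypeMatrix(
        g.values[:, keep],
        list(g.sample_ids),
        [g.marker_ids[j] for j in keep],
        g.missing_mask[:, keep],
        g.centered,
    )


# ---------------------------------------------------------------------------
# Imputation and centering
# ---------------------------------------------------------------------------

def impute_missing(
    g: GenotypeMatrix, rank: int = 10, max_iter: int = 100, tol: float = 1e-6
) -> GenotypeMatrix:
    """Complete missing genotypes by iterative truncated-SVD reconstruction.

    Missing cells are initialized at their row means, then the matrix is
    alternately replaced by its rank-``rank`` SVD reconstruction and reset
    to the observed values at observed cells, until the relative change of
    the imputed cells drops below ``tol``.  Dosage-coded input (all
    observed values in [0, 2]) is clipped back into [0, 2].
    """
    if rank >= min(g.shape):
        raise ValueError("rank must be smaller than min(n, p)")
    mask = g.missing_mask
    if not mask.any():
        return g.copy()
    X = g.values.copy()
    obs_vals = X[~mask]
    dosage = obs_vals.size > 0 and obs_vals.min() >= 0 and obs_vals.max() <= 2
    row_means = np.nanmean(np.where(mask, np.nan, X), axis=1)
    row_means = np.where(np.isnan(row_means), np.nanmean(obs_vals), row_means)
    X[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]

    converged = False
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        low = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new = np.where(mask, low, g.values)
        if dosage:
            new[mask] = np.clip(new[mask], 0.0, 2.0)
        denom = np.linalg.norm(X[mask]) or 1.0
        delta = np.linalg.norm(new[mask] - X[mask]) / denom
        X = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("imputation did not converge; returning last iterate")
    return GenotypeMatrix(
        X, list(g.sample_ids), list(g.marker_ids),
        np.zeros_like(mask), g.centered,
    )


def center_rows(g: GenotypeMatrix) -> GenotypeMatrix:
    """Center each row (individual) to zero mean.

    Centering by individual rather than by marker is the convention used by
    the temporal factor model: the row variances feed the time transform.
    """
    if g.missing_mask.any():
        raise ValueError("impute missing genotypes before centering")
    vals = g.values - g.values.mean(axis=1, keepdims=True)
    return GenotypeMatrix(
        vals, list(g.sample_ids), list(g.marker_ids),
        np.zeros_like(g.missing_mask), True,
    )
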