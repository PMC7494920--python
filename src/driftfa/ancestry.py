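"""Ancestry (admixture) coefficients from factor geometry.

In a two-way admixture model the first factor axis orders samples between
the two source populations; an individual's ancestry coefficient for
source ``a`` is its relative position between the source cluster centers,

    q_ai = (c_b - u_i) / (c_b - c_a),

truncated to [0, 1] and averaged over target individuals for a population
estimate.  With three or more sources the coefficients are the barycentric
coordinates of the sample in the affine frame of the source centers on the
first ``K_src - 1`` factors; negative raw coordinates indicate no
contribution from the corresponding source.  A PC-projection baseline
(principal components of the modern samples, ancient samples projected)
is included for comparison only: it suffers the shrinkage bias that the
drift-corrected factors avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd


class DegenerateSourceError(ValueError):
    """Source centers coincide (or are affinely dependent)."""


@dataclass
class SourceSpec:
    """Ordered source populations and a target population.

    sources : mapping label -> list of member sample IDs (insertion order
        defines the coefficient order).
    target : (label, list of member sample IDs).
    """

    sources: Dict[str, List[str]]
    target: tuple

    def __post_init__(self):
        if not self.sources:
            raise ValueError("at least one source population required")
        for lab, members in self.sources.items():
            if not members:
                raise ValueError(f"source {lab!r} has no members")
        tgt = set(self.target[1])
        for lab, members in self.sources.items():
            if tgt & set(members):
                raise ValueError(f"source {lab!r} overlaps the target")

    @property
    def source_labels(self) -> list:
        return list(self.sources)


@dataclass
class AncestryEstimate:
    """Per-individual and per-population mixture coefficients.

    ``per_individual`` holds truncated (and, K-way, renormalized)
    coefficients in [0, 1]; ``raw_coordinates`` the untruncated values
    (exactly summing to one in barycentric form, possibly negative);
    ``truncated_flags`` marks individuals clipped by the truncation.
    """

    per_individual: pd.DataFrame
    per_population: pd.Series
    raw_coordinates: pd.DataFrame
    truncated_flags: pd.Series
    source_centers: pd.DataFrame = None


def _series(scores, ids=None) -> pd.Series:
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    scores = np.asarray(scores, dtype=float)
    if ids is None:
        raise ValueError("sample ids required when scores are a bare array")
    return pd.Series(scores, index=[str(s) for s in ids])


def two_way_ancestry(u1, spec: SourceSpec, sample_ids=None) -> AncestryEstimate:
    """Two-way ancestry from factor-1 positions.

    ``u1`` is a pandas Series of factor-1 scores indexed by sample ID (or
    an array with ``sample_ids`` given).  The coefficient of the first
    source is ``(c_b - u_i)/(c_b - c_a)``; truncation to [0, 1] happens
    before averaging over the target, and the second coefficient is
    ``1 - q`` by convention.
    """
    if len(spec.sources) != 2:
        raise ValueError("two_way_ancestry requires exactly two sources")
    u = _series(u1, sample_ids)
    lab_a, lab_b = spec.source_labels
    c_a = u.loc[spec.sources[lab_a]].mean()
    c_b = u.loc[spec.sources[lab_b]].mean()
    if np.isclose(c_a, c_b):
        raise DegenerateSourceError(
            "source centers coincide on factor 1; sources are indistinguishable"
        )
    targets = spec.target[1]
    raw = (c_b - u.loc[targets]) / (c_b - c_a)
    q = raw.clip(0.0, 1.0)
    per_ind = pd.DataFrame({lab_a: q, lab_b: 1.0 - q})
    raw_df = pd.DataFrame({lab_a: raw, lab_b: 1.0 - raw})
    flags = (raw < 0) | (raw > 1)
    per_pop = per_ind.mean(axis=0)
    centers = pd.DataFrame({"u1": [c_a, c_b]}, index=[lab_a, lab_b])
    return AncestryEstimate(per_ind, per_pop, raw_df, flags, centers)


def k_way_ancestry(U, spec: SourceSpec, sample_ids=None) -> AncestryEstimate:
    """Barycentric ancestry coordinates for K_src >= 3 sources.

    ``U`` is an (n x K_src-1) frame of factor scores (factors 1..K_src-1)
    indexed by sample ID.  Solves ``sum_k q_k center_k = u_i`` with
    ``sum_k q_k = 1``; raw coordinates sum to one exactly and may be
    negative (read: no contribution from that source).  Truncated
    coordinates are clipped at zero and renormalized.
    """
    K_src = len(spec.sources)
    if K_src < 3:
        raise ValueError("k_way_ancestry requires at least three sources")
    if isinstance(U, pd.DataFrame):
        df = U.astype(float)
    else:
        U = np.asarray(U, dtype=float)
        if sample_ids is None:
            raise ValueError("sample ids required when scores are a bare array")
        df = pd.DataFrame(U, index=[str(s) for s in sample_ids])
    dim = K_src - 1
    if df.shape[1] < dim:
        raise ValueError(f"need scores on {dim} factors for {K_src} sources")
    df = df.iloc[:, :dim]

    centers = np.vstack([df.loc[m].mean(axis=0).to_numpy() for m in spec.sources.values()])
    # affine system: rows [center_k; 1]
    M = np.vstack([centers.T, np.ones(K_src)])
    if np.linalg.matrix_rank(M) < K_src:
        raise DegenerateSourceError("source centers are affinely dependent")

    targets = spec.target[1]
    X = df.loc[targets].to_numpy()
    rhs = np.vstack([X.T, np.ones(len(targets))])
    raw, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    raw = raw.T  # (targets x K_src)
    trunc = np.clip(raw, 0.0, None)
    trunc = trunc / trunc.sum(axis=1, keepdims=True)

    labels = spec.source_labels
    raw_df = pd.DataFrame(raw, index=targets, columns=labels)
    per_ind = pd.DataFrame(trunc, index=targets, columns=labels)
    flags = pd.Series((raw < 0).any(axis=1), index=targets)
    per_pop = per_ind.mean(axis=0)
    centers_df = pd.DataFrame(centers, index=labels, columns=df.columns)
    return AncestryEstimate(per_ind, per_pop, raw_df, flags, centers_df)


def pc_projection_estimator(
    Y_modern,
    Y_ancient,
    spec: SourceSpec,
    K: int,
    modern_ids=None,
    ancient_ids=None,
) -> AncestryEstimate:
    """Baseline estimator: project ancient samples onto modern PCs.

    Principal components are computed on the column-centered modern matrix
    (standard projection protocol); ancient samples are centered with the
    modern column means and projected onto the top-K axes.  Ancestry is
    then read from the projected coordinates with the same center-based
    formulas as for factor scores.  The marker sets must match.
    """
    Ym, ids_m = _matrix_and_ids(Y_modern, modern_ids)
    Ya, ids_a = _matrix_and_ids(Y_ancient, ancient_ids)
    if Ym.shape[1] != Ya.shape[1]:
        raise ValueError("modern and ancient matrices must share the marker set")
    mu = Ym.mean(axis=0)
    Ymc = Ym - mu
    U, s, Vt = np.linalg.svd(Ymc, full_matrices=False)
    K = min(K, len(s))
    scores_m = U[:, :K] * s[:K]
    scores_a = (Ya - mu) @ Vt[:K].T
    all_scores = pd.DataFrame(
        np.vstack([scores_m, scores_a]), index=list(ids_m) + list(ids_a)
    )
    if len(spec.sources) == 2:
        return two_way_ancestry(all_scores.iloc[:, 0], spec)
    return k_way_ancestry(all_scores, spec)


def _matrix_and_ids(Y, ids):
    from driftfa.genotype_io import GenotypeMatrix

    if isinstance(Y, GenotypeMatrix):
        return Y.values, Y.sample_ids
    Y = np.asarray(Y, dtype=float)
    if ids is None:
        raise ValueError("sample ids required for bare arrays")
    return Y, [str(s) for s in ids]
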