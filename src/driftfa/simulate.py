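"""Simulators for serial-sample genotype data.

Two families of scenarios are provided, matching the simulation studies
the model is validated on:

* **Generative probit factor models** (:func:`simulate_generative`): latent
  scores with population structure on factor 1, temporal drift injected
  through the Brownian basis of the sampled ages, Gaussian loadings and
  residuals, and genotypes emitted through a probit link.  These carry an
  exact ground truth for factors and admixture coefficients.

* **Forward Wright-Fisher scenarios** (:func:`simulate_wf_serial`):
  independent allele frequencies evolved by binomial resampling in a
  population of size ``Ne``, with optional split and admixture events and
  individuals drawn at scheduled ages.  These emulate serial-sampling
  coalescent setups (single population, divergence, admixture) without an
  external engine; any coalescent simulator producing the same
  :class:`SimulatedDataset` shape can be substituted.

All randomness flows through a single seed; identical seeds give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

from driftfa.genotype_io import GenotypeMatrix, SampleMetadata
from driftfa.temporal import brownian_covariance, spectral_basis

# Calibration of the probit emission: the separation of ancestral centers
# on factor 1 is CENTER_SEP_PER_S1 * s1 latent units.  With unit
# within-cluster spread on factor 1, standard-normal loadings, sigma = 1
# and column-standardized probit emission, this maps the divergence grid
# s1 in [2, 10] onto Hudson F_ST approximately in [0.02, 0.25].
CENTER_SEP_PER_S1 = 0.5


@dataclass
class GenerativeScenario:
    """Parameters of a probit factor-model scenario.

    factor_sds : (s1, s2, s3); s1 scales the divergence of the ancestral
        centers on factor 1, s2/s3 the spreads of the remaining factors.
    center_distance : separation of the ancestral centers on factor 1;
        defaults to ``CENTER_SEP_PER_S1 * s1``.
    admix_a : ancestry proportion of population 1 in the admixed samples,
        or None for a pure divergence scenario.
    lam : drift parameter lambda = sigma^2 / alpha; the drift effect sizes
        are drawn N(0, alpha).
    sigma : residual standard deviation.
    loading_sd : standard deviation of the i.i.d. Gaussian loadings.
    age_window : ages are drawn uniformly on [0, age_window] (admixed
        samples, when present, are sampled in the present at age 0).
    output : "dosage" for probit-Binomial genotypes, "continuous" for the
        latent matrix itself.
    """

    n: int = 200
    p: int = 5000
    factor_sds: Tuple[float, float, float] = (10.0, 1.5, 0.5)
    center_distance: Optional[float] = None
    admix_a: Optional[float] = None
    lam: float = 0.1
    sigma: float = 1.0
    loading_sd: float = 1.0
    age_window: float = 4000.0
    output: str = "dosage"
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0 or self.sigma <= 0 or self.loading_sd <= 0:
            raise ValueError("lam, sigma and loading_sd must be > 0")
        if self.admix_a is not None and not 0.0 <= self.admix_a <= 1.0:
            raise ValueError("admix_a must lie in [0, 1]")
        if self.center_distance is None:
            self.center_distance = CENTER_SEP_PER_S1 * self.factor_sds[0]


def divergence_scenario(s1: float = 10.0, seed: int = 0, **kw) -> GenerativeScenario:
    """Two populations diverged on factor 1, no admixture (stated defaults:
    s2 = 1.5, s3 = 0.5, sigma = 1, weak drift lambda = 0.1)."""
    kw.setdefault("factor_sds", (s1, 1.5, 0.5))
    return GenerativeScenario(admix_a=None, seed=seed, **kw)


def admixture_scenario(
    admix_a: float = 0.25, center_distance: float = 11.0, seed: int = 0, **kw
) -> GenerativeScenario:
    """Two diverged sources plus a present-day admixed population.

    Defaults follow the strong-drift benchmarking setup: center distance
    around 11 (F_ST ~ 25%), s2 = 1.2, s3 = 1, loadings N(0, 0.2),
    sigma = 0.1, lambda = 5e-2.
    """
    kw.setdefault("factor_sds", (center_distance, 1.2, 1.0))
    kw.setdefault("loading_sd", float(np.sqrt(0.2)))
    kw.setdefault("sigma", 0.1)
    kw.setdefault("lam", 5e-2)
    return GenerativeScenario(
        admix_a=admix_a, center_distance=center_distance, seed=seed, **kw
    )


@dataclass
class WFScenario:
    """Forward Wright-Fisher scenario with optional split and admixture.

    sample_schedule : list of (age_in_generations, population, count);
        populations are "pop" (single-population model) or "p1"/"p2"
        after a split and "adm" after the admixture event.
    split_time / contact_time : generations before present; None disables
        the corresponding event.
    admix_fractions : (from_p1, from_p2) contributions forming "adm".
    """

    Ne: int = 10_000
    split_time: Optional[int] = None
    contact_time: Optional[int] = None
    sample_schedule: List[Tuple[int, str, int]] = field(default_factory=list)
    n_snps: int = 9000
    admix_fractions: Tuple[float, float] = (0.75, 0.25)
    init_freq_range: Tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if not self.sample_schedule:
            raise ValueError("empty sample schedule")
        ages = [a for a, _, c in self.sample_schedule if c > 0]
        if not ages:
            raise ValueError("no positive sample counts in schedule")
        for age, pop, _ in self.sample_schedule:
            if pop == "adm":
                if self.contact_time is None or age >= self.contact_time:
                    raise ValueError("admixed samples must postdate the contact time")
            if pop in ("p1", "p2"):
                if self.split_time is None or age > self.split_time:
                    raise ValueError(f"population {pop} does not exist at age {age}")
        if self.contact_time is not None:
            if self.split_time is None or self.contact_time >= self.split_time:
                raise ValueError("contact must postdate the split")
            if not np.isclose(sum(self.admix_fractions), 1.0):
                raise ValueError("admix fractions must sum to 1")


def wf_single_population(
    Ne: int = 10_000, age_max: int = 4000, step: int = 100,
    n_snps: int = 9000, seed: int = 0,
) -> WFScenario:
    """One panmictic population, one individual sampled every ``step``
    generations from ``age_max`` to the present (41 samples by default)."""
    schedule = [(int(a), "pop", 1) for a in range(0, age_max + 1, step)]
    return WFScenario(Ne=Ne, sample_schedule=schedule, n_snps=n_snps, seed=seed)


def wf_divergence(
    Ne: int = 10_000, split_time: int = 1500, n_per_pop: int = 12,
    age_max: int = 1000, n_snps: int = 8800, seed: int = 0,
) -> WFScenario:
    """Two sister populations split ``split_time`` generations ago, sampled
    serially between the present and ``age_max`` generations ago."""
    ages = np.linspace(0, age_max, n_per_pop).round().astype(int)
    schedule = [(int(a), p, 1) for p in ("p1", "p2") for a in ages]
    return WFScenario(
        Ne=Ne, split_time=split_time, sample_schedule=schedule,
        n_snps=n_snps, seed=seed,
    )


def wf_admixture(
    Ne: int = 10_000, split_time: int = 1300, contact_time: int = 500,
    admix_a: float = 0.75, n_admixed: int = 100, n_source: int = 50,
    source_age: int = 1000, n_snps: int = 9600, seed: int = 0,
) -> WFScenario:
    """Serial-sampling admixture scenario: the ancestral population splits,
    the two branches meet again forming an admixed population; sources are
    sampled before the contact, the admixed population in the present."""
    schedule = [
        (source_age, "p1", n_source),
        (source_age, "p2", n_source),
        (0, "adm", n_admixed),
    ]
    return WFScenario(
        Ne=Ne, split_time=split_time, contact_time=contact_time,
        sample_schedule=schedule, n_snps=n_snps,
        admix_fractions=(admix_a, 1.0 - admix_a), seed=seed,
    )


@dataclass
class SimulatedDataset:
    """Genotypes, metadata and the hidden truth of a simulated scenario."""

    genotypes: GenotypeMatrix
    metadata: List[SampleMetadata]
    truth: Dict

    @property
    def ages(self) -> np.ndarray:
        return np.array([m.age for m in self.metadata], dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.population for m in self.metadata])


# ---------------------------------------------------------------------------
# Generative probit factor model
# ---------------------------------------------------------------------------

def simulate_generative(sc: GenerativeScenario) -> SimulatedDataset:
    """Draw a dataset from the probit factor model with temporal drift.

    Ancestral populations sit at ``-d/2`` and ``+d/2`` on factor 1
    (``d = sc.center_distance``) with unit within-cluster spread; an
    admixed population, when requested, is centered at the ancestry-
    weighted barycenter ``a c_1 + (1-a) c_2``.  The latent matrix is
    ``Y* = U V^T + Z B^T + sigma eps`` with ``B ~ N(0, alpha)``,
    ``alpha = sigma^2 / lam``, and ``Z`` the Brownian basis of the
    forward-scaled sample ages.  Genotypes are emitted as
    ``Binomial(2, Phi(y*/tau_j))`` with ``tau_j`` the column standard
    deviation of the latent matrix.
    """
    rng = np.random.default_rng(sc.seed)
    n, p = sc.n, sc.p
    s1, s2, s3 = sc.factor_sds
    d = sc.center_distance

    if sc.admix_a is None:
        half = n // 2
        labels = np.array(["pop1"] * half + ["pop2"] * (n - half))
        centers = np.where(labels == "pop1", -d / 2.0, d / 2.0)
        ages = rng.uniform(0.0, sc.age_window, n)
    else:
        n_adm = n // 2
        n_src = (n - n_adm) // 2
        labels = np.array(
            ["src1"] * n_src + ["src2"] * (n - n_adm - n_src) + ["adm"] * n_adm
        )
        c1, c2 = -d / 2.0, d / 2.0
        c_adm = sc.admix_a * c1 + (1.0 - sc.admix_a) * c2
        centers = np.select(
            [labels == "src1", labels == "src2"], [c1, c2], default=c_adm
        )
        ages = np.where(
            labels == "adm", 0.0, rng.uniform(0.0, sc.age_window, n)
        )

    u1 = centers + rng.standard_normal(n)
    U = np.column_stack(
        [u1, s2 * rng.standard_normal(n), s3 * rng.standard_normal(n)]
    )
    V = sc.loading_sd * rng.standard_normal((p, 3))

    # temporal drift on the Brownian basis of forward-scaled ages
    span = ages.max() - ages.min()
    t = 1.0 - (ages - ages.min()) / span if span > 0 else np.ones(n)
    basis = spectral_basis(brownian_covariance(t).C)
    alpha = sc.sigma**2 / sc.lam
    B = np.sqrt(alpha) * rng.standard_normal((p, n))
    latent = U @ V.T + basis.Z @ B.T + sc.sigma * rng.standard_normal((n, p))

    if sc.output == "continuous":
        values = latent
    else:
        tau = latent.std(axis=0)
        tau[tau == 0] = 1.0
        values = rng.binomial(2, norm.cdf(latent / tau)).astype(float)

    sample_ids = [f"{lab}_{i:04d}" for i, lab in enumerate(labels)]
    marker_ids = [f"snp{j:05d}" for j in range(p)]
    g = GenotypeMatrix(values, sample_ids, marker_ids, np.zeros((n, p), bool))
    meta = [
        SampleMetadata(sample_id=s, age=float(a), population=lab)
        for s, a, lab in zip(sample_ids, ages, labels)
    ]
    truth = {
        "factors": U,
        "labels": labels,
        "admix_a": sc.admix_a,
        "lam": sc.lam,
        "forward_times": t,
    }
    return SimulatedDataset(g, meta, truth)


# ---------------------------------------------------------------------------
# Forward Wright-Fisher engine
# ---------------------------------------------------------------------------

def _evolve(f: np.ndarray, gens: int, Ne: int, rng, clamp=(1e-4, 1 - 1e-4)):
    """Binomial Wright-Fisher resampling of allele frequencies; frequencies
    are clamped away from 0/1 so absorption does not distort F_ST at the
    marker counts used here."""
    for _ in range(gens):
        f = rng.binomial(2 * Ne, f) / (2.0 * Ne)
        f = np.clip(f, clamp[0], clamp[1])
    return f


def _wf_batch(sc: WFScenario, p: int, rng) -> Dict[Tuple[int, str], np.ndarray]:
    """Simulate ``p`` independent loci and return frequency snapshots for
    every (age, population) in the schedule."""
    lo, hi = sc.init_freq_range
    snap_points = sorted({(a, pop) for a, pop, c in sc.sample_schedule if c > 0},
                         key=lambda x: (-x[0], x[1]))
    ages_needed = {a for a, _ in snap_points}
    start = max([a for a in ages_needed] + ([sc.split_time] if sc.split_time else []))
    f = rng.uniform(lo, hi, p)
    pops: Dict[str, np.ndarray] = {}
    snaps: Dict[Tuple[int, str], np.ndarray] = {}

    if sc.split_time is None:
        pops["pop"] = f
        timeline_start = start
    else:
        # evolve the ancestral population from the oldest needed age (if any
        # predates the split) down to the split, then branch
        if start > sc.split_time:
            f = _evolve(f, start - sc.split_time, sc.Ne, rng)
        pops["p1"] = f
        pops["p2"] = f.copy()
        timeline_start = sc.split_time

    for age in range(timeline_start, -1, -1):
        if sc.contact_time is not None and age == sc.contact_time:
            a1, a2 = sc.admix_fractions
            pops["adm"] = np.clip(a1 * pops["p1"] + a2 * pops["p2"], 1e-4, 1 - 1e-4)
        for pop in list(pops):
            if (age, pop) in snap_points:
                snaps[(age, pop)] = pops[pop].copy()
        if age > 0:
            for pop in pops:
                pops[pop] = _evolve(pops[pop], 1, sc.Ne, rng)
    return snaps


def simulate_wf_serial(sc: WFScenario) -> SimulatedDataset:
    """Simulate serially sampled genotypes under forward Wright-Fisher drift.

    Loci are independent; initial frequencies are uniform on
    ``init_freq_range``.  Individuals are drawn ``Binomial(2, f_pop(age))``
    at their scheduled ages.  Markers monomorphic across the whole sample
    are dropped and fresh loci are simulated until ``n_snps`` polymorphic
    markers are available.
    """
    rng = np.random.default_rng(sc.seed)
    cols = []
    total = 0
    for _ in range(6):
        batch_p = max(int((sc.n_snps - total) * 1.25), 64)
        snaps = _wf_batch(sc, batch_p, rng)
        G_parts = []
        for age, pop, count in sc.sample_schedule:
            if count <= 0:
                continue
            f = snaps[(age, pop)]
            G_parts.append(rng.binomial(2, np.tile(f, (count, 1))))
        G = np.vstack(G_parts).astype(float)
        poly = G.std(axis=0) > 0
        cols.append(G[:, poly])
        total += int(poly.sum())
        if total >= sc.n_snps:
            break
    G = np.hstack(cols)[:, : sc.n_snps]

    sample_ids, ages, labels = [], [], []
    for age, pop, count in sc.sample_schedule:
        for i in range(count):
            sample_ids.append(f"{pop}_t{age}_{i:03d}")
            ages.append(float(age))
            labels.append(pop)
    marker_ids = [f"snp{j:05d}" for j in range(G.shape[1])]
    g = GenotypeMatrix(G, sample_ids, marker_ids, np.zeros(G.shape, bool))
    meta = [
        SampleMetadata(sample_id=s, age=a, population=lab)
        for s, a, lab in zip(sample_ids, ages, labels)
    ]
    truth = {
        "labels": np.array(labels),
        "admix_a": sc.admix_fractions[0] if sc.contact_time is not None else None,
        "Ne": sc.Ne,
    }
    return SimulatedDataset(g, meta, truth)
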